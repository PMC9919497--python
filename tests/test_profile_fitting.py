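"""Sigmoid fitting, onset landmarks and comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from psmmet import (
    binned_boxplot_summary,
    compare_groups,
    fit_domain_profiles,
    fit_sigmoid,
    landmarks,
    logistic4,
)


class TestFitSigmoid:
    def test_zero_noise_parameter_recovery(self):
        x = np.linspace(0, 100, 50)
        y = logistic4(x, 1.0, 7.0, 50.0, 0.3)
        fit = fit_sigmoid(x, y)
        assert fit.a == pytest.approx(1.0, rel=1e-6)
        assert fit.b == pytest.approx(7.0, rel=1e-6)
        assert fit.x0 == pytest.approx(50.0, rel=1e-6)
        assert fit.k == pytest.approx(0.3, rel=1e-6)
        assert not fit.no_sigmoid

    def test_constant_response_collapses_flat(self):
        x = np.linspace(0, 100, 50)
        fit = fit_sigmoid(x, np.full(50, 2.0))
        assert fit.b - fit.a == pytest.approx(0.0, abs=1e-6)

    def test_decreasing_data_gets_negative_k(self):
        x = np.linspace(0, 100, 60)
        fit = fit_sigmoid(x, logistic4(x, 6.0, 1.0, 40.0, 0.2))
        assert fit.b >= fit.a  # canonical form
        assert fit.decreasing and fit.k < 0

    def test_preconditions(self):
        with pytest.raises(ValueError, match="observations"):
            fit_sigmoid([1, 2, 3], [1, 2, 3])
        x = np.linspace(40, 50, 20)  # span < 30 points
        with pytest.raises(ValueError, match="span"):
            fit_sigmoid(x, x)

    def test_noisy_recovery_within_3_points(self):
        """Lognormal-noise AR profiles (truth x0=70, k=0.25, n=600)
        recover the inflection within +/-3 percentage points in >=95% of
        seeded replicates (reduced replicate count; the full 200-seed
        check lives in the acceptance suite)."""
        hits = 0
        reps = 20
        for seed in range(reps):
            rng = np.random.default_rng(1000 + seed)
            x = rng.uniform(0, 100, 600)
            y = logistic4(x, 1.5, 6.0, 70.0, 0.25) * np.exp(
                rng.normal(0, 0.15, 600))
            fit = fit_sigmoid(x, y)
            hits += abs(fit.x0 - 70.0) <= 3.0
        assert hits >= 0.95 * reps


class TestLandmarks:
    def test_closed_form_height10(self):
        x = np.linspace(0, 100, 80)
        fit = fit_sigmoid(x, logistic4(x, 1.0, 7.0, 50.0, 0.2))
        lm = landmarks(fit)
        assert lm.x_inflection == pytest.approx(50.0, rel=1e-6)
        assert lm.x_height10 == pytest.approx(50.0 - np.log(9.0) / 0.2, rel=1e-6)
        assert lm.x_height10 == pytest.approx(39.014, abs=1e-3)

    def test_step_limit(self):
        # k -> infinity: the 10%-height point converges onto the inflection
        x = np.sort(np.concatenate([np.linspace(0, 100, 60),
                                    np.linspace(49, 51, 40)]))
        fit = fit_sigmoid(x, logistic4(x, 0.0, 1.0, 50.0, 100.0))
        lm = landmarks(fit)
        assert lm.x_height10 == pytest.approx(50.0, abs=0.1)

    def test_closed_form_agrees_with_root_finding(self):
        """x_height10 = x0 - ln(9)/k matches numeric root-finding on the
        fitted curve to 1e-8 across a parameter grid (incl. decreasing)."""
        for a, b in [(0.0, 1.0), (1.5, 6.0), (2.0, 30.0)]:
            for x0 in (30.0, 50.0, 70.0):
                for k in (0.05, 0.2, 0.5, -0.3):
                    target = a + 0.1 * (b - a)
                    root = optimize.brentq(
                        lambda x: logistic4(x, a, b, x0, k) - target,
                        x0 - 2000.0, x0 + 2000.0, xtol=1e-12)
                    assert x0 - np.log(9.0) / k == pytest.approx(root, abs=1e-8)

    def test_f_test_detects_a_real_sigmoid(self, rng):
        x = rng.uniform(0, 100, 300)
        y = logistic4(x, 1.5, 6.0, 55.0, 0.3) + rng.normal(0, 0.3, 300)
        lm = landmarks(fit_sigmoid(x, y))
        assert lm.p_value < 1e-30
        assert lm.f_statistic > 0

    def test_flat_core_data_yields_large_p(self):
        """Profiles of unpolarized core cells should not be declared
        sigmoidal with any confidence (directional check; the calibration
        of the F-test itself is examined in the acceptance suite)."""
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(20):
            x = rng.uniform(0, 100, 600)
            y = 2.2 * np.exp(rng.normal(0, 0.15, 600))
            fit = fit_sigmoid(x, y)
            ps.append(1.0 if fit.no_sigmoid else landmarks(fit).p_value)
        assert np.median(ps) > 0.05

    def test_landmarks_refuse_flat_fallback(self):
        x = np.linspace(0, 100, 50)
        fit = fit_sigmoid(x, np.full(50, 2.0))
        if fit.no_sigmoid or fit.k == 0:
            with pytest.raises(ValueError):
                landmarks(fit)


class TestCompareGroups:
    @staticmethod
    def _table(a, b, bin_id=0):
        return pd.DataFrame({
            "value": np.concatenate([a, b]),
            "domain": ["dorsal"] * len(a) + ["core"] * len(b),
            "bin": bin_id,
        })

    def test_null_groups_give_uniform_p_and_holm_monotone(self):
        rng = np.random.default_rng(7)
        t_ps = []
        for _ in range(200):
            a, b = rng.normal(0, 1, (2, 25))
            out = compare_groups(self._table(a, b),
                                 "between_domains_within_bin")
            t_ps.append(out.t_p[0])
            assert out.t_p_holm[0] >= out.t_p[0]
            assert out.wilcoxon_p_holm[0] >= out.wilcoxon_p[0]
        assert stats.kstest(t_ps, "uniform").pvalue > 0.01

    def test_separated_groups_reject_hard(self):
        rng = np.random.default_rng(8)
        a = rng.normal(2.0, 0.5, 30)
        b = rng.normal(6.0, 0.5, 30)
        out = compare_groups(self._table(a, b), "between_domains_within_bin")
        assert out.t_p[0] < 1e-10
        assert out.wilcoxon_p[0] < 1e-10

    def test_identical_groups_wilcoxon_p_is_one(self):
        a = np.arange(10.0)
        out = compare_groups(self._table(a, a.copy()),
                             "between_domains_within_bin")
        assert out.wilcoxon_p[0] == pytest.approx(1.0)

    def test_small_group_contrast_skipped(self, caplog):
        out = compare_groups(self._table(np.arange(10.0), np.array([1.0])),
                             "between_domains_within_bin")
        assert len(out) == 0

    def test_anterior_posterior_design(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame({
            "value": np.concatenate([rng.normal(2, 0.5, 20),
                                     rng.normal(5, 0.5, 20)]),
            "domain": ["anterior"] * 20 + ["posterior"] * 20,
            "somite_index": 1,
        })
        out = compare_groups(table, "anterior_vs_posterior")
        assert out.contrast[0] == "s1:anterior_vs_posterior"
        assert out.t_p[0] < 1e-6


class TestBinnedBoxplot:
    def test_single_bin_basic_stats(self):
        table = pd.DataFrame({"domain": "dorsal",
                              "position_percent": [10.0] * 5,
                              "aspect_ratio": [1.0, 2.0, 3.0, 4.0, 5.0]})
        out = binned_boxplot_summary(table, [10.0], 5.0)
        assert out.loc[0, "median"] == 3.0
        assert out.loc[0, "q3"] - out.loc[0, "q1"] == 2.0
        assert out.loc[0, "n"] == 5

    def test_value_on_shared_edge_goes_to_lower_bin(self):
        table = pd.DataFrame({"domain": "dorsal",
                              "position_percent": [20.0],
                              "aspect_ratio": [2.0]})
        out = binned_boxplot_summary(table, [15.0, 25.0], 5.0)
        assert list(out.bin_center) == [15.0]

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            binned_boxplot_summary(
                pd.DataFrame({"domain": [], "position_percent": [],
                              "aspect_ratio": []}),
                [10.0, 15.0], 5.0)

    def test_synthetic_medians_rise_for_surface_not_core(self):
        from psmmet.shape_metrics import measure_cells
        from psmmet.synthetic_data import SyntheticTruth, generate_outline_field

        field = generate_outline_field(
            SyntheticTruth(seed=31, cells_per_domain=300), "transverse")
        table = measure_cells(field.cells).merge(field.truth_table,
                                                 on="cell_id")
        table["domain"] = table["domain_true"]
        table["position_percent"] = table["position_percent"]
        out = binned_boxplot_summary(table, [10, 40, 65, 90], 10.0)
        for domain in ("dorsal", "medial", "ventral", "lateral"):
            med = out[out.domain == domain].sort_values("bin_center")["median"]
            assert med.iloc[-1] > med.iloc[0] + 1.0
        core = out[out.domain == "core"].sort_values("bin_center")["median"]
        assert abs(core.iloc[-1] - core.iloc[0]) < 0.5


def test_fit_domain_profiles_table(rng):
    x = rng.uniform(0, 100, 400)
    table = pd.DataFrame({
        "domain": ["dorsal"] * 400,
        "position_percent": x,
        "aspect_ratio": logistic4(x, 1.5, 6.0, 40.0, 0.3)
        * np.exp(rng.normal(0, 0.1, 400)),
    })
    out = fit_domain_profiles(table)
    assert set(out.columns) >= {"domain", "a", "b", "x0", "k",
                                "x_height10", "p_value", "n"}
    assert out.loc[0, "x0"] == pytest.approx(40.0, abs=2.0)
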