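"""Sigmoid profiles of a response against axis position, onset landmarks
and group-comparison statistics.

The response (aspect ratio, or an apical-basal intensity difference) is
modelled per domain as a 4-parameter logistic of position x (% PSM):

    y(x) = a + (b - a) / (1 + exp(-k (x - x0)))

with lower asymptote ``a``, upper asymptote ``b``, inflection ``x0`` and
slope ``k``.  Two onset landmarks are read off the fit: the inflection
point ``x0`` and the position where the curve has risen by 10% of its
vertical height, which under this parameterization has the closed form
``x0 - ln(9)/k``.  A nested F-test against the constant-mean model gives
one p-value per domain; note that because ``x0`` and ``k`` are
unidentified under the flat null, the F(3, n-4) reference distribution is
an approximation (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

# fixed multi-start grid: deterministic fits
_X0_STARTS = (25.0, 50.0, 75.0)
_K_STARTS = (0.05, 0.2, 0.5)


def logistic4(x, a, b, x0, k):
    """4-parameter logistic, overflow-safe."""
    z = np.clip(-k * (np.asarray(x, dtype=float) - x0), -500.0, 500.0)
    return a + (b - a) / (1.0 + np.exp(z))


def _logistic4_jac(x, a, b, x0, k):
    """Analytic Jacobian of :func:`logistic4` w.r.t. (a, b, x0, k)."""
    x = np.asarray(x, dtype=float)
    z = np.clip(-k * (x - x0), -500.0, 500.0)
    s = 1.0 / (1.0 + np.exp(z))
    sp = s * (1.0 - s)
    return np.column_stack(
        [1.0 - s, s, -(b - a) * k * sp, (b - a) * (x - x0) * sp]
    )


@dataclass(frozen=True)
class SigmoidFit:
    """A fitted 4-parameter logistic profile.

    ``b >= a`` always (fits are canonicalized by swapping asymptotes and
    negating ``k``); a decreasing profile therefore has ``k < 0``.
    ``no_sigmoid`` marks the flat fallback used when no start converges.
    """

    a: float
    b: float
    x0: float
    k: float
    rss: float
    rss_flat: float
    n: int
    no_sigmoid: bool = False

    @property
    def decreasing(self) -> bool:
        return self.k < 0

    def predict(self, x):
        if self.no_sigmoid:
            return np.full_like(np.asarray(x, dtype=float), self.a)
        return logistic4(x, self.a, self.b, self.x0, self.k)


@dataclass(frozen=True)
class OnsetLandmarks:
    """Onset positions of a fitted profile plus its flat-model F-test."""

    x_inflection: float
    x_height10: float
    f_statistic: float
    p_value: float
    decreasing: bool = False


def fit_sigmoid(
    positions: Sequence[float],
    response: Sequence[float],
    *,
    min_n: int = 8,
    min_span: float = 30.0,
) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit of response against position.

    Initialization is a fixed 3x3 grid over (x0, k) with asymptotes seeded
    from the 5th/95th response percentiles; the best-RSS converged start
    wins, so the fit is deterministic.  If no start converges the flat
    model (a = b = mean) is returned flagged ``no_sigmoid``.

    Requires ``n >= min_n`` observations spanning at least ``min_span``
    percentage points of position.
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("positions and response must be matching 1-D arrays")
    n = len(x)
    if n < min_n:
        raise ValueError(f"need >= {min_n} observations, got {n}")
    span = x.max() - x.min()
    if span < min_span:
        raise ValueError(
            f"positions span {span:.1f} points; >= {min_span} required"
        )

    rss_flat = float(((y - y.mean()) ** 2).sum())
    a0, b0 = np.percentile(y, [5.0, 95.0])
    if b0 - a0 < 1e-12:
        a0, b0 = float(y.mean()), float(y.mean()) + 1e-6

    best: tuple[float, np.ndarray] | None = None
    for x0s in _X0_STARTS:
        for ks in _K_STARTS:
            try:
                popt, _ = optimize.curve_fit(
                    logistic4,
                    x,
                    y,
                    p0=[a0, b0, x0s, ks],
                    jac=_logistic4_jac,
                    maxfev=2000,
                )
            except (RuntimeError, optimize.OptimizeWarning):
                continue
            rss = float(((y - logistic4(x, *popt)) ** 2).sum())
            if np.isfinite(rss) and (best is None or rss < best[0]):
                best = (rss, popt)
    if best is None:
        logger.warning("sigmoid fit did not converge from any start; flat fallback")
        m = float(y.mean())
        return SigmoidFit(
            a=m, b=m, x0=float(np.median(x)), k=0.0,
            rss=rss_flat, rss_flat=rss_flat, n=n, no_sigmoid=True,
        )
    rss, (a, b, x0, k) = best
    if b < a:  # canonical form: logistic(a,b,x0,k) == logistic(b,a,x0,-k)
        a, b, k = b, a, -k
    return SigmoidFit(
        a=float(a), b=float(b), x0=float(x0), k=float(k),
        rss=rss, rss_flat=rss_flat, n=n,
    )


def landmarks(fit: SigmoidFit) -> OnsetLandmarks:
    """Onset landmarks and flat-model F-test for a sigmoid fit.

    ``x_height10`` solves ``y(x) = a + 0.1 (b - a)`` in closed form:
    ``x0 - ln(9)/k`` (for decreasing fits, ``k < 0``, the landmark lies on
    the decreasing branch rostral of the inflection and the result is
    flagged).  The F statistic compares the 4-parameter logistic against
    the constant-mean model: ``F = ((RSS_flat - RSS_sig)/3) /
    (RSS_sig/(n-4))`` with p from F(3, n-4).
    """
    if fit.no_sigmoid:
        raise ValueError("landmarks are undefined for a no_sigmoid flat fit")
    if fit.k == 0:
        raise ValueError("landmarks are undefined for k = 0")
    x10 = fit.x0 - np.log(9.0) / fit.k
    dfd = fit.n - 4
    if dfd <= 0:
        raise ValueError("need n > 4 observations for the F-test")
    if fit.rss <= 0.0:
        # perfect sigmoid fit: infinitely unlikely under the flat model
        # unless the data were flat to begin with
        f = np.inf if fit.rss_flat > 0.0 else 0.0
    else:
        f = max(0.0, (fit.rss_flat - fit.rss) / 3.0 / (fit.rss / dfd))
    p = float(stats.f.sf(f, 3, dfd))
    return OnsetLandmarks(
        x_inflection=fit.x0,
        x_height10=float(x10),
        f_statistic=float(f),
        p_value=p,
        decreasing=fit.decreasing,
    )


def fit_domain_profiles(
    table: pd.DataFrame,
    *,
    response: str = "aspect_ratio",
    position: str = "position_percent",
    log_response: bool = False,
    flat_domains: Sequence[str] = ("core",),
) -> pd.DataFrame:
    """Per-domain sigmoid fits + landmarks for a per-cell record table.

    Returns one row per domain with the fit parameters (a, b, x0, k), the
    two onset landmarks, the F-test and the observation count.  Domains
    listed in ``flat_domains`` are still fitted (their F-test p reports
    whether the profile departs from flat, which for core cells it should
    not).
    """
    rows = []
    for domain, grp in table.groupby("domain", sort=False):
        y = grp[response].to_numpy(dtype=float)
        if log_response:
            y = np.log(y)
        fit = fit_sigmoid(grp[position].to_numpy(dtype=float), y)
        row = {
            "domain": domain, "n": fit.n,
            "a": fit.a, "b": fit.b, "x0": fit.x0, "k": fit.k,
            "rss": fit.rss, "no_sigmoid": fit.no_sigmoid,
        }
        if not fit.no_sigmoid and fit.k != 0:
            lm = landmarks(fit)
            row.update(
                x_inflection=lm.x_inflection,
                x_height10=lm.x_height10,
                f_statistic=lm.f_statistic,
                p_value=lm.p_value,
                decreasing=lm.decreasing,
            )
        else:
            row.update(
                x_inflection=np.nan, x_height10=np.nan,
                f_statistic=0.0, p_value=1.0, decreasing=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

_DESIGNS = (
    "between_domains_within_bin",
    "same_domain_across_bins",
    "left_vs_right",
    "anterior_vs_posterior",
)


def _contrasts(table: pd.DataFrame, design: str):
    """Yield (label, values_a, values_b) per contrast of the design."""
    if design == "between_domains_within_bin":
        for bin_id, grp in table.groupby("bin", sort=True):
            domains = [d for d, _ in grp.groupby("domain", sort=False)]
            for d1, d2 in combinations(domains, 2):
                yield (
                    f"bin={bin_id}:{d1}_vs_{d2}",
                    grp.loc[grp.domain == d1, "value"],
                    grp.loc[grp.domain == d2, "value"],
                )
    elif design == "same_domain_across_bins":
        for domain, grp in table.groupby("domain", sort=False):
            bins = sorted(grp["bin"].unique())
            for b1, b2 in zip(bins[:-1], bins[1:]):
                yield (
                    f"{domain}:bin{b1}_vs_bin{b2}",
                    grp.loc[grp.bin == b1, "value"],
                    grp.loc[grp.bin == b2, "value"],
                )
    elif design == "left_vs_right":
        for bin_id, grp in table.groupby("bin", sort=True):
            yield (
                f"bin={bin_id}:left_vs_right",
                grp.loc[grp.side == "left", "value"],
                grp.loc[grp.side == "right", "value"],
            )
    elif design == "anterior_vs_posterior":
        for somite, grp in table.groupby("somite_index", sort=True):
            yield (
                f"s{somite}:anterior_vs_posterior",
                grp.loc[grp.domain == "anterior", "value"],
                grp.loc[grp.domain == "posterior", "value"],
            )
    else:
        raise ValueError(f"unknown design {design!r}; one of {_DESIGNS}")


def compare_groups(table: pd.DataFrame, design: str) -> pd.DataFrame:
    """Welch t and Wilcoxon rank-sum tests for each contrast of a design.

    ``table`` needs columns ``value`` plus whatever the design groups by
    (``domain``, ``bin``, ``side``, ``somite_index``).  Output rows carry
    both group sizes, both statistics, raw p-values and Holm-adjusted
    p-values (per test family).  Contrasts with an empty or undersized
    group (n < 3) are skipped with a log entry.
    """
    from statsmodels.stats.multitest import multipletests

    rows = []
    for label, va, vb in _contrasts(table, design):
        a = np.asarray(va, dtype=float)
        b = np.asarray(vb, dtype=float)
        if len(a) < 3 or len(b) < 3:
            logger.warning("skipping contrast %s: group too small", label)
            continue
        t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
        w_stat, w_p = stats.ranksums(a, b)
        rows.append(
            {
                "contrast": label, "n_a": len(a), "n_b": len(b),
                "t_statistic": float(t_stat), "t_p": float(t_p),
                "wilcoxon_statistic": float(w_stat), "wilcoxon_p": float(w_p),
            }
        )
    result = pd.DataFrame(rows)
    if len(result):
        result["t_p_holm"] = multipletests(result["t_p"], method="holm")[1]
        result["wilcoxon_p_holm"] = multipletests(
            result["wilcoxon_p"], method="holm"
        )[1]
    return result


def binned_boxplot_summary(
    table: pd.DataFrame,
    bin_centers: Sequence[float],
    bin_halfwidth: float,
    *,
    response: str = "aspect_ratio",
    position: str = "position_percent",
) -> pd.DataFrame:
    """Box-plot statistics per (domain, position bin).

    Bins are ``(c - h, c + h]``: a value exactly on a shared edge belongs
    to the lower bin.  Whiskers follow the 1.5*IQR rule (most extreme
    observation inside the fence); points beyond them are counted as
    outliers.
    """
    centers = np.asarray(bin_centers, dtype=float)
    if np.any(np.diff(np.sort(centers)) < 2 * bin_halfwidth):
        raise ValueError("bins overlap")
    rows = []
    for domain, grp in table.groupby("domain", sort=False):
        x = grp[position].to_numpy(dtype=float)
        y = grp[response].to_numpy(dtype=float)
        for c in centers:
            inside = (x > c - bin_halfwidth) & (x <= c + bin_halfwidth)
            v = y[inside]
            if v.size == 0:
                continue
            q1, med, q3 = np.percentile(v, [25.0, 50.0, 75.0])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inliers = v[(v >= lo_fence) & (v <= hi_fence)]
            rows.append(
                {
                    "domain": domain, "bin_center": c, "n": int(v.size),
                    "median": med, "q1": q1, "q3": q3,
                    "whisker_low": float(inliers.min()),
                    "whisker_high": float(inliers.max()),
                    "n_outliers": int(v.size - inliers.size),
                }
            )
    return pd.DataFrame(rows)
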