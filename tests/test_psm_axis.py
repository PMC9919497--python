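"""Midline straightening and tissue-domain assignment."""

import numpy as np
import pytest

from psmmet import AxisModel, DomainGeometry, assign_domains, straighten
from psmmet.synthetic_data import SyntheticTruth, generate_outline_field

from conftest import make_outline


def _cell_at(x, y, cell_id="c", r=3.0, **kw):
    t = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    return make_outline(
        np.column_stack([x + r * np.cos(t), y + r * np.sin(t)]),
        cell_id=cell_id, **kw)


class TestStraighten:
    def test_straight_midline_position_and_offset(self):
        axis = AxisModel([[0.0, 0.0], [1000.0, 0.0]])
        cell = _cell_at(440.0, -25.0)  # above the midline (image y down)
        out = straighten([cell], axis)
        assert out.position_percent[0] == pytest.approx(44.0)
        assert out.transverse_offset_px[0] > 0

    def test_posterior_tip_is_zero_even_on_bent_midline(self):
        axis = AxisModel([[0, 0], [500, 0], [500, 500]])  # 90-degree bend
        out = straighten([_cell_at(0.0, 0.0)], axis)
        assert out.position_percent[0] == pytest.approx(0.0, abs=1e-9)

    def test_dense_projection_oracle_on_circular_arc(self, rng):
        """Projection positions match brute-force nearest-of-10000
        densely resampled midline points within 0.2%."""
        theta = np.linspace(0.0, np.pi / 2, 60)
        radius = 500.0
        midline = radius * np.column_stack([np.sin(theta), 1 - np.cos(theta)])
        axis = AxisModel(midline)

        # dense oracle on the same polyline
        seg = np.diff(midline, axis=0)
        seg_len = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0], np.cumsum(seg_len)])
        s_dense = np.linspace(0.0, cum[-1], 10_000)
        dense = np.column_stack([
            np.interp(s_dense, cum, midline[:, 0]),
            np.interp(s_dense, cum, midline[:, 1]),
        ])

        t = rng.uniform(0.05, 0.95, 200) * np.pi / 2
        offset = rng.uniform(-40.0, 40.0, 200)
        pts = np.column_stack([
            radius * np.sin(t) + offset * np.sin(t + np.pi / 2),
            radius * (1 - np.cos(t)) - offset * np.cos(t + np.pi / 2),
        ])
        for p in pts:
            arc, _ = axis.project(p)
            pos = 100.0 * arc / axis.total_psm_length_px
            i = np.argmin(((dense - p) ** 2).sum(axis=1))
            oracle = 100.0 * s_dense[i] / cum[-1]
            assert pos == pytest.approx(oracle, abs=0.2)

    def test_position_invariant_under_rigid_motion(self, rng):
        midline = np.column_stack([np.linspace(0, 800, 30),
                                   50 * np.sin(np.linspace(0, 3, 30))])
        pts = np.column_stack([rng.uniform(50, 750, 20),
                               rng.uniform(-30, 80, 20)])
        base = [100 * AxisModel(midline).project(p)[0]
                / AxisModel(midline).total_psm_length_px for p in pts]
        ang = 0.83
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shift = np.array([123.4, -567.8])
        axis2 = AxisModel(midline @ rot.T + shift)
        moved = [100 * axis2.project(p @ rot.T + shift)[0]
                 / axis2.total_psm_length_px for p in pts]
        np.testing.assert_allclose(moved, base, atol=1e-9)

    def test_somite_cells_report_position_beyond_100(self):
        axis = AxisModel([[0.0, 0.0], [1000.0, 0.0]])
        cell = _cell_at(1050.0, 0.0, structure="somite", somite_index=2)
        out = straighten([cell], axis)
        assert out.position_percent[0] == pytest.approx(120.0)

    def test_straighten_is_identity_on_straight_synthetic_psm(self):
        field = generate_outline_field(
            SyntheticTruth(seed=21, cells_per_domain=40), "sagittal")
        pos = straighten(field.cells, field.axis).merge(
            field.truth_table, on="cell_id")
        np.testing.assert_allclose(
            pos.position_percent_x, pos.position_percent_y, atol=1e-9)


class TestAssignDomains:
    def test_synthetic_transverse_labels_recovered(self):
        field = generate_outline_field(
            SyntheticTruth(seed=22, cells_per_domain=60), "transverse")
        cells = assign_domains(field.cells, field.geometry, "transverse")
        truth = field.truth_table.set_index("cell_id").domain_true
        agree = np.mean([c.domain == truth[c.cell_id] for c in cells])
        assert agree >= 0.95

    def test_partition_property(self):
        field = generate_outline_field(
            SyntheticTruth(seed=23, cells_per_domain=30), "transverse")
        cells = assign_domains(field.cells, field.geometry, "transverse")
        counts = {}
        for c in cells:
            counts[c.domain] = counts.get(c.domain, 0) + 1
        assert sum(counts.values()) == len(cells)
        assert "unassigned" not in counts

    def test_central_cell_is_core(self):
        geom = DomainGeometry(
            outer_boundary=[[0, 0], [200, 0], [200, 200], [0, 200]],
            surface_band_depth_px=12.0)
        (cell,) = assign_domains([_cell_at(100, 100)], geom, "transverse")
        assert cell.domain == "core"

    def test_sagittal_top_edge_cell_is_dorsal(self):
        geom = DomainGeometry(
            outer_boundary=[[0, 0], [400, 0], [400, 150], [0, 150]],
            surface_band_depth_px=12.0)
        top, bottom = _cell_at(200, 6, "t"), _cell_at(200, 144, "b")
        assign_domains([top, bottom], geom, "sagittal")
        assert top.domain == "dorsal"
        assert bottom.domain == "ventral"

    def test_cell_outside_boundary_is_an_error(self):
        geom = DomainGeometry(
            outer_boundary=[[0, 0], [100, 0], [100, 100], [0, 100]],
            surface_band_depth_px=10.0)
        with pytest.raises(ValueError, match="outside"):
            assign_domains([_cell_at(500, 500)], geom, "transverse")

    def test_somite_sagittal_uses_four_sectors(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        geom = DomainGeometry(
            outer_boundary=np.column_stack(
                [100 + 80 * np.cos(t), 100 + 80 * np.sin(t)]),
            surface_band_depth_px=12.0)
        kw = dict(structure="somite", somite_index=1)
        cells = [
            _cell_at(100, 26, "d", **kw),    # top -> dorsal
            _cell_at(100, 174, "v", **kw),   # bottom -> ventral
            _cell_at(174, 100, "a", **kw),   # rostral (+x) -> anterior
            _cell_at(26, 100, "p", **kw),    # caudal -> posterior
        ]
        assign_domains(cells, geom, "sagittal")
        assert [c.domain for c in cells] == [
            "dorsal", "ventral", "anterior", "posterior"]
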