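"""QSM geometry: metrics, branch-unit extraction, crown classification."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

import qsmflora as qf
from qsmflora.errors import MetricError
from qsmflora.qsm import (
    CYLINDER_COLUMNS,
    QSM,
    alpha_shape_volume,
    classify_crown_position,
    derive_tree_metrics,
    extract_branch_units,
    layer_from_hull,
    slice_hull,
    stratum_of,
)


def _cyl(cid, parent, start, axis, length, radius, order):
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    return {
        "cyl_id": cid,
        "parent_id": parent,
        "start_x_m": start[0],
        "start_y_m": start[1],
        "start_z_m": start[2],
        "axis_x": a[0],
        "axis_y": a[1],
        "axis_z": a[2],
        "length_m": length,
        "radius_m": radius,
        "branch_order": order,
    }


def _qsm(rows, tree="T1"):
    return QSM(tree, pd.DataFrame(rows, columns=CYLINDER_COLUMNS))


class TestMetrics:
    def test_single_trunk_dbh_and_height(self):
        q = _qsm([_cyl(1, None, (0, 0, 0), (0, 0, 1), 10.0, 0.10, 0)])
        m = derive_tree_metrics(q)
        assert m.dbh_cm == pytest.approx(20.0)
        assert m.height_m == pytest.approx(10.0)

    def test_short_tree_raises(self):
        q = _qsm([_cyl(1, None, (0, 0, 0), (0, 0, 1), 1.0, 0.05, 0)])
        with pytest.raises(MetricError):
            derive_tree_metrics(q)

    def test_square_crown_projection_and_diameter(self):
        rows = [_cyl(1, None, (0, 0, 0), (0, 0, 1), 6.0, 0.08, 0)]
        corners = [(2, 2), (2, -2), (-2, 2), (-2, -2)]
        for i, (x, y) in enumerate(corners, start=2):
            d = np.array([x, y, 1.0])
            rows.append(_cyl(i, 1, (0, 0, 5.0), d, float(np.linalg.norm(d)), 0.02, 1))
        m_max = derive_tree_metrics(_qsm(rows), diameter_mode="max")
        assert m_max.crown_projection_area_m2 == pytest.approx(16.0, rel=1e-6)
        assert m_max.crown_diameter_m == pytest.approx(4 * np.sqrt(2), rel=1e-6)
        m_mean = derive_tree_metrics(_qsm(rows), diameter_mode="mean8")
        assert 4.0 <= m_mean.crown_diameter_m <= 4 * np.sqrt(2)

    def test_alpha_shape_approaches_convex_hull_on_dense_cuboid(self):
        xs, ys, zs = np.meshgrid(
            np.linspace(0, 4, 5), np.linspace(0, 4, 5), np.linspace(0, 5, 6)
        )
        pts = np.column_stack([xs.ravel(), ys.ravel(), zs.ravel()])
        hull_vol = alpha_shape_volume(pts, alpha=None)
        assert hull_vol == pytest.approx(80.0, rel=1e-9)
        assert alpha_shape_volume(pts, alpha=1.5) == pytest.approx(80.0, rel=0.10)

    def test_metrics_invariant_under_translation_and_z_rotation(self, demo_qsm):
        m0 = derive_tree_metrics(demo_qsm)
        df = demo_qsm.df.copy()
        th = np.deg2rad(33.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        for prefix in (("start_x_m", "start_y_m"), ("axis_x", "axis_y")):
            xy = df[list(prefix)].to_numpy() @ R.T
            df[prefix[0]], df[prefix[1]] = xy[:, 0], xy[:, 1]
        df["start_x_m"] += 12.0
        df["start_y_m"] -= 7.0
        df["start_z_m"] += 3.0
        m1 = derive_tree_metrics(QSM("T1", df))
        assert m1.dbh_cm == pytest.approx(m0.dbh_cm, rel=1e-9)
        assert m1.height_m == pytest.approx(m0.height_m, rel=1e-9)
        assert m1.crown_projection_area_m2 == pytest.approx(
            m0.crown_projection_area_m2, rel=1e-6
        )
        assert m1.crown_volume_m3 == pytest.approx(m0.crown_volume_m3, rel=1e-6)
        assert m1.crown_diameter_m == pytest.approx(m0.crown_diameter_m, rel=0.05)


class TestBranchUnits:
    def test_threshold_entry_hand_trace(self):
        rows = [
            _cyl(1, None, (0, 0, 0), (0, 0, 1), 3.0, 0.050, 0),  # 100 mm trunk
            _cyl(2, 1, (0, 0, 3), (1, 0, 1), 1.0, 0.020, 1),  # 40 mm
            _cyl(3, 2, (0.7, 0, 3.7), (1, 0, 1), 1.0, 0.0125, 1),  # 25 mm
            _cyl(4, 3, (1.4, 0, 4.4), (1, 0, 1), 1.0, 0.005, 1),  # 10 mm
        ]
        units = extract_branch_units(_qsm(rows))
        assert len(units) == 1
        assert units[0].root_cyl_id == 3
        assert sorted(units[0].member_cyl_ids) == [3, 4]
        assert units[0].root_diameter_mm == pytest.approx(25.0)

    def test_whole_thin_tree_is_one_unit(self):
        rows = [
            _cyl(1, None, (0, 0, 0), (0, 0, 1), 2.0, 0.010, 0),
            _cyl(2, 1, (0, 0, 2), (0, 0, 1), 2.0, 0.005, 0),
        ]
        units = extract_branch_units(_qsm(rows))
        assert len(units) == 1
        assert sorted(units[0].member_cyl_ids) == [1, 2]

    def test_no_eligible_cylinder_gives_empty(self):
        rows = [_cyl(1, None, (0, 0, 0), (0, 0, 1), 5.0, 0.10, 0)]
        assert extract_branch_units(_qsm(rows)) == []

    def test_units_disjoint_and_cover_all_thin_cylinders(self, demo_qsm):
        units = extract_branch_units(demo_qsm)
        seen = []
        for u in units:
            seen.extend(u.member_cyl_ids)
            assert u.root_diameter_mm <= 30.0
        assert len(seen) == len(set(seen))  # disjoint
        thin = set(
            int(c)
            for c, d in zip(demo_qsm.df["cyl_id"], demo_qsm.diameters_mm())
            if d <= 30.0
        )
        assert thin == set(seen)  # monotone taper: units cover every thin cylinder
        # idempotence
        units2 = extract_branch_units(demo_qsm)
        assert [u.root_cyl_id for u in units2] == [u.root_cyl_id for u in units]


class TestCrownPosition:
    def test_stratum_thirds_partition(self):
        # crown spans z = 2..11 above a base at z=0 (crown length 9)
        args = (0.0, 2.0, 11.0)
        assert stratum_of(1.0, *args) == "bot"  # below crown base
        assert stratum_of(2.0, *args) == "bot"
        assert stratum_of(4.999, *args) == "bot"
        assert stratum_of(5.0, *args) == "mid"  # boundary goes upward
        assert stratum_of(8.0, *args) == "top"
        assert stratum_of(11.0, *args) == "top"

    def test_layer_from_square_hulls(self):
        big = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
        assert layer_from_hull(big, (5, 5)) == "in"  # centroid is 5 m from edges
        assert layer_from_hull(big, (0.3, 5)) == "out"  # 0.3 m from the hull edge
        narrow = Polygon([(0, 0), (3, 0), (3, 3), (0, 3)])
        assert layer_from_hull(narrow, (1.5, 1.5)) == "out"  # erosion empties
        assert layer_from_hull(None, (0, 0)) == "out"

    def test_classification_of_constructed_unit(self):
        # tall trunk with a wide flat crown disc near the top
        rows = [_cyl(1, None, (0, 0, 0), (0, 0, 1), 12.0, 0.10, 0)]
        cid = 2
        for ang in np.linspace(0, 2 * np.pi, 12, endpoint=False):
            d = np.array([np.cos(ang), np.sin(ang), 0.02])
            rows.append(_cyl(cid, 1, (0, 0, 10.0), d, 6.0, 0.01, 1))
            cid += 1
        q = _qsm(rows)
        units = extract_branch_units(q)
        pos = [classify_crown_position(u, q) for u in units]
        # bbox centers sit near z=10 of a 10..12 m crown (base 10 m): stratum top... crown
        # base is 10 m, top 12 m; centers ~10.06 m are in the bottom third
        assert {p.stratum for p in pos} <= {"bot", "mid", "top"}
        # the disc is 12 m wide; interior centers within 2 m of the rim are out,
        # the bounding-box center of each radial branch lies 3 m from the rim
        assert any(p.layer == "in" for p in pos)

    def test_degenerate_slice_falls_back_to_out(self):
        pts = np.array([[0.0, 0.0, 5.0], [1.0, 0.0, 5.0]])  # two points only
        assert slice_hull(pts, 0.0, 10) is None
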