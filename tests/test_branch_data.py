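"""Branch data model: cumulation, diameter-class segmentation, densities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qsmflora as qf
from qsmflora.branch_data import (
    BranchRecord,
    DiameterMeasurement,
    flowers_per_cm_summary,
    frame_to_records,
    measurements_to_frame,
    records_to_frame,
    segment_diameter_classes,
)
from qsmflora.errors import HierarchyError, InsufficientDataError, OrderingError
from qsmflora.synthetic import SyntheticForestSpec


def _rec(bid, parent=None, count=0, D=10.0, tree="T1", **kw):
    return BranchRecord(
        branch_id=bid,
        tree_id=tree,
        parent_branch_id=parent,
        cutoff_diameter_mm=D,
        crown_stratum=kw.get("stratum", "bot"),
        crown_layer=kw.get("layer", "out"),
        own_flower_count=count,
        measurements=kw.get("measurements", []),
        flower_positions_cm=kw.get("flower_positions_cm"),
        detailed=kw.get("detailed", False),
    )


class TestCumulation:
    def test_leaf_and_chain_totals(self):
        assert qf.cumulate_flower_counts([_rec("a", count=7)]) == {"a": 7}
        chain = [_rec("a", count=1), _rec("b", "a", 2), _rec("c", "b", 3)]
        assert qf.cumulate_flower_counts(chain) == {"a": 6, "b": 5, "c": 3}
        assert qf.cumulate_flower_counts([]) == {}

    def test_totals_are_order_independent_and_monotone(self):
        rng = np.random.default_rng(0)
        recs = [_rec("r", count=int(rng.integers(0, 5)))]
        for i in range(30):
            parent = recs[int(rng.integers(0, len(recs)))].branch_id
            recs.append(_rec(f"b{i}", parent, int(rng.integers(0, 9))))
        totals = qf.cumulate_flower_counts(recs)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        assert qf.cumulate_flower_counts(shuffled) == totals
        own = {r.branch_id: r.own_flower_count for r in recs}
        for r in recs:
            assert totals[r.branch_id] >= own[r.branch_id]
            if r.parent_branch_id is not None:
                assert totals[r.parent_branch_id] >= totals[r.branch_id]

    def test_cycle_and_dangling_parent_raise(self):
        a = _rec("a", parent="b")
        b = _rec("b", parent="a")
        with pytest.raises(HierarchyError):
            qf.cumulate_flower_counts([a, b])
        with pytest.raises(HierarchyError):
            qf.cumulate_flower_counts([_rec("x", parent="ghost")])


class TestDiameterClasses:
    def test_linear_taper_crossing_two_boundaries(self):
        # d(x) = 12 - 0.1 x over 100 cm crosses 10 mm at x=20 and 5 mm at x=70
        meas = [DiameterMeasurement(0, 12.0), DiameterMeasurement(100, 2.0)]
        out = segment_diameter_classes(meas)
        assert out[(10.0, 15.0)] == pytest.approx(20.0)
        assert out[(5.0, 10.0)] == pytest.approx(50.0)
        assert out[(0.0, 5.0)] == pytest.approx(30.0)

    def test_constant_diameter_single_class(self):
        meas = [DiameterMeasurement(0, 8.0), DiameterMeasurement(40, 8.0)]
        out = segment_diameter_classes(meas)
        assert out == {(5.0, 10.0): 40.0}

    def test_boundary_diameter_goes_to_upper_class(self):
        meas = [DiameterMeasurement(0, 10.0), DiameterMeasurement(25, 10.0)]
        assert segment_diameter_classes(meas) == {(10.0, 15.0): 25.0}

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            segment_diameter_classes([DiameterMeasurement(0, 5.0)])
        with pytest.raises(OrderingError):
            BranchRecord(
                branch_id="x",
                tree_id="T",
                cutoff_diameter_mm=5,
                crown_stratum="bot",
                crown_layer="out",
                own_flower_count=0,
                measurements=[DiameterMeasurement(10, 5.0), DiameterMeasurement(10, 4.0)],
            )

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.1, max_value=500),
                st.floats(min_value=0.5, max_value=60),
            ),
            min_size=2,
            max_size=8,
            unique_by=lambda t: round(t[0], 3),
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_class_lengths_conserve_total_shoot_length(self, raw):
        raw = sorted(raw)
        meas = [DiameterMeasurement(p, d) for p, d in raw]
        out = segment_diameter_classes(meas)
        assert all(v >= -1e-12 for v in out.values())
        total = meas[-1].position_cm - meas[0].position_cm
        assert math.isclose(sum(out.values()), total, abs_tol=1e-9)


class TestDensitySummary:
    def test_simple_density(self):
        meas = [DiameterMeasurement(0, 4.0), DiameterMeasurement(15, 3.0)]
        rec = _rec("a", count=30, detailed=True, measurements=meas)
        tab = flowers_per_cm_summary([rec])
        row = tab.loc[tab["class_lo_mm"] == 0.0].iloc[0]
        assert row["flowers_per_cm"] == pytest.approx(2.0)

    def test_empty_input_gives_empty_table(self):
        assert len(flowers_per_cm_summary([])) == 0

    def test_generator_attachment_rule_zero_density_above_20mm(self, truth_no_re):
        spec = SyntheticForestSpec(n_trees=6, cutoffs_per_tree=8, hurdle=truth_no_re)
        records, _, _ = qf.generate_branch_dataset(spec, seed=9)
        tab = flowers_per_cm_summary(records)
        thick = tab.loc[tab["class_lo_mm"] >= 20.0]
        assert len(thick) > 0
        assert (thick["flowers_per_cm"] == 0.0).all()


class TestRoundTrip:
    def test_csv_frames_round_trip_losslessly(self, small_dataset):
        records, _ = small_dataset
        df = records_to_frame(records)
        mdf = measurements_to_frame(records)
        back = frame_to_records(df, mdf)
        assert len(back) == len(records)
        orig = {r.branch_id: r for r in records}
        for r in back:
            o = orig[r.branch_id]
            assert r.own_flower_count == o.own_flower_count
            assert r.parent_branch_id == o.parent_branch_id
            assert r.cutoff_diameter_mm == pytest.approx(o.cutoff_diameter_mm)
            assert len(r.measurements) == len(o.measurements)
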