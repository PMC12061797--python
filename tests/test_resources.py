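"""Resource budgets: pollen/nectar arithmetic and uncertainty propagation."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from qsmflora import constants as C
from qsmflora.errors import InsufficientDataError
from qsmflora.resources import (
    BeeSpecies,
    NectarParams,
    PollenParams,
    bootstrap_mc_ci,
    default_species,
    larvae_supported,
    pollen_volume_per_flower,
    tree_resources,
)


class TestPollenArithmetic:
    def test_grain_and_flower_volume(self):
        d_mm = 32.63 / 1000.0
        grain = math.pi / 6.0 * d_mm**3
        assert grain == pytest.approx(1.819e-5, rel=1e-3)
        per_flower = pollen_volume_per_flower()
        assert per_flower == pytest.approx(grain * 16059, rel=1e-12)
        assert round(per_flower, 2) == 0.29

    def test_cubic_scaling_with_diameter(self):
        base = pollen_volume_per_flower()
        doubled = pollen_volume_per_flower(
            PollenParams(grain_diameter_um=2 * 32.63)
        )
        assert doubled == pytest.approx(8 * base, rel=1e-12)


class TestBudgets:
    def test_budget_at_large_tree_flower_count(self):
        b = tree_resources(195_535)
        assert round(b.pollen_cm3) == 57
        assert round(b.sugar_g_per_day) == 170
        assert b.larvae["Lasioglossum laticeps"] == 5202
        assert b.larvae["Bombus terrestris"] == 927

    def test_budget_at_small_tree_flower_count(self):
        b = tree_resources(16_163)
        assert round(b.pollen_cm3) == 5
        assert round(b.sugar_g_per_day) == 14
        assert b.larvae["Lasioglossum laticeps"] == 430

    def test_zero_flowers_zero_everything(self):
        b = tree_resources(0)
        assert b.pollen_cm3 == b.nectar_g_per_day == b.sugar_g_per_day == 0.0
        assert all(v == 0 for v in b.larvae.values())

    def test_unit_conservation_round_trip(self):
        b = tree_resources(1000.0)
        assert b.pollen_cm3 * 1000.0 == pytest.approx(
            1000.0 * pollen_volume_per_flower(), rel=1e-12
        )
        assert b.nectar_g_per_day * 1000.0 == pytest.approx(1000.0 * 3.7, rel=1e-12)
        assert b.sugar_g_per_day == pytest.approx(b.nectar_g_per_day * 0.235, rel=1e-12)

    def test_larvae_monotonicity(self):
        small = BeeSpecies("small", 10.0)
        big = BeeSpecies("big", 60.0)
        assert larvae_supported(1.0, small) >= larvae_supported(1.0, big)
        assert larvae_supported(2.0, small) >= larvae_supported(1.0, small)
        assert larvae_supported(0.00001, big) == 0  # requirement exceeds supply


def _exact_curve_table(n=8, b0=6.0, b1=0.15):
    dbh = np.linspace(10, 24, n)
    flowers = np.round(np.exp(b0 + b1 * dbh))
    return pd.DataFrame({"tree_id": [f"T{i}" for i in range(n)], "dbh": dbh, "flowers": flowers})


class TestBootstrap:
    def test_degenerate_propagation_gives_zero_width(self):
        # data exactly on an NB mean curve: every resample refits the same
        # curve, and near-zero parameter SDs kill the Monte Carlo spread
        table = _exact_curve_table()
        pollen = PollenParams(grains_per_flower_se=1e-9, grain_diameter_se_um=1e-9)
        nectar = NectarParams(
            production_range_mg=(3.7 - 1e-9, 3.7 + 1e-9), sugar_range=(0.235 - 1e-9, 0.235 + 1e-9)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = bootstrap_mc_ci(table, [15.0], pollen, nectar, B=40, seed=0)
        row = out.iloc[0]
        assert row["flowers_hi"] - row["flowers_lo"] <= 1e-3 * row["flowers"]
        assert row["sugar_hi"] - row["sugar_lo"] <= 1e-3 * row["sugar_g"]
        assert row["flowers_lo"] <= row["flowers"] <= row["flowers_hi"]

    def test_wider_nectar_range_widens_sugar_ci(self):
        rng = np.random.default_rng(2)
        table = _exact_curve_table()
        table["flowers"] = np.round(table["flowers"] * rng.lognormal(0, 0.15, len(table)))
        narrow = NectarParams(production_range_mg=(3.2, 4.2))
        wide = NectarParams(production_range_mg=(1.4, 6.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            o1 = bootstrap_mc_ci(table, [15.0], nectar=narrow, B=120, seed=7)
            o2 = bootstrap_mc_ci(table, [15.0], nectar=wide, B=120, seed=7)
        w1 = o1.iloc[0]["sugar_hi"] - o1.iloc[0]["sugar_lo"]
        w2 = o2.iloc[0]["sugar_hi"] - o2.iloc[0]["sugar_lo"]
        assert w2 > w1

    def test_ci_order_and_point_coverage(self):
        rng = np.random.default_rng(5)
        table = _exact_curve_table(n=12)
        table["flowers"] = np.round(table["flowers"] * rng.lognormal(0, 0.1, len(table)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = bootstrap_mc_ci(table, [12.0, 18.0, 22.0], B=150, seed=3)
        for _, row in out.iterrows():
            assert row["flowers_lo"] <= row["flowers_hi"]
            assert row["pollen_lo"] <= row["pollen_hi"]
            assert row["flowers_lo"] <= row["flowers"] <= row["flowers_hi"]
        for s in default_species():
            key = s.name.replace(" ", "_")
            assert (out[f"larvae_{key}_lo"] <= out[f"larvae_{key}_hi"]).all()

    def test_too_few_trees_raise(self):
        with pytest.raises(InsufficientDataError):
            bootstrap_mc_ci(_exact_curve_table(n=3), [15.0], B=10)
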