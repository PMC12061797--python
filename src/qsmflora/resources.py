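"""Pollen, nectar-sugar and bee-larvae budgets with propagated uncertainty.

Per flower, the pollen volume is the sphere volume of the mean grain
diameter times the mean grain count; nectar and sugar follow from the
per-flower production rate and sugar fraction.  Tree-level budgets multiply
these constants by the predicted flower total.  95% CIs combine a bootstrap
over trees (refitting the dbh flower model each repetition) with Monte
Carlo draws of the four uncertain flower-level parameters: measured means
use their SE as the draw SD, literature ranges are treated as 95% intervals
(range/4 as SD).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants
from .errors import CIError, InsufficientDataError
from .tree_model import fit_tree_model, predict_tree_flowers

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PollenParams:
    """Pollen grain count and diameter per flower (means with SEs)."""

    grains_per_flower_mean: float = constants.POLLEN_GRAINS_MEAN
    grains_per_flower_se: float = constants.POLLEN_GRAINS_SE
    grain_diameter_um: float = constants.POLLEN_DIAMETER_UM
    grain_diameter_se_um: float = constants.POLLEN_DIAMETER_SE_UM

    def __post_init__(self) -> None:
        vals = (
            self.grains_per_flower_mean,
            self.grains_per_flower_se,
            self.grain_diameter_um,
            self.grain_diameter_se_um,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("pollen parameters must be positive")


@dataclass(frozen=True)
class NectarParams:
    """Nectar production (mg/flower/24 h) and sugar mass fraction."""

    production_mean_mg: float = constants.NECTAR_MG_PER_FLOWER
    production_range_mg: tuple[float, float] = constants.NECTAR_RANGE_MG
    sugar_fraction_mean: float = constants.SUGAR_FRACTION
    sugar_range: tuple[float, float] = constants.SUGAR_RANGE

    def __post_init__(self) -> None:
        lo, hi = self.production_range_mg
        if not (lo <= self.production_mean_mg <= hi):
            raise ValueError("nectar range must bracket the mean")
        lo, hi = self.sugar_range
        if not (0 < lo <= self.sugar_fraction_mean <= hi < 1):
            raise ValueError("sugar range must bracket the mean within (0, 1)")


@dataclass(frozen=True)
class BeeSpecies:
    """A bee species with its per-larva pollen requirement (mm^3)."""

    name: str
    pollen_requirement_mm3: float

    def __post_init__(self) -> None:
        if self.pollen_requirement_mm3 <= 0:
            raise ValueError("pollen requirement must be > 0")


def default_species() -> list[BeeSpecies]:
    return [BeeSpecies(n, r) for n, r in constants.BEE_REQUIREMENTS_MM3.items()]


@dataclass
class ResourceBudget:
    """Point budget (optionally with 95% CIs) for one flower total."""

    flowers: float
    pollen_cm3: float
    nectar_g_per_day: float
    sugar_g_per_day: float
    larvae: dict[str, int] = field(default_factory=dict)
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)


def pollen_volume_per_flower(params: PollenParams | None = None) -> float:
    """Pollen volume per flower in mm^3: (pi/6) d^3 x grain count."""
    if params is None:
        params = PollenParams()
    d_mm = params.grain_diameter_um / 1000.0
    grain_mm3 = math.pi / 6.0 * d_mm**3
    return grain_mm3 * params.grains_per_flower_mean


def larvae_supported(pollen_cm3: float, species: BeeSpecies) -> int:
    """Number of larvae a pollen volume can provision (floor division)."""
    return int(math.floor(pollen_cm3 * 1000.0 / species.pollen_requirement_mm3))


def tree_resources(
    flowers: float,
    pollen: PollenParams | None = None,
    nectar: NectarParams | None = None,
    species: list[BeeSpecies] | None = None,
) -> ResourceBudget:
    """Point resource budget for a given flower total.

    Pollen in cm^3, nectar and sugar in g per 24 h, larvae per species.
    """
    if flowers < 0:
        raise ValueError("flower total must be >= 0")
    pollen = pollen or PollenParams()
    nectar = nectar or NectarParams()
    species = default_species() if species is None else species
    per_flower_mm3 = pollen_volume_per_flower(pollen)
    pollen_cm3 = flowers * per_flower_mm3 / 1000.0
    nectar_g = flowers * nectar.production_mean_mg / 1000.0
    sugar_g = nectar_g * nectar.sugar_fraction_mean
    return ResourceBudget(
        flowers=float(flowers),
        pollen_cm3=float(pollen_cm3),
        nectar_g_per_day=float(nectar_g),
        sugar_g_per_day=float(sugar_g),
        larvae={s.name: larvae_supported(pollen_cm3, s) for s in species},
    )


def _draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw truncated below at 1% of the mean (guards negativity)."""
    return max(float(rng.normal(mean, sd)), 0.01 * mean)


def bootstrap_mc_ci(
    tree_table: pd.DataFrame,
    dbh_grid,
    pollen: PollenParams | None = None,
    nectar: NectarParams | None = None,
    species: list[BeeSpecies] | None = None,
    B: int = 1000,
    seed: int = 0,
    predictor: str = "dbh",
) -> pd.DataFrame:
    """Bootstrap + Monte Carlo 95% CIs for flower and resource predictions.

    Each of the B repetitions resamples trees with replacement, refits the
    NB flower model, predicts flowers on the dbh grid and converts them to
    resources with randomly drawn flower-level parameters.  CIs are the
    2.5%/97.5% percentiles over repetitions.  Larvae CIs reuse the same
    B pollen predictions transformed per species.  Repetitions whose refit
    fails are dropped; more than 10% failures aborts.
    """
    if len(tree_table) < 5:
        raise InsufficientDataError("need at least 5 trees for the bootstrap")
    if B < 2:
        raise ValueError("B must be >= 2")
    pollen = pollen or PollenParams()
    nectar = nectar or NectarParams()
    species = default_species() if species is None else species
    grid = np.atleast_1d(np.asarray(dbh_grid, dtype=float))
    rng = np.random.default_rng(seed)

    nectar_sd = (nectar.production_range_mg[1] - nectar.production_range_mg[0]) / 4.0
    sugar_sd = (nectar.sugar_range[1] - nectar.sugar_range[0]) / 4.0

    n = len(tree_table)
    flowers_mat = np.full((B, len(grid)), np.nan)
    pollen_mat = np.full((B, len(grid)), np.nan)
    sugar_mat = np.full((B, len(grid)), np.nan)
    failures = 0
    import warnings as _warnings

    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sample = tree_table.iloc[idx]
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                m = fit_tree_model(sample, predictor=predictor, loocv=False)
                fl = np.asarray(predict_tree_flowers(m, grid))
        except Exception:
            failures += 1
            continue
        grains = _draw(rng, pollen.grains_per_flower_mean, pollen.grains_per_flower_se)
        diam = _draw(rng, pollen.grain_diameter_um, pollen.grain_diameter_se_um)
        prod = _draw(rng, nectar.production_mean_mg, nectar_sd)
        frac = _draw(rng, nectar.sugar_fraction_mean, sugar_sd)
        per_flower_mm3 = math.pi / 6.0 * (diam / 1000.0) ** 3 * grains
        flowers_mat[b] = fl
        pollen_mat[b] = fl * per_flower_mm3 / 1000.0
        sugar_mat[b] = fl * prod / 1000.0 * frac
    if failures > 0.10 * B:
        raise CIError(f"{failures}/{B} bootstrap repetitions failed")
    if failures:
        log.info("dropped %d failed bootstrap repetitions", failures)

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        point_model = fit_tree_model(tree_table, predictor=predictor, loocv=False)
        point_flowers = np.asarray(predict_tree_flowers(point_model, grid))

    rows = []
    for j, d in enumerate(grid):
        budget = tree_resources(point_flowers[j], pollen, nectar, species)
        fcol = flowers_mat[:, j]
        pcol = pollen_mat[:, j]
        scol = sugar_mat[:, j]
        ok = ~np.isnan(fcol)
        row = {
            predictor: d,
            "flowers": budget.flowers,
            "flowers_lo": float(np.percentile(fcol[ok], 2.5)),
            "flowers_hi": float(np.percentile(fcol[ok], 97.5)),
            "pollen_cm3": budget.pollen_cm3,
            "pollen_lo": float(np.percentile(pcol[ok], 2.5)),
            "pollen_hi": float(np.percentile(pcol[ok], 97.5)),
            "sugar_g": budget.sugar_g_per_day,
            "sugar_lo": float(np.percentile(scol[ok], 2.5)),
            "sugar_hi": float(np.percentile(scol[ok], 97.5)),
        }
        for s in species:
            lar = pcol[ok] * 1000.0 / s.pollen_requirement_mm3
            key = s.name.replace(" ", "_")
            row[f"larvae_{key}"] = budget.larvae[s.name]
            row[f"larvae_{key}_lo"] = float(np.floor(np.percentile(lar, 2.5)))
            row[f"larvae_{key}_hi"] = float(np.floor(np.percentile(lar, 97.5)))
        rows.append(row)
    return pd.DataFrame(rows)
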