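"""Upscale the branch-level hurdle model over QSMs to per-tree flower totals.

For every branch unit of a QSM replicate the occurrence probability is
evaluated at the unit's root diameter, the tree's dbh and its crown
position (random intercepts at zero — marginal prediction for unobserved
branches).  A Bernoulli draw decides whether the unit flowers; flowering
units contribute the zero-truncated NB expected count (or a sampled ZTNB
count on request).  Per-tree totals are the median over QSM replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import nbinom

from .errors import AggregationError, ThresholdError
from .hurdle import HurdleCoefficients, linear_predictor, ztnb_mean
from .qsm import QSM, TreeMetrics, classify_crown_position, crown_base_height, derive_tree_metrics, extract_branch_units
from scipy.special import expit


@dataclass
class TreeFlowerEstimate:
    """Per-tree flower total: one value per QSM replicate plus the median."""

    tree_id: str
    per_replicate_totals: list[float]
    median_total: float
    dispersion_sd: float


def sample_ztnb(mu, theta: float, rng: np.random.Generator):
    """Draw from the zero-truncated NB2 by inverse-cdf above P(0)."""
    mu = np.asarray(mu, dtype=float)
    p = theta / (theta + mu)
    f0 = nbinom.cdf(0, theta, p)
    u = f0 + rng.uniform(size=mu.shape) * (1.0 - f0)
    return nbinom.ppf(np.clip(u, None, 1.0 - 1e-12), theta, p)


def upscale_replicate(
    qsm: QSM,
    coefs: HurdleCoefficients,
    metrics: TreeMetrics | None = None,
    seed: int | np.random.Generator | None = 0,
    d_max_mm: float = 30.0,
    sample_counts: bool = False,
    force_occurrence: bool = False,
    layer_depth_m: float = 2.0,
    slice_height_m: float = 0.5,
) -> float:
    """Flower total of one QSM replicate.

    ``force_occurrence=True`` skips the Bernoulli stage (every unit
    flowers), making the total the deterministic sum of ZTNB means — the
    analytic oracle used in tests.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if metrics is None:
        metrics = derive_tree_metrics(qsm)
    units = extract_branch_units(qsm, d_max_mm=d_max_mm)
    if not units:
        return 0.0
    cbh = metrics.crown_base_height_m
    crown_pts = qsm.crown_points()
    D = np.array([u.root_diameter_mm for u in units])
    if np.any(D <= 0) or np.any(D > d_max_mm + 1e-9):
        raise ThresholdError("branch-unit root diameter outside (0, d_max]")
    layers, strata = [], []
    for u in units:
        pos = classify_crown_position(
            u, qsm, cbh, layer_depth_m=layer_depth_m, slice_height_m=slice_height_m,
            crown_points=crown_pts,
        )
        layers.append(pos.layer)
        strata.append(pos.stratum)
    layers = np.array(layers)
    strata = np.array(strata)
    dbh = metrics.dbh_cm

    p = expit(linear_predictor(coefs.occurrence, D, dbh, layers, strata))
    flowering = np.ones(len(units), dtype=bool) if force_occurrence else rng.uniform(size=len(units)) < p
    if not flowering.any():
        return 0.0
    mu = np.exp(linear_predictor(coefs.abundance, D[flowering], dbh, layers[flowering], strata[flowering]))
    if sample_counts:
        counts = sample_ztnb(mu, coefs.theta, rng)
    else:
        counts = ztnb_mean(mu, coefs.theta)
    return float(np.sum(counts))


def aggregate_tree(tree_id: str, per_replicate_totals) -> TreeFlowerEstimate:
    """Median (and SD) of per-replicate totals for one tree."""
    totals = [float(t) for t in per_replicate_totals]
    if not totals:
        raise AggregationError(f"no replicate totals for tree {tree_id!r}")
    arr = np.asarray(totals)
    return TreeFlowerEstimate(
        tree_id=str(tree_id),
        per_replicate_totals=totals,
        median_total=float(np.median(arr)),
        dispersion_sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
    )


def upscale_tree(
    qsms: list[QSM],
    coefs: HurdleCoefficients,
    seed: int = 0,
    **kwargs,
) -> TreeFlowerEstimate:
    """Upscale all replicates of one tree and aggregate.

    Per-replicate random streams are derived from the master seed and the
    replicate index, so a fixed seed reproduces every total exactly.
    """
    if not qsms:
        raise AggregationError("no QSM replicates supplied")
    totals = []
    for q in qsms:
        rng = np.random.default_rng([int(seed) % (2**31), q.replicate_id])
        metrics = derive_tree_metrics(q)
        totals.append(upscale_replicate(q, coefs, metrics, rng, **kwargs))
    return aggregate_tree(qsms[0].tree_id, totals)
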