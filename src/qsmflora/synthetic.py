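"""Synthetic branch datasets and cylinder trees with known ground truth.

The generator emulates the study conditions of the field campaign this
pipeline is built for: ~39 wild cherry trees spanning 9-28 cm dbh, branch
hierarchies (cut-off branches with nested subbranches) whose flower counts
are drawn from the two-part hurdle process with nested normal random
intercepts, and TreeQSM-style cylinder tables with tapering branches down
to a 3 mm minimum diameter plus replicate models with multiplicative
reconstruction noise.  Flower attachment in detailed branches is restricted
to shoot segments thinner than 20 mm, mirroring the empirical finding that
flowers sit exclusively on segments and spurs below 2 cm.

Geometry is deliberately schematic — it exercises the pipeline (taper,
branching topology, crown extent), not cherry crown architecture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import constants
from .branch_data import BranchRecord, DiameterMeasurement, TreeRecord
from .hurdle import HurdleCoefficients, linear_predictor
from .qsm import QSM, CYLINDER_COLUMNS
from .upscaling import sample_ztnb
from scipy.special import expit

STRATA = ("bot", "mid", "top")
LAYERS = ("in", "out")
COMPASS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


@dataclass
class SyntheticForestSpec:
    """Study conditions for the synthetic forest.

    Defaults follow the emulated field sample: 39 trees, dbh 9-28 cm,
    30 QSM replicates per tree, 3 mm minimum cylinder diameter, 5%
    multiplicative reconstruction noise, hurdle truth at the reference
    coefficients with theta = 1.5 and random SDs 0.3.
    """

    n_trees: int = 39
    dbh_range_cm: tuple[float, float] = (9.0, 28.0)
    cutoffs_per_tree: int = 4
    subbranch_mean: float = 2.0
    subsub_mean: float = 1.0
    hurdle: HurdleCoefficients = field(default_factory=lambda: constants.REFERENCE_HURDLE)
    n_replicates: int = 30
    noise_sd: float = 0.05
    # cylinder-tree geometry
    branch_spawn_rate: float = 1.0
    branch_taper: float = 0.75
    subbranch_prob: float = 0.35
    min_diameter_mm: float = 3.0
    trunk_segment_m: float = 0.5
    branch_segment_m: float = 0.4
    max_branch_depth: int = 3


# ---------------------------------------------------------------------------
# branch dataset


def _draw_count(
    coefs: HurdleCoefficients,
    D: float,
    dbh: float,
    layer: str,
    stratum: str,
    ri_occ: float,
    ri_ab: float,
    rng: np.random.Generator,
) -> int:
    p = expit(linear_predictor(coefs.occurrence, D, dbh, layer, stratum, ri_occ))
    if rng.uniform() >= p:
        return 0
    mu = math.exp(linear_predictor(coefs.abundance, D, dbh, layer, stratum, ri_ab))
    return int(sample_ztnb(np.array([mu]), coefs.theta, rng)[0])


def _measurements(D0: float, rng: np.random.Generator) -> list[DiameterMeasurement]:
    """Along-shoot taper from the cut-off diameter to a ~2 mm tip."""
    length = float(np.clip(D0 * 8.0 + rng.normal(0, 5), 20.0, 600.0))
    k = 5
    pos = np.linspace(0.0, length, k)
    tip = 2.0
    diam = D0 + (tip - D0) * pos / length
    jitter = rng.normal(0, 0.02 * D0, size=k)
    jitter[0] = 0.0
    diam = np.maximum(diam + jitter, 0.5)
    return [DiameterMeasurement(float(p), float(d)) for p, d in zip(pos, diam)]


def _flower_positions(
    meas: list[DiameterMeasurement], count: int, rng: np.random.Generator,
    attach_below_mm: float = 20.0,
) -> list[float]:
    """Attachment positions restricted to segments thinner than 20 mm.

    Rejection-samples along the measured polyline so the restriction holds
    under the interpolated (jittered) diameter profile, not just the
    endpoint taper.
    """
    if count == 0:
        return []
    from .branch_data import interpolated_diameter

    x0, x1 = meas[0].position_cm, meas[-1].position_cm
    out: list[float] = []
    for _ in range(200):
        cand = rng.uniform(x0, x1, size=4 * count)
        keep = [
            float(p) for p in cand
            if interpolated_diameter(meas, float(p)) < attach_below_mm - 1e-9
        ]
        out.extend(keep[: count - len(out)])
        if len(out) >= count:
            break
    while len(out) < count:  # thin tip always qualifies
        out.append(x1)
    return sorted(out)


def generate_branch_dataset(
    spec: SyntheticForestSpec, seed: int = 0
) -> tuple[list[BranchRecord], list[TreeRecord], HurdleCoefficients]:
    """Branch and tree tables drawn from the hurdle truth.

    Counts are Bernoulli(occurrence) x ZTNB(abundance) at each branch's own
    cut-off diameter, with independent nested normal random intercepts per
    part (tree level and cut-off-branch level).  Hierarchies include
    subbranches and sub-subbranches so cumulation and subsampling have
    structure to work on.  Returns (records, trees, truth).
    """
    rng = np.random.default_rng([int(seed) % (2**31), 101])
    coefs = spec.hurdle
    records: list[BranchRecord] = []
    trees: list[TreeRecord] = []
    for t in range(spec.n_trees):
        tree_id = f"T{t+1:03d}"
        dbh = float(rng.uniform(*spec.dbh_range_cm))
        trees.append(TreeRecord(tree_id, dbh))
        u_occ = rng.normal(0, coefs.sd_tree) if coefs.sd_tree > 0 else 0.0
        u_ab = rng.normal(0, coefs.sd_tree) if coefs.sd_tree > 0 else 0.0
        for c in range(spec.cutoffs_per_tree):
            cut_id = f"{tree_id}B{c+1:02d}"
            v_occ = rng.normal(0, coefs.sd_branch) if coefs.sd_branch > 0 else 0.0
            v_ab = rng.normal(0, coefs.sd_branch) if coefs.sd_branch > 0 else 0.0
            D0 = float(np.clip(np.exp(rng.normal(np.log(12.0), 0.7)), 3.0, 55.0))
            stratum = str(rng.choice(STRATA))
            layer = str(rng.choice(LAYERS))
            compass = str(rng.choice(COMPASS))

            def make(branch_id, parent_id, D):
                count = _draw_count(
                    coefs, D, dbh, layer, stratum, u_occ + v_occ, u_ab + v_ab, rng
                )
                # thick branches get the simplified protocol (count only);
                # detailed shoots still taper through flowerless thick classes
                detailed = D < 35.0
                meas = _measurements(D, rng) if detailed else []
                fpos = _flower_positions(meas, count, rng) if detailed else None
                return BranchRecord(
                    branch_id=branch_id,
                    tree_id=tree_id,
                    parent_branch_id=parent_id,
                    cutoff_diameter_mm=D,
                    crown_stratum=stratum,
                    crown_layer=layer,
                    compass=compass,
                    own_flower_count=count,
                    measurements=meas,
                    flower_positions_cm=fpos,
                    detailed=detailed,
                )

            records.append(make(cut_id, None, D0))
            n_sub = rng.poisson(spec.subbranch_mean)
            for s in range(n_sub):
                sub_id = f"{cut_id}S{s+1:02d}"
                Ds = float(np.clip(D0 * rng.uniform(0.3, 0.7), 3.0, 55.0))
                records.append(make(sub_id, cut_id, Ds))
                for ss in range(rng.poisson(spec.subsub_mean)):
                    Dss = float(np.clip(Ds * rng.uniform(0.3, 0.7), 3.0, 55.0))
                    records.append(make(f"{sub_id}T{ss+1:02d}", sub_id, Dss))
    return records, trees, coefs


# ---------------------------------------------------------------------------
# cylinder trees


def _vertical(z0: float, length: float) -> dict:
    return {"axis_x": 0.0, "axis_y": 0.0, "axis_z": 1.0, "length_m": length}


def generate_qsm(
    dbh_cm: float,
    spec: SyntheticForestSpec | None = None,
    seed: int = 0,
    tree_id: str = "T001",
) -> QSM:
    """A schematic cylinder tree with the requested dbh.

    Vertical trunk with linear taper (the cylinder spanning 1.3 m gets
    exactly the requested radius, so the derived dbh matches by
    construction), branches spawned along the crown with multiplicative
    taper per segment and recursive subbranches, terminating below the
    minimum cylinder diameter (3 mm).
    """
    if dbh_cm <= 0:
        raise ValueError("dbh must be > 0")
    spec = spec or SyntheticForestSpec()
    rng = np.random.default_rng([int(seed) % (2**31), 202])
    r13 = dbh_cm / 200.0
    height = float(np.clip(6.0 + 0.5 * dbh_cm + rng.normal(0, 0.5), 5.0, 25.0))
    crown_base = 0.3 * height
    rows: list[dict] = []
    next_id = [1]

    def add(parent, x, y, z, ax, ay, az, length, radius, order) -> int:
        cid = next_id[0]
        next_id[0] += 1
        rows.append(
            {
                "cyl_id": cid,
                "parent_id": parent,
                "start_x_m": x,
                "start_y_m": y,
                "start_z_m": z,
                "axis_x": ax,
                "axis_y": ay,
                "axis_z": az,
                "length_m": length,
                "radius_m": radius,
                "branch_order": order,
            }
        )
        return cid

    def trunk_radius(z: float) -> float:
        if z <= 1.3:
            return r13 * (1.0 + 0.1 * (1.3 - z) / 1.3)
        return max(r13 * (height - z) / (height - 1.3), 0.0015)

    def grow_branch(parent_id, x, y, z, direction, radius, order, depth):
        d = np.asarray(direction, dtype=float)
        d /= np.linalg.norm(d)
        min_r = spec.min_diameter_mm / 2000.0
        while radius >= min_r:
            L = spec.branch_segment_m
            parent_id = add(parent_id, x, y, z, *d, L, radius, order)
            x, y, z = x + d[0] * L, y + d[1] * L, z + d[2] * L
            new_radius = radius * spec.branch_taper
            if depth < spec.max_branch_depth and rng.uniform() < spec.subbranch_prob:
                sub_r = new_radius * 0.7
                if sub_r >= min_r:
                    az = rng.uniform(0, 2 * np.pi)
                    elev = rng.uniform(0.1, 0.7)
                    sd = np.array(
                        [np.cos(az) * np.cos(elev), np.sin(az) * np.cos(elev), np.sin(elev)]
                    )
                    grow_branch(parent_id, x, y, z, sd, sub_r, order + 1, depth + 1)
            # slight random reorientation of the running tip
            wob = rng.normal(0, 0.15, size=3)
            d = d + wob
            d[2] = abs(d[2]) * 0.5 + d[2] * 0.5  # bias against diving
            d /= np.linalg.norm(d)
            radius = new_radius

    # trunk
    z = 0.0
    parent = None
    while z < height:
        L = min(spec.trunk_segment_m, height - z)
        if L < 0.05:
            break
        mid = z + L / 2.0
        r = r13 if (z <= 1.3 < z + L) else trunk_radius(mid)
        parent = add(parent, 0.0, 0.0, z, 0.0, 0.0, 1.0, L, r, 0)
        if z + L / 2.0 > crown_base:
            for _ in range(rng.poisson(spec.branch_spawn_rate)):
                br = float(np.clip(0.35 * r, 0.002, 0.035))
                az = rng.uniform(0, 2 * np.pi)
                elev = rng.uniform(0.15, 0.6)
                d = np.array(
                    [np.cos(az) * np.cos(elev), np.sin(az) * np.cos(elev), np.sin(elev)]
                )
                grow_branch(parent, 0.0, 0.0, z + L, d, br, 1, 1)
        z += L
    df = pd.DataFrame(rows, columns=CYLINDER_COLUMNS)
    return QSM(tree_id, df, replicate_id=0)


def generate_replicates(
    qsm: QSM, k: int = 30, noise_sd: float = 0.05, seed: int = 0
) -> list[QSM]:
    """k jittered copies of a QSM emulating reconstruction stochasticity.

    Radii and lengths are perturbed multiplicatively by 1 + N(0, noise_sd)
    (factors clipped to [0.5, 1.5]); noise 0 returns identical copies.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = []
    for r in range(k):
        df = qsm.df.copy()
        if noise_sd > 0:
            rng = np.random.default_rng([int(seed) % (2**31), 303, r])
            f_r = np.clip(1.0 + rng.normal(0, noise_sd, len(df)), 0.5, 1.5)
            f_l = np.clip(1.0 + rng.normal(0, noise_sd, len(df)), 0.5, 1.5)
            df["radius_m"] = df["radius_m"] * f_r
            df["length_m"] = df["length_m"] * f_l
        out.append(QSM(qsm.tree_id, df, replicate_id=r))
    return out


def generate_forest(
    spec: SyntheticForestSpec, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, list[QSM]]]:
    """Tree table (tree_id, dbh_cm) and replicate QSMs for every tree."""
    rng = np.random.default_rng([int(seed) % (2**31), 404])
    trees = []
    qsms: dict[str, list[QSM]] = {}
    for t in range(spec.n_trees):
        tree_id = f"T{t+1:03d}"
        dbh = float(rng.uniform(*spec.dbh_range_cm))
        trees.append({"tree_id": tree_id, "dbh_cm": dbh})
        base = generate_qsm(dbh, spec, seed=seed + 7919 * (t + 1), tree_id=tree_id)
        qsms[tree_id] = generate_replicates(
            base, spec.n_replicates, spec.noise_sd, seed=seed + 104729 * (t + 1)
        )
    return pd.DataFrame(trees), qsms
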