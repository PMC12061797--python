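"""Farthest-distance subsampling of the branch hierarchy.

Measured branches form nested hierarchies (a cut-off branch and all its
subbranches), so using them all in one regression would pseudo-replicate:
a subbranch's flowers are contained in its parent's total.  To obtain a
balanced, independent fitting set, every branch is embedded as a point in a
six-dimensional space (branch diameter, crown layer, crown stratum, compass
direction, tree identity, tree dbh), coordinates are standardized so each
dimension carries similar weight, and branches are picked greedily so that
each new pick maximizes the minimum distance to the already-selected set.
Whenever a branch is selected, all its ancestors and descendants are removed
from the candidate pool, so no selected branch contains another's flowers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .branch_data import BranchRecord, TreeRecord
from .errors import EmptySelectionError, EncodingError, HierarchyError

#: ordinal / circular encodings for the categorical sampling dimensions
STRATUM_CODES = {"bot": 0.0, "mid": 1.0, "top": 2.0}
LAYER_CODES = {"in": 0.0, "out": 1.0}
COMPASS_CODES = {c: float(i) for i, c in enumerate(("N", "NE", "E", "SE", "S", "SW", "W", "NW"))}

DIMENSIONS = ("diameter", "layer", "stratum", "compass", "tree", "dbh")


@dataclass
class SamplingSpace:
    """Encoding and scaling of the six sampling dimensions.

    ``center``/``spread`` hold the per-dimension mean and SD estimated on
    the input set; a zero-spread dimension maps every point to coordinate 0.
    ``log_diameter`` applies a natural-log transform to branch diameter
    before standardization, matching its use in the branch models.
    """

    log_diameter: bool = True
    tree_codes: dict[str, float] = field(default_factory=dict)
    center: np.ndarray | None = None
    spread: np.ndarray | None = None


def _raw_coordinates(
    records: Sequence[BranchRecord],
    trees: Sequence[TreeRecord],
    space: SamplingSpace,
) -> np.ndarray:
    dbh = {t.tree_id: t.dbh_cm for t in trees}
    if not space.tree_codes:
        space.tree_codes = {
            tid: float(i) for i, tid in enumerate(sorted({r.tree_id for r in records}))
        }
    n = len(records)
    X = np.empty((n, 6))
    compass_vals = []
    for i, r in enumerate(records):
        if r.tree_id not in space.tree_codes:
            raise EncodingError(f"unknown tree id {r.tree_id!r}")
        if r.tree_id not in dbh:
            raise EncodingError(f"no dbh for tree {r.tree_id!r}")
        try:
            X[i, 1] = LAYER_CODES[r.crown_layer]
            X[i, 2] = STRATUM_CODES[r.crown_stratum]
        except KeyError as e:  # pragma: no cover - records validate on build
            raise EncodingError(str(e)) from e
        d = r.cutoff_diameter_mm
        X[i, 0] = np.log(d) if space.log_diameter else d
        if r.compass is None:
            X[i, 3] = np.nan
        else:
            if r.compass not in COMPASS_CODES:
                raise EncodingError(f"unknown compass {r.compass!r}")
            X[i, 3] = COMPASS_CODES[r.compass]
            compass_vals.append(X[i, 3])
        X[i, 4] = space.tree_codes[r.tree_id]
        X[i, 5] = dbh[r.tree_id]
    # missing compass -> dimension mean (coordinate 0 after centring)
    if np.isnan(X[:, 3]).any():
        fill = float(np.mean(compass_vals)) if compass_vals else 0.0
        X[np.isnan(X[:, 3]), 3] = fill
    return X


def scale_coordinates(
    records: Sequence[BranchRecord],
    trees: Sequence[TreeRecord],
    space: SamplingSpace | None = None,
) -> pd.DataFrame:
    """Standardized point table (one row per branch, six columns).

    Each dimension is z-standardized (mean 0, SD 1) over the input set;
    dimensions with zero spread are mapped to a constant 0.
    """
    if space is None:
        space = SamplingSpace()
    X = _raw_coordinates(records, trees, space)
    if space.center is None:
        space.center = X.mean(axis=0)
        space.spread = X.std(axis=0)
    Z = X - space.center
    ok = space.spread > 0
    Z[:, ok] = Z[:, ok] / space.spread[ok]
    Z[:, ~ok] = 0.0
    return pd.DataFrame(Z, index=[r.branch_id for r in records], columns=list(DIMENSIONS))


def _relatives(records: Sequence[BranchRecord]) -> dict[str, set[str]]:
    """For each branch: the set of its ancestors and descendants."""
    parent = {r.branch_id: r.parent_branch_id for r in records}
    ids = set(parent)
    for b, p in parent.items():
        if p is not None and p not in ids:
            raise HierarchyError(f"branch {b!r} references missing parent {p!r}")
    ancestors: dict[str, set[str]] = {}
    for b in parent:
        seen: set[str] = set()
        p = parent[b]
        while p is not None:
            if p in seen or p == b:
                raise HierarchyError(f"cycle detected at branch {b!r}")
            seen.add(p)
            p = parent[p]
        ancestors[b] = seen
    relatives: dict[str, set[str]] = {b: set(a) for b, a in ancestors.items()}
    for b, anc in ancestors.items():
        for a in anc:
            relatives[a].add(b)
    return relatives


def farthest_distance_sample(
    records: Sequence[BranchRecord],
    trees: Sequence[TreeRecord],
    space: SamplingSpace | None = None,
) -> list[str]:
    """Greedy hierarchy-aware farthest-point selection of branch ids.

    Seeded with the largest cut-off diameter; each subsequent pick maximizes
    the minimum Euclidean distance to all already-selected points.  Picking
    a branch removes its ancestors and descendants from the pool; selection
    stops when the pool is empty.  Ties (in diameter or distance) break on
    the lexicographically smallest branch id, so the result is deterministic
    and independent of input order.
    """
    if not records:
        raise EmptySelectionError("no branches to sample from")
    records = sorted(records, key=lambda r: r.branch_id)
    coords = scale_coordinates(records, trees, space).to_numpy()
    ids = [r.branch_id for r in records]
    index = {b: i for i, b in enumerate(ids)}
    relatives = _relatives(records)

    diameters = np.array([r.cutoff_diameter_mm for r in records])
    seed_i = int(np.argmax(diameters))  # first occurrence = smallest id on ties
    selected = [ids[seed_i]]
    active = np.ones(len(ids), dtype=bool)
    active[seed_i] = False
    for rel in relatives[ids[seed_i]]:
        active[index[rel]] = False

    mindist = np.linalg.norm(coords - coords[seed_i], axis=1)
    while active.any():
        cand = np.where(active)[0]
        best = cand[int(np.argmax(mindist[cand]))]
        selected.append(ids[best])
        active[best] = False
        for rel in relatives[ids[best]]:
            active[index[rel]] = False
        mindist = np.minimum(mindist, np.linalg.norm(coords - coords[best], axis=1))
    return selected
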