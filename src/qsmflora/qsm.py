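"""Cylinder-based tree models (QSMs): metrics, branch units, crown position.

A QSM represents a tree as a rooted hierarchy of cylinders (start point,
axis, length, radius, parent link, branch order), the standard output of
TLS-based tree reconstruction.  Coordinates are meters in a right-handed
frame with +z up.  This module derives tree metrics (dbh, height, crown
diameter/area/volume), extracts the flower-bearing *branch units* — maximal
cylinder subtrees entered where the diameter first drops to or below 3 cm —
and classifies each unit's bounding-box center into a crown stratum
(vertical thirds of the crown) and layer (outer = within 2 m of the crown
surface, via convex hulls of 0.5 m crown slices eroded inward).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError
from shapely.geometry import MultiPoint, Point, Polygon

from .errors import HierarchyError, MetricError

log = logging.getLogger(__name__)

CYLINDER_COLUMNS = [
    "cyl_id",
    "parent_id",
    "start_x_m",
    "start_y_m",
    "start_z_m",
    "axis_x",
    "axis_y",
    "axis_z",
    "length_m",
    "radius_m",
    "branch_order",
]


@dataclass(frozen=True)
class Cylinder:
    """One geometric primitive of a QSM."""

    cyl_id: int
    parent_id: int | None
    start: tuple[float, float, float]
    axis: tuple[float, float, float]
    length_m: float
    radius_m: float
    branch_order: int

    def __post_init__(self) -> None:
        if self.length_m <= 0 or self.radius_m <= 0:
            raise ValueError("length and radius must be > 0")
        norm = float(np.linalg.norm(self.axis))
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"axis must be a unit vector (norm {norm:.6f})")


class QSM:
    """A single cylinder model of one tree.

    Wraps a validated cylinder table (see :data:`CYLINDER_COLUMNS`); exactly
    one root cylinder (parent_id missing) is required and the parent graph
    must be acyclic.
    """

    def __init__(self, tree_id: str, cylinders: pd.DataFrame, replicate_id: int = 0):
        if len(cylinders) == 0:
            raise ValueError("QSM needs at least one cylinder")
        df = cylinders.reset_index(drop=True).copy()
        missing = [c for c in CYLINDER_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cylinder table lacks columns {missing}")
        axes = df[["axis_x", "axis_y", "axis_z"]].to_numpy(float)
        norms = np.linalg.norm(axes, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-5):
            raise ValueError("cylinder axes must be unit vectors")
        roots = df["parent_id"].isna()
        if roots.sum() != 1:
            raise ValueError(f"QSM must have exactly one root cylinder, found {roots.sum()}")
        self.tree_id = str(tree_id)
        self.replicate_id = int(replicate_id)
        self.df = df
        self._index = {int(c): i for i, c in enumerate(df["cyl_id"])}
        self._children: dict[int, list[int]] = {int(c): [] for c in df["cyl_id"]}
        for cid, pid in zip(df["cyl_id"], df["parent_id"]):
            if pd.isna(pid):
                continue
            pid = int(pid)
            if pid not in self._index:
                raise HierarchyError(f"cylinder {cid} references missing parent {pid}")
            self._children[pid].append(int(cid))
        self.root_id = int(df.loc[roots, "cyl_id"].iloc[0])
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen: set[int] = set()
        stack = [self.root_id]
        while stack:
            c = stack.pop()
            if c in seen:
                raise HierarchyError(f"cycle involving cylinder {c}")
            seen.add(c)
            stack.extend(self._children[c])
        if len(seen) != len(self.df):
            raise HierarchyError("cylinders not reachable from the root")

    @classmethod
    def from_cylinders(
        cls, tree_id: str, cylinders: Iterable[Cylinder], replicate_id: int = 0
    ) -> "QSM":
        rows = [
            {
                "cyl_id": c.cyl_id,
                "parent_id": c.parent_id,
                "start_x_m": c.start[0],
                "start_y_m": c.start[1],
                "start_z_m": c.start[2],
                "axis_x": c.axis[0],
                "axis_y": c.axis[1],
                "axis_z": c.axis[2],
                "length_m": c.length_m,
                "radius_m": c.radius_m,
                "branch_order": c.branch_order,
            }
            for c in cylinders
        ]
        return cls(tree_id, pd.DataFrame(rows, columns=CYLINDER_COLUMNS), replicate_id)

    # geometry helpers -----------------------------------------------------
    def starts(self) -> np.ndarray:
        return self.df[["start_x_m", "start_y_m", "start_z_m"]].to_numpy(float)

    def ends(self) -> np.ndarray:
        a = self.df[["axis_x", "axis_y", "axis_z"]].to_numpy(float)
        return self.starts() + a * self.df["length_m"].to_numpy(float)[:, None]

    def diameters_mm(self) -> np.ndarray:
        return 2000.0 * self.df["radius_m"].to_numpy(float)

    def children(self, cyl_id: int) -> list[int]:
        return self._children[int(cyl_id)]

    def row(self, cyl_id: int) -> pd.Series:
        return self.df.iloc[self._index[int(cyl_id)]]

    def subtree(self, cyl_id: int) -> list[int]:
        out, stack = [], [int(cyl_id)]
        while stack:
            c = stack.pop()
            out.append(c)
            stack.extend(self._children[c])
        return out

    def base_z(self) -> float:
        return float(self.row(self.root_id)["start_z_m"])

    def top_z(self) -> float:
        return float(max(self.starts()[:, 2].max(), self.ends()[:, 2].max()))

    def crown_mask(self) -> np.ndarray:
        return (self.df["branch_order"].to_numpy(int) >= 1)

    def crown_points(self) -> np.ndarray:
        """Start and end points of all crown (branch-order >= 1) cylinders."""
        m = self.crown_mask()
        return np.vstack([self.starts()[m], self.ends()[m]])


@dataclass(frozen=True)
class TreeMetrics:
    """Tree dimensions derived from a QSM."""

    dbh_cm: float
    height_m: float
    crown_diameter_m: float
    crown_projection_area_m2: float
    crown_volume_m3: float
    crown_base_height_m: float


@dataclass
class BranchUnit:
    """A maximal cylinder subtree entered at diameter <= the threshold."""

    root_cyl_id: int
    member_cyl_ids: list[int]
    root_diameter_mm: float
    bbox_center: tuple[float, float, float]


@dataclass(frozen=True)
class CrownPosition:
    stratum: str  # bot / mid / top
    layer: str  # in / out


# ---------------------------------------------------------------------------
# metrics


def _trunk_path(qsm: QSM) -> list[int]:
    """Cylinder ids along the stem (branch order 0) from the root upward."""
    path = [qsm.root_id]
    while True:
        nxt = [c for c in qsm.children(path[-1]) if int(qsm.row(c)["branch_order"]) == 0]
        if not nxt:
            return path
        # at forks keep the thickest continuation
        path.append(max(nxt, key=lambda c: float(qsm.row(c)["radius_m"])))


def _dbh_cm(qsm: QSM) -> float:
    target = qsm.base_z() + 1.3
    best, best_gap = None, np.inf
    for c in _trunk_path(qsm):
        r = qsm.row(c)
        z0 = float(r["start_z_m"])
        z1 = z0 + float(r["axis_z"]) * float(r["length_m"])
        lo, hi = min(z0, z1), max(z0, z1)
        if lo <= target <= hi:
            return 200.0 * float(r["radius_m"])
        gap = min(abs(target - lo), abs(target - hi))
        if gap < best_gap:
            best, best_gap = c, gap
    if best is None:  # pragma: no cover
        raise MetricError("empty trunk")
    return 200.0 * float(qsm.row(best)["radius_m"])


def crown_base_height(qsm: QSM) -> float:
    """Height of the lowest crown (branch-order >= 1) cylinder base above
    the stem base."""
    m = qsm.crown_mask()
    if not m.any():
        raise MetricError("QSM has no crown cylinders (branch order >= 1)")
    return float(qsm.starts()[m, 2].min() - qsm.base_z())


def _tet_volume(p: np.ndarray) -> float:
    return abs(np.linalg.det(p[1:] - p[0])) / 6.0


def _tet_circumradius(p: np.ndarray) -> float:
    A = 2.0 * (p[1:] - p[0])
    b = np.sum(p[1:] ** 2 - p[0] ** 2, axis=1)
    try:
        c = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf
    return float(np.linalg.norm(c - p[0]))


def alpha_shape_volume(points: np.ndarray, alpha: float | None = 1.0) -> float:
    """Volume of the 3-D alpha shape of a point set.

    Tetrahedra of the Delaunay triangulation with circumradius below
    ``alpha`` are kept and their volumes summed.  ``alpha=None`` gives the
    convex-hull volume (the alpha -> infinity limit), which also serves as
    an independent oracle.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        return 0.0
    if alpha is None:
        try:
            return float(ConvexHull(points).volume)
        except QhullError:
            return 0.0
    try:
        tri = Delaunay(points)
    except QhullError:
        return 0.0
    vol = 0.0
    for simplex in tri.simplices:
        p = points[simplex]
        if _tet_circumradius(p) < alpha:
            vol += _tet_volume(p)
    return float(vol)


def _hull_extent_diameter(xy: np.ndarray, mode: str = "mean8") -> float:
    """Crown diameter from the horizontal hull: either the mean extent over
    8 azimuthal directions or the maximum extent."""
    if len(xy) < 2:
        return 0.0
    try:
        hull = xy[ConvexHull(xy).vertices]
    except QhullError:
        hull = xy
    angles = np.arange(8) * np.pi / 8.0
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = hull @ dirs.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    return float(extents.max() if mode == "max" else extents.mean())


def derive_tree_metrics(
    qsm: QSM, alpha: float | None = 1.0, diameter_mode: str = "mean8"
) -> TreeMetrics:
    """dbh, height, crown base height and crown dimensions of a QSM.

    dbh comes from the trunk cylinder spanning 1.3 m above the stem base;
    the crown projection area is the convex hull of vertically projected
    crown cylinder endpoints; crown volume is a 3-D alpha shape of those
    endpoints (``alpha=None`` -> convex hull).
    """
    base = qsm.base_z()
    height = qsm.top_z() - base
    if height < 1.3:
        raise MetricError(f"tree height {height:.2f} m is below breast height")
    dbh = _dbh_cm(qsm)
    try:
        cbh = crown_base_height(qsm)
    except MetricError:
        # bare stem: no crown, crown metrics degenerate to zero
        log.warning("QSM %s has no crown cylinders; crown metrics set to 0", qsm.tree_id)
        return TreeMetrics(dbh, float(height), 0.0, 0.0, 0.0, float(height))
    pts = qsm.crown_points()
    xy = pts[:, :2]
    try:
        area = float(ConvexHull(xy).volume)  # 2-D hull "volume" is the area
    except QhullError:
        area = 0.0
    return TreeMetrics(
        dbh_cm=dbh,
        height_m=float(height),
        crown_diameter_m=_hull_extent_diameter(xy, diameter_mode),
        crown_projection_area_m2=area,
        crown_volume_m3=alpha_shape_volume(pts, alpha),
        crown_base_height_m=cbh,
    )


# ---------------------------------------------------------------------------
# branch units


def extract_branch_units(qsm: QSM, d_max_mm: float = 30.0) -> list[BranchUnit]:
    """Disjoint cylinder subtrees entered where diameter first drops to
    <= ``d_max_mm``.

    Cylinders are visited root-down; an unvisited cylinder with diameter at
    or below the threshold roots a new unit that absorbs its whole subtree
    (so duplicates — a cylinder reachable as part of another unit — never
    spawn their own unit).
    """
    diam = {int(c): d for c, d in zip(qsm.df["cyl_id"], qsm.diameters_mm())}
    starts = qsm.starts()
    ends = qsm.ends()
    idx = {int(c): i for i, c in enumerate(qsm.df["cyl_id"])}
    units: list[BranchUnit] = []
    taken: set[int] = set()
    stack = [qsm.root_id]
    order: list[int] = []
    while stack:  # breadth-ish traversal root-down
        c = stack.pop()
        order.append(c)
        stack.extend(qsm.children(c))
    for c in order:
        if c in taken or diam[c] > d_max_mm:
            continue
        members = qsm.subtree(c)
        taken.update(members)
        rows = [idx[m] for m in members]
        pts = np.vstack([starts[rows], ends[rows]])
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        center = tuple(0.5 * (lo + hi))
        units.append(
            BranchUnit(
                root_cyl_id=c,
                member_cyl_ids=members,
                root_diameter_mm=float(diam[c]),
                bbox_center=center,
            )
        )
    return units


# ---------------------------------------------------------------------------
# crown position


def stratum_of(z: float, base_z: float, crown_base_height_m: float, top_z: float) -> str:
    """Vertical stratum of a height: thirds of [crown base, tree top],
    half-open upward; centers below the crown base count as ``bot``."""
    lo = base_z + crown_base_height_m
    L = top_z - lo
    if L <= 0:
        return "bot"
    rel = (z - lo) / L
    if rel < 1.0 / 3.0:
        return "bot"
    if rel < 2.0 / 3.0:
        return "mid"
    return "top"


def slice_hull(
    crown_points: np.ndarray, base_z: float, slice_index: int, slice_height_m: float = 0.5
) -> Polygon | None:
    """Convex hull of the crown points whose z falls in slice k
    (half-open: a point exactly on a boundary belongs to the upper slice)."""
    z = crown_points[:, 2]
    lo = base_z + slice_index * slice_height_m
    m = (z >= lo) & (z < lo + slice_height_m)
    pts = crown_points[m, :2]
    if len(pts) < 3:
        return None
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if not isinstance(hull, Polygon):
        return None
    return hull


def layer_from_hull(
    hull: Polygon | None, center_xy: tuple[float, float], layer_depth_m: float = 2.0
) -> str:
    """'in' when the center lies inside the hull eroded inward by the layer
    depth, else 'out' (also for degenerate/empty hulls)."""
    if hull is None:
        return "out"
    eroded = hull.buffer(-layer_depth_m)
    if eroded.is_empty:
        return "out"
    return "in" if eroded.contains(Point(*center_xy)) else "out"


def classify_crown_position(
    unit: BranchUnit,
    qsm: QSM,
    crown_base_height_m: float | None = None,
    layer_depth_m: float = 2.0,
    slice_height_m: float = 0.5,
    crown_points: np.ndarray | None = None,
) -> CrownPosition:
    """Crown stratum and layer of a branch unit's bounding-box center.

    The layer test erodes the convex hull of the unit's 0.5 m crown slice
    inward by ``layer_depth_m``; centers inside the eroded polygon are
    ``in``, everything else (including degenerate slices) is ``out``.
    """
    if crown_base_height_m is None:
        crown_base_height_m = crown_base_height(qsm)
    if crown_points is None:
        crown_points = qsm.crown_points()
    base = qsm.base_z()
    cx, cy, cz = unit.bbox_center
    stratum = stratum_of(cz, base, crown_base_height_m, qsm.top_z())
    k = int(np.floor((cz - base) / slice_height_m))
    hull = slice_hull(crown_points, base, k, slice_height_m)
    if hull is None:
        log.debug("degenerate slice %d for unit %d: layer set to 'out'", k, unit.root_cyl_id)
    layer = layer_from_hull(hull, (cx, cy), layer_depth_m)
    return CrownPosition(stratum=stratum, layer=layer)


# ---------------------------------------------------------------------------
# tabular IO


def qsms_to_frame(qsms: Sequence[QSM]) -> pd.DataFrame:
    frames = []
    for q in qsms:
        df = q.df.copy()
        df.insert(0, "tree_id", q.tree_id)
        df.insert(1, "replicate_id", q.replicate_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def frame_to_qsms(df: pd.DataFrame) -> list[QSM]:
    out = []
    for (tid, rid), grp in df.groupby(["tree_id", "replicate_id"], sort=False):
        out.append(QSM(str(tid), grp[CYLINDER_COLUMNS], int(rid)))
    return out


def write_cylinder_csv(qsms: Sequence[QSM], path: str | Path) -> None:
    qsms_to_frame(qsms).to_csv(path, index=False)


def read_cylinder_csv(path: str | Path) -> list[QSM]:
    return frame_to_qsms(pd.read_csv(path, dtype={"tree_id": str}))


def metrics_to_frame(metrics: dict[str, TreeMetrics]) -> pd.DataFrame:
    rows = [
        {
            "tree_id": tid,
            "dbh_cm": m.dbh_cm,
            "height_m": m.height_m,
            "crown_diameter_m": m.crown_diameter_m,
            "crown_projection_area_m2": m.crown_projection_area_m2,
            "crown_volume_m3": m.crown_volume_m3,
            "crown_base_height_m": m.crown_base_height_m,
        }
        for tid, m in metrics.items()
    ]
    return pd.DataFrame(rows)
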