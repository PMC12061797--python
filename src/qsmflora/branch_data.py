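"""Data model and preprocessing for manually measured branches.

A *branch record* is one cut-off branch or subbranch of a wild cherry tree:
its diameter at the cut-off point, its position in the crown (vertical
stratum bot/mid/top, horizontal layer in/out, compass direction), the number
of flowers counted on it, and — for branches measured in detail — a series
of along-shoot diameter measurements that allow segmenting the shoot into
5 mm diameter classes under a linear-taper assumption.

Flower totals per branch include the flowers of all subbranches; the
cumulation over the branch hierarchy is performed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import HierarchyError, InconsistencyError, InsufficientDataError, OrderingError

STRATA = ("bot", "mid", "top")
LAYERS = ("in", "out")
COMPASS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


@dataclass(frozen=True)
class DiameterMeasurement:
    """One along-shoot measurement: position from the cut-off point (cm)
    and shoot diameter at that position (mm)."""

    position_cm: float
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.position_cm < 0:
            raise ValueError(f"position must be >= 0, got {self.position_cm}")
        if self.diameter_mm <= 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter_mm}")


@dataclass
class BranchRecord:
    """One measured branch (or subbranch) with its crown position labels."""

    branch_id: str
    tree_id: str
    cutoff_diameter_mm: float
    crown_stratum: str
    crown_layer: str
    own_flower_count: int
    parent_branch_id: str | None = None
    compass: str | None = None
    measurements: list[DiameterMeasurement] = field(default_factory=list)
    flower_positions_cm: list[float] | None = None
    detailed: bool = False

    def __post_init__(self) -> None:
        if self.cutoff_diameter_mm <= 0:
            raise ValueError("cutoff diameter must be > 0")
        if self.own_flower_count < 0 or int(self.own_flower_count) != self.own_flower_count:
            raise ValueError("own_flower_count must be a non-negative integer")
        if self.crown_stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.crown_stratum!r}")
        if self.crown_layer not in LAYERS:
            raise ValueError(f"unknown layer {self.crown_layer!r}")
        if self.compass is not None and self.compass not in COMPASS:
            raise ValueError(f"unknown compass direction {self.compass!r}")
        positions = [m.position_cm for m in self.measurements]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise OrderingError("measurement positions must be strictly increasing")


@dataclass(frozen=True)
class TreeRecord:
    """A tree with its stem diameter at breast height (1.3 m), in cm."""

    tree_id: str
    dbh_cm: float

    def __post_init__(self) -> None:
        if self.dbh_cm <= 0:
            raise ValueError("dbh must be > 0")


def _children_map(records: Sequence[BranchRecord]) -> dict[str, list[str]]:
    by_id = {r.branch_id: r for r in records}
    children: dict[str, list[str]] = {r.branch_id: [] for r in records}
    for r in records:
        if r.parent_branch_id is None:
            continue
        parent = by_id.get(r.parent_branch_id)
        if parent is None:
            raise HierarchyError(
                f"branch {r.branch_id!r} references missing parent {r.parent_branch_id!r}"
            )
        if parent.tree_id != r.tree_id:
            raise HierarchyError(
                f"branch {r.branch_id!r} and its parent belong to different trees"
            )
        children[parent.branch_id].append(r.branch_id)
    return children


def cumulate_flower_counts(records: Sequence[BranchRecord]) -> dict[str, int]:
    """Total flowers per branch: own count plus all subbranch counts.

    Returns a mapping branch_id -> cumulated total covering every input
    record.  Raises :class:`HierarchyError` on cycles or dangling parents.
    """
    children = _children_map(records)
    own = {r.branch_id: int(r.own_flower_count) for r in records}
    totals: dict[str, int] = {}
    state: dict[str, int] = {}  # 1 = on stack, 2 = done

    for start in own:
        if state.get(start) == 2:
            continue
        stack = [(start, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                totals[node] = own[node] + sum(totals[c] for c in children[node])
                state[node] = 2
                continue
            if state.get(node) == 2:
                continue
            if state.get(node) == 1:
                raise HierarchyError(f"cycle detected at branch {node!r}")
            state[node] = 1
            stack.append((node, True))
            for c in children[node]:
                if state.get(c) == 1:
                    raise HierarchyError(f"cycle detected at branch {c!r}")
                if state.get(c) != 2:
                    stack.append((c, False))
    return totals


def segment_diameter_classes(
    measurements: Sequence[DiameterMeasurement], class_width_mm: float = 5.0
) -> dict[tuple[float, float], float]:
    """Shoot length (cm) per 5 mm diameter class under linear taper.

    Between consecutive measurements the diameter is interpolated linearly;
    the shoot length falling in each half-open class [lower, upper) is
    accumulated.  Class boundaries sit at multiples of ``class_width_mm``.
    """
    if len(measurements) < 2:
        raise InsufficientDataError("need at least two measurements to segment a shoot")
    positions = [m.position_cm for m in measurements]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise OrderingError("measurement positions must be strictly increasing")

    out: dict[tuple[float, float], float] = {}

    def add(diam_lo: float, diam_hi: float, length: float) -> None:
        # assign the diameter sub-interval to its class via the midpoint;
        # sub-intervals never straddle a boundary by construction
        mid = 0.5 * (diam_lo + diam_hi)
        k = math.floor(mid / class_width_mm)
        key = (k * class_width_mm, (k + 1) * class_width_mm)
        out[key] = out.get(key, 0.0) + length

    for a, b in zip(measurements, measurements[1:]):
        x0, d0 = a.position_cm, a.diameter_mm
        x1, d1 = b.position_cm, b.diameter_mm
        seg_len = x1 - x0
        if d0 == d1:
            # constant diameter: the whole segment lies in one class;
            # a diameter exactly on a boundary belongs to the upper class
            k = math.floor(d0 / class_width_mm)
            key = (k * class_width_mm, (k + 1) * class_width_mm)
            out[key] = out.get(key, 0.0) + seg_len
            continue
        dmin, dmax = min(d0, d1), max(d0, d1)
        # diameter breakpoints: class boundaries strictly inside (dmin, dmax)
        k_lo = math.floor(dmin / class_width_mm) + 1
        k_hi = math.ceil(dmax / class_width_mm) - 1
        breaks = [dmin] + [k * class_width_mm for k in range(k_lo, k_hi + 1)] + [dmax]
        slope = (d1 - d0) / seg_len  # mm per cm
        for lo, hi in zip(breaks, breaks[1:]):
            # invert d(x) = d0 + slope (x - x0) for the two diameters
            xa = x0 + (lo - d0) / slope
            xb = x0 + (hi - d0) / slope
            add(lo, hi, abs(xb - xa))
    return out


def interpolated_diameter(
    measurements: Sequence[DiameterMeasurement], position_cm: float
) -> float:
    """Diameter (mm) at a position along the shoot, by linear interpolation."""
    if len(measurements) < 2:
        raise InsufficientDataError("need at least two measurements to interpolate")
    pts = measurements
    if position_cm <= pts[0].position_cm:
        return pts[0].diameter_mm
    for a, b in zip(pts, pts[1:]):
        if position_cm <= b.position_cm:
            t = (position_cm - a.position_cm) / (b.position_cm - a.position_cm)
            return a.diameter_mm + t * (b.diameter_mm - a.diameter_mm)
    return pts[-1].diameter_mm


def flowers_per_cm_summary(
    records: Sequence[BranchRecord], class_width_mm: float = 5.0
) -> pd.DataFrame:
    """Flower density per diameter class and crown section.

    Only detailed records (with along-shoot measurements) contribute.  When
    a record carries flower attachment positions, each flower is mapped to
    the diameter class at its position; otherwise its flowers are assigned
    at the class level of the whole shoot (only when the shoot lies entirely
    within one class — else the flowers stay unallocated and only the shoot
    length contributes).
    """
    rows: dict[tuple[str, str, float, float], dict[str, float]] = {}

    def cell(stratum: str, layer: str, key: tuple[float, float]) -> dict[str, float]:
        k = (stratum, layer, key[0], key[1])
        if k not in rows:
            rows[k] = {"length_cm": 0.0, "flowers": 0.0}
        return rows[k]

    for r in records:
        if not r.detailed or len(r.measurements) < 2:
            continue
        lengths = segment_diameter_classes(r.measurements, class_width_mm)
        for key, length in lengths.items():
            cell(r.crown_stratum, r.crown_layer, key)["length_cm"] += length
        if r.flower_positions_cm is not None:
            for pos in r.flower_positions_cm:
                d = interpolated_diameter(r.measurements, pos)
                k = math.floor(d / class_width_mm)
                key = (k * class_width_mm, (k + 1) * class_width_mm)
                cell(r.crown_stratum, r.crown_layer, key)["flowers"] += 1
        elif r.own_flower_count > 0:
            occupied = [k for k, v in lengths.items() if v > 0]
            if len(occupied) == 1:
                cell(r.crown_stratum, r.crown_layer, occupied[0])["flowers"] += r.own_flower_count
            # else: shoot spans several classes and attachment is unknown

    out_rows = []
    for (stratum, layer, lo, hi), v in sorted(rows.items()):
        if v["length_cm"] <= 0 and v["flowers"] > 0:
            raise InconsistencyError(
                f"{v['flowers']} flowers on zero shoot length in class [{lo}, {hi})"
            )
        density = v["flowers"] / v["length_cm"] if v["length_cm"] > 0 else 0.0
        out_rows.append(
            {
                "stratum": stratum,
                "layer": layer,
                "class_lo_mm": lo,
                "class_hi_mm": hi,
                "length_cm": v["length_cm"],
                "flowers": v["flowers"],
                "flowers_per_cm": density,
            }
        )
    return pd.DataFrame(
        out_rows,
        columns=[
            "stratum",
            "layer",
            "class_lo_mm",
            "class_hi_mm",
            "length_cm",
            "flowers",
            "flowers_per_cm",
        ],
    )


# ---------------------------------------------------------------------------
# tabular interchange

BRANCH_COLUMNS = [
    "tree_id",
    "branch_id",
    "parent_branch_id",
    "cutoff_diameter_mm",
    "stratum",
    "layer",
    "compass",
    "flowers",
    "detailed",
]


def records_to_frame(records: Iterable[BranchRecord]) -> pd.DataFrame:
    """Branch records as a flat table (one row per branch)."""
    rows = [
        {
            "tree_id": r.tree_id,
            "branch_id": r.branch_id,
            "parent_branch_id": r.parent_branch_id,
            "cutoff_diameter_mm": r.cutoff_diameter_mm,
            "stratum": r.crown_stratum,
            "layer": r.crown_layer,
            "compass": r.compass,
            "flowers": int(r.own_flower_count),
            "detailed": bool(r.detailed),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=BRANCH_COLUMNS)


def measurements_to_frame(records: Iterable[BranchRecord]) -> pd.DataFrame:
    """Long-format companion table (branch_id, position_cm, diameter_mm)."""
    rows = [
        {"branch_id": r.branch_id, "position_cm": m.position_cm, "diameter_mm": m.diameter_mm}
        for r in records
        for m in r.measurements
    ]
    return pd.DataFrame(rows, columns=["branch_id", "position_cm", "diameter_mm"])


def frame_to_records(
    branches: pd.DataFrame, measurements: pd.DataFrame | None = None
) -> list[BranchRecord]:
    """Rebuild :class:`BranchRecord` objects from the two tables."""
    meas: Mapping[str, list[DiameterMeasurement]] = {}
    if measurements is not None and len(measurements):
        for bid, grp in measurements.groupby("branch_id", sort=False):
            grp = grp.sort_values("position_cm")
            meas[bid] = [
                DiameterMeasurement(p, d)
                for p, d in zip(grp["position_cm"], grp["diameter_mm"])
            ]
    records = []
    for row in branches.itertuples(index=False):
        parent = row.parent_branch_id
        if parent is not None and (parent != parent or parent in ("", "NA")):  # NaN check
            parent = None
        compass = row.compass
        if compass is not None and (compass != compass or compass == ""):
            compass = None
        records.append(
            BranchRecord(
                branch_id=str(row.branch_id),
                tree_id=str(row.tree_id),
                parent_branch_id=None if parent is None else str(parent),
                cutoff_diameter_mm=float(row.cutoff_diameter_mm),
                crown_stratum=row.stratum,
                crown_layer=row.layer,
                compass=compass,
                own_flower_count=int(row.flowers),
                measurements=meas.get(str(row.branch_id), []),
                detailed=bool(row.detailed),
            )
        )
    return records


def write_branch_csv(
    records: Sequence[BranchRecord], path: str | Path, measurements_path: str | Path | None = None
) -> None:
    records_to_frame(records).to_csv(path, index=False)
    if measurements_path is not None:
        measurements_to_frame(records).to_csv(measurements_path, index=False)


def read_branch_csv(
    path: str | Path, measurements_path: str | Path | None = None
) -> list[BranchRecord]:
    branches = pd.read_csv(path, dtype={"tree_id": str, "branch_id": str, "parent_branch_id": str})
    measurements = None
    if measurements_path is not None:
        measurements = pd.read_csv(measurements_path, dtype={"branch_id": str})
    return frame_to_records(branches, measurements)


def trees_to_frame(trees: Iterable[TreeRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"tree_id": t.tree_id, "dbh_cm": t.dbh_cm} for t in trees],
        columns=["tree_id", "dbh_cm"],
    )


def frame_to_trees(df: pd.DataFrame) -> list[TreeRecord]:
    return [TreeRecord(str(r.tree_id), float(r.dbh_cm)) for r in df.itertuples(index=False)]
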