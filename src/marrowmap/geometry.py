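"""Radius-corrected 3D distance analyses on segmented marrow coordinates.

All distances are computed in continuous µm, in 3D, between cell *surfaces*:
the Euclidean centre distance minus the radii of the participating objects
("gap distance").  Gaps may be negative (interpenetrating segmentations) and
are never clamped; "direct contact" means gap ≤ ``CONTACT_TOL_UM``.

Vessels are modelled as capsules — an ordered polyline plus a constant
radius — so point-to-surface distances are exact without meshes.  A branch
point is a junction where two or more lumens join a third (node degree ≥ 3
in the segment graph); a vessel is the continuous lumen between branch
points, so segment chains that merely continue through a degree-2 junction
are merged before morphometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .catalog import KNOWN_TYPES, mean_radius
from .errors import EmptyTargetError, MarrowError, SchemaError

__all__ = [
    "CONTACT_TOL_UM",
    "CellRecord",
    "DistanceResult",
    "TissueVolume",
    "VesselSegment",
    "VesselNetwork",
    "gap_distance_cells",
    "distance_to_vessel",
    "distance_to_vessels",
    "distance_to_endosteum",
    "nearest_by_type",
    "nearest_gap",
    "measure_vessels",
    "daughter_separation",
    "cells_dataframe",
]

#: Surface gap (µm) at or below which two objects are "in direct contact".
#: Exact zero is brittle under segmentation jitter.
CONTACT_TOL_UM = 0.5

CELL_COLUMNS = ["id", "cell_type", "x_um", "y_um", "z_um", "radius_um", "confetti"]


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: stage label, 3D centre (µm), radius, Confetti colour."""

    id: int | str
    cell_type: str
    centre: tuple[float, float, float]
    radius_um: float | None = None
    confetti: str = "none"

    def __post_init__(self):
        if self.cell_type not in KNOWN_TYPES:
            raise SchemaError(f"unknown cell type: {self.cell_type!r}")
        if self.radius_um is not None and self.radius_um <= 0:
            raise SchemaError(f"cell {self.id}: radius must be positive")

    @property
    def radius(self) -> float:
        """Measured radius, falling back on the catalogue mean for the type."""
        if self.radius_um is not None:
            return self.radius_um
        return mean_radius(self.cell_type)


@dataclass(frozen=True)
class DistanceResult:
    """Gap distance from one source cell to the nearest target."""

    source_id: int | str
    target: str
    gap_um: float
    nearest_id: int | str | None = None

    @property
    def in_contact(self) -> bool:
        return self.gap_um <= CONTACT_TOL_UM


@dataclass(frozen=True)
class TissueVolume:
    """Axis-aligned marrow slab: x–y extent × optical-slice depth (µm).

    The endosteal (bone) surfaces are idealised as the planes y = 0 and
    y = extent_y, standing in for the bone shell flanking the marrow cavity.
    """

    extent_um: tuple[float, float, float]

    def __post_init__(self):
        if any(e <= 0 for e in self.extent_um):
            raise MarrowError("volume extents must be positive")

    @property
    def depth_um(self) -> float:
        return self.extent_um[2]

    @property
    def area_mm2(self) -> float:
        """x–y projected marrow area in mm² (the per-mm² census denominator)."""
        return self.extent_um[0] * self.extent_um[1] / 1e6

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ext = np.asarray(self.extent_um)
        return np.all((pts >= 0.0) & (pts <= ext), axis=1)

    def endosteum_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance from points to the nearer endosteal plane (no radius term)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        y = pts[:, 1]
        return np.minimum(y, self.extent_um[1] - y)


@dataclass(frozen=True)
class VesselSegment:
    """Capsule segment: ordered polyline (µm), constant radius, vessel class."""

    id: int | str
    points: np.ndarray
    radius_um: float
    vclass: str  # "sinusoid" | "arteriole"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise SchemaError(f"segment {self.id}: polyline needs >= 2 3D points")
        if self.radius_um <= 0:
            raise SchemaError(f"segment {self.id}: radius must be positive")
        if self.vclass not in ("sinusoid", "arteriole"):
            raise SchemaError(f"segment {self.id}: bad vessel class {self.vclass!r}")
        object.__setattr__(self, "points", pts)

    @property
    def arc_length_um(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


def _node_key(p: np.ndarray) -> tuple:
    # Shared polyline endpoints are matched to 0.01 µm.
    return tuple(np.round(np.asarray(p, dtype=float), 2))


class VesselNetwork:
    """A set of capsule segments with derived junction topology."""

    def __init__(self, segments: Sequence[VesselSegment]):
        self.segments: list[VesselSegment] = list(segments)
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise SchemaError("duplicate vessel segment ids")
        self._cache: dict = {}

    def __len__(self) -> int:
        return len(self.segments)

    def of_class(self, vclass: str) -> list[VesselSegment]:
        return [s for s in self.segments if s.vclass == vclass]

    # -- topology ---------------------------------------------------------

    def _graph(self) -> nx.MultiGraph:
        if "graph" not in self._cache:
            g = nx.MultiGraph()
            for seg in self.segments:
                a, b = _node_key(seg.points[0]), _node_key(seg.points[-1])
                g.add_edge(a, b, key=seg.id, segment=seg)
            self._cache["graph"] = g
        return self._cache["graph"]

    def branch_points(self) -> list[tuple]:
        """Junctions where >= 2 lumens join a third (node degree >= 3)."""
        g = self._graph()
        return [n for n in g.nodes if g.degree(n) >= 3]

    def vessel_of_segment(self) -> dict:
        """Map segment id -> vessel id (segments merged through degree-2 joins)."""
        if "vessel_of_segment" in self._cache:
            return self._cache["vessel_of_segment"]
        g = self._graph()
        # Build a line graph over segments: two segments belong to the same
        # vessel iff they share a junction of degree exactly 2 (a lumen
        # continuation, not a branch).
        seg_graph = nx.Graph()
        seg_graph.add_nodes_from(s.id for s in self.segments)
        for node in g.nodes:
            if g.degree(node) == 2:
                incident = [k for _, _, k in g.edges(node, keys=True)]
                if len(incident) == 2 and incident[0] != incident[1]:
                    seg_graph.add_edge(incident[0], incident[1])
        mapping: dict = {}
        for vid, comp in enumerate(nx.connected_components(seg_graph)):
            for sid in sorted(comp, key=str):
                mapping[sid] = vid
        self._cache["vessel_of_segment"] = mapping
        return mapping

    # -- stacked capsule arrays for vectorised distance queries -----------

    def _stacked(self, vclass: str | None):
        key = ("stacked", vclass)
        if key not in self._cache:
            segs = self.segments if vclass is None else self.of_class(vclass)
            p0, p1, radii, seg_ids = [], [], [], []
            for seg in segs:
                pts = seg.points
                n = pts.shape[0] - 1
                p0.append(pts[:-1])
                p1.append(pts[1:])
                radii.append(np.full(n, seg.radius_um))
                seg_ids.extend([seg.id] * n)
            if p0:
                stacked = (
                    np.concatenate(p0),
                    np.concatenate(p1),
                    np.concatenate(radii),
                    np.asarray(seg_ids, dtype=object),
                )
            else:
                stacked = None
            self._cache[key] = stacked
        return self._cache[key]

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per polyline vertex."""
        rows = []
        for seg in self.segments:
            for i, (x, y, z) in enumerate(seg.points):
                rows.append((seg.id, seg.vclass, seg.radius_um, i, x, y, z))
        return pd.DataFrame(
            rows,
            columns=["segment_id", "vclass", "radius_um", "point_index",
                     "x_um", "y_um", "z_um"],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VesselNetwork":
        segs = []
        for sid, grp in frame.groupby("segment_id", sort=False):
            grp = grp.sort_values("point_index")
            segs.append(
                VesselSegment(
                    id=sid,
                    points=grp[["x_um", "y_um", "z_um"]].to_numpy(float),
                    radius_um=float(grp["radius_um"].iloc[0]),
                    vclass=str(grp["vclass"].iloc[0]),
                )
            )
        return cls(segs)


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def cells_dataframe(records: Iterable[CellRecord]) -> pd.DataFrame:
    """Materialise CellRecords as the canonical tidy cell table."""
    rows = [
        (r.id, r.cell_type, r.centre[0], r.centre[1], r.centre[2], r.radius,
         r.confetti)
        for r in records
    ]
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def _positions(cells: pd.DataFrame) -> np.ndarray:
    return cells[["x_um", "y_um", "z_um"]].to_numpy(float)


def _radii(cells: pd.DataFrame) -> np.ndarray:
    if "radius_um" in cells.columns and cells["radius_um"].notna().all():
        return cells["radius_um"].to_numpy(float)
    return np.asarray([mean_radius(t) for t in cells["cell_type"]], dtype=float)


# ---------------------------------------------------------------------------
# cell–cell distances
# ---------------------------------------------------------------------------

def gap_distance_cells(a: CellRecord, b: CellRecord) -> float:
    """Surface-to-surface gap: centre distance minus both radii (µm).

    Negative values (overlapping segmentations) are preserved.
    """
    if a.id == b.id:
        raise MarrowError(f"self-distance undefined (id {a.id!r})")
    d = float(np.linalg.norm(np.asarray(a.centre) - np.asarray(b.centre)))
    return d - a.radius - b.radius


def nearest_gap(
    sources: pd.DataFrame,
    targets: pd.DataFrame,
    exclude_same_id: bool = True,
) -> pd.DataFrame:
    """Per-source nearest-target gap distance.

    Exact for arbitrary per-cell radii: candidate neighbours are screened on
    centre distance with a kd-tree, expanded by the target radius spread so
    the radius-corrected minimum cannot be missed.
    """
    if len(targets) == 0:
        raise EmptyTargetError("no target cells")
    spos, tpos = _positions(sources), _positions(targets)
    srad, trad = _radii(sources), _radii(targets)
    tids = targets["id"].to_numpy()
    sids = sources["id"].to_numpy()

    if len(targets) <= 1500:
        # brute force, fully vectorised
        d = np.linalg.norm(spos[:, None, :] - tpos[None, :, :], axis=2)
        gaps = d - srad[:, None] - trad[None, :]
        if exclude_same_id:
            same = sids[:, None] == tids[None, :]
            gaps = np.where(same, np.inf, gaps)
        idx = np.argmin(gaps, axis=1)
        best = gaps[np.arange(len(sources)), idx]
    else:
        tree = cKDTree(tpos)
        spread = float(trad.max() - trad.min())
        k0 = 2 if exclude_same_id else 1
        k = min(len(targets), k0 + 8)
        dist, ind = tree.query(spos, k=k)
        dist, ind = np.atleast_2d(dist), np.atleast_2d(ind)
        best = np.full(len(sources), np.inf)
        idx = np.zeros(len(sources), dtype=int)
        for i in range(len(sources)):
            cand = ind[i]
            if spread > 0:
                # widen the candidate set so a larger-radius target slightly
                # farther in centre distance cannot be missed
                extra = tree.query_ball_point(spos[i], dist[i][-1] + spread)
                cand = np.unique(np.concatenate([cand, np.asarray(extra, int)]))
            g = (
                np.linalg.norm(tpos[cand] - spos[i], axis=1)
                - srad[i]
                - trad[cand]
            )
            if exclude_same_id:
                g = np.where(tids[cand] == sids[i], np.inf, g)
            j = int(np.argmin(g))
            best[i], idx[i] = g[j], cand[j]

    if not np.isfinite(best).all():
        raise EmptyTargetError("source had no admissible target (self only)")
    return pd.DataFrame(
        {"id": sids, "gap_um": best, "nearest_id": tids[idx]}
    )


def nearest_by_type(
    cells: pd.DataFrame, source_type: str, target_type: str
) -> pd.DataFrame:
    """Gap from every source-type cell to its nearest target-type cell.

    A source cell is never its own target (relevant when the types match).
    """
    src = cells[cells["cell_type"] == source_type]
    tgt = cells[cells["cell_type"] == target_type]
    if len(src) == 0:
        raise EmptyTargetError(f"no source cells of type {source_type!r}")
    if len(tgt) == 0 or (source_type == target_type and len(tgt) < 2):
        raise EmptyTargetError(f"no target cells of type {target_type!r}")
    out = nearest_gap(src, tgt, exclude_same_id=True)
    out.insert(1, "target", target_type)
    return out


# ---------------------------------------------------------------------------
# cell–vessel / endosteum distances
# ---------------------------------------------------------------------------

def _min_dist_to_capsules(
    points: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    radii: np.ndarray,
    chunk: int = 4096,
) -> tuple[np.ndarray, np.ndarray]:
    """Min over capsule sub-segments of (point-to-segment distance − radius).

    Returns (surface distance, index of the nearest sub-segment).
    """
    seg = p1 - p0
    seg_len2 = np.einsum("ij,ij->i", seg, seg)
    seg_len2 = np.where(seg_len2 == 0.0, 1.0, seg_len2)
    out_d = np.empty(points.shape[0])
    out_i = np.empty(points.shape[0], dtype=int)
    for lo in range(0, points.shape[0], chunk):
        pts = points[lo:lo + chunk]
        w = pts[:, None, :] - p0[None, :, :]
        t = np.clip(np.einsum("nmj,mj->nm", w, seg) / seg_len2[None, :], 0.0, 1.0)
        closest = p0[None, :, :] + t[:, :, None] * seg[None, :, :]
        d = np.linalg.norm(pts[:, None, :] - closest, axis=2) - radii[None, :]
        out_i[lo:lo + chunk] = np.argmin(d, axis=1)
        out_d[lo:lo + chunk] = d[np.arange(d.shape[0]), out_i[lo:lo + chunk]]
    return out_d, out_i


def distance_to_vessels(
    cells: pd.DataFrame, network: VesselNetwork, vclass: str | None
) -> pd.DataFrame:
    """Radius-corrected gap from each cell to the closest vessel of *vclass*.

    gap = min over segments of (point-to-polyline distance − vessel radius −
    cell radius); negative inside the lumen.
    """
    stacked = network._stacked(vclass)
    if stacked is None:
        raise EmptyTargetError(f"no vessel segments of class {vclass!r}")
    p0, p1, radii, seg_ids = stacked
    surf_d, idx = _min_dist_to_capsules(_positions(cells), p0, p1, radii)
    gap = surf_d - _radii(cells)
    return pd.DataFrame(
        {
            "id": cells["id"].to_numpy(),
            "target": vclass if vclass is not None else "vessel",
            "gap_um": gap,
            "nearest_id": seg_ids[idx],
        }
    )


def distance_to_vessel(
    cell: CellRecord, network: VesselNetwork, vclass: str | None
) -> DistanceResult:
    """Single-cell convenience wrapper around :func:`distance_to_vessels`."""
    table = distance_to_vessels(cells_dataframe([cell]), network, vclass)
    row = table.iloc[0]
    return DistanceResult(
        source_id=cell.id,
        target=str(row["target"]),
        gap_um=float(row["gap_um"]),
        nearest_id=row["nearest_id"],
    )


def distance_to_endosteum(cells: pd.DataFrame, volume: TissueVolume) -> pd.DataFrame:
    gap = volume.endosteum_distance(_positions(cells)) - _radii(cells)
    return pd.DataFrame(
        {
            "id": cells["id"].to_numpy(),
            "target": "endosteum",
            "gap_um": gap,
            "nearest_id": None,
        }
    )


# ---------------------------------------------------------------------------
# vessel morphometry
# ---------------------------------------------------------------------------

def measure_vessels(network: VesselNetwork) -> tuple[pd.DataFrame, int]:
    """Per-vessel length, diameter and the network branch count.

    A vessel is the continuous lumen between branch points: chains of
    segments joined at degree-2 junctions are merged.  Length is polyline arc
    length; the diameter reported is the largest (2 × radius) along the
    vessel.  Zero-length polylines are skipped with a warning.
    """
    mapping = network.vessel_of_segment()
    by_vessel: dict = {}
    for seg in network.segments:
        if seg.arc_length_um == 0.0:
            warnings.warn(
                f"segment {seg.id}: degenerate zero-length polyline skipped",
                stacklevel=2,
            )
            continue
        by_vessel.setdefault(mapping[seg.id], []).append(seg)
    rows = []
    for vid in sorted(by_vessel):
        segs = by_vessel[vid]
        rows.append(
            (
                vid,
                segs[0].vclass,
                sum(s.arc_length_um for s in segs),
                2.0 * max(s.radius_um for s in segs),
                len(segs),
            )
        )
    table = pd.DataFrame(
        rows, columns=["vessel_id", "vclass", "length_um", "diameter_um",
                       "n_segments"]
    )
    return table, len(network.branch_points())


# ---------------------------------------------------------------------------
# daughter-cell separation
# ---------------------------------------------------------------------------

#: Live-imaging separation threshold (µm): daughters farther apart than this
#: (strictly) are classified "separated".
SEPARATION_THRESHOLD_UM = 50.0


def _track_position(track: np.ndarray, t: float, nominal: float) -> np.ndarray:
    """Position at time t from a (frame, x, y, z) track.

    Linear interpolation is allowed only between adjacent frames (flanking
    samples at most one nominal frame interval apart); a gap in the track at
    t is missing data.
    """
    track = np.asarray(track, dtype=float)
    times = track[:, 0]
    if t < times.min() or t > times.max():
        raise MarrowError(f"track does not cover t={t}")
    exact = np.isclose(times, t)
    if exact.any():
        return track[np.argmax(exact), 1:4]
    below = times[times < t].max()
    above = times[times > t].min()
    if (above - below) > 1.5 * nominal:
        raise MarrowError(
            f"track gap at t={t}: flanking frames {below} and {above} are more "
            "than one frame apart"
        )
    w = (t - below) / (above - below)
    pa = track[np.argmax(np.isclose(times, below)), 1:4]
    pb = track[np.argmax(np.isclose(times, above)), 1:4]
    return (1.0 - w) * pa + w * pb


def daughter_separation(
    track_a: np.ndarray, track_b: np.ndarray, t_after_division: float
) -> tuple[float, bool]:
    """Centre-to-centre separation of two daughter tracks at a time point.

    Returns (separation µm, separated) where separated means strictly more
    than ``SEPARATION_THRESHOLD_UM``.
    """
    # the acquisition frame interval is shared by both daughters; a track
    # whose own sampling is coarser has dropped frames
    nominal = min(
        float(np.median(np.diff(np.unique(np.asarray(track)[:, 0]))))
        for track in (track_a, track_b)
    )
    pa = _track_position(track_a, t_after_division, nominal)
    pb = _track_position(track_b, t_after_division, nominal)
    sep = float(np.linalg.norm(pa - pb))
    return sep, sep > SEPARATION_THRESHOLD_UM
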