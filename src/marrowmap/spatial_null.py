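"""Empirical random-placement null for niche enrichment/depletion calls.

The null is built from the data, not from a parametric point process: the
candidate locations are the positions of *all* segmented haematopoietic
cells in the analysed window (the "pool", tens of thousands of positions per
35-µm optical slice).  For each replicate, pseudo-cells of each type are
drawn from the pool at the observed per-type frequencies, given the type's
catalogue radius, and pushed through the identical radius-corrected distance
code path as the observed cells.  Repeating this 100–200 times yields the
null distance distribution against which observed distributions are tested.

The Confetti variant permutes colour labels over fixed coordinates,
preserving per-colour counts, to null out clonal spatial structure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .catalog import mean_radius
from .errors import DegenerateDataError, EmptyTargetError, MarrowError
from .geometry import (
    TissueVolume,
    VesselNetwork,
    distance_to_endosteum,
    distance_to_vessels,
    nearest_gap,
)
from .stats import TestResult, dispatch_two_sample

__all__ = [
    "PointPool",
    "NullDistribution",
    "EnrichmentResult",
    "AnalysisContext",
    "build_pool",
    "sample_random_cells",
    "distances_to_target",
    "null_distances",
    "compare_to_null",
    "shuffle_confetti_null",
    "same_colour_nn_statistic",
    "DEFAULT_N_REPS",
]

#: Midpoint of the 100–200 replicate range used for the random simulations.
DEFAULT_N_REPS = 150

#: Plausible per-slice haematopoietic cell counts; sizes outside are logged.
PLAUSIBLE_POOL_RANGE = (48_964, 81_248)


@dataclass(frozen=True)
class PointPool:
    """Candidate locations for random pseudo-cells (all haematopoietic)."""

    positions: np.ndarray   # (n, 3) µm
    ids: np.ndarray

    @property
    def size(self) -> int:
        return int(self.positions.shape[0])


@dataclass
class NullDistribution:
    """Per-replicate distance samples from random-placement resampling."""

    target: str
    n_reps: int
    seed: int | None
    samples: list[np.ndarray] = field(default_factory=list)

    @property
    def medians(self) -> np.ndarray:
        return np.asarray([np.median(s) for s in self.samples])

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.samples) if self.samples else np.array([])


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed-vs-null comparison and the resulting localisation call."""

    target: str
    observed_median: float
    null_median: float
    test: TestResult
    call: str   # "enriched" (closer) | "depleted" (farther) | "ns" | "insufficient-data"


@dataclass
class AnalysisContext:
    """Everything a distance query needs: cells, vessels, volume."""

    cells: pd.DataFrame
    vessels: VesselNetwork | None = None
    volume: TissueVolume | None = None


def build_pool(cells: pd.DataFrame) -> PointPool:
    """All segmented cell positions as candidate random-cell locations.

    The pool is type-agnostic: every haematopoietic position is a candidate
    regardless of its classified type.
    """
    if len(cells) == 0:
        raise MarrowError("cannot build a point pool from an empty cell table")
    pool = PointPool(
        positions=cells[["x_um", "y_um", "z_um"]].to_numpy(float),
        ids=cells["id"].to_numpy(),
    )
    lo, hi = PLAUSIBLE_POOL_RANGE
    if not (lo <= pool.size <= hi):
        warnings.warn(
            f"pool size {pool.size} outside the plausible per-slice range "
            f"[{lo}, {hi}]", stacklevel=2,
        )
    return pool


def sample_random_cells(
    pool: PointPool,
    counts_by_type: dict[str, int],
    n_reps: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[pd.DataFrame]:
    """Replicated pseudo-cell sets drawn from the pool.

    Within one replicate, positions are drawn *without* replacement (a
    random cell set should not contain duplicated positions) at the observed
    per-type counts; draws are independent across replicates.  Pseudo-cells
    receive the catalogue mean radius of their type and negative ids so they
    can never collide with observed cell ids.
    """
    total = sum(counts_by_type.values())
    if total > pool.size:
        raise MarrowError(
            f"requested {total} pseudo-cells but pool holds {pool.size}"
        )
    rng = rng if rng is not None else np.random.default_rng(seed)
    replicates = []
    for _rep in range(n_reps):
        chosen = rng.choice(pool.size, size=total, replace=False)
        rows = []
        k = 0
        for cell_type, count in counts_by_type.items():
            r = mean_radius(cell_type)
            for _ in range(int(count)):
                p = pool.positions[chosen[k]]
                rows.append((-(k + 1), cell_type, p[0], p[1], p[2], r, "none"))
                k += 1
        replicates.append(
            pd.DataFrame(
                rows,
                columns=["id", "cell_type", "x_um", "y_um", "z_um",
                         "radius_um", "confetti"],
            )
        )
    return replicates


def distances_to_target(
    cells: pd.DataFrame, target: str, context: AnalysisContext
) -> np.ndarray:
    """Gap distances from each cell to the named target class.

    ``target`` is a vessel class (``sinusoid``/``arteriole``), ``endosteum``,
    ``MK``, or ``type:<cell type>``.  Observed and null cells use this single
    code path, so there is no parallel implementation to drift.
    """
    if target in ("sinusoid", "arteriole"):
        if context.vessels is None:
            raise EmptyTargetError("no vessel network in context")
        return distance_to_vessels(cells, context.vessels, target)["gap_um"].to_numpy()
    if target == "endosteum":
        if context.volume is None:
            raise EmptyTargetError("no tissue volume in context")
        return distance_to_endosteum(cells, context.volume)["gap_um"].to_numpy()
    if target == "MK" or target.startswith("type:"):
        type_name = "MK" if target == "MK" else target.split(":", 1)[1]
        targets = context.cells[context.cells["cell_type"] == type_name]
        if len(targets) == 0:
            raise EmptyTargetError(f"no cells of type {type_name!r} in context")
        return nearest_gap(cells, targets, exclude_same_id=True)["gap_um"].to_numpy()
    raise MarrowError(f"unknown target descriptor {target!r}")


def null_distances(
    replicates: Sequence[pd.DataFrame],
    target: str,
    context: AnalysisContext,
    seed: int | None = None,
) -> NullDistribution:
    """Distance distribution of the pseudo-cell replicates to a target."""
    null = NullDistribution(target=target, n_reps=len(replicates), seed=seed)
    for rep in replicates:
        null.samples.append(distances_to_target(rep, target, context))
    return null


def compare_to_null(
    observed: np.ndarray | pd.DataFrame,
    null: NullDistribution,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Classify a cell type as enriched near / depleted from a target.

    The pooled observed gaps are tested against the pooled null gaps with
    the normality-gated two-sample dispatch; "enriched" means significantly
    *closer* than random cells (observed median below the null median),
    "depleted" significantly farther.  Replicate medians remain available on
    the null object for diagnostics.
    """
    if isinstance(observed, pd.DataFrame):
        observed = observed["gap_um"].to_numpy()
    observed = np.asarray(observed, dtype=float)
    pooled = null.pooled()
    obs_median = float(np.median(observed)) if observed.size else float("nan")
    null_median = float(np.median(pooled)) if pooled.size else float("nan")
    if observed.size < 3:
        return EnrichmentResult(
            target=null.target,
            observed_median=obs_median,
            null_median=null_median,
            test=TestResult("insufficient-data", float("nan"), float("nan"),
                            observed.size, pooled.size, None, None),
            call="insufficient-data",
        )
    test = dispatch_two_sample(observed, pooled)
    if test.p is not None and test.p <= alpha:
        call = "enriched" if obs_median < null_median else "depleted"
    else:
        call = "ns"
    return EnrichmentResult(
        target=null.target,
        observed_median=obs_median,
        null_median=null_median,
        test=test,
        call=call,
    )


# ---------------------------------------------------------------------------
# Confetti label permutation null
# ---------------------------------------------------------------------------

def same_colour_nn_statistic(cells: pd.DataFrame) -> float:
    """Median gap from each labelled cell to its nearest same-colour cell."""
    labelled = cells[cells["confetti"] != "none"]
    gaps = []
    for _colour, grp in labelled.groupby("confetti"):
        if len(grp) < 2:
            continue
        gaps.append(nearest_gap(grp, grp, exclude_same_id=True)["gap_um"].to_numpy())
    if not gaps:
        raise DegenerateDataError("no colour with >= 2 labelled cells")
    return float(np.median(np.concatenate(gaps)))


def _distinct_arrangements(colours: tuple) -> list[tuple]:
    """All distinct orderings of a colour multiset (each equally likely
    under uniform random permutation)."""
    return sorted(set(itertools.permutations(colours)))


def shuffle_confetti_null(
    cells: pd.DataFrame,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
    statistic: Callable[[pd.DataFrame], float] = same_colour_nn_statistic,
    exact: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Null distribution of a colour statistic under label permutation.

    Colours are permuted over the fixed cell coordinates, preserving the
    per-colour counts exactly in every replicate.  With ``exact=True`` all
    distinct colour arrangements are enumerated instead of sampled (feasible
    for small toys) and the returned array holds one statistic per
    arrangement.
    """
    labelled_mask = cells["confetti"] != "none"
    if int(labelled_mask.sum()) < 2:
        raise DegenerateDataError("need >= 2 labelled cells to shuffle")
    colours = tuple(cells["confetti"])
    observed_counts = pd.Series(colours).value_counts()
    if len(observed_counts[observed_counts.index != "none"]) < 2:
        warnings.warn(
            "single Confetti colour present: shuffle statistic is constant "
            "(degenerate null)", stacklevel=2,
        )

    def _stat_for(arrangement) -> float:
        permuted = cells.copy()
        permuted["confetti"] = list(arrangement)
        counts = pd.Series(arrangement).value_counts()
        assert counts.equals(observed_counts.reindex(counts.index)), (
            "permutation changed per-colour counts"
        )
        return statistic(permuted)

    if exact:
        return np.asarray(
            [_stat_for(arr) for arr in _distinct_arrangements(colours)]
        )
    rng = rng if rng is not None else np.random.default_rng(seed)
    out = np.empty(n_reps)
    arr = np.asarray(colours, dtype=object)
    for i in range(n_reps):
        out[i] = _stat_for(arr[rng.permutation(len(arr))])
    return out
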