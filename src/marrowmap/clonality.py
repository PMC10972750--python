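"""Confetti-based clonal analysis.

The Confetti reporter stochastically and irreversibly labels cells in one of
four colours (GFP/YFP/RFP/CFP); a shared colour proxies shared clonal
origin.  Because the imaging dump channel shares the GFP band, cells with
green fluorescence are discarded before any clonal analysis and only
YFP/RFP/CFP cells are compared.

Site clonality: a site is *monoclonal* when its ≥ 2 labelled (non-green)
members all carry one colour, *oligoclonal* when they span ≥ 2 colours, and
*unlabelled* when 0–1 members carry a label (a single labelled cell carries
no clonal information).

The same-colour distance test asks whether progeny sharing a focal
progenitor's colour sit closer to it than label-randomised cells: colours
are permuted over fixed coordinates (preserving per-colour counts) and the
observed statistic is ranked two-sidedly within the permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError
from .geometry import nearest_gap
from .spatial_null import DEFAULT_N_REPS, shuffle_confetti_null

__all__ = [
    "ClonalityResult",
    "SameColourTestResult",
    "filter_dump_channel",
    "classify_site_clonality",
    "same_colour_distance_test",
]

ANALYSIS_COLOURS = ("YFP", "RFP", "CFP")


@dataclass(frozen=True)
class ClonalityResult:
    site_id: str
    colour_counts: dict
    classification: str   # "monoclonal" | "oligoclonal" | "unlabelled"
    n_labelled: int


@dataclass(frozen=True)
class SameColourTestResult:
    statistic: float | None   # median same-colour progeny→focal gap (µm)
    p: float | None
    n_null: int
    n_pairs: int
    test: str                 # "permutation" | "exact-permutation" | "no-test"


def filter_dump_channel(cells: pd.DataFrame) -> pd.DataFrame:
    """Discard green-fluorescent cells (GFP shares the dump channel).

    YFP/RFP/CFP-labelled and unlabelled cells are retained unchanged.
    """
    if "confetti" not in cells.columns:
        raise SchemaError("cell table has no 'confetti' colour column")
    return cells[cells["confetti"] != "GFP"].copy()


def _member_ids(site) -> tuple[str, list]:
    """Accept a ProductionSite, a truth-site dict, or a bare id list."""
    if hasattr(site, "member_ids"):
        return site.site_id, list(site.member_ids)
    if isinstance(site, dict):
        ids = [cid for ids in site["members"].values() for cid in ids]
        return site.get("site_id", "?"), ids
    return "?", list(site)


def classify_site_clonality(site, cells: pd.DataFrame) -> ClonalityResult:
    """Colour composition and clonality class of one production site."""
    site_id, ids = _member_ids(site)
    members = cells[cells["id"].isin(ids)]
    labelled = members[members["confetti"].isin(ANALYSIS_COLOURS)]
    counts = labelled["confetti"].value_counts().to_dict()
    n = int(len(labelled))
    if n <= 1:
        cls = "unlabelled"
    elif len(counts) == 1:
        cls = "monoclonal"
    else:
        cls = "oligoclonal"
    return ClonalityResult(
        site_id=site_id, colour_counts=counts, classification=cls, n_labelled=n
    )


def _same_colour_progeny_statistic(focal_type: str, progeny_type: str):
    def statistic(cells: pd.DataFrame) -> float:
        focals = cells[
            (cells["cell_type"] == focal_type)
            & cells["confetti"].isin(ANALYSIS_COLOURS)
        ]
        gaps = []
        for colour, grp in focals.groupby("confetti"):
            progeny = cells[
                (cells["cell_type"] == progeny_type)
                & (cells["confetti"] == colour)
            ]
            if len(progeny) == 0:
                continue
            gaps.append(
                nearest_gap(progeny, grp, exclude_same_id=True)["gap_um"].to_numpy()
            )
        if not gaps:
            return np.nan
        return float(np.median(np.concatenate(gaps)))
    return statistic


def same_colour_distance_test(
    cells: pd.DataFrame,
    focal_type: str,
    progeny_type: str,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
    exact: bool = False,
) -> SameColourTestResult:
    """Do same-colour progeny map closer to their focal cell than chance?

    The statistic is the median gap from each progeny cell to the nearest
    focal cell of its own colour, after dump-channel filtering.  The null
    permutes the Confetti labels over the fixed coordinates of the focal and
    progeny cells; the two-sided p-value is the permutation rank with the
    add-one correction (so p is never exactly 0), or the exact enumeration
    fraction when ``exact=True``.
    """
    pool = filter_dump_channel(
        cells[cells["cell_type"].isin([focal_type, progeny_type])]
    )
    statistic = _same_colour_progeny_statistic(focal_type, progeny_type)
    n_focal = int(
        ((pool["cell_type"] == focal_type)
         & pool["confetti"].isin(ANALYSIS_COLOURS)).sum()
    )
    n_progeny = int(
        ((pool["cell_type"] == progeny_type)
         & pool["confetti"].isin(ANALYSIS_COLOURS)).sum()
    )
    labelled_colours = set(pool.loc[pool["confetti"] != "none", "confetti"])
    if n_focal < 1 or n_progeny < 2 or len(labelled_colours) < 2:
        return SameColourTestResult(None, None, 0, 0, "no-test")
    observed = statistic(pool)
    if np.isnan(observed):
        return SameColourTestResult(None, None, 0, 0, "no-test")
    null = shuffle_confetti_null(
        pool, n_reps=n_reps, seed=seed, statistic=statistic, exact=exact
    )
    null = null[~np.isnan(null)]
    if exact:
        n = null.size
        p = 2.0 * min(
            float(np.sum(null <= observed)) / n,
            float(np.sum(null >= observed)) / n,
        )
        name = "exact-permutation"
    else:
        n = null.size
        p = 2.0 * min(
            (float(np.sum(null <= observed)) + 1.0) / (n + 1.0),
            (float(np.sum(null >= observed)) + 1.0) / (n + 1.0),
        )
        name = "permutation"
    return SameColourTestResult(
        statistic=observed,
        p=min(1.0, p),
        n_null=int(n),
        n_pairs=n_progeny,
        test=name,
    )
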