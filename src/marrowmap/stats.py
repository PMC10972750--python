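"""Statistical procedures used throughout the pipeline.

Two-sample comparisons follow a normality-gated dispatch: an unpaired
two-tailed Student's t-test when both samples look normal (Shapiro–Wilk at
α = 0.05), a two-tailed Mann–Whitney test otherwise.  Proportions from two
groups are compared with a Pearson chi-square on the 2×2 table with Yates
continuity correction (df = 1).  The marker screen encodes the imaging
panel selection rule: a surface marker is useful only if it is uniformly
expressed in at least one HSPC type at ≥ 10³ fluorescence over background
while being absent from at least one other type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, MarrowError

__all__ = [
    "TestResult",
    "dispatch_two_sample",
    "chi_square_two_proportions",
    "marker_screen",
    "MARKER_THRESHOLD",
]

#: Minimum absolute fluorescence over background for reliable imaging.
MARKER_THRESHOLD = 1e3

#: Positive-fraction bounds operationalising "uniformly expressed"/"absent".
UNIFORM_POSITIVE_FRACTION = 0.9
ABSENT_FRACTION = 0.1


@dataclass(frozen=True)
class TestResult:
    test: str            # "t" | "mann-whitney" | "chi-square-yates" | ...
    statistic: float
    p: float | None
    n_x: int
    n_y: int
    normal_x: bool | None = None
    normal_y: bool | None = None


def _is_normal(sample: np.ndarray, alpha: float) -> bool:
    if np.ptp(sample) == 0:
        return False  # constant data: Shapiro undefined, clearly non-normal path
    return bool(sps.shapiro(sample).pvalue > alpha)


def dispatch_two_sample(
    x, y, alpha_norm: float = 0.05
) -> TestResult:
    """Normality-gated two-sample test dispatch.

    Both samples normal (Shapiro–Wilk at ``alpha_norm``) → two-tailed
    unpaired Student's t; otherwise two-tailed Mann–Whitney.  Fewer than 3
    observations in either sample yields an insufficient-data result rather
    than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        return TestResult("insufficient-data", float("nan"), None,
                          x.size, y.size)
    nx_ok = _is_normal(x, alpha_norm)
    ny_ok = _is_normal(y, alpha_norm)
    if nx_ok and ny_ok:
        res = sps.ttest_ind(x, y, equal_var=True)
        return TestResult("t", float(res.statistic), float(res.pvalue),
                          x.size, y.size, nx_ok, ny_ok)
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return TestResult("mann-whitney", float(res.statistic), float(res.pvalue),
                      x.size, y.size, nx_ok, ny_ok)


def chi_square_two_proportions(
    successes_a: int,
    n_a: int,
    successes_b: int,
    n_b: int,
    continuity: bool = True,
) -> TestResult:
    """Compare two proportions via chi-square on the 2×2 table (df = 1).

    Yates continuity correction is applied by default.  An empty row or
    column margin makes the table degenerate.
    """
    if n_a < 1 or n_b < 1:
        raise DegenerateDataError("each group needs at least one trial")
    if not (0 <= successes_a <= n_a and 0 <= successes_b <= n_b):
        raise MarrowError("successes must be between 0 and n")
    table = np.array(
        [[successes_a, n_a - successes_a], [successes_b, n_b - successes_b]],
        dtype=float,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateDataError("degenerate 2x2 table: empty margin")
    res = sps.chi2_contingency(table, correction=continuity)
    name = "chi-square-yates" if continuity else "chi-square"
    return TestResult(name, float(res.statistic), float(res.pvalue),
                      int(n_a), int(n_b))


def marker_screen(
    profiles: pd.DataFrame,
    threshold: float = MARKER_THRESHOLD,
    uniform_fraction: float = UNIFORM_POSITIVE_FRACTION,
    absent_fraction: float = ABSENT_FRACTION,
) -> pd.DataFrame:
    """Select imaging-suitable surface markers from an expression panel.

    ``profiles`` has one row per (marker, cell_type) with columns
    ``positive_fraction`` (fraction of events above background),
    ``median_signal`` and ``background``.  Per type the call is:

    * ``uniform-positive`` — positive fraction ≥ ``uniform_fraction`` and
      median signal at least ``threshold`` over background (inclusive);
    * ``absent`` — positive fraction ≤ ``absent_fraction``;
    * ``heterogeneous`` — anything else.

    A marker is selected iff at least one type is uniform-positive and at
    least one type is absent.  Returns the profile table with a ``call``
    column and a boolean ``selected`` per marker (broadcast).
    """
    required = {"marker", "cell_type", "positive_fraction", "median_signal",
                "background"}
    if not required.issubset(profiles.columns):
        raise MarrowError(f"marker profile table needs columns {sorted(required)}")
    if profiles["cell_type"].nunique() < 2:
        raise DegenerateDataError(
            "marker screen undefined with a single HSPC type"
        )
    out = profiles.copy()
    over_bg = out["median_signal"] - out["background"]
    call = np.where(
        (out["positive_fraction"] >= uniform_fraction) & (over_bg >= threshold),
        "uniform-positive",
        np.where(out["positive_fraction"] <= absent_fraction, "absent",
                 "heterogeneous"),
    )
    out["call"] = call
    selected = (
        out.groupby("marker")["call"]
        .apply(lambda c: ("uniform-positive" in set(c)) and ("absent" in set(c)))
    )
    out["selected"] = out["marker"].map(selected)
    return out
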