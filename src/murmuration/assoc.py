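"""Classical inferential battery for murmuration records.

Pearson correlation (size vs duration, reporting lag vs either), pooled
independent t-tests (UK vs non-UK comparisons), one-way ANOVA (habitat
effects), and the terminal-behaviour contingency analysis: whether a
murmuration ends with all birds descending en masse to roost, rather than
dispersing, more often when a bird of prey is present.

Corvids and gulls are recorded because their silhouettes can be mistaken
for a predator at dusk, and they enter the regression designs on that
basis — but they are never counted as "bird of prey present" in the
terminal-behaviour table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from murmuration.errors import InsufficientDataError
from murmuration.records import MurmurationRecord
from murmuration.taxa import RAPTOR_SPECIES

__all__ = [
    "ContingencyTable",
    "pearson",
    "independent_t_test",
    "one_way_anova",
    "chi_square_association",
    "terminal_behaviour_table",
]

#: Default ending categories for the terminal-behaviour table. "other"
#: collects partial roosting / flock splitting so the table is 2×3.
DEFAULT_ENDING_CATEGORIES = ("roost_en_masse", "dispersed", "other")


@dataclass(frozen=True)
class ContingencyTable:
    """An r×c table of non-negative counts with labelled margins."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        for row in self.counts:
            if len(row) != len(self.col_labels):
                raise ValueError("ragged contingency table")
            if any(c < 0 for c in row):
                raise ValueError("negative cell count")
        if len(self.counts) != len(self.row_labels):
            raise ValueError("row label / count mismatch")
        if self.grand_total == 0:
            raise ValueError("empty contingency table")

    @property
    def grand_total(self) -> int:
        return sum(sum(row) for row in self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [list(r) for r in self.counts],
            index=list(self.row_labels),
            columns=list(self.col_labels),
        )


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Pearson correlation with a two-sided p from the t transform.

    Returns ``(r, n, p)``; requires equal lengths of at least 3 and
    non-degenerate variance on both sides.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise InsufficientDataError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), int(x.size), float(res.pvalue)


def independent_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Two-sample t-test, pooled-variance form; ``df = n_a + n_b - 2``.

    With zero pooled variance the statistic is 0 for equal means and
    signed infinity otherwise. A Welch variant is available via
    ``scipy.stats.ttest_ind(equal_var=False)`` for sensitivity checks.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    df = a.size + b.size - 2
    pooled = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / df
    if pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def one_way_anova(groups: Iterable[Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way ANOVA across two or more groups.

    Empty groups are dropped with a warning. Returns ``(F, df1, df2, p)``
    with ``df1 = k - 1`` and ``df2 = n - k``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    kept = [g for g in arrays if g.size > 0]
    if len(kept) < len(arrays):
        warnings.warn(f"dropped {len(arrays) - len(kept)} empty group(s)", stacklevel=2)
    if len(kept) < 2:
        raise InsufficientDataError("need at least 2 non-empty groups")
    n = sum(g.size for g in kept)
    k = len(kept)
    if n <= k:
        raise InsufficientDataError("total n must exceed the number of groups")
    res = stats.f_oneway(*kept)
    f = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(f):  # all values identical -> zero between and within variance
        f, p = 0.0, 1.0
    return f, k - 1, n - k, p


def chi_square_association(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of association, no continuity correction.

    ``df = (rows - 1) · (cols - 1)``. A warning is issued when any
    expected count falls below 5; a zero row or column margin makes the
    expected counts degenerate and raises.
    """
    obs = np.asarray(table.counts, dtype=float)
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: a zero row or column margin")
    x2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    if (expected < 5).any():
        warnings.warn("some expected cell counts are below 5", stacklevel=2)
    return float(x2), int(df), float(p)


def _raptor_present(rec: MurmurationRecord) -> bool:
    return any(rec.activity_of(sp) != "absent" for sp in RAPTOR_SPECIES)


def terminal_behaviour_table(
    records: Iterable[MurmurationRecord],
    ending_categories: Sequence[str] = DEFAULT_ENDING_CATEGORIES,
) -> ContingencyTable:
    """Cross-tabulate raptor presence against how the murmuration ended.

    Only records where the end of the event was witnessed are counted.
    Rows are bird-of-prey present/absent (corvids and gulls never count
    as present); columns are the configured ending categories, with any
    ending not named in *ending_categories* folded into the last category
    when it is ``"other"``.
    """
    counts = {
        (present, cat): 0 for present in (True, False) for cat in ending_categories
    }
    for rec in records:
        if not rec.end_seen or rec.ending == "unknown":
            continue
        cat = rec.ending
        if cat not in ending_categories:
            if "other" in ending_categories:
                cat = "other"
            else:
                continue
        counts[(_raptor_present(rec), cat)] += 1
    return ContingencyTable(
        row_labels=("raptor_present", "raptor_absent"),
        col_labels=tuple(ending_categories),
        counts=(
            tuple(counts[(True, c)] for c in ending_categories),
            tuple(counts[(False, c)] for c in ending_categories),
        ),
    )
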