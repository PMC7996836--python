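"""Extreme-group cohort selection from stress questionnaire scores.

Participants answer four stress-related items: neuroticism (five-factor
personality model), worries and tension (Perceived Stress Questionnaire), and
trait anxiety (STAI).  The selection is an extreme-group design: compute the
two-sided 95% t-confidence interval of the cohort mean for each item, then
keep participants whose scores fall strictly below the lower bound on *all
four* items (LOW group) or strictly above the upper bound on all four (HIGH
group).  The larger group is then reduced to the size of the smaller one by
choosing the subset whose z-scored questionnaire vectors are mutually closest
in Euclidean distance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import CohortError

__all__ = [
    "ITEM_NAMES",
    "QuestionnaireTable",
    "CIBound",
    "CohortSelection",
    "drop_missing",
    "item_ci",
    "select_extremes",
    "balance_groups",
    "filter_rows",
]

#: The four stress-related questionnaire items, in canonical column order.
ITEM_NAMES: tuple[str, ...] = ("neuroticism", "worries", "tension", "stai_trait")

#: Exhaustive subset search is used when the number of candidate subsets is
#: at most this; larger instances fall back to greedy best-first growth.
EXHAUSTIVE_LIMIT = 10**6


@dataclass(frozen=True)
class QuestionnaireTable:
    """Participants x 4 item scores, with optional metadata columns.

    ``data`` is indexed by unique participant id and must contain the four
    item columns of :data:`ITEM_NAMES`; extra columns (age group, sex, ...)
    are carried along untouched.  Missing responses are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ITEM_NAMES if c not in df.columns]
        if missing:
            raise CohortError(f"questionnaire table missing item columns: {missing}")
        if not df.index.is_unique:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise CohortError(f"duplicate participant ids: {dupes}")
        object.__setattr__(self, "data", df)

    @property
    def participant_ids(self) -> list:
        return list(self.data.index)

    @property
    def scores(self) -> pd.DataFrame:
        """The participants x 4 item-score block, in canonical item order."""
        return self.data[list(ITEM_NAMES)]

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path, id_column: str = "participant_id") -> "QuestionnaireTable":
        df = pd.read_csv(path)
        if id_column not in df.columns:
            raise CohortError(f"{path}: missing id column {id_column!r}")
        return cls(df.set_index(id_column))

    def to_csv(self, path, id_column: str = "participant_id") -> None:
        self.data.rename_axis(id_column).to_csv(path)


class CIBound(NamedTuple):
    """Two-sided confidence interval of an item mean."""

    lower: float
    upper: float
    degenerate: bool = False


@dataclass(frozen=True)
class CohortSelection:
    """Result of extreme-group selection and (optionally) balancing."""

    ci_bounds: dict[str, CIBound]
    high_ids: tuple
    low_ids: tuple
    balanced_high_ids: tuple = ()
    balanced_low_ids: tuple = ()
    n_excluded_missing: int = 0
    balance_objective: float | None = None

    def __post_init__(self) -> None:
        if not set(self.balanced_high_ids) <= set(self.high_ids):
            raise CohortError("balanced HIGH set is not a subset of the HIGH set")
        if not set(self.balanced_low_ids) <= set(self.low_ids):
            raise CohortError("balanced LOW set is not a subset of the LOW set")

    def to_dict(self) -> dict:
        return {
            "ci_bounds": {
                k: {"lower": b.lower, "upper": b.upper, "degenerate": b.degenerate}
                for k, b in self.ci_bounds.items()
            },
            "high_ids": list(self.high_ids),
            "low_ids": list(self.low_ids),
            "balanced_high_ids": list(self.balanced_high_ids),
            "balanced_low_ids": list(self.balanced_low_ids),
            "n_excluded_missing": self.n_excluded_missing,
            "balance_objective": self.balance_objective,
        }


def drop_missing(table: QuestionnaireTable) -> tuple[QuestionnaireTable, int]:
    """Remove participants missing any of the four item responses."""
    complete = table.scores.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if complete.sum() == 0:
        raise CohortError("every participant is missing at least one item response")
    return QuestionnaireTable(table.data.loc[complete]), n_dropped


def item_ci(scores, level: float = 0.95) -> CIBound:
    """Two-sided t-based confidence interval of the mean of one item.

    ``mean +/- t_{(1+level)/2, n-1} * sd / sqrt(n)``.  Zero-variance input
    yields a degenerate interval (lower = upper = mean) with a flag.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 3:
        raise CohortError(f"confidence interval needs >= 3 finite scores, got {n}")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return CIBound(mean, mean, degenerate=True)
    half = stats.t.ppf(0.5 + level / 2, n - 1) * sd / np.sqrt(n)
    return CIBound(mean - half, mean + half)


def select_extremes(
    table: QuestionnaireTable, level: float = 0.95, n_excluded_missing: int = 0
) -> CohortSelection:
    """Identify HIGH and LOW extreme groups against per-item CI bounds.

    LOW: strictly below the lower CI bound on all four items; HIGH: strictly
    above the upper bound on all four.  The two sets are disjoint by
    construction; either may be empty.
    """
    scores = table.scores
    if scores.isna().any().any():
        raise CohortError("table has missing responses; run drop_missing first")
    bounds = {item: item_ci(scores[item], level) for item in ITEM_NAMES}
    lower = np.array([bounds[i].lower for i in ITEM_NAMES])
    upper = np.array([bounds[i].upper for i in ITEM_NAMES])
    values = scores.to_numpy(dtype=float)
    high_mask = (values > upper).all(axis=1)
    low_mask = (values < lower).all(axis=1)
    ids = np.array(table.participant_ids, dtype=object)
    return CohortSelection(
        ci_bounds=bounds,
        high_ids=tuple(ids[high_mask]),
        low_ids=tuple(ids[low_mask]),
        n_excluded_missing=n_excluded_missing,
    )


def _subset_objective(dist: np.ndarray, idx: tuple, objective: str) -> float:
    sub = dist[np.ix_(idx, idx)]
    if objective == "sum":
        return float(sub.sum() / 2.0)
    if objective == "max":
        return float(sub.max())
    raise CohortError(f"unknown balance objective {objective!r}")


def _centroid_objective(z: np.ndarray, idx: tuple) -> float:
    sub = z[list(idx)]
    centroid = sub.mean(axis=0)
    return float(np.linalg.norm(sub - centroid, axis=1).sum())


def _best_subset(
    z: np.ndarray, dist: np.ndarray, k: int, objective: str
) -> tuple[tuple, float]:
    n = len(dist)
    if objective == "centroid":
        score = lambda idx: _centroid_objective(z, idx)
    else:
        score = lambda idx: _subset_objective(dist, idx, objective)
    if comb(n, k) <= EXHAUSTIVE_LIMIT:
        best, best_val = None, np.inf
        for idx in itertools.combinations(range(n), k):
            val = score(idx)
            if val < best_val:  # strict: first (id-ordered) subset wins ties
                best, best_val = idx, val
        return best, best_val
    # greedy best-first from the medoid
    current = [int(np.argmin(dist.sum(axis=0)))]
    while len(current) < k:
        best_j, best_val = None, np.inf
        for j in range(n):
            if j in current:
                continue
            val = score(tuple(current + [j]))
            if val < best_val:
                best_j, best_val = j, val
        current.append(best_j)
    return tuple(sorted(current)), score(tuple(current))


def balance_groups(
    table: QuestionnaireTable,
    selection: CohortSelection,
    k: int | None = None,
    objective: str = "sum",
) -> CohortSelection:
    """Reduce the larger extreme group to ``k`` mutually-closest members.

    The larger group's 4-item vectors are z-scored per item (that group's own
    mean/sd, to put items on a common scale), all-pair Euclidean distances
    computed, and the size-``k`` subset minimizing the chosen within-subset
    objective selected (``sum`` of pairwise distances by default; ``max`` and
    ``centroid`` are alternatives).  The search is exhaustive whenever
    ``C(n, k) <= 10**6``, else greedy best-first from the medoid.  Candidate
    subsets are scanned in participant-id order, so ties resolve to the
    earliest ids.  The smaller group passes through unchanged.
    """
    high, low = list(selection.high_ids), list(selection.low_ids)
    if k is None:
        k = min(len(high), len(low))
    if k <= 0:
        raise CohortError(f"balance size k must be positive, got {k}")
    larger, smaller = (high, low) if len(high) >= len(low) else (low, high)
    if k > len(larger):
        raise CohortError(
            f"cannot balance to k={k}: larger group has only {len(larger)} members"
        )
    if k < len(smaller):
        raise CohortError(
            f"k={k} is below the smaller group size {len(smaller)}; "
            "the smaller group is never reduced"
        )
    larger_sorted = sorted(larger, key=str)
    if len(larger) == k:
        chosen, obj = tuple(larger_sorted), None
    else:
        vectors = table.scores.loc[larger_sorted].to_numpy(dtype=float)
        sd = vectors.std(axis=0, ddof=0)
        sd[sd == 0.0] = 1.0  # constant item: centering suffices
        z = (vectors - vectors.mean(axis=0)) / sd
        dist = np.linalg.norm(z[:, None, :] - z[None, :, :], axis=-1)
        idx, obj = _best_subset(z, dist, k, objective)
        chosen = tuple(larger_sorted[i] for i in idx)
    if larger is high:
        bal_high, bal_low = chosen, tuple(sorted(smaller, key=str))
    else:
        bal_high, bal_low = tuple(sorted(smaller, key=str)), chosen
    return CohortSelection(
        ci_bounds=selection.ci_bounds,
        high_ids=selection.high_ids,
        low_ids=selection.low_ids,
        balanced_high_ids=bal_high,
        balanced_low_ids=bal_low,
        n_excluded_missing=selection.n_excluded_missing,
        balance_objective=obj,
    )


def filter_rows(table: QuestionnaireTable, mask) -> QuestionnaireTable:
    """Generic metadata filter: keep rows where ``mask(row) is True``.

    ``mask`` may be a boolean Series aligned to the index or a callable
    applied per row.  Demographic exclusions (age group, sex, ...) are
    expressed through this rather than being hard-coded.
    """
    if callable(mask):
        keep = table.data.apply(mask, axis=1).astype(bool)
    else:
        keep = pd.Series(mask, index=table.data.index).astype(bool)
    if keep.sum() == 0:
        raise CohortError("metadata filter removed every participant")
    return QuestionnaireTable(table.data.loc[keep])
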