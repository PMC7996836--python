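"""Representational similarity analysis over conditional-entropy profiles.

Each participant is represented by their per-channel expected conditional
entropy vector; similarity between two participants is the Pearson
correlation of those vectors, with the usual two-sided t-transform p-value
(df = number of channels - 2).  Group structure is summarized block-wise:
within-HIGH, within-LOW (off-diagonal pairs inside a group) and between
(all cross-group pairs).

Pearson correlation is invariant to per-participant affine rescaling of the
profiles, so constant-factor conventions in the profile definition (e.g.
dividing the pairwise sum by N versus N-1) cannot affect any RSA result.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import AnalysisError
from .infotheory import profiles_to_frame

__all__ = ["SimilarityMatrix", "BlockStats", "RSASummary", "similarity_matrix", "summarize"]


@dataclass(frozen=True)
class SimilarityMatrix:
    """All-pair Pearson similarity of participants' CE profiles.

    ``r`` is symmetric with unit diagonal; ``p`` holds the matching
    two-sided p-values with NaN on the (undefined) diagonal.
    """

    participant_ids: tuple
    r: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.participant_ids)
        if self.r.shape != (n, n) or self.p.shape != (n, n):
            raise AnalysisError("similarity matrix shape mismatch")

    def reorder(self, ids) -> "SimilarityMatrix":
        """Return the matrix with rows/columns permuted to the given id order."""
        index = {pid: i for i, pid in enumerate(self.participant_ids)}
        try:
            perm = [index[pid] for pid in ids]
        except KeyError as exc:
            raise AnalysisError(f"unknown participant id {exc}") from exc
        return SimilarityMatrix(
            tuple(ids), self.r[np.ix_(perm, perm)], self.p[np.ix_(perm, perm)]
        )

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        ids = list(self.participant_ids)
        return (
            pd.DataFrame(self.r, index=ids, columns=ids),
            pd.DataFrame(self.p, index=ids, columns=ids),
        )

    def write_csv(self, r_path, p_path) -> None:
        r_df, p_df = self.to_frames()
        r_df.rename_axis("participant_id").to_csv(r_path)
        p_df.rename_axis("participant_id").to_csv(p_path)


@dataclass(frozen=True)
class BlockStats:
    """Mean/SD/median of r and of p over one block of participant pairs."""

    r_mean: float
    r_sd: float
    r_median: float
    p_mean: float
    p_sd: float
    p_median: float
    n_pairs: int

    @classmethod
    def from_values(cls, r_vals: np.ndarray, p_vals: np.ndarray) -> "BlockStats":
        return cls(
            r_mean=float(np.mean(r_vals)),
            r_sd=float(np.std(r_vals, ddof=1)) if len(r_vals) > 1 else 0.0,
            r_median=float(np.median(r_vals)),
            p_mean=float(np.mean(p_vals)),
            p_sd=float(np.std(p_vals, ddof=1)) if len(p_vals) > 1 else 0.0,
            p_median=float(np.median(p_vals)),
            n_pairs=len(r_vals),
        )

    def to_dict(self) -> dict:
        return {
            "r": {"mean": self.r_mean, "sd": self.r_sd, "median": self.r_median},
            "p": {"mean": self.p_mean, "sd": self.p_sd, "median": self.p_median},
            "n_pairs": self.n_pairs,
        }


@dataclass(frozen=True)
class RSASummary:
    """Block-wise similarity summary; a block is None when undefined."""

    within_high: BlockStats | None
    within_low: BlockStats | None
    between: BlockStats | None

    def to_dict(self) -> dict:
        return {
            name: (blk.to_dict() if blk is not None else None)
            for name, blk in (
                ("within_high", self.within_high),
                ("within_low", self.within_low),
                ("between", self.between),
            )
        }

    def write_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


def similarity_matrix(profiles) -> SimilarityMatrix:
    """All-pair Pearson correlations between participants' CE vectors."""
    frame = profiles_to_frame(profiles)
    if len(frame) < 2:
        raise AnalysisError("similarity_matrix needs >= 2 profiles")
    values = frame.to_numpy(dtype=float)
    sds = values.std(axis=1)
    flat = np.flatnonzero(sds == 0.0)
    if flat.size:
        raise AnalysisError(
            f"zero-variance CE vector for participant {frame.index[flat[0]]!r}; "
            "Pearson correlation undefined"
        )
    n = len(frame)
    r = np.eye(n)
    p = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            res = stats.pearsonr(values[i], values[j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return SimilarityMatrix(tuple(frame.index), r, p)


def summarize(matrix: SimilarityMatrix, group_labels) -> RSASummary:
    """Block-wise mean/sd/median of r and p given HIGH/LOW labels.

    ``group_labels`` maps participant id to ``"HIGH"`` or ``"LOW"``.  Within
    blocks use each unordered off-diagonal pair once; the between block uses
    every HIGH x LOW pair.  A group with fewer than two members yields a
    ``None`` within-block (and a single-group input a ``None`` between
    block).
    """
    if isinstance(group_labels, pd.Series):
        group_labels = group_labels.to_dict()
    missing = [pid for pid in matrix.participant_ids if pid not in group_labels]
    if missing:
        raise AnalysisError(f"no group label for participants: {missing}")
    ids = matrix.participant_ids
    high_idx = [i for i, pid in enumerate(ids) if group_labels[pid] == "HIGH"]
    low_idx = [i for i, pid in enumerate(ids) if group_labels[pid] == "LOW"]

    def within(idx) -> BlockStats | None:
        if len(idx) < 2:
            return None
        pairs = [(a, b) for ai, a in enumerate(idx) for b in idx[ai + 1 :]]
        rows, cols = zip(*pairs)
        return BlockStats.from_values(matrix.r[rows, cols], matrix.p[rows, cols])

    def between() -> BlockStats | None:
        if not high_idx or not low_idx:
            return None
        rows, cols = np.ix_(high_idx, low_idx)
        return BlockStats.from_values(
            matrix.r[rows, cols].ravel(), matrix.p[rows, cols].ravel()
        )

    return RSASummary(
        within_high=within(high_idx), within_low=within(low_idx), between=between()
    )
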