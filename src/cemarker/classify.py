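"""Leave-one-out KNN classification and permutation-based channel importance.

Group membership (HIGH vs LOW stress) is predicted from participants'
conditional-entropy profiles with a k-nearest-neighbour classifier under
leave-one-out cross-validation: each participant in turn is held out and
predicted from all the others.  Channel relevance is measured by permutation
importance — shuffle one channel's values across participants, re-run the
leave-one-out evaluation, and record the accuracy drop — and two derived
channel subsets are reported: channels with strictly positive importance,
and channels whose importance exceeds the across-channel mean.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import LeaveOneOut
from sklearn.neighbors import KNeighborsClassifier

from ._errors import AnalysisError
from .infotheory import profiles_to_frame
from .montage import reference_order

__all__ = [
    "LOOResult",
    "ImportanceReport",
    "loo_knn",
    "permutation_importance",
    "reduce_channels",
]


@dataclass(frozen=True)
class LOOResult:
    """Leave-one-out predictions: one fold per participant."""

    participant_ids: tuple
    predictions: tuple[str, ...]
    truths: tuple[str, ...]
    accuracy: float
    k_used: int

    def __post_init__(self) -> None:
        n = len(self.participant_ids)
        if len(self.predictions) != n or len(self.truths) != n:
            raise AnalysisError("one prediction and one truth per participant required")
        if not 0.0 <= self.accuracy <= 1.0:
            raise AnalysisError("accuracy must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "k": self.k_used,
            "accuracy": self.accuracy,
            "folds": [
                {"participant_id": pid, "truth": t, "predicted": p}
                for pid, t, p in zip(self.participant_ids, self.truths, self.predictions)
            ],
        }

    def write_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path


@dataclass(frozen=True)
class ImportanceReport:
    """Per-channel permutation importances and derived channel subsets."""

    channel_names: tuple[str, ...]
    mean_importance: np.ndarray
    sd_importance: np.ndarray
    baseline_accuracy: float
    overall_mean: float
    ci_low: float
    ci_high: float
    n_repeats: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mean_importance", np.asarray(self.mean_importance, dtype=float)
        )
        object.__setattr__(
            self, "sd_importance", np.asarray(self.sd_importance, dtype=float)
        )
        if len(self.mean_importance) != len(self.channel_names):
            raise AnalysisError("one importance per channel required")

    @property
    def positive_channels(self) -> tuple[str, ...]:
        """Channels with strictly positive mean importance, montage-ordered."""
        chans = [
            c for c, v in zip(self.channel_names, self.mean_importance) if v > 0.0
        ]
        return tuple(reference_order(chans))

    @property
    def above_average_channels(self) -> tuple[str, ...]:
        """Channels strictly above the across-channel mean importance."""
        chans = [
            c
            for c, v in zip(self.channel_names, self.mean_importance)
            if v > self.overall_mean
        ]
        return tuple(reference_order(chans))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": list(self.channel_names),
                "mean_importance": self.mean_importance,
                "sd_importance": self.sd_importance,
            }
        )

    def to_dict(self) -> dict:
        return {
            "baseline_accuracy": self.baseline_accuracy,
            "overall_mean_importance": self.overall_mean,
            "ci95": [self.ci_low, self.ci_high],
            "n_repeats": self.n_repeats,
            "channels": self.to_frame().to_dict(orient="records"),
            "positive_channels": list(self.positive_channels),
            "above_average_channels": list(self.above_average_channels),
        }


def _as_matrix(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return profiles_to_frame(profiles)


def _labels_vector(frame: pd.DataFrame, labels) -> np.ndarray:
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    if isinstance(labels, dict):
        missing = [pid for pid in frame.index if pid not in labels]
        if missing:
            raise AnalysisError(f"no label for participants: {missing}")
        return np.array([labels[pid] for pid in frame.index])
    labels = np.asarray(labels)
    if len(labels) != len(frame):
        raise AnalysisError("one label per participant required")
    return labels


def _loo_accuracy(X: np.ndarray, y: np.ndarray, k: int) -> tuple[list, float]:
    preds = []
    for train, test in LeaveOneOut().split(X):
        clf = KNeighborsClassifier(n_neighbors=k, metric="euclidean")
        clf.fit(X[train], y[train])
        preds.append(clf.predict(X[test])[0])
    preds = list(preds)
    acc = float(np.mean([p == t for p, t in zip(preds, y)]))
    return preds, acc


def loo_knn(profiles, labels, k: int = 3, standardize: bool = False) -> LOOResult:
    """Leave-one-out KNN group prediction from CE profiles.

    ``profiles`` is a list of CE profiles or a participants x channels
    DataFrame.  Euclidean distances on the raw profile values by default
    (``standardize=True`` z-scores each channel first).  With binary labels
    an even ``k`` can produce neighbour-vote ties; a warning is issued and
    ties resolve to the class encountered first in training order.
    """
    frame = _as_matrix(profiles)
    y = _labels_vector(frame, labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise AnalysisError(
            f"each class needs >= 2 participants, got {dict(zip(classes, counts))}"
        )
    if k >= len(frame) - 1:
        raise AnalysisError(f"k={k} must be < n-1={len(frame) - 1}")
    if len(classes) == 2 and k % 2 == 0:
        warnings.warn(
            f"even k={k} with binary labels can tie; ties resolve to the class "
            "encountered first in training order",
            stacklevel=2,
        )
    X = frame.to_numpy(dtype=float)
    if standardize:
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1.0, X.std(axis=0))
    preds, acc = _loo_accuracy(X, y, k)
    return LOOResult(
        participant_ids=tuple(frame.index),
        predictions=tuple(preds),
        truths=tuple(y),
        accuracy=acc,
        k_used=k,
    )


def permutation_importance(
    profiles,
    labels,
    k: int = 3,
    n_repeats: int = 30,
    seed: int = 0,
    n_bootstrap: int = 2000,
) -> ImportanceReport:
    """Channel importance as the leave-one-out accuracy drop under shuffling.

    For each channel, its column is permuted across participants
    ``n_repeats`` times (seeded) and the leave-one-out accuracy recomputed;
    the channel's importance is the mean drop from the unpermuted baseline.
    With ~20 participants a leave-one-out evaluation has accuracy
    granularity 1/n, so the default repeat count is generous (30) to
    stabilize the *sign* of small importances.
    A constant column is unaffected by permutation, so its importance is
    exactly zero.  The across-channel mean importance and its bootstrap 95%
    confidence interval (percentile, ``n_bootstrap`` resamples over
    channels) are attached for thresholding.
    """
    if n_repeats < 1:
        raise AnalysisError("n_repeats must be >= 1")
    frame = _as_matrix(profiles)
    y = _labels_vector(frame, labels)
    X = frame.to_numpy(dtype=float)
    _, baseline = _loo_accuracy(X, y, k)
    rng = np.random.default_rng(seed)
    C = X.shape[1]
    drops = np.zeros((C, n_repeats))
    for c in range(C):
        for r in range(n_repeats):
            perm = rng.permutation(len(X))
            if np.all(X[perm, c] == X[:, c]):
                drops[c, r] = 0.0
                continue
            Xp = X.copy()
            Xp[:, c] = X[perm, c]
            _, acc = _loo_accuracy(Xp, y, k)
            drops[c, r] = baseline - acc
    mean_imp = drops.mean(axis=1)
    sd_imp = drops.std(axis=1, ddof=1) if n_repeats > 1 else np.zeros(C)
    overall = float(mean_imp.mean())
    boots = rng.choice(mean_imp, size=(n_bootstrap, C), replace=True).mean(axis=1)
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    return ImportanceReport(
        channel_names=tuple(frame.columns),
        mean_importance=mean_imp,
        sd_importance=sd_imp,
        baseline_accuracy=baseline,
        overall_mean=overall,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_repeats=n_repeats,
    )


def reduce_channels(report: ImportanceReport, rule: str = "above_average") -> tuple[str, ...]:
    """Derive a reduced channel subset from an importance report.

    ``rule="positive"`` keeps channels with importance strictly above zero;
    ``rule="above_average"`` keeps those strictly above the across-channel
    mean.  Raises with guidance if the subset is empty.
    """
    if rule == "positive":
        subset = report.positive_channels
    elif rule == "above_average":
        subset = report.above_average_channels
    else:
        raise AnalysisError(f"unknown reduction rule {rule!r}")
    if not subset:
        raise AnalysisError(
            f"reduction rule {rule!r} selected no channels (importances may all "
            "be equal or non-positive); inspect the importance table, increase "
            "n_repeats, or use rule='positive'"
        )
    return subset
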