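"""Synthetic questionnaire and EEG cohorts with planted ground truth.

Every downstream stage (cohort selection, conditional-entropy profiling,
RSA, classification) is testable without any external recordings because the
generators plant a known structure:

* **Questionnaires** — a background population answers the four stress items
  near mid-scale (integer Likert responses from a rounded truncated normal);
  HIGH-stress plants score strictly above every background response on all
  four items and LOW-stress plants strictly below, which guarantees they fall
  strictly outside the per-item confidence bounds the selection stage will
  compute.

* **EEG** — each participant's channels are a group-specific linear mixing
  of shared latent autoregressive sources plus independent channel noise.
  On a designated subset of "discriminative" channels the LOW group loads on
  one *common* synchronizing source (high pairwise mutual information, hence
  low conditional entropy), while the HIGH group loads on *private* sources
  of identical variance (marginals match, shared information does not).  The
  two groups therefore differ in their conditional-entropy topography but
  not in single-channel amplitude statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import SyntheticError
from .cohort import ITEM_NAMES, QuestionnaireTable
from .io import EEGRecording, write_delimited
from .montage import DEFAULT_16

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticEEGSpec",
    "generate_questionnaires",
    "generate_eeg_cohort",
    "default_eeg_spec",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Questionnaire-cohort specification.

    ``n_background`` mid-scale responders plus ``n_high``/``n_low`` planted
    extremes on a ``likert_min``..``likert_max`` integer scale.  Background
    responses are drawn from a truncated normal centred at mid-scale with
    standard deviation ``background_sd_frac`` of the scale range and rounded
    to the nearest step; the default fraction (7.5%) keeps the confidence
    bounds interior to the scale while making it overwhelmingly unlikely that
    a background responder lands outside them on all four items at once.
    """

    n_background: int = 100
    n_high: int = 10
    n_low: int = 10
    item_names: tuple[str, ...] = ITEM_NAMES
    likert_min: int = 1
    likert_max: int = 5
    background_sd_frac: float = 0.075
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background < 2:
            raise SyntheticError("n_background must be >= 2")
        if self.n_high < 0 or self.n_low < 0:
            raise SyntheticError("n_high and n_low must be >= 0")
        if self.likert_min >= self.likert_max:
            raise SyntheticError("likert_min must be < likert_max")
        if len(self.item_names) != 4:
            raise SyntheticError("exactly 4 item names required")


@dataclass(frozen=True)
class SyntheticEEGSpec:
    """Multichannel-EEG cohort specification.

    Channels are ``coupling_matrix_{high,low} @ sources + noise``; the two
    coupling matrices share a shape (channels x sources) and differ only on
    ``discriminative_channels``.  All latent sources follow the same AR
    process with coefficients ``ar_coeffs``.
    """

    channel_names: tuple[str, ...]
    sampling_rate: float
    duration: float
    coupling_matrix_high: np.ndarray
    coupling_matrix_low: np.ndarray
    discriminative_channels: tuple[int, ...]
    ar_coeffs: tuple[float, ...] = (0.5, -0.3)
    noise_sd: float = 1.0
    coupling_jitter: float = 0.1
    participant_gain_sd: float = 0.25
    normalize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        high = np.asarray(self.coupling_matrix_high, dtype=float)
        low = np.asarray(self.coupling_matrix_low, dtype=float)
        if high.shape != low.shape:
            raise SyntheticError(
                f"coupling matrices must share a shape, got {high.shape} vs {low.shape}"
            )
        if high.shape[0] != len(self.channel_names):
            raise SyntheticError(
                f"{high.shape[0]} coupling rows for {len(self.channel_names)} channels"
            )
        for name, m in (("high", high), ("low", low)):
            zero_rows = np.flatnonzero(~m.any(axis=1))
            if zero_rows.size:
                raise SyntheticError(
                    f"coupling_matrix_{name}: all-zero mixing row(s) {zero_rows.tolist()}"
                )
        bad = [c for c in self.discriminative_channels if not 0 <= c < high.shape[0]]
        if bad:
            raise SyntheticError(f"discriminative channel indices out of range: {bad}")
        n_samples = self.duration * self.sampling_rate
        if n_samples < 1000:
            raise SyntheticError(
                f"duration x sampling_rate = {n_samples:.0f} samples; >= 1000 "
                "required for stable information estimates"
            )
        if self.noise_sd <= 0:
            raise SyntheticError("noise_sd must be > 0")
        object.__setattr__(self, "coupling_matrix_high", high)
        object.__setattr__(self, "coupling_matrix_low", low)
        object.__setattr__(
            self, "discriminative_channels", tuple(self.discriminative_channels)
        )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def n_sources(self) -> int:
        return self.coupling_matrix_high.shape[1]

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


# ---------------------------------------------------------------------------
# questionnaires
# ---------------------------------------------------------------------------

def generate_questionnaires(
    spec: SyntheticCohortSpec,
) -> tuple[QuestionnaireTable, pd.Series]:
    """Generate a questionnaire table with planted extremes and truth labels.

    Returns the table and a Series mapping participant id to ``"HIGH"``,
    ``"LOW"`` or ``"MID"``.  Planted scores sit one Likert step beyond the
    background extremes (clipped to the scale); generation fails explicitly
    if the scale is too narrow for the plants to clear the confidence bounds
    the selection stage will compute.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = float(spec.likert_min), float(spec.likert_max)
    mid, scale = (lo + hi) / 2.0, (hi - lo) * spec.background_sd_frac
    a, b = (lo - mid) / scale, (hi - mid) / scale
    raw = stats.truncnorm.rvs(
        a, b, loc=mid, scale=scale, size=(spec.n_background, 4), random_state=rng
    )
    background = np.clip(np.round(raw), lo, hi)

    high_scores = np.minimum(background.max(axis=0) + 1.0, hi)
    low_scores = np.maximum(background.min(axis=0) - 1.0, lo)
    if spec.n_high > 0 and np.any(high_scores <= background.max(axis=0)):
        raise SyntheticError(
            "Likert scale too narrow: background responses already reach the "
            "scale maximum, HIGH plants cannot be placed strictly above them"
        )
    if spec.n_low > 0 and np.any(low_scores >= background.min(axis=0)):
        raise SyntheticError(
            "Likert scale too narrow: background responses already reach the "
            "scale minimum, LOW plants cannot be placed strictly below them"
        )

    scores = np.vstack(
        [
            background,
            np.tile(high_scores, (spec.n_high, 1)),
            np.tile(low_scores, (spec.n_low, 1)),
        ]
    )
    labels = (
        ["MID"] * spec.n_background + ["HIGH"] * spec.n_high + ["LOW"] * spec.n_low
    )
    width = len(str(len(scores)))
    ids = [f"sub-{i + 1:0{width}d}" for i in range(len(scores))]
    table = QuestionnaireTable(
        pd.DataFrame(scores, columns=list(spec.item_names), index=pd.Index(ids, name="participant_id"))
    )
    truth = pd.Series(labels, index=table.data.index, name="group")

    # self-check: every plant must clear the full-table confidence bounds
    from .cohort import item_ci

    for j, item in enumerate(spec.item_names):
        bound = item_ci(scores[:, j])
        if spec.n_high > 0 and high_scores[j] <= bound.upper:
            raise SyntheticError(
                f"scale too narrow: planted HIGH score {high_scores[j]} does not "
                f"exceed the {item!r} CI upper bound {bound.upper:.3f}"
            )
        if spec.n_low > 0 and low_scores[j] >= bound.lower:
            raise SyntheticError(
                f"scale too narrow: planted LOW score {low_scores[j]} is not "
                f"below the {item!r} CI lower bound {bound.lower:.3f}"
            )
    return table, truth


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def default_eeg_spec(
    n_channels: int = 16,
    n_discriminative: int = 4,
    sampling_rate: float = 250.0,
    duration: float = 20.0,
    source_weight: float = 1.2,
    global_weight: float = 0.4,
    noise_sd: float = 1.0,
    seed: int = 0,
    full_montage: bool = False,
) -> SyntheticEEGSpec:
    """Build the default planted-coupling EEG specification.

    Every channel loads weakly (``global_weight``) on one *global* source —
    the diffuse baseline dependence volume conduction produces in real EEG —
    and strongly (``source_weight``) on exactly one strong source.  For
    background channels, and for the HIGH group's discriminative channels,
    that strong source is *private* to the channel; for the LOW group's
    discriminative channels it is one *common* synchronizing source.  Each
    channel therefore has the same marginal composition in both groups (one
    weak shared + one strong source + noise): the groups differ only in
    *which* information is shared, with the LOW group's discriminative
    channels carrying high mutual pairwise information (low conditional
    entropy) and the HIGH group's only the weak diffuse coupling.  With
    ``full_montage=True`` the packaged 53-channel reference montage replaces
    the compact 16-channel default.
    """
    from .montage import REFERENCE_53

    names = REFERENCE_53 if full_montage else DEFAULT_16
    if full_montage:
        n_channels = len(names)
    if n_channels > len(names):
        raise SyntheticError(f"at most {len(names)} channels in the default montage")
    names = tuple(names[:n_channels])
    if n_discriminative > n_channels:
        raise SyntheticError("n_discriminative cannot exceed n_channels")
    # spread the discriminative channels across the montage
    disc = tuple(
        int(round(i * (n_channels - 1) / max(n_discriminative - 1, 1)))
        for i in range(n_discriminative)
    )
    # source 0: global; source 1: synchronizing; 2..: one private per channel
    n_sources = 2 + n_channels
    high = np.zeros((n_channels, n_sources))
    low = np.zeros((n_channels, n_sources))
    high[:, 0] = low[:, 0] = global_weight
    for ch in range(n_channels):
        if ch in disc:
            low[ch, 1] = source_weight  # LOW: common synchronizing source
            high[ch, 2 + ch] = source_weight  # HIGH: private, same variance
        else:
            low[ch, 2 + ch] = high[ch, 2 + ch] = source_weight
    return SyntheticEEGSpec(
        channel_names=names,
        sampling_rate=sampling_rate,
        duration=duration,
        coupling_matrix_high=high,
        coupling_matrix_low=low,
        discriminative_channels=disc,
        noise_sd=noise_sd,
        seed=seed,
    )


def _ar_sources(
    rng: np.random.Generator, n_sources: int, n_samples: int, coeffs
) -> np.ndarray:
    """Stationary AR(p) latent sources, unit-variance innovations."""
    from scipy.signal import lfilter

    burn = 500
    innov = rng.standard_normal((n_sources, n_samples + burn))
    denom = np.concatenate([[1.0], -np.asarray(coeffs, dtype=float)])
    out = lfilter([1.0], denom, innov, axis=1)
    return out[:, burn:]


def generate_eeg_cohort(
    spec: SyntheticEEGSpec, group_labels
) -> list[EEGRecording]:
    """Generate one recording per participant under group-specific mixing.

    ``group_labels`` maps participant id to ``"HIGH"`` or ``"LOW"`` (a dict or
    a pandas Series).  Each participant receives freshly drawn latent sources
    and channel noise (independent across participants), a participant-level
    multiplicative jitter on the coupling weights (``coupling_jitter``
    relative sd, emulating inter-individual variability), and the mixing
    matrix of their group.  Fully seeded: the same spec and labels reproduce
    byte-identical data.
    """
    if isinstance(group_labels, pd.Series):
        group_labels = group_labels.to_dict()
    bad = {pid: g for pid, g in group_labels.items() if g not in ("HIGH", "LOW")}
    if bad:
        raise SyntheticError(f"labels must be 'HIGH' or 'LOW', got {bad}")
    n_samples = spec.n_samples
    recordings = []
    root = np.random.SeedSequence(spec.seed)
    # one child sequence per participant, keyed by sorted id for stability
    for pid, child in zip(
        sorted(group_labels), root.spawn(len(group_labels))
    ):
        rng = np.random.default_rng(child)
        mixing = (
            spec.coupling_matrix_high
            if group_labels[pid] == "HIGH"
            else spec.coupling_matrix_low
        )
        if spec.coupling_jitter > 0:
            factors = 1.0 + spec.coupling_jitter * rng.standard_normal(mixing.shape)
            mixing = mixing * np.clip(factors, 0.2, None)
        if spec.participant_gain_sd > 0:
            # participant-level gain on the non-global sources: how strongly
            # this individual expresses the source structure (inter-individual
            # variability; weak expressors are genuinely borderline cases)
            gain = 1.0 + spec.participant_gain_sd * rng.standard_normal()
            mixing = mixing.copy()
            mixing[:, 1:] *= max(gain, 0.1)
        sources = _ar_sources(rng, spec.n_sources, n_samples, spec.ar_coeffs)
        noise = spec.noise_sd * rng.standard_normal((spec.n_channels, n_samples))
        data = mixing @ sources + noise
        if spec.normalize:
            # unit channel variance: amplitude carries no group information,
            # only the cross-channel shared-information structure differs
            data = data / data.std(axis=1, keepdims=True)
        recordings.append(
            EEGRecording(
                participant_id=pid,
                channel_names=spec.channel_names,
                sampling_rate=spec.sampling_rate,
                data=data,
            )
        )
    return recordings


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(
    recordings,
    table: QuestionnaireTable,
    labels: pd.Series,
    out_dir,
) -> Path:
    """Write a synthetic cohort to disk.

    One delimited-text file per participant, the questionnaire table as CSV,
    and a manifest CSV (participant id, group, file path).  Returns the
    manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        path = write_delimited(rec, out_dir / f"{rec.participant_id}.tsv")
        rows.append(
            {
                "participant_id": rec.participant_id,
                "group": labels.get(rec.participant_id, "MID"),
                "path": path.name,
            }
        )
    table.to_csv(out_dir / "questionnaires.csv")
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
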