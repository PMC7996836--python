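"""Differential entropy, mutual information and conditional entropy.

For two continuous signals X and Y the conditional entropy is computed
through the decomposition

    H(X|Y) = H(X) - MI(X;Y),

so only a marginal-entropy and a mutual-information estimate are needed; the
joint and conditional densities are never materialized.  Two estimator
families are provided:

* ``knn`` (default) — non-parametric k-nearest-neighbour estimators:
  Kozachenko-Leonenko for differential entropy and the Kraskov-
  Stoegbauer-Grassberger (KSG, algorithm 1) estimator for mutual
  information.  These make no assumption about the underlying densities.
* ``gaussian`` — closed forms under a Gaussian assumption,
  ``H(X) = 0.5 log(2 pi e sigma_x^2)`` and ``MI = -0.5 log(1 - rho^2)``.
  These serve as analytic oracles for the non-parametric estimators and as a
  cheap parametric alternative.

Significance of a mutual-information estimate is assessed with a surrogate
permutation test: Y's samples are shuffled to destroy any X-Y dependence
while preserving both marginals, MI is re-estimated on each surrogate, and
the p-value is the (add-one corrected) fraction of surrogates at or above
the observed value.

The per-channel summary statistic of a multichannel recording is the
*expected conditional-entropy profile*: for channel c_i, the average of
H(c_i | c_j) over all other channels c_j.  Low values mean the channel's
signal is largely explained by the rest of the montage (high shared
information); high values mean it carries mostly unshared information.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import digamma

from ._errors import EstimatorError
from .io import EEGRecording

__all__ = [
    "EstimatorConfig",
    "PairwiseCE",
    "CEProfile",
    "entropy",
    "mutual_information",
    "conditional_entropy",
    "surrogate_pvalue",
    "expected_ce_profile",
    "profiles_to_frame",
    "write_profiles_csv",
    "read_profiles_csv",
]

LN2 = float(np.log(2.0))
_JITTER_SCALE = 1e-10  # relative tie-breaking noise for quantized inputs


@dataclass(frozen=True)
class EstimatorConfig:
    """Configuration shared by all information estimates.

    Parameters
    ----------
    method:
        ``"knn"`` for the non-parametric k-NN estimators (default) or
        ``"gaussian"`` for the closed forms under a Gaussian assumption.
    k_neighbors:
        Neighbour order of the k-NN estimators; small k lowers bias at the
        price of variance.  Default 4, the customary choice for KSG.
    units:
        ``"nats"`` (natural log, default) or ``"bits"``.
    n_surrogates:
        Number of permutation surrogates for significance testing; 100 by
        default; 0 disables p-values.
    seed:
        Seeds surrogate permutations and subsampling.
    max_samples:
        Long signals are evenly strided down to at most this many samples
        before k-NN estimation (O(n log n) per pair, C^2 pairs).
    zero_nonsignificant:
        If true, pairwise MI terms whose surrogate p-value exceeds ``alpha``
        are treated as zero inside the expected-CE average.
    """

    method: str = "knn"
    k_neighbors: int = 4
    units: str = "nats"
    n_surrogates: int = 100
    seed: int = 0
    max_samples: int = 15000
    zero_nonsignificant: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.method not in ("knn", "gaussian"):
            raise EstimatorError(f"unknown estimator method {self.method!r}")
        if self.units not in ("nats", "bits"):
            raise EstimatorError(f"unknown units {self.units!r}")
        if self.k_neighbors < 1:
            raise EstimatorError("k_neighbors must be >= 1")
        if self.n_surrogates < 0:
            raise EstimatorError("n_surrogates must be >= 0")
        if self.max_samples < 100:
            raise EstimatorError("max_samples must be >= 100")

    def _convert(self, nats: float) -> float:
        return nats / LN2 if self.units == "bits" else nats


@dataclass(frozen=True)
class PairwiseCE:
    """Conditional entropy of one ordered channel pair.

    The identity ``value = h_x - mi_xy`` is enforced arithmetically: ``value``
    is *defined* as that difference.
    """

    value: float
    h_x: float
    mi_xy: float
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.value != self.h_x - self.mi_xy:
            raise EstimatorError("PairwiseCE identity violated: value != h_x - mi_xy")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise EstimatorError(f"p_value must lie in (0, 1], got {self.p_value}")


@dataclass(frozen=True)
class CEProfile:
    """One participant's per-channel expected conditional-entropy vector."""

    participant_id: str
    channel_names: tuple[str, ...]
    ce_values: np.ndarray
    p_values: np.ndarray | None = None
    units: str = "nats"

    def __post_init__(self) -> None:
        ce = np.asarray(self.ce_values, dtype=float)
        if len(ce) != len(self.channel_names):
            raise EstimatorError(
                f"{self.participant_id}: {len(ce)} CE values for "
                f"{len(self.channel_names)} channels"
            )
        if not np.all(np.isfinite(ce)):
            raise EstimatorError(f"{self.participant_id}: non-finite CE values")
        object.__setattr__(self, "ce_values", ce)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        if self.p_values is not None:
            object.__setattr__(
                self, "p_values", np.asarray(self.p_values, dtype=float)
            )


# ---------------------------------------------------------------------------
# sample preparation
# ---------------------------------------------------------------------------

def _check_samples(x: np.ndarray, name: str = "x", min_n: int = 100) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < min_n:
        raise EstimatorError(f"{name}: need >= {min_n} samples, got {len(x)}")
    if not np.all(np.isfinite(x)):
        raise EstimatorError(f"{name}: non-finite samples")
    if np.std(x) == 0.0:
        raise EstimatorError(
            f"{name}: constant input (differential entropy diverges to -inf)"
        )
    return x


def _subsample_idx(n: int, config: EstimatorConfig) -> np.ndarray | None:
    """Evenly strided subsample indices (seeded phase) or None if unneeded."""
    if n <= config.max_samples:
        return None
    stride = n / config.max_samples
    offset = np.random.default_rng(config.seed).uniform(0, stride)
    return np.minimum((offset + stride * np.arange(config.max_samples)).astype(int), n - 1)


def _jitter(x: np.ndarray) -> np.ndarray:
    """Deterministic per-array tie-breaking noise.

    The jitter seed is derived from the array's own bytes, so identical data
    always receives identical jitter regardless of argument order — this
    keeps ``mutual_information(x, y) == mutual_information(y, x)`` exact.
    """
    seed = zlib.crc32(np.ascontiguousarray(x).tobytes()) & 0x7FFFFFFF
    rng = np.random.default_rng(seed)
    return x + _JITTER_SCALE * np.std(x) * rng.standard_normal(len(x))


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _kl_entropy(x: np.ndarray, k: int) -> float:
    """Kozachenko-Leonenko k-NN differential entropy (1-D), in nats."""
    n = len(x)
    if k >= n:
        raise EstimatorError(f"k_neighbors={k} must be < n={n}")
    tree = cKDTree(x[:, None])
    dist, _ = tree.query(x[:, None], k=k + 1)
    eps = dist[:, -1]
    if np.any(eps == 0.0):
        raise EstimatorError("duplicate samples survived jitter; cannot estimate")
    return float(digamma(n) - digamma(k) + np.log(2.0) + np.mean(np.log(eps)))


def _ksg_mi(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """KSG (algorithm 1) mutual information between two 1-D samples, in nats."""
    n = len(x)
    if k >= n:
        raise EstimatorError(f"k_neighbors={k} must be < n={n}")
    xy = np.column_stack([x, y])
    tree = cKDTree(xy)
    dist, _ = tree.query(xy, k=k + 1, p=np.inf)
    eps = dist[:, -1]
    xs, ys = np.sort(x), np.sort(y)
    # strict count of marginal neighbours within eps (self excluded)
    nx = np.searchsorted(xs, x + eps, "left") - np.searchsorted(xs, x - eps, "right") - 1
    ny = np.searchsorted(ys, y + eps, "left") - np.searchsorted(ys, y - eps, "right") - 1
    return float(
        digamma(k) + digamma(n) - np.mean(digamma(nx + 1) + digamma(ny + 1))
    )


def entropy(x, config: EstimatorConfig = EstimatorConfig()) -> float:
    """Differential entropy H(X) of a sample vector, in configured units."""
    x = _check_samples(x, "x")
    idx = _subsample_idx(len(x), config)
    if idx is not None:
        x = x[idx]
    if config.method == "gaussian":
        var = float(np.var(x, ddof=1))
        return config._convert(0.5 * np.log(2.0 * np.pi * np.e * var))
    return config._convert(_kl_entropy(_jitter(x), config.k_neighbors))


def mutual_information(x, y, config: EstimatorConfig = EstimatorConfig()) -> float:
    """Mutual information MI(X;Y), symmetric in its arguments.

    Small negative values (down to estimator noise) are possible for the
    k-NN estimator under independence and are returned as-is.
    """
    x = _check_samples(x, "x")
    y = _check_samples(y, "y")
    if len(x) != len(y):
        raise EstimatorError(f"length mismatch: len(x)={len(x)}, len(y)={len(y)}")
    idx = _subsample_idx(len(x), config)
    if idx is not None:
        x, y = x[idx], y[idx]
    if config.method == "gaussian":
        rho = float(np.corrcoef(x, y)[0, 1])
        rho = min(abs(rho), 1.0 - 1e-15)
        return config._convert(-0.5 * np.log(1.0 - rho * rho))
    # standardize so the Chebyshev ball treats both coordinates alike;
    # KSG is invariant to monotone per-variable rescaling asymptotically
    xs = _jitter((x - np.mean(x)) / np.std(x))
    ys = _jitter((y - np.mean(y)) / np.std(y))
    return config._convert(_ksg_mi(xs, ys, config.k_neighbors))


def surrogate_pvalue(
    x, y, observed_mi: float, config: EstimatorConfig = EstimatorConfig()
) -> float:
    """Permutation-surrogate significance of an observed MI estimate.

    Y is shuffled ``n_surrogates`` times (destroying dependence, preserving
    marginals), MI re-estimated on each surrogate, and

        p = (1 + #{MI_surrogate >= MI_observed}) / (n_surrogates + 1),

    the add-one estimator, so p is never exactly zero.
    """
    if config.n_surrogates < 1:
        raise EstimatorError("surrogate_pvalue requires n_surrogates >= 1")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(config.seed)
    exceed = 0
    for _ in range(config.n_surrogates):
        y_perm = rng.permutation(y)
        if mutual_information(x, y_perm, config) >= observed_mi:
            exceed += 1
    return (1 + exceed) / (config.n_surrogates + 1)


def conditional_entropy(
    x, y, config: EstimatorConfig = EstimatorConfig()
) -> PairwiseCE:
    """Conditional entropy H(X|Y) = H(X) - MI(X;Y) with optional p-value."""
    h_x = entropy(x, config)
    mi = mutual_information(x, y, config)
    p = surrogate_pvalue(x, y, mi, config) if config.n_surrogates > 0 else None
    return PairwiseCE(value=h_x - mi, h_x=h_x, mi_xy=mi, p_value=p)


# ---------------------------------------------------------------------------
# per-channel profile
# ---------------------------------------------------------------------------

def expected_ce_profile(
    recording: EEGRecording, config: EstimatorConfig = EstimatorConfig()
) -> CEProfile:
    """Per-channel expected conditional entropy of a multichannel recording.

    For channel c_i the profile entry is the mean of H(c_i | c_j) over all
    other channels c_j — a true average over the N-1 summed terms.  The MI
    matrix is symmetric, so only C(C-1)/2 pairwise estimates are needed.
    When surrogates are configured, each channel's aggregate p-value is the
    median of its pairwise surrogate p-values.
    """
    C = recording.n_channels
    if C < 2:
        raise EstimatorError("expected_ce_profile needs >= 2 channels")
    data = recording.data
    idx = _subsample_idx(data.shape[1], config)
    if idx is not None:
        data = data[:, idx]
    sub_config = EstimatorConfig(
        method=config.method,
        k_neighbors=config.k_neighbors,
        units=config.units,
        n_surrogates=config.n_surrogates,
        seed=config.seed,
        max_samples=max(data.shape[1], 100),  # already subsampled jointly
        zero_nonsignificant=config.zero_nonsignificant,
        alpha=config.alpha,
    )
    h = np.array([entropy(data[i], sub_config) for i in range(C)])
    mi = np.zeros((C, C))
    pvals = np.full((C, C), np.nan) if config.n_surrogates > 0 else None
    for i in range(C):
        for j in range(i + 1, C):
            mi_ij = mutual_information(data[i], data[j], sub_config)
            mi[i, j] = mi[j, i] = mi_ij
            if pvals is not None:
                p = surrogate_pvalue(data[i], data[j], mi_ij, sub_config)
                pvals[i, j] = pvals[j, i] = p
    mi_eff = mi.copy()
    if config.zero_nonsignificant and pvals is not None:
        mi_eff[pvals > config.alpha] = 0.0
    off_diag = ~np.eye(C, dtype=bool)
    ce = np.array(
        [np.mean(h[i] - mi_eff[i, off_diag[i]]) for i in range(C)]
    )
    channel_p = (
        np.array([np.median(pvals[i, off_diag[i]]) for i in range(C)])
        if pvals is not None
        else None
    )
    return CEProfile(
        participant_id=recording.participant_id,
        channel_names=recording.channel_names,
        ce_values=ce,
        p_values=channel_p,
        units=config.units,
    )


# ---------------------------------------------------------------------------
# profile I/O
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles) -> pd.DataFrame:
    """Stack CE profiles into a participants x channels wide matrix."""
    profiles = list(profiles)
    if not profiles:
        raise EstimatorError("no profiles given")
    channels = profiles[0].channel_names
    for p in profiles[1:]:
        if p.channel_names != channels:
            raise EstimatorError(
                f"profile {p.participant_id}: channel set/order differs from "
                f"{profiles[0].participant_id}"
            )
    return pd.DataFrame(
        np.vstack([p.ce_values for p in profiles]),
        index=pd.Index([p.participant_id for p in profiles], name="participant_id"),
        columns=list(channels),
    )


def write_profiles_csv(profiles, path) -> Path:
    """Write profiles in long form: participant_id, channel, ce, p_value."""
    rows = []
    for prof in profiles:
        for i, ch in enumerate(prof.channel_names):
            rows.append(
                {
                    "participant_id": prof.participant_id,
                    "channel": ch,
                    "ce": prof.ce_values[i],
                    "p_value": None if prof.p_values is None else prof.p_values[i],
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_profiles_csv(path, units: str = "nats") -> list[CEProfile]:
    df = pd.read_csv(path)
    profiles = []
    for pid, grp in df.groupby("participant_id", sort=False):
        has_p = "p_value" in grp.columns and grp["p_value"].notna().all()
        profiles.append(
            CEProfile(
                participant_id=str(pid),
                channel_names=tuple(grp["channel"]),
                ce_values=grp["ce"].to_numpy(),
                p_values=grp["p_value"].to_numpy() if has_p else None,
                units=units,
            )
        )
    return profiles
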