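"""10-10 montage channel names and label normalization.

EEG channel labels in the extended international 10-20 ("10-10") system are
written with inconsistent casing across vendors and publications (``FP2`` vs
``Fp2``, ``AFZ`` vs ``AFz``).  All label handling in this package goes through
:func:`normalize_channel`, which maps case-insensitively onto a canonical
spelling, so that recordings from different sources can be intersected and
reordered safely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "REFERENCE_53",
    "DEFAULT_16",
    "Montage",
    "normalize_channel",
    "normalize_channels",
    "reference_order",
]

#: The 53 scalp channels used as the packaged reference montage, in reference
#: order (frontal-polar to occipital).  This is the canonical channel universe
#: for cross-participant intersection; recordings may carry extra labels.
REFERENCE_53: tuple[str, ...] = (
    "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4",
    "F5", "F3", "Fz", "F1", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO9", "PO7", "POz", "PO3", "PO4", "PO8",
    "O1", "Oz", "O2",
)

#: Compact 16-channel scalp coverage used by the synthetic generator's default
#: montage: keeps the O(C^2) pairwise conditional-entropy computation cheap
#: while spanning frontal, central, parietal and occipital sites.
DEFAULT_16: tuple[str, ...] = (
    "Fp2", "AF3", "AF4", "F3", "Fz", "F4",
    "FC3", "Cz", "C4", "CP3", "CPz",
    "P3", "Pz", "P4", "POz", "O2",
)

_CANONICAL = {name.lower(): name for name in REFERENCE_53}
_REFERENCE_RANK = {name: i for i, name in enumerate(REFERENCE_53)}


def reference_montage_path():
    """Path of the packaged plain-text copy of the 53-channel reference list."""
    from importlib.resources import files

    return files("cemarker") / "data" / "reference_montage_53.txt"


def normalize_channel(name: str) -> str:
    """Return the canonical spelling of an EEG channel label.

    Labels present in the packaged 53-channel reference set are matched
    case-insensitively (``FP2`` -> ``Fp2``); unknown labels are returned
    whitespace-stripped but otherwise untouched.
    """
    stripped = name.strip()
    return _CANONICAL.get(stripped.lower(), stripped)


def normalize_channels(names) -> list[str]:
    """Normalize a sequence of labels, rejecting duplicates after folding."""
    out = [normalize_channel(n) for n in names]
    seen: set[str] = set()
    for n in out:
        key = n.lower()
        if key in seen:
            raise ValueError(f"duplicate channel label after normalization: {n!r}")
        seen.add(key)
    return out


def reference_order(names) -> list[str]:
    """Order labels by the packaged reference montage, extras alphabetically.

    Channels belonging to :data:`REFERENCE_53` come first, in reference order;
    any remaining labels follow in alphabetical order.
    """
    normalized = [normalize_channel(n) for n in names]
    inside = sorted(
        (n for n in normalized if n in _REFERENCE_RANK), key=_REFERENCE_RANK.__getitem__
    )
    outside = sorted(n for n in normalized if n not in _REFERENCE_RANK)
    return inside + outside


@dataclass(frozen=True)
class Montage:
    """An ordered set of channel labels with optional 2-D scalp positions."""

    channel_names: tuple[str, ...]
    positions: dict[str, tuple[float, float]] | None = field(default=None)

    def __post_init__(self) -> None:
        names = normalize_channels(self.channel_names)
        object.__setattr__(self, "channel_names", tuple(names))
        if self.positions is not None:
            missing = [n for n in self.positions if normalize_channel(n) not in names]
            if missing:
                raise ValueError(f"positions given for unknown channels: {missing}")

    def __len__(self) -> int:
        return len(self.channel_names)

    def __contains__(self, name: str) -> bool:
        return normalize_channel(name) in self.channel_names
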