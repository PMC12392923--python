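"""32-channel 10-20 montage used throughout the package.

Channel labels follow the actiCAP 32-electrode layout. Homologous
left/right pairs drive the alpha-laterality computation; the four
midline channels are defined to carry a laterality of exactly zero.
"""

from __future__ import annotations

CHANNELS: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "Fz", "F7", "F8",
    "FC1", "FC2", "FC5", "FC6", "FT9", "FT10",
    "C3", "C4", "Cz", "T7", "T8",
    "CP1", "CP2", "CP5", "CP6", "TP9", "TP10",
    "P3", "P4", "P7", "P8", "Pz", "O1", "O2", "Oz",
)

#: (left, right) homologous electrode pairs.
HOMOLOGOUS_PAIRS: tuple[tuple[str, str], ...] = (
    ("FP1", "FP2"), ("F3", "F4"), ("F7", "F8"),
    ("FC1", "FC2"), ("FC5", "FC6"), ("FT9", "FT10"),
    ("C3", "C4"), ("T7", "T8"),
    ("CP1", "CP2"), ("CP5", "CP6"), ("TP9", "TP10"),
    ("P3", "P4"), ("P7", "P8"), ("O1", "O2"),
)

MIDLINE: tuple[str, ...] = ("Fz", "Cz", "Pz", "Oz")

FRONTAL: tuple[str, ...] = ("FP1", "FP2", "F3", "F4", "Fz", "F7", "F8")
RIGHT_PARIETAL: tuple[str, ...] = ("P4", "P8", "CP2", "CP6")


def pair_of(channel: str) -> str | None:
    """Return the homologous partner of *channel*, or None for midline."""
    for left, right in HOMOLOGOUS_PAIRS:
        if channel == left:
            return right
        if channel == right:
            return left
    return None


def is_left(channel: str) -> bool:
    return any(channel == left for left, _ in HOMOLOGOUS_PAIRS)
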