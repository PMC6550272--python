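"""Canonical 8-emotion vocabulary.

The system recognizes the eight theoretically universal emotions. Two naming
conventions circulate for the same set (child-friendly vs. clinical), so
aliases are accepted on input and canonicalized on output.
"""

from __future__ import annotations

EMOTIONS: tuple[str, ...] = (
    "happy",
    "sad",
    "angry",
    "scared",
    "surprised",
    "neutral",
    "disgust",
    "contempt",
)

#: aliases accepted on input; canonical names on output
ALIASES: dict[str, str] = {
    "calm": "neutral",
    "meh": "contempt",
    "afraid": "scared",
    "fear": "scared",
}

LABEL_TO_INDEX: dict[str, int] = {e: i for i, e in enumerate(EMOTIONS)}

#: sentinel for "no confident detection"
NONE_LABEL = "none"


class UnknownLabelError(ValueError):
    """Raised for a label outside the canonical vocabulary and its aliases."""


def canonical(label: str) -> str:
    """Map a label (canonical or alias, any case) to its canonical form."""
    key = str(label).strip().lower()
    key = ALIASES.get(key, key)
    if key not in LABEL_TO_INDEX:
        raise UnknownLabelError(f"unknown emotion label: {label!r}")
    return key


def label_index(label: str) -> int:
    """Canonical index (0..7) of a label, accepting aliases."""
    return LABEL_TO_INDEX[canonical(label)]


def is_valid(label: str) -> bool:
    try:
        canonical(label)
    except UnknownLabelError:
        return False
    return True
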