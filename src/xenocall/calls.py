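"""Shared response-call vocabulary.

Every classifier in the package emits a :class:`ResponseCall`: a
system-specific objective-response category (patient and mouse use the
solid-tumor alphabet ``MCR/CR/PR/SD/PD``; larval zebrafish groups use
``R/SD/PD``) plus its projection onto the harmonized three-level scale
``{R, SD, PD}`` used for cross-model comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SYSTEMS = ("patient", "mouse", "zebrafish")

#: system-specific category alphabets
PATIENT_CATEGORIES = ("CR", "PR", "SD", "PD")
MOUSE_CATEGORIES = ("MCR", "CR", "PR", "SD", "PD")
FISH_CATEGORIES = ("R", "SD", "PD")

#: ordering used for "best" response and group medians (worst first)
MOUSE_ORDER = ("PD", "SD", "PR", "CR", "MCR")
PATIENT_ORDER = ("PD", "SD", "PR", "CR")

#: maintained CR, CR and PR all count as response on the harmonized scale
HARMONIZED = ("R", "SD", "PD")
_HARMONIZE_MAP = {
    "MCR": "R",
    "CR": "R",
    "PR": "R",
    "R": "R",
    "SD": "SD",
    "PD": "PD",
}


def harmonize_category(category: str) -> str:
    """Map a system-specific category onto the common ``{R, SD, PD}`` scale."""
    try:
        return _HARMONIZE_MAP[category]
    except KeyError:
        raise ValueError(f"unknown response category: {category!r}") from None


@dataclass(frozen=True)
class ResponseCall:
    """One objective-response call.

    Parameters
    ----------
    system:
        Which model system produced the call (``patient``, ``mouse`` or
        ``zebrafish``).
    category:
        The system-specific category.
    harmonized:
        The three-level projection; derived from ``category`` when omitted.
    qualifier:
        Optional free-text flag (e.g. ``"unconfirmed"`` for an
        unconfirmed partial response, or ``"not evaluable"``).
    """

    system: str
    category: str
    harmonized: str = field(default="")
    qualifier: str | None = None

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown system: {self.system!r}")
        alphabet = {
            "patient": PATIENT_CATEGORIES,
            "mouse": MOUSE_CATEGORIES,
            "zebrafish": FISH_CATEGORIES,
        }[self.system]
        if self.category not in alphabet:
            raise ValueError(
                f"category {self.category!r} not valid for system {self.system!r}"
            )
        expected = harmonize_category(self.category)
        if not self.harmonized:
            object.__setattr__(self, "harmonized", expected)
        elif self.harmonized != expected:
            raise ValueError(
                f"harmonized {self.harmonized!r} inconsistent with "
                f"category {self.category!r} (expected {expected!r})"
            )
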