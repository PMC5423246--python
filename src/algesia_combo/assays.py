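"""The three behavioral assays of the CCI neuropathic-pain battery.

Each assay measures one evoked-pain modality on the injured hind paw:

* ``von_frey`` — mechanical allodynia; paw withdrawal threshold (PWT) in
  grams, instrument cutoff 60 g.
* ``acetone`` — cold allodynia; paw withdrawal frequency (PWF), the count of
  withdrawal responses out of 5 acetone applications.
* ``radiant_heat`` — thermal hyperalgesia; paw withdrawal latency (PWL) in
  seconds, cutoff 30 s to avoid tissue damage.

Nerve injury *decreases* the von Frey threshold and the heat latency and
*increases* the acetone response count; the ``direction_of_injury`` field
encodes this sign.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UnknownAssayError

__all__ = ["AssaySpec", "ASSAYS", "ASSAY_NAMES", "get_assay"]


@dataclass(frozen=True)
class AssaySpec:
    """Static description of one behavioral assay."""

    name: str
    unit: str
    cutoff: float
    direction_of_injury: str  # "decrease" | "increase"
    integer_valued: bool = False

    @property
    def sign(self) -> float:
        """Injury sign on the measurement scale: -1 decrease, +1 increase."""
        return 1.0 if self.direction_of_injury == "increase" else -1.0


ASSAYS: dict[str, AssaySpec] = {
    "von_frey": AssaySpec("von_frey", "g", 60.0, "decrease"),
    "acetone": AssaySpec("acetone", "count", 5.0, "increase", integer_valued=True),
    "radiant_heat": AssaySpec("radiant_heat", "s", 30.0, "decrease"),
}

ASSAY_NAMES = tuple(sorted(ASSAYS))


def get_assay(name: str) -> AssaySpec:
    try:
        return ASSAYS[name]
    except KeyError:
        raise UnknownAssayError(
            f"unknown assay {name!r}; expected one of {', '.join(ASSAY_NAMES)}"
        ) from None
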