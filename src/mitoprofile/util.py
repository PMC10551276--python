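"""Small shared primitives: mutation keys, notation, and rounding policy."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

from .exceptions import ValidationError

VALID_BASES = frozenset("ACGT")

GENOME_LENGTH = 16569

_NOTATION_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")


class MutationKey(NamedTuple):
    """Identity of a substitution on the heavy strand: (position, ref, alt).

    Hashable; used for all cross-sample matching (tumor vs normal vs EV).
    """

    position: int
    ref: str
    alt: str

    def __str__(self) -> str:  # e.g. "G1888A"
        return f"{self.ref}{self.position}{self.alt}"


def format_mutation(key: MutationKey) -> str:
    return str(key)


def parse_mutation(text: str) -> MutationKey:
    """Parse "<ref><position><alt>" notation, e.g. "T7953G"."""
    m = _NOTATION_RE.match(text.strip())
    if not m:
        raise ValidationError(f"cannot parse mutation notation {text!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    return make_key(pos, ref, alt)


def make_key(position: int, ref: str, alt: str) -> MutationKey:
    ref, alt = ref.upper(), alt.upper()
    if ref not in VALID_BASES or alt not in VALID_BASES:
        raise ValidationError(f"bases must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValidationError(f"ref and alt are identical at {position}: {ref}")
    if not 1 <= position <= GENOME_LENGTH:
        raise ValidationError(f"position {position} outside 1..{GENOME_LENGTH}")
    return MutationKey(int(position), ref, alt)


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the reporting policy for all percents).

    Python's built-in round() is banker's rounding; cohort reports instead use
    half-up so that e.g. 12/32 = 37.5% prints as 38%.
    """
    q = Decimal(1).scaleb(-ndigits)
    value = float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    return value


def percent(numerator: float, denominator: float) -> int:
    """Half-up integer percentage; 0 when the denominator is 0."""
    if denominator == 0:
        return 0
    return int(round_half_up(100.0 * numerator / denominator))
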