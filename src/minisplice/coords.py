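"""HGVS-style coding (c.) coordinates with intronic offsets.

Positions are 1-based within the CDS. An offset of ``+k`` means *k* nt
downstream of the exonic base (into the intron past a donor site); ``-k``
means *k* nt upstream (into the intron before an acceptor). Offset 0 is
exonic. Printed sources mix en-dash, minus-sign and hyphen glyphs; all are
normalized to ``-`` before parsing.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "CodingPosition", "ParseError", "normalize_dashes",
    "parse_cposition", "parse_variant_position",
]

_DASHES = str.maketrans({"–": "-", "—": "-", "−": "-"})

_CPOS_RE = re.compile(r"^c?\.?(\d+)([+-]\d+)?$")
# leading position of a variant token such as "c.643+5G>A" or "1129-293_1129-218"
_VARIANT_POS_RE = re.compile(r"^c?\.?(\d+(?:[+-]\d+)?)")


class ParseError(ValueError):
    """A token could not be interpreted as a c. position or variant."""


def normalize_dashes(text: str) -> str:
    return text.translate(_DASHES)


@dataclass(frozen=True, order=False)
class CodingPosition:
    """One c. coordinate: CDS base plus signed intronic offset."""

    base: int
    offset: int = 0
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.base < 1:
            raise ParseError(f"c. base must be >= 1, got {self.base}")

    @property
    def is_exonic(self) -> bool:
        return self.offset == 0

    def serialize(self) -> str:
        if self.offset:
            return f"{self.base}{self.offset:+d}"
        return str(self.base)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()

    def sort_key(self) -> tuple[int, int]:
        """Orders positions along the pre-mRNA: 643 < 643+5 < 644-5 < 644."""
        return (self.base, self.offset) if self.offset >= 0 else (
            self.base - 1, 10 ** 9 + self.offset)


def parse_cposition(token: str) -> CodingPosition:
    """Parse ``"643+5"``, ``"c.675"`` or ``"1129-293"`` into a position.

    An explicit zero offset (``"643+0"``) is rejected: offset 0 is written
    by omitting the offset entirely.
    """
    raw = token
    tok = normalize_dashes(token).strip()
    m = _CPOS_RE.match(tok)
    if not m:
        raise ParseError(f"not a c. position token: {token!r}")
    base = int(m.group(1))
    offset = int(m.group(2)) if m.group(2) else 0
    if m.group(2) and offset == 0:
        raise ParseError(f"explicit zero offset in {token!r}")
    return CodingPosition(base=base, offset=offset, raw=raw)


def parse_variant_position(token: str) -> CodingPosition:
    """Extract the (first) c. position from a variant token.

    ``"c.643+5G>A"`` -> 643+5; ``"c.1129-293_1129-218"`` -> 1129-293.
    """
    tok = normalize_dashes(token).strip()
    m = _VARIANT_POS_RE.match(tok)
    if not m:
        raise ParseError(f"no c. position at start of {token!r}")
    return parse_cposition(m.group(1))
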