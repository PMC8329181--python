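"""Promoter-frame coordinate arithmetic.

Promoter positions are signed integers with no position 0: ... -2, -1, +1, +2 ...
where +1 is the first base of the annotated first exon.  Internally everything
is 0-based half-open; this module converts between the two frames.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PromoterCoordinate",
    "promoter_to_offset",
    "offset_to_promoter",
    "interval_length_promoter",
]


@dataclass(frozen=True)
class PromoterCoordinate:
    """A position in the signed promoter frame (no zero)."""

    value: int

    def __post_init__(self) -> None:
        if self.value == 0:
            raise ValueError("promoter frame has no position 0")


def _coerce(coord: "PromoterCoordinate | int") -> int:
    value = coord.value if isinstance(coord, PromoterCoordinate) else int(coord)
    if value == 0:
        raise ValueError("promoter frame has no position 0")
    return value


def promoter_to_offset(coord: "PromoterCoordinate | int", plus_one_offset: int) -> int:
    """Map a signed promoter coordinate to a 0-based internal offset.

    ``plus_one_offset`` is the internal offset of promoter position +1.
    Positive coordinates map to ``plus_one_offset + (value - 1)``; negative
    coordinates to ``plus_one_offset + value`` (position -1 sits immediately
    upstream of +1).
    """
    value = _coerce(coord)
    if value > 0:
        return plus_one_offset + (value - 1)
    return plus_one_offset + value


def offset_to_promoter(offset: int, plus_one_offset: int) -> PromoterCoordinate:
    """Inverse of :func:`promoter_to_offset`."""
    delta = offset - plus_one_offset
    if delta >= 0:
        return PromoterCoordinate(delta + 1)
    return PromoterCoordinate(delta)


def interval_length_promoter(
    frm: "PromoterCoordinate | int", to: "PromoterCoordinate | int"
) -> int:
    """Number of positions in the inclusive promoter interval [frm, to].

    Position 0 does not exist, so an interval straddling the origin is one
    shorter than plain subtraction suggests: -117..+103 spans 220 positions.
    """
    a, b = _coerce(frm), _coerce(to)
    if a > b:
        raise ValueError(f"interval endpoints out of order: {a} > {b}")
    n = b - a + 1
    if a < 0 < b:
        n -= 1  # the nonexistent position 0
    return n
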