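"""Chord patterns indexing the Gauss integrals of orders 1-3.

A Gauss integral of order ``k`` sums, over strictly increasing tuples of
``2k`` segment indices, a product of ``k`` writhe factors ``W(i_a, i_b)``.
Which index pairs up with which is encoded by a perfect matching of the
ordered positions ``1..2k`` -- the *chord pattern*.  Each chord may also be
flagged to enter the product as ``|W|`` instead of ``W``, which makes that
factor achiral (the order-1 all-absolute integral is the average crossing
number, the plain one the writhe).

The descriptor uses a fixed enumeration of 29 patterns:

* order 1: the single matching ``(1,2)``, plain and absolute (2 invariants);
* order 2: the 3 matchings of 4 positions, each in the 4 absolute-value
  combinations (12 invariants);
* order 3: the 15 matchings of 6 positions, plain only (15 invariants).

The enumeration order (order, then matching lexicographically, then
abs-flag combination) is frozen and versioned; descriptor vectors are only
comparable between builds with the same version string.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product

#: Version tag of the pattern enumeration, stored in database headers.
PATTERN_VERSION = "order123-lex-1"


@dataclass(frozen=True)
class ChordPattern:
    """A perfect matching of ``2*order`` ordered positions with per-chord
    absolute-value flags."""

    order: int
    pairing: tuple[tuple[int, int], ...]
    abs_flags: tuple[bool, ...]

    def __post_init__(self) -> None:
        if self.order not in (1, 2, 3):
            raise ValueError(f"order must be 1, 2 or 3, got {self.order}")
        if len(self.pairing) != self.order:
            raise ValueError("pairing must contain one chord per order")
        if len(self.abs_flags) != self.order:
            raise ValueError("abs_flags must contain one flag per chord")
        seen = [p for chord in self.pairing for p in chord]
        if sorted(seen) != list(range(1, 2 * self.order + 1)):
            raise ValueError(
                f"pairing {self.pairing} is not a perfect matching of "
                f"1..{2 * self.order}"
            )
        for a, b in self.pairing:
            if a >= b:
                raise ValueError(f"chord {(a, b)} must be ordered a < b")

    @property
    def label(self) -> str:
        """Human-readable name, e.g. ``I(1,3)(2,4)`` or ``I|1,2|``."""
        parts = []
        for (a, b), absf in zip(self.pairing, self.abs_flags):
            parts.append(f"|{a},{b}|" if absf else f"({a},{b})")
        return "I" + "".join(parts)

    @property
    def n_plain(self) -> int:
        """Number of non-absolute W factors (parity governs mirror
        antisymmetry: odd -> the invariant flips sign under reflection)."""
        return sum(not f for f in self.abs_flags)


def perfect_matchings(n: int) -> list[tuple[tuple[int, int], ...]]:
    """All perfect matchings of positions ``1..n`` (``n`` even), each chord
    ordered and chords sorted by first element; lexicographic output order."""
    if n % 2:
        raise ValueError("n must be even")

    def rec(avail: tuple[int, ...]) -> list[tuple[tuple[int, int], ...]]:
        if not avail:
            return [()]
        first, rest = avail[0], avail[1:]
        out = []
        for i, partner in enumerate(rest):
            sub = rest[:i] + rest[i + 1:]
            for tail in rec(sub):
                out.append(((first, partner),) + tail)
        return out

    return sorted(rec(tuple(range(1, n + 1))))


@lru_cache(maxsize=None)
def descriptor_patterns() -> tuple[ChordPattern, ...]:
    """The frozen 29-pattern enumeration behind descriptor components 2-30."""
    pats: list[ChordPattern] = []
    # order 1: plain writhe and average crossing number
    pats.append(ChordPattern(1, ((1, 2),), (False,)))
    pats.append(ChordPattern(1, ((1, 2),), (True,)))
    # order 2: 3 matchings x 4 abs combinations
    for pairing in perfect_matchings(4):
        for flags in product((False, True), repeat=2):
            pats.append(ChordPattern(2, pairing, flags))
    # order 3: 15 matchings, plain only
    for pairing in perfect_matchings(6):
        pats.append(ChordPattern(3, pairing, (False, False, False)))
    assert len(pats) == 29
    return tuple(pats)


def component_labels() -> tuple[str, ...]:
    """Labels of all 30 descriptor components, length measure first."""
    return ("N",) + tuple(p.label for p in descriptor_patterns())
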