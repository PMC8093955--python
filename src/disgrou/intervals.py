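"""Closed-interval arithmetic for subgroup descriptions.

Subgroup descriptions in this package restrict a numeric attribute to a
*union of closed intervals*.  Raw selectors carry at most two components
(one continuous interval or a union of two disjoint ones); intersections of
selectors on the same attribute may produce more.  :class:`IntervalSet` is
the canonical representation: components sorted ascending, pairwise
disjoint, overlapping or touching components merged on construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = ["Interval", "IntervalSet"]


@dataclass(frozen=True, order=True)
class Interval:
    """A closed numeric interval [low; high]; both endpoints included."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.high):
            raise ValueError(f"invalid interval: low={self.low} > high={self.high}")

    def contains(self, value: float) -> bool:
        return self.low <= value <= self.high

    @property
    def length(self) -> float:
        return self.high - self.low

    def __str__(self) -> str:  # bracket-and-semicolon field convention
        return f"[{fmt(self.low)};{fmt(self.high)}]"


def fmt(x: float) -> str:
    """Render an endpoint without losing precision (ints without '.0')."""
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


class IntervalSet:
    """An ordered union of pairwise-disjoint closed intervals.

    Construction canonicalizes: components are sorted by their lower
    endpoint and any overlapping or touching pair is merged, so two
    IntervalSets describing the same point set compare equal.  The set is
    never empty; use ``intersect`` (which may return None) for operations
    that can annihilate.
    """

    __slots__ = ("components", "_hash")

    def __init__(self, components: Iterable[Interval]) -> None:
        comps = sorted(components, key=lambda iv: (iv.low, iv.high))
        if not comps:
            raise ValueError("IntervalSet must have at least one component")
        merged: list[Interval] = [comps[0]]
        for iv in comps[1:]:
            last = merged[-1]
            if iv.low <= last.high:  # overlap or touch -> merge
                if iv.high > last.high:
                    merged[-1] = Interval(last.low, iv.high)
            else:
                merged.append(iv)
        object.__setattr__(self, "components", tuple(merged))
        object.__setattr__(self, "_hash", hash(self.components))

    @classmethod
    def from_bounds(cls, *bounds: tuple[float, float]) -> "IntervalSet":
        return cls(Interval(lo, hi) for lo, hi in bounds)

    # -- set predicates -------------------------------------------------

    def contains(self, value: float) -> bool:
        return any(c.contains(value) for c in self.components)

    def contains_array(self, values: np.ndarray) -> np.ndarray:
        """Vectorized membership over a 1-D value array."""
        mask = np.zeros(len(values), dtype=bool)
        for c in self.components:
            mask |= (values >= c.low) & (values <= c.high)
        return mask

    def issuperset(self, other: "IntervalSet") -> bool:
        """True iff every point of *other* lies in *self*."""
        i = 0
        for oc in other.components:
            while i < len(self.components) and self.components[i].high < oc.low:
                i += 1
            if i == len(self.components):
                return False
            sc = self.components[i]
            if not (sc.low <= oc.low and oc.high <= sc.high):
                return False
        return True

    # -- set algebra ----------------------------------------------------

    def intersect(self, other: "IntervalSet") -> Optional["IntervalSet"]:
        """Intersection; None when the point sets are disjoint."""
        out: list[Interval] = []
        for a in self.components:
            for b in other.components:
                lo, hi = max(a.low, b.low), min(a.high, b.high)
                if lo <= hi:
                    out.append(Interval(lo, hi))
        return IntervalSet(out) if out else None

    def subtract_open(self, hole: "IntervalSet") -> Optional["IntervalSet"]:
        """Remove the open interior of *hole*, keeping its endpoints.

        Used by the planted-effect generator: a favorable range degraded on
        the strict inside of a hostile sub-range keeps its boundary values.
        """
        comps = list(self.components)
        for h in hole.components:
            nxt: list[Interval] = []
            for c in comps:
                if c.high <= h.low or c.low >= h.high:
                    nxt.append(c)
                    continue
                if c.low <= h.low:
                    nxt.append(Interval(c.low, min(c.high, h.low)))
                if c.high >= h.high:
                    nxt.append(Interval(max(c.low, h.high), c.high))
            comps = nxt
        return IntervalSet(comps) if comps else None

    @property
    def total_length(self) -> float:
        return sum(c.length for c in self.components)

    def jaccard(self, other: "IntervalSet") -> float:
        """Length-based (Lebesgue) Jaccard index in [0, 1].

        Identical sets score 1 even when all components are points
        (zero measure); otherwise a zero-measure overlap scores 0.
        """
        if self == other:
            return 1.0
        inter = self.intersect(other)
        ilen = inter.total_length if inter is not None else 0.0
        ulen = self.total_length + other.total_length - ilen
        if ulen == 0.0:
            return 0.0
        return ilen / ulen

    # -- dunder ---------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IntervalSet) and self.components == other.components

    def __hash__(self) -> int:
        return self._hash

    def __len__(self) -> int:
        return len(self.components)

    def __iter__(self):
        return iter(self.components)

    def __str__(self) -> str:
        return " ∪ ".join(str(c) for c in self.components)

    def __repr__(self) -> str:
        return f"IntervalSet({list(self.components)!r})"

    def endpoint_key(self) -> tuple:
        """Flat endpoint tuple, usable as a deterministic sort key."""
        return tuple(x for c in self.components for x in (c.low, c.high))


def parse_interval_set(text: str) -> IntervalSet:
    """Parse the rendering convention "[a;b] ∪ [c;d]" back to a set.

    Accepts either the Unicode union sign or a bare "U" separator and
    tolerates surrounding whitespace.
    """
    parts = text.replace("∪", "U").split("U")
    comps = []
    for part in parts:
        p = part.strip()
        if not (p.startswith("[") and p.endswith("]")):
            raise ValueError(f"malformed interval component: {part!r}")
        lo_s, _, hi_s = p[1:-1].partition(";")
        if not _:
            raise ValueError(f"malformed interval component: {part!r}")
        comps.append(Interval(float(lo_s), float(hi_s)))
    return IntervalSet(comps)
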