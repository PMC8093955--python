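"""Raw-selector extraction by interval erosion.

For each attribute the search starts from the attribute's complete range
and erodes it: endpoints may be drawn in, and a continuous interval may be
split into a union of two disjoint intervals.  Interval endpoints are
always actual attribute values observed among the positive transactions
(the value grid), so no prior discretization is needed.  An eroded set is
kept when it satisfies the three rules:

1. it is a single closed interval or a union of two disjoint ones;
2. for a union, each component holds strictly more than a fifth of the
   other component's positive-transaction count (the balance rule, which
   stops a meaningful interval from dragging along an irrelevant sliver);
3. its positive support strictly exceeds the support threshold β.

Enumerating every grid interval and every balanced disjoint pair visits
all erosion orders at once; candidates whose extent over the full dataset
coincides are duplicates of one another (they admit exactly the same
transactions) and are emitted once, represented by the candidate with the
fewest components, then the largest total length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_model import Config, DataError, Dataset, Selector, positive_transactions
from .intervals import Interval, IntervalSet

__all__ = [
    "SelectorVocabulary",
    "candidate_grid",
    "balance_ok",
    "erode_attribute",
    "make_raw_selectors",
]


def candidate_grid(dataset: Dataset, attribute: str) -> np.ndarray:
    """Sorted distinct values of *attribute* among positive transactions.

    Interval endpoints are always drawn from this grid: endpoints taken
    from negative-only values cannot change a selector's positive support.
    """
    pos = positive_transactions(dataset)
    if len(pos) == 0:
        raise DataError("no positive transactions; no subgroup can beat the mean")
    return np.unique(dataset.column(attribute)[pos])


def balance_ok(count_left: int, count_right: int) -> bool:
    """One-fifth balance rule for union selectors (strict both ways)."""
    return count_left > count_right / 5 and count_right > count_left / 5


def _dedup_key(ranges: IntervalSet) -> tuple:
    # fewer components, then larger total length, then endpoint order
    return (len(ranges), -ranges.total_length, ranges.endpoint_key())


def erode_attribute(
    dataset: Dataset, attribute: str, beta_abs: int
) -> list[Selector]:
    """All rule-satisfying selectors on one attribute, deduplicated.

    Returns selectors in a deterministic order (by the dedup preference
    key); global frequency sorting happens in :func:`make_raw_selectors`.
    """
    if beta_abs < 1:
        raise ValueError("beta_abs must be >= 1")
    grid = candidate_grid(dataset, attribute)
    pos = positive_transactions(dataset)
    col = dataset.column(attribute)
    pos_vals = col[pos]
    g = len(grid)
    # positive count at each grid value, and prefix sums for interval support
    counts = np.array([(pos_vals == v).sum() for v in grid], dtype=int)
    csum = np.concatenate([[0], np.cumsum(counts)])

    def possup(i: int, j: int) -> int:  # grid interval [grid[i]; grid[j]]
        return int(csum[j + 1] - csum[i])

    candidates: list[tuple[IntervalSet, int]] = []
    # the complete attribute range over the full dataset (erosion root)
    full = IntervalSet([Interval(dataset.attr_min(attribute),
                                 dataset.attr_max(attribute))])
    n_pos_total = len(pos)
    if n_pos_total > beta_abs:
        candidates.append((full, n_pos_total))
    # continuous grid intervals
    for i in range(g):
        for j in range(i, g):
            s = possup(i, j)
            if s > beta_abs:
                candidates.append(
                    (IntervalSet([Interval(grid[i], grid[j])]), s)
                )
    # disjoint pairs of grid intervals
    for i1 in range(g):
        for j1 in range(i1, g - 1):
            c1 = possup(i1, j1)
            if c1 == 0:
                continue
            for i2 in range(j1 + 1, g):
                for j2 in range(i2, g):
                    c2 = possup(i2, j2)
                    if c1 + c2 <= beta_abs:
                        continue
                    if not balance_ok(c1, c2):
                        continue
                    candidates.append(
                        (
                            IntervalSet(
                                [
                                    Interval(grid[i1], grid[j1]),
                                    Interval(grid[i2], grid[j2]),
                                ]
                            ),
                            c1 + c2,
                        )
                    )

    # deduplicate by extent over the full dataset; membership of the
    # column's distinct values determines the extent, so the dedup key is
    # computed on the (much shorter) unique-value vector
    uniq = np.unique(col)
    best: dict[bytes, tuple[tuple, IntervalSet, int]] = {}
    for ranges, support in candidates:
        ext_key = np.packbits(ranges.contains_array(uniq)).tobytes()
        key = _dedup_key(ranges)
        kept = best.get(ext_key)
        if kept is None or key < kept[0]:
            best[ext_key] = (key, ranges, support)
    out = [
        Selector(attribute, ranges, support)
        for _, ranges, support in sorted(best.values(), key=lambda t: t[0])
    ]
    return out


@dataclass
class SelectorVocabulary:
    """The globally ordered selector list used to build the FP-tree.

    Order is descending positive support ("frequency"); ties are broken by
    larger full extent, then attribute position, then endpoint order, so
    runs are reproducible.  ``extents`` caches each selector's boolean
    extent mask over the dataset it was built from.
    """

    selectors: list[Selector]
    extents: list[np.ndarray] = field(default_factory=list)
    source: Optional[Dataset] = None  # dataset the cached extents refer to

    def __len__(self) -> int:
        return len(self.selectors)

    def __iter__(self):
        return iter(self.selectors)

    def __getitem__(self, i: int) -> Selector:
        return self.selectors[i]

    def index_by_attribute(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.selectors):
            out.setdefault(s.attribute, []).append(i)
        return out

    @classmethod
    def from_selectors(
        cls,
        selectors: Sequence[Selector],
        dataset: Dataset,
        sort: bool = False,
    ) -> "SelectorVocabulary":
        """Build a vocabulary from explicit selectors (mainly for tests)."""
        attr_pos = {a: i for i, a in enumerate(dataset.attribute_names)}
        sels = list(selectors)
        exts = [
            s.ranges.contains_array(dataset.column(s.attribute)) for s in sels
        ]
        if sort:
            order = sorted(
                range(len(sels)),
                key=lambda k: (
                    -sels[k].pos_support,
                    -int(exts[k].sum()),
                    attr_pos[sels[k].attribute],
                    sels[k].ranges.endpoint_key(),
                ),
            )
            sels = [sels[k] for k in order]
            exts = [exts[k] for k in order]
        return cls(sels, exts, dataset)

    def to_table(self) -> list[tuple[str, str, int]]:
        """(attribute, rendered ranges, pos_support) rows for diagnostics."""
        return [(s.attribute, str(s.ranges), s.pos_support) for s in self.selectors]


def make_raw_selectors(dataset: Dataset, config: Config) -> SelectorVocabulary:
    """Erode every attribute and sort the union of selectors by frequency."""
    pos = positive_transactions(dataset)
    if len(pos) == 0:
        raise DataError("no positive transactions; no subgroup can beat the mean")
    beta_abs = config.resolve_beta_abs(len(pos))
    selectors: list[Selector] = []
    for attribute in dataset.attribute_names:
        selectors.extend(erode_attribute(dataset, attribute, beta_abs))
    return SelectorVocabulary.from_selectors(selectors, dataset, sort=True)
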