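"""The frequency-ordered prefix tree over selector matches.

Every node is a triplet (selector, transaction count, target sum): the
transactions counted at a node are exactly those matching every selector
on the root path, inserted in global vocabulary order.  Unlike a classic
FP-tree, several selectors of the same attribute may lie on one branch
(nested or overlapping ranges all match), so depth is bounded by the
selector count, not the attribute count.

Construction is insertion-order independent: permuting the transactions
yields an isomorphic tree with identical path aggregates, which is what
licenses building partial trees in parallel and merging them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional
import warnings

import numpy as np

from .data_model import Dataset
from .selectors import SelectorVocabulary

__all__ = ["FPNode", "FPTree", "insert_transaction", "build_tree"]


@dataclass
class FPNode:
    """A prefix-tree node: selector index, count and target sum."""

    selector: int  # index into the vocabulary; -1 for the root
    count: int = 0
    target_sum: float = 0.0
    children: dict[int, "FPNode"] = field(default_factory=dict)
    parent: Optional["FPNode"] = None

    def path_selectors(self) -> tuple[int, ...]:
        """Selector indices on the root path, in vocabulary order."""
        path = []
        node = self
        while node.parent is not None:
            path.append(node.selector)
            node = node.parent
        return tuple(reversed(path))


@dataclass
class FPTree:
    root: FPNode = field(default_factory=lambda: FPNode(selector=-1))
    header: dict[int, list[FPNode]] = field(default_factory=dict)

    def nodes(self) -> list[FPNode]:
        out, stack = [], list(self.root.children.values())
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children.values())
        return out

    # -- diagnostics ----------------------------------------------------

    def to_text(self, vocabulary: SelectorVocabulary) -> str:
        lines: list[str] = []

        def walk(node: FPNode, depth: int) -> None:
            for key in sorted(node.children):
                child = node.children[key]
                s = vocabulary[child.selector]
                lines.append(
                    "  " * depth
                    + f"{s} (count={child.count}, sum={child.target_sum:g})"
                )
                walk(child, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines)

    def to_dot(self, vocabulary: SelectorVocabulary) -> str:
        lines = ["digraph fptree {", '  root [label="root"];']
        counter = [0]

        def walk(node: FPNode, name: str) -> None:
            for key in sorted(node.children):
                child = node.children[key]
                counter[0] += 1
                cname = f"n{counter[0]}"
                s = vocabulary[child.selector]
                lines.append(
                    f'  {cname} [label="{s}\\n'
                    f'count={child.count} sum={child.target_sum:g}"];'
                )
                lines.append(f"  {name} -> {cname};")
                walk(child, cname)

        walk(self.root, "root")
        lines.append("}")
        return "\n".join(lines)


def insert_transaction(
    tree: FPTree,
    transaction: int,
    dataset: Dataset,
    vocabulary: SelectorVocabulary,
    matches: Optional[np.ndarray] = None,
) -> FPTree:
    """Insert one transaction, descending through its matched selectors.

    Walking the vocabulary in order, a matched selector either increments
    the corresponding child (count and target sum) or creates it; skipped
    selectors leave no node, and a transaction matching nothing leaves the
    tree unchanged.
    """
    if matches is None:
        matches = np.array(
            [
                vocabulary[i].ranges.contains(
                    float(dataset.column(vocabulary[i].attribute)[transaction])
                )
                for i in range(len(vocabulary))
            ]
        )
    t_val = float(dataset.target[transaction])
    node = tree.root
    for i in np.flatnonzero(matches):
        i = int(i)
        child = node.children.get(i)
        if child is None:
            child = FPNode(selector=i, parent=node)
            node.children[i] = child
            tree.header.setdefault(i, []).append(child)
        child.count += 1
        child.target_sum += t_val
        node = child
    return tree


def build_tree(dataset: Dataset, vocabulary: SelectorVocabulary) -> FPTree:
    """Insert every transaction of the dataset (all of T, not only pos(T)).

    Counts and sums therefore reflect the full population, which the
    quality function needs: a subgroup mean is a full-population mean.
    """
    tree = FPTree()
    if len(vocabulary) == 0:
        warnings.warn("empty selector vocabulary: FP-tree has a root only")
        return tree
    if (
        vocabulary.source is dataset
        and vocabulary.extents
        and len(vocabulary.extents) == len(vocabulary)
    ):
        match_matrix = np.column_stack(vocabulary.extents)
    else:
        match_matrix = np.column_stack(
            [
                s.ranges.contains_array(dataset.column(s.attribute))
                for s in vocabulary
            ]
        )
    for t in range(dataset.n_transactions):
        insert_transaction(tree, t, dataset, vocabulary, matches=match_matrix[t])
    return tree
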