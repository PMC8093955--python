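"""Branch combination: from tree paths to ranked subgroups.

For each selector s (in vocabulary order) and each tree node carrying s,
every sub-combination of the node's root path whose latest-ordered element
is s is tallied with the node's (count, target sum).  Because a transaction
matching all selectors of a combination passes through exactly one node of
the combination's latest selector whose path contains the rest, each
(combination, transaction) pair is counted exactly once, and summing the
tallies across branches yields the combination's exact extent size and
target sum.

Two pruning rules keep the enumeration at the scale of distinct
descriptions rather than of all selector subsets.  A selector is not added
to a combination when (i) its ranges contain the running per-attribute
intersection (it would add no constraint), or (ii) adding it would make an
already-included same-attribute selector redundant (the intersection of
the others is already inside it, so removing it would not change the
description).  Every combination skipped by either rule describes the same
point set - hence the same subgroup, with identical count and sum - as a
smaller combination that is still enumerated, and both rules depend only
on the combination's own content, never on the branch, so the tallies of
every enumerated combination remain exact.  The brute-force oracle
enumerates without these rules and must agree.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .data_model import (
    Config,
    Dataset,
    Selector,
    Subgroup,
    quality,
    subgroup_extent,
    target_mean,
    positive_transactions,
)
from .fptree import FPTree, build_tree
from .intervals import IntervalSet
from .selectors import SelectorVocabulary, make_raw_selectors

__all__ = [
    "BranchEntry",
    "CandidateExplosionError",
    "collect_branches",
    "enumerate_candidates",
    "combination_to_description",
    "rank_subgroups",
    "run_disgrou",
]


class CandidateExplosionError(RuntimeError):
    """The combination space exceeded the enumeration budget.

    The candidate language grows exponentially with the number of
    overlapping same-attribute selectors; a stricter support threshold (or
    ``max_attrs``) shrinks it.
    """


@dataclass(frozen=True)
class BranchEntry:
    """A root-to-node path with the end node's aggregates."""

    path_selectors: tuple[int, ...]  # vocabulary indices, in vocabulary order
    count: int
    target_sum: float


def collect_branches(
    tree: FPTree, selector: Selector, vocabulary: SelectorVocabulary
) -> list[BranchEntry]:
    """One entry per tree node carrying *selector* (via the header table)."""
    try:
        idx = vocabulary.selectors.index(selector)
    except ValueError:
        return []
    return [
        BranchEntry(node.path_selectors(), node.count, node.target_sum)
        for node in tree.header.get(idx, [])
    ]


def _redundant(sel: Selector, inter: dict[str, IntervalSet]) -> bool:
    cur = inter.get(sel.attribute)
    return cur is not None and sel.ranges.issuperset(cur)


def _makes_member_redundant(
    sel: Selector, members_on_attr: list[IntervalSet]
) -> bool:
    """Would adding *sel* make an included same-attribute selector useless?

    A member is redundant when the intersection of the other same-attribute
    members (including the newcomer) already lies inside it.
    """
    k = len(members_on_attr)
    for i in range(k):
        inter: Optional[IntervalSet] = sel.ranges
        for j in range(k):
            if j == i:
                continue
            inter = inter.intersect(members_on_attr[j])
            if inter is None:
                break
        if inter is not None and members_on_attr[i].issuperset(inter):
            return True
    return False


def enumerate_candidates(
    tree: FPTree,
    vocabulary: SelectorVocabulary,
    config: Config,
    beta_abs: Optional[int] = None,
    max_candidates: int = 200_000,
    max_ops: int = 300_000,
) -> dict[tuple[int, ...], tuple[int, float]]:
    """Tally all selector combinations across branches.

    Returns a map from combination (ascending vocabulary indices) to its
    aggregated (count, target_sum).  Combinations whose aggregated count
    does not strictly exceed the support threshold are dropped
    (removeNonFrequent), mirroring the rule used for raw selectors.
    """
    if beta_abs is None:
        if config.beta_abs is None:
            raise ValueError(
                "enumerate_candidates needs an absolute support threshold; "
                "pass beta_abs or use Config(beta_abs=...)"
            )
        beta_abs = config.beta_abs
    max_attrs = config.max_attrs
    table: dict[tuple[int, ...], list] = {}

    # One depth-first walk of the tree.  The walk carries the list of
    # irredundant sub-combinations of the current root path; entering a
    # node extends each of them (rules permitting) by the node's selector,
    # and exactly those extended combinations - the path combinations
    # whose latest-ordered element is this node's selector - are tallied
    # with the node's aggregates.  Sibling subtrees share all prefix work.
    ops = 0

    def visit(node, subsets) -> None:
        nonlocal ops
        ops += len(subsets)
        if ops > max_ops:
            raise CandidateExplosionError(
                f"combination enumeration exceeded its budget of {max_ops} "
                "extension attempts; raise the support threshold beta or "
                "set max_attrs"
            )
        i = node.selector
        sel = vocabulary[i]
        new = []
        for combo, inter, members in subsets:
            if _redundant(sel, inter):
                continue
            if _makes_member_redundant(sel, members.get(sel.attribute, [])):
                continue
            if max_attrs is not None and (
                len(inter) + (sel.attribute not in inter) > max_attrs
            ):
                continue
            cur = inter.get(sel.attribute)
            if cur is None:
                nxt = sel.ranges
            else:
                nxt = cur.intersect(sel.ranges)
                assert nxt is not None, "selectors on one branch must intersect"
            new.append(
                (
                    combo + (i,),
                    {**inter, sel.attribute: nxt},
                    {
                        **members,
                        sel.attribute: members.get(sel.attribute, [])
                        + [sel.ranges],
                    },
                )
            )
        count, tsum = node.count, node.target_sum
        for combo, _, _ in new:
            cell = table.get(combo)
            if cell is None:
                table[combo] = [count, tsum]
            else:
                cell[0] += count
                cell[1] += tsum
        if len(table) > max_candidates:
            raise CandidateExplosionError(
                f"over {max_candidates} candidate combinations; "
                "raise the support threshold beta or set max_attrs"
            )
        merged = subsets + new
        for child in node.children.values():
            visit(child, merged)

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, len(vocabulary) + 500))
    try:
        for child in tree.root.children.values():
            visit(child, [((), {}, {})])
    finally:
        sys.setrecursionlimit(old_limit)

    return {
        key: (cnt, tsum)
        for key, (cnt, tsum) in table.items()
        if cnt > beta_abs
    }


def combination_to_description(
    combination: Sequence[Selector],
) -> dict[str, IntervalSet]:
    """Conjunctive description: same-attribute selectors are intersected.

    The result may carry more than two components per attribute even
    though raw selectors never do.
    """
    if not combination:
        raise ValueError("empty combination")
    out: dict[str, IntervalSet] = {}
    for sel in combination:
        cur = out.get(sel.attribute)
        if cur is None:
            out[sel.attribute] = sel.ranges
        else:
            inter = cur.intersect(sel.ranges)
            if inter is None:
                raise AssertionError(
                    "empty same-attribute intersection in a populated combination"
                )
            out[sel.attribute] = inter
    return out


def _description_key(description: Mapping[str, IntervalSet]) -> tuple:
    return tuple(
        (attr, description[attr].endpoint_key()) for attr in sorted(description)
    )


def _render(description: Mapping[str, IntervalSet]) -> str:
    return " AND ".join(
        f"{a} ∈ {description[a]}" for a in sorted(description)
    )


def _tie_key(sub: Subgroup) -> tuple:
    n_comp = sum(len(v) for v in sub.description.values())
    return (-sub.quality, len(sub.description), n_comp, _render(sub.description))


def rank_subgroups(
    candidates: Mapping[tuple[int, ...], tuple[int, float]],
    dataset: Dataset,
    config: Config,
    vocabulary: SelectorVocabulary,
) -> list[Subgroup]:
    """Score candidates, merge description-duplicates, sort and truncate.

    Ties in quality are broken toward simpler subgroups: fewer attributes,
    then fewer interval components, then lexicographic rendering.  Every
    candidate's aggregates are cross-checked against direct filtering of
    the dataset (exact count, floating-point-level sum agreement).
    """
    if not candidates:
        warnings.warn("no candidate subgroups (support threshold too strict?)")
        return []
    m0 = target_mean(dataset)
    by_desc: dict[tuple, Subgroup] = {}
    for combo, (count, tsum) in candidates.items():
        description = combination_to_description(
            [vocabulary[i] for i in combo]
        )
        key = _description_key(description)
        prev = by_desc.get(key)
        if prev is None:
            by_desc[key] = Subgroup(
                description=description,
                n=count,
                target_sum=tsum,
                quality=quality(count, tsum, m0, config.alpha),
            )
        elif prev.n != count:
            raise AssertionError(
                f"inconsistent tallies for {_render(description)}: "
                f"{prev.n} vs {count}"
            )
    ranked = sorted(by_desc.values(), key=_tie_key)[: config.top_k]
    for sub in ranked:  # extent-consistency of everything reported
        ext = subgroup_extent(sub.description, dataset)
        if len(ext) != sub.n or not np.isclose(
            float(dataset.target[ext].sum()), sub.target_sum,
            rtol=1e-9, atol=1e-6,
        ):
            raise AssertionError(
                f"extent inconsistency for {_render(sub.description)}: "
                f"tree ({sub.n}, {sub.target_sum}) vs direct "
                f"({len(ext)}, {float(dataset.target[ext].sum())})"
            )
    return ranked


def run_disgrou(dataset: Dataset, config: Config) -> list[Subgroup]:
    """The full pipeline: selectors -> tree -> combinations -> ranking."""
    vocabulary = make_raw_selectors(dataset, config)
    if len(vocabulary) == 0:
        warnings.warn("empty selector vocabulary; no subgroups")
        return []
    beta_abs = config.resolve_beta_abs(len(positive_transactions(dataset)))
    tree = build_tree(dataset, vocabulary)
    candidates = enumerate_candidates(tree, vocabulary, config, beta_abs=beta_abs)
    return rank_subgroups(candidates, dataset, config, vocabulary)
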