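"""Core domain types, target statistics, extents and the quality function.

The quality of a subgroup P of size n with target mean m_P, against a
population with target mean m_0, is

    q_a(P) = n**a * (m_P - m_0),        a in [0, 1]

where the exponent ``a`` (``alpha`` here) trades subgroup size against mean
shift: a=0 ranks by mean shift alone, a=1 weighs every member.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .intervals import IntervalSet

__all__ = [
    "Dataset",
    "Selector",
    "Subgroup",
    "Config",
    "DataError",
    "target_mean",
    "positive_transactions",
    "selector_extent",
    "subgroup_extent",
    "quality",
]


class DataError(ValueError):
    """Invalid input data (missing values, unknown columns, empty table)."""


@dataclass(frozen=True)
class Selector:
    """A condition "attribute value ∈ ranges" with its cached pos-support.

    Raw selectors carry at most two interval components; ``pos_support`` is
    the number of positive transactions (target strictly above the
    population mean) whose attribute value lies in ``ranges``.
    """

    attribute: str
    ranges: IntervalSet
    pos_support: int = 0

    def __str__(self) -> str:
        return f"{self.attribute} ∈ {self.ranges}"


class Dataset:
    """A numeric transaction table with one designated numeric target.

    Rejects missing or non-finite cells at construction: the method has no
    notion of imputation, and a silent NaN would corrupt every count and
    target sum downstream.
    """

    def __init__(
        self,
        attribute_names: Sequence[str],
        values: np.ndarray,
        target: np.ndarray,
        target_name: str = "target",
    ) -> None:
        values = np.asarray(values, dtype=float)
        target = np.asarray(target, dtype=float)
        if values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        n, m = values.shape
        if n < 1:
            raise DataError("empty dataset")
        if m != len(attribute_names):
            raise DataError(
                f"{len(attribute_names)} attribute names for {m} value columns"
            )
        if m < 1:
            raise DataError("no attributes")
        if target.shape != (n,):
            raise DataError("target length does not match transaction count")
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite value at row {r}, column {attribute_names[c]!r}"
            )
        if not np.all(np.isfinite(target)):
            r = int(np.argwhere(~np.isfinite(target))[0][0])
            raise DataError(f"non-finite target at row {r}")
        self.attribute_names = list(attribute_names)
        self.values = values
        self.target = target
        self.target_name = target_name
        self._col = {a: i for i, a in enumerate(self.attribute_names)}
        if len(self._col) != len(self.attribute_names):
            raise DataError("duplicate attribute names")

    # -- basic accessors ------------------------------------------------

    @property
    def n_transactions(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def column(self, attribute: str) -> np.ndarray:
        try:
            return self.values[:, self._col[attribute]]
        except KeyError:
            raise DataError(
                f"unknown attribute {attribute!r}; have {self.attribute_names}"
            ) from None

    def attr_min(self, attribute: str) -> float:
        return float(self.column(attribute).min())

    def attr_max(self, attribute: str) -> float:
        return float(self.column(attribute).max())


@dataclass(frozen=True)
class Subgroup:
    """A ranked result: a conjunctive description with its exact extent.

    ``n`` and ``target_sum`` always equal the values obtained by filtering
    the dataset directly with ``description`` (extent-consistency); the
    mining pipeline asserts this rather than assuming it.
    """

    description: Mapping[str, IntervalSet]
    n: int
    target_sum: float
    quality: float

    @property
    def mean(self) -> float:
        return self.target_sum / self.n

    def render(self) -> str:
        return " AND ".join(
            f"{a} ∈ {self.description[a]}" for a in sorted(self.description)
        )


@dataclass
class Config:
    """Run parameters.

    beta
        support threshold: fraction in (0, 1) of |pos(T)|, or an absolute
        count via ``beta_abs``.  A selector (and an aggregated combination)
        must have support *strictly greater* than the resolved absolute
        threshold.  No default: the threshold is dataset-dependent.
    alpha
        quality exponent in [0, 1]; default 1.0.
    top_k
        number of subgroups reported; default 10.
    max_attrs
        optional cap on the number of distinct attributes per description.
    """

    beta: Optional[float] = None
    beta_abs: Optional[int] = None
    alpha: float = 1.0
    top_k: int = 10
    max_attrs: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0;1], got {self.alpha}")
        if self.beta is None and self.beta_abs is None:
            raise ValueError("a support threshold is required (beta or beta_abs)")
        if self.beta is not None and not (0.0 < self.beta < 1.0):
            raise ValueError(f"beta fraction must be in (0,1), got {self.beta}")
        if self.beta_abs is not None and self.beta_abs < 1:
            raise ValueError(f"absolute beta must be >= 1, got {self.beta_abs}")
        if self.top_k < 1:
            raise ValueError("top_k must be positive")

    def resolve_beta_abs(self, n_pos: int) -> int:
        """Absolute support threshold for a dataset with |pos(T)| = n_pos."""
        if self.beta_abs is not None:
            return self.beta_abs
        return max(1, math.ceil(self.beta * n_pos))


# -- target statistics and extents --------------------------------------


def target_mean(dataset: Dataset) -> float:
    """Population target mean m_0."""
    if dataset.n_transactions == 0:
        raise DataError("empty dataset")
    return float(dataset.target.mean())


def positive_transactions(dataset: Dataset) -> np.ndarray:
    """Ids of pos(T): transactions whose target strictly exceeds m_0.

    Strictly — transactions tied with the mean sit outside pos(T).  May be
    empty (e.g. a constant target), in which case no subgroup can beat the
    population mean.
    """
    m0 = target_mean(dataset)
    return np.flatnonzero(dataset.target > m0)


def selector_extent(selector: Selector, dataset: Dataset) -> np.ndarray:
    """Ids of transactions whose value lies in the selector's ranges."""
    col = dataset.column(selector.attribute)
    return np.flatnonzero(selector.ranges.contains_array(col))


def subgroup_extent(
    description: Mapping[str, IntervalSet], dataset: Dataset
) -> np.ndarray:
    """Extent of a conjunction: intersection of per-attribute extents.

    An empty description denotes the empty conjunction and matches every
    transaction.
    """
    mask = np.ones(dataset.n_transactions, dtype=bool)
    for attribute, ranges in description.items():
        mask &= ranges.contains_array(dataset.column(attribute))
    return np.flatnonzero(mask)


def quality(n: int, target_sum: float, m0: float, alpha: float) -> float:
    """q_a = n**alpha * (target_sum / n - m0)."""
    if n < 1:
        raise ValueError("empty subgroup has no quality")
    return float(n) ** alpha * (target_sum / n - m0)
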