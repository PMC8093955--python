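"""Independent oracle and planted-subgroup synthetic benchmarks.

``brute_force_search`` re-derives the best subgroup from first principles
- every selector combination, extents by direct filtering - and is the
independent cross-check for the tree + combiner path.  ``generate_planted``
builds datasets with a known elevated region so recovery can be measured
with no external data.

The stock scenario mirrors a crop-climate story: banana grows between 9 and
40 degrees C with a favorable harvest window of [23;33], but the black
sigatoka fungus thrives in [25;28] and depresses yield there, so the truly
favorable set is the discontinuous [23;25] ∪ [28;33] - exactly the kind of
description a continuous-interval method cannot express.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .data_model import (
    Config,
    DataError,
    Dataset,
    Subgroup,
    quality,
    target_mean,
)
from .combiner import _description_key, _tie_key, combination_to_description
from .intervals import Interval, IntervalSet
from .selectors import SelectorVocabulary

__all__ = [
    "PlantedSpec",
    "banana_spec",
    "generate_planted",
    "recovery_score",
    "brute_force_search",
    "random_instance",
]


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_search(
    dataset: Dataset,
    vocabulary: SelectorVocabulary,
    config: Config,
    beta_abs: Optional[int] = None,
    allow_large: bool = False,
) -> Optional[Subgroup]:
    """Exhaustive search over all selector combinations.

    Extents are computed by direct filtering (boolean masks), the same
    strict support rule is applied to each combination, and the
    quality-maximal subgroup is returned under the same tie-break as the
    mining pipeline.  Guarded against vocabularies over 20 selectors,
    where full enumeration stops being a desk-scale oracle.
    """
    if len(vocabulary) == 0:
        return None
    if len(vocabulary) > 20 and not allow_large:
        raise ValueError(
            f"vocabulary of {len(vocabulary)} selectors is too large for "
            "exhaustive search; use a smaller instance or allow_large=True"
        )
    if beta_abs is None:
        if config.beta_abs is not None:
            beta_abs = config.beta_abs
        else:
            from .data_model import positive_transactions

            beta_abs = config.resolve_beta_abs(
                len(positive_transactions(dataset))
            )
    masks = [
        s.ranges.contains_array(dataset.column(s.attribute)) for s in vocabulary
    ]
    target = dataset.target
    m0 = target_mean(dataset)
    max_attrs = config.max_attrs
    best: dict[tuple, Subgroup] = {}

    def consider(combo: list[int], mask: np.ndarray) -> None:
        count = int(mask.sum())
        tsum = float(target[mask].sum())
        description = combination_to_description(
            [vocabulary[i] for i in combo]
        )
        key = _description_key(description)
        sub = Subgroup(description, count, tsum,
                       quality(count, tsum, m0, config.alpha))
        prev = best.get(key)
        if prev is not None:
            assert prev.n == count, "description-duplicate count mismatch"
        else:
            best[key] = sub

    def walk(start: int, combo: list[int], mask: np.ndarray,
             attrs: frozenset) -> None:
        for i in range(start, len(vocabulary)):
            sel = vocabulary[i]
            new_attrs = attrs | {sel.attribute}
            if max_attrs is not None and len(new_attrs) > max_attrs:
                continue
            new_mask = mask & masks[i]
            if int(new_mask.sum()) <= beta_abs:
                continue  # anti-monotone: no superset can be frequent
            combo.append(i)
            consider(combo, new_mask)
            walk(i + 1, combo, new_mask, new_attrs)
            combo.pop()

    walk(0, [], np.ones(dataset.n_transactions, dtype=bool), frozenset())
    if not best:
        return None
    return min(best.values(), key=_tie_key)


# ---------------------------------------------------------------------------
# planted-effect generator


@dataclass
class PlantedSpec:
    """A synthetic dataset recipe with a known favorable region.

    Attribute values are uniform over their baseline ranges (optionally
    recorded at a fixed resolution, as sensor data would be).  The target
    is baseline Gaussian noise, shifted up by ``effect`` inside the planted
    region (conjunction over attributes with a planted set) and shifted by
    ``depressed_shift`` on the *open interior* of the depressed region -
    keeping the hole's boundary values favorable, so the recoverable
    elevated set is the planted set minus the hole's interior.
    """

    ranges: Mapping[str, tuple[float, float]]
    planted: Mapping[str, IntervalSet]
    n: int
    seed: int
    base_mean: float = 50.0
    noise_sd: float = 1.0
    effect: float = 10.0
    depressed: Mapping[str, IntervalSet] = field(default_factory=dict)
    depressed_shift: float = 0.0
    resolution: Mapping[str, float] = field(default_factory=dict)
    target_name: str = "yield"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if self.effect <= 0:
            raise ValueError("effect size must be positive")
        for a, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"degenerate range for {a!r}: [{lo};{hi}]")

    def elevated(self, attribute: str) -> Optional[IntervalSet]:
        """Planted set minus the open interior of the depressed set."""
        planted = self.planted.get(attribute)
        if planted is None:
            return None
        hole = self.depressed.get(attribute)
        if hole is None:
            return planted
        return planted.subtract_open(hole)


def banana_spec(n: int = 500, seed: int = 0, effect: float = 10.0) -> PlantedSpec:
    """The banana / black-sigatoka scenario.

    Temperature uniform over the crop's viable [9;40] degrees C, recorded
    at 0.5 degree resolution (territory-averaged station data); favorable
    window [23;33]; fungus hole [25;28] depressed back to baseline.  Noise
    standard deviation is a tenth of the effect size.
    """
    return PlantedSpec(
        ranges={"temperature": (9.0, 40.0)},
        planted={"temperature": IntervalSet([Interval(23.0, 33.0)])},
        depressed={"temperature": IntervalSet([Interval(25.0, 28.0)])},
        depressed_shift=-effect,
        effect=effect,
        noise_sd=0.1 * effect,
        resolution={"temperature": 0.5},
        n=n,
        seed=seed,
    )


def _open_membership(values: np.ndarray, sets: IntervalSet) -> np.ndarray:
    mask = np.zeros(len(values), dtype=bool)
    for c in sets.components:
        mask |= (values > c.low) & (values < c.high)
    return mask


def generate_planted(spec: PlantedSpec) -> Dataset:
    """Draw a dataset from a planted-effect recipe; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    names = list(spec.ranges)
    cols = []
    for a in names:
        lo, hi = spec.ranges[a]
        raw = rng.uniform(lo, hi, spec.n)
        res = spec.resolution.get(a)
        if res:
            raw = np.round(raw / res) * res
        cols.append(raw)
    values = np.column_stack(cols)

    in_planted = np.ones(spec.n, dtype=bool)
    any_planted = False
    for a in names:
        pset = spec.planted.get(a)
        if pset is not None:
            any_planted = True
            in_planted &= pset.contains_array(values[:, names.index(a)])
    if not any_planted:
        in_planted[:] = False

    in_depressed = np.ones(spec.n, dtype=bool) if spec.depressed else np.zeros(
        spec.n, dtype=bool
    )
    for a, dset in spec.depressed.items():
        in_depressed &= _open_membership(values[:, names.index(a)], dset)

    target = (
        spec.base_mean
        + spec.effect * in_planted
        + spec.depressed_shift * in_depressed
        + rng.normal(0.0, spec.noise_sd, spec.n)
    )
    return Dataset(names, values, target, target_name=spec.target_name)


def recovery_score(found: IntervalSet, planted: IntervalSet) -> float:
    """Length-based Jaccard index between found and planted interval sets."""
    return found.jaccard(planted)


# ---------------------------------------------------------------------------
# banana-study workflow: support-threshold scan

#: descending support-threshold ladder for the per-dataset beta scan
BETA_LADDER = (0.97, 0.96, 0.95, 0.94, 0.93, 0.92, 0.91, 0.90, 0.88, 0.86)


def scan_beta(
    dataset: Dataset,
    alpha: float = 1.0,
    top_k: int = 10,
    betas: tuple[float, ...] = BETA_LADDER,
    max_vocab: int = 60,
) -> tuple[list, float]:
    """Run the miner over a descending β ladder; keep the best result.

    The support threshold is dataset-dependent: the search language grows
    as β drops (never losing candidates, so the best quality is monotone
    non-increasing in β), but the number of extent-distinct selectors -
    and with it the combination space - grows explosively once the drop
    budget exceeds the smallest grid-value multiplicities.  The scan
    therefore walks β downward, mines at every rung whose vocabulary stays
    within ``max_vocab`` selectors, stops at the first rung that exceeds
    it, and returns the subgroup list with the best top-1 quality together
    with the β that produced it.
    """
    from .combiner import CandidateExplosionError, run_disgrou
    from .selectors import make_raw_selectors

    best_subs: list = []
    best_beta = betas[0]
    for beta in betas:
        config = Config(beta=beta, alpha=alpha, top_k=top_k)
        vocab = make_raw_selectors(dataset, config)
        if len(vocab) > max_vocab:
            break
        try:
            subs = run_disgrou(dataset, config)
        except CandidateExplosionError:
            break
        if subs and (
            not best_subs or subs[0].quality > best_subs[0].quality
        ):
            best_subs, best_beta = subs, beta
    return best_subs, best_beta


# ---------------------------------------------------------------------------
# small random instances for fuzz / oracle-equivalence testing


def random_instance(
    seed: int,
    max_vocab: int = 20,
    n_range: tuple[int, int] = (8, 30),
    n_attrs_range: tuple[int, int] = (1, 3),
    n_levels: int = 4,
) -> tuple[Dataset, Config]:
    """A small random dataset + config whose vocabulary fits the oracle.

    Attribute values are drawn from a small integer alphabet so the value
    grid stays tiny; the instance is resampled (deterministically) until
    the selector vocabulary has at most ``max_vocab`` entries.
    """
    from .selectors import make_raw_selectors

    for attempt in range(200):
        rng = np.random.default_rng(seed * 1009 + attempt)
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        m = int(rng.integers(n_attrs_range[0], n_attrs_range[1] + 1))
        values = rng.integers(0, n_levels, size=(n, m)).astype(float)
        target = np.round(rng.normal(0.0, 1.0, n), 3)
        if np.ptp(target) == 0.0:
            continue
        dataset = Dataset([f"a{j}" for j in range(m)], values, target)
        config = Config(
            beta_abs=int(rng.integers(1, 4)),
            alpha=float(rng.choice([0.0, 0.5, 1.0])),
            top_k=5,
        )
        try:
            vocab = make_raw_selectors(dataset, config)
        except DataError:
            continue
        if 0 < len(vocab) <= max_vocab:
            return dataset, config
    raise RuntimeError(f"could not draw a small instance for seed {seed}")
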