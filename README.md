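# disgrou

Subgroup discovery on numeric tables with a numeric target, where subgroup
descriptions may use **discontinuous attribute intervals** — unions of two
disjoint closed ranges per attribute — found directly on the raw values,
with no prior discretization.

## The problem

Subgroup discovery looks for subsets of records whose target variable
deviates interestingly from the population. Classical numeric methods
restrict each attribute to one continuous interval. That is often too
coarse: a favorable range may contain a hostile sub-range, and averaging
over both dilutes the signal. The canonical example implemented in this
package's synthetic benchmark: banana grows between 9 °C and 40 °C with a
favorable harvest window around [23;33] °C — but the black sigatoka fungus
thrives at [25;28] °C and depresses yield exactly there. The truly
favorable description is the *discontinuous* set [23;25] ∪ [28;33], which
no continuous-interval method can express.

## The method

For a subgroup P of size n with target mean m_P, against a population of
mean m_0, quality is

    q_a(P) = n^a (m_P − m_0),    a ∈ [0;1]

The search runs in three steps:

1. **Raw selector extraction by erosion.** For each attribute, starting
   from the complete value range, intervals are eroded — endpoints drawn
   in, or a continuous interval split into a union of two disjoint ones —
   with endpoints always taken from observed values of the *positive*
   transactions pos(T) (those whose target strictly exceeds m_0). A
   candidate survives if it is one interval or a balanced union of two
   (each part holds strictly more than a fifth of the other part's
   positive count) and its positive support strictly exceeds the support
   threshold β. Extent-duplicate candidates are emitted once.
2. **A frequency-ordered prefix tree.** Selectors are sorted by positive
   support and every transaction of the full table is inserted along its
   matched selectors; each node carries (selector, transaction count,
   target sum). Several selectors of one attribute may lie on one branch,
   so depth is bounded by the selector count, not the attribute count.
3. **Branch combination.** Sub-combinations of selectors along branches
   are tallied, aggregates merged across branches carrying the same
   combination, infrequent combinations dropped, same-attribute selectors
   intersected into the final per-attribute interval sets, and the top-k
   subgroups by quality returned.

An exhaustive direct-filtering oracle (`brute_force_search`) and a
planted-subgroup generator (`generate_planted`) make every stage testable
without external data.

## Worked example

```sh
disgrou simulate --scenario banana --n 500 --seed 7 --out banana.csv
disgrou run --input banana.csv --target yield --beta 0.95 --out result.tsv
head -3 result.tsv
```

```
rank	quality	n	mean	population_mean	description
1	1006.84	138	60.0327	52.7368	temperature ∈ [23;25] ∪ [28;33]
2	984.856	135	60.032	52.7368	temperature ∈ [23;25] ∪ [28;30] ∪ [31;33]
```

The top subgroup is the 138 simulated years whose temperature falls in
[23;25] ∪ [28;33] °C: mean yield 60.0 against a population mean of 52.7,
quality 138 × (60.0 − 52.7) ≈ 1007 at a = 1. The miner has excised the
planted fungus window (25;28) from the favorable range — the discontinuous
description a continuous-interval search cannot produce.

The same can be done from Python:

```python
from disgrou import Config, run_disgrou
from disgrou.validation import banana_spec, generate_planted

dataset = generate_planted(banana_spec(n=500, seed=7))
best = run_disgrou(dataset, Config(beta=0.95))[0]
print(best.render(), best.n, round(best.quality, 1))
# temperature ∈ [23;25] ∪ [28;33] 138 1006.8
```

`disgrou validate --input FILE --target NAME --beta-abs N` cross-checks
the miner against the exhaustive oracle on a small file and prints
`AGREE`/`DISAGREE`.

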