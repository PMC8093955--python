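# Methods

## Model and quality function

Given a numeric table with transactions T, attributes A and a numeric
target, a subgroup P is the extent of a conjunctive description mapping
attributes to sets of closed intervals. Its quality is

    q_a(P) = n^a (m_P − m_0)

with n = |P|, m_P the subgroup's target mean, m_0 the population mean and
a ∈ [0;1] the size/shift trade-off (default 1.0, exposed as `--alpha`;
a = 0 ranks by mean shift alone, a = 1 by total excess target mass
`target_sum − n·m_0`). m_P is always a mean over the *full* population's
members of P, not only over above-average transactions; the mining tree
therefore aggregates all transactions. Intervals are closed on both ends;
pos(T), the positive transactions that drive selector generation, is
defined strictly (target > m_0), so ties with the mean are negative.

## Selector generation (erosion)

For each attribute the candidate endpoints are the distinct values of the
attribute among pos(T) — endpoints drawn from negative-only values cannot
change positive support, so this grid loses nothing. Erosion is realized
as enumeration of every grid interval and every disjoint pair of grid
intervals, which visits all erosion orders at once, under three rules:

* at most two components per raw selector;
* the one-fifth balance rule on a union's per-component *positive* counts
  (strict both ways) — the counts are positive counts, consistent with
  the support rule's positive basis;
* positive support strictly greater than β (given as a fraction f of
  |pos(T)|, resolved as `beta_abs = ceil(f·|pos(T)|)`, or as an absolute
  count).

Candidates whose extent over the full dataset coincides admit exactly the
same transactions in every downstream role, so they are one selector, not
several: each extent class is represented by the candidate with the
fewest components, then the largest total length, then lexicographically
smallest endpoints. This canonicalization is what keeps a union selector
meaningful — a split that excludes nothing collapses onto its continuous
form — and is required to reproduce the intended selector sets on small
grids (e.g. grid {1,2,3}, one positive transaction each, β = 1 yields
exactly [1;3], [1;2], [2;3] and [1;1] ∪ [3;3]).

The attribute's complete range [Min;Max] over the full dataset is always
a candidate; since it holds all of pos(T) it survives β whenever anything
does, so the vocabulary contains a full-range selector for every
attribute or is empty. Selectors are ordered by descending positive
support with a deterministic tie-break (larger full extent, earlier
attribute, endpoint order).

## Tree and combination

The prefix tree inserts every transaction along its matched selectors in
vocabulary order; nodes carry (selector, count, target sum). Construction
is insertion-order independent (asserted by a permutation test), which is
the contract that would license parallel partial trees; this
implementation builds sequentially.

Combinations are tallied with a latest-element discipline: a combination
is counted at the nodes of its latest-ordered selector whose path
contains the rest, so each (combination, transaction) pair is counted
exactly once and cross-branch aggregation is exact. Two data-independent
pruning rules skip combinations that describe the same point set as a
smaller combination (a selector containing the running intersection adds
nothing; a selector that makes an included same-attribute selector
redundant is already covered by the combination without it). Aggregated
combinations whose count does not strictly exceed `beta_abs` are dropped,
mirroring the selector-level rule. Same-attribute selectors are
intersected into the final description, which may then carry more than
two components. Every candidate's aggregates are cross-checked against
direct filtering for the reported top-k; counts must match exactly and
sums to floating-point reproducibility (different summation orders of the
same floats).

Ranking sorts by quality descending with ties broken toward simpler
subgroups: fewer attributes, then fewer total interval components, then
lexicographic rendering. The component tie-break matters on gridded data,
where descriptions differing only by a split across an unpopulated gap
are extent-identical; the simplest representative is reported.

### Combinatorial budget

The candidate language is exponential in the number of overlapping
same-attribute selectors: once the support threshold's drop budget
exceeds the multiplicity of single grid values, every droppable value
spawns extent-distinct selector variants and their intersections multiply.
`enumerate_candidates` therefore carries an explicit budget (200 000
aggregated combinations, 300 000 extension attempts) and raises
`CandidateExplosionError` beyond it rather than thrashing; the remedy is
a stricter β or `max_attrs`. `brute_force_search`, the oracle, refuses
vocabularies over 20 selectors for the same reason.

### Choosing β

β is dataset-dependent and has no universal default; the CLI requires it.
`validation.scan_beta` implements the natural protocol for the synthetic
study: walk a descending ladder (0.97 … 0.86), mine at every rung whose
vocabulary stays within 60 selectors, stop at the first rung that exceeds
the vocabulary cap or the enumeration budget, and keep the result with
the best top-1 quality. Because lowering β only enlarges the candidate
set, the best quality is monotone along the ladder; the scan simply finds
the most permissive *computable* rung.

## Synthetic planted-effect data

`generate_planted` draws attribute values uniformly over baseline ranges,
optionally recorded at a fixed resolution as sensor data would be, and
sets the target to baseline Gaussian noise plus `effect` inside the
planted region and `depressed_shift` on the *open interior* of the
depressed region. Keeping the hole's boundary values favorable makes the
recoverable elevated set exactly "planted minus the hole's interior" —
with a closed hole the boundary grid values would silently leave the
favorable set and no method could return them.

The stock `banana_spec` scenario: temperature uniform on [9;40] °C at
0.5 °C resolution (territory-averaged station readings), favorable window
[23;33], fungus hole [25;28], n = 500, baseline yield 50 with noise
sd 1.0, effect +10 (so noise is a tenth of the effect), hole shift −10.
The recoverable set is [23;25] ∪ [28;33]. Recovery is scored by
length-based (Lebesgue) Jaccard between the found and planted interval
sets; zero-length point components therefore neither help nor hurt.

What the generator does *not* emulate: correlated attributes, temporal
autocorrelation (real yield series are not i.i.d. years), heavy-tailed or
heteroscedastic noise, and measurement error in the target. Passing the
recovery tests shows the pipeline can excise a hostile sub-range under
honest noise at a realistic sample size; it does not certify performance
on correlated climate records.

## Numerical and procedural choices

* Interval sets are canonical on construction (sorted, overlapping or
  touching components merged), so structural equality is point-set
  equality.
* Missing or non-finite cells are rejected at load time; the method has
  no imputation semantics.
* A constant target (empty pos(T)) is a hard error: no subgroup can beat
  the mean.
* β resolved from a fraction uses ceiling, keeping the strict ">" of the
  support rule.
* Oracle comparisons assert extent sizes exactly and sums/qualities to
  1e-9; bit-exact sums across different summation orders are not a
  meaningful requirement.
* Problem sizes in the test suite: 100 random instances (≤ 30
  transactions, ≤ 3 attributes, ≤ 20 selectors) for oracle equivalence;
  n = 500 for the banana scenario; value alphabets of ≤ 7 levels for
  selector-completeness fuzzing. These sizes make exhaustive oracles
  exact while exercising every code path.

## Known limitations

* The combination stage is inherently exponential in overlapping
  same-attribute selectors; very permissive β on large data is
  unworkable by design, as the budget errors make explicit.
* Nominal attributes are unsupported (numeric only); nominal *targets*
  must be mapped to numbers by the user beforehand.
* No optimistic-estimate pruning or tight upper bounds: the search is
  exact within its language rather than best-first.
* Multi-threaded tree construction is not implemented; order
  independence of insertion is verified instead.
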