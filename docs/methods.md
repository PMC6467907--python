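# Methods

## The model

`breederinvest` implements a maternal risk-management model of breeder
investment. The focal organism is the breeding female; her fitness is a
*replacement constant* `w`: at least `w = 2` fertile offspring (one daughter,
one outbreeding son) must survive to the next generation, regardless of how
many she produces. Given per-breeding-event offspring quantity `N`, offspring
mass at dispersal `m`, and breeder mass `M`, the model computes

- **Predation mortality** `P = 1 − w/N`: the fraction of the brood that can
  be lost to consumers (predators, parasites, microbes, viruses, or abiotic
  lethality) while still achieving replacement. Large clutches imply — and
  tolerate — high predation mortality.
- **Relative offspring quality** `S = m/M`: the share of the breeder's own
  mass embodied in one offspring at dispersal, which doubles as the modelled
  probability of offspring mortality by spatiotemporal resource scarcity
  (starvation, desiccation, exposure).
- **Brood inequality** `G`: a bias-corrected Gini coefficient over
  per-offspring masses, 0 for equal allocation, exactly 1 when one offspring
  holds all mass.
- **Convergent index** `C = P·S`: the joint mortality product, high where
  both pressures are severe at once. The model conjectures — it does not
  establish — that high `C` favours unequal broods (high `G`); the
  simulation harness below exists to measure that association under an
  explicit mechanism.

Two user-chosen *set points* partition the `(S, N)` plane into four
natural-selection categories:

| category   | S            | N           | favoured strategy            |
|------------|--------------|-------------|------------------------------|
| predation  | ≤ s_setpoint | > n_setpoint| quantity over quality        |
| scarcity   | > s_setpoint | ≤ n_setpoint| quality over quantity        |
| weak       | ≤ s_setpoint | ≤ n_setpoint| minimal investment           |
| convergent | > s_setpoint | > n_setpoint| diversified broods, sociality|

Defaults are `s_setpoint = 0.1` and `n_setpoint = 10`, the values used for a
broad 87-species cross-taxon classification; they are configuration, not
quantities the package ever infers from data, because appropriate set points
depend on the scope of a study. Comparisons are `≤` on the low side and
strictly `>` on the high side, exactly as the thresholds are written, which
makes the four regions an exhaustive, mutually exclusive partition with no
further choices. The `map_to_legacy` operation records how the categories
line up with r/K selection and Grime's CSR triangle (scarcity ↔ r- and
S-selection; weak ↔ K- and C-selection; predation ↔ R-selection; convergent
has no counterpart in either).

## The Gini reconstruction

The rank-form inequality index is stated with its symbols garbled in the
printed source this model derives from (an undefined symbol and ambiguous
parenthesisation). We implement the unique standard form consistent with the
stated rank convention (largest offspring gets rank 1, smallest rank `N`) and
the stated endpoints (0 for an equal brood, 1 when one offspring holds all
mass): the bias-corrected rank-form Gini

```
G = (N+1)/(N−1) − 2/(N(N−1)µ) · Σ_i R_i m_i ,
```

with `µ` the mean offspring mass. Ranks are ambiguous under ties, so the
canonical implementation (`gini`) uses the algebraically identical,
tie-invariant mean-absolute-difference form

```
G = Σ_{i,j} |m_i − m_j| / (2 N (N−1) µ) ,
```

and the rank form is exposed separately (`gini_rank_form`) and verified
equivalent for distinct masses to 1e−12. The divisor `N−1` (rather than `N`)
is what makes the one-owner brood score exactly 1 at any brood size.

Numerical detail: the sorted-weights evaluation shifts masses by the
smallest value before the weighted sum (the weights sum to zero, so this is
an identity) so that a perfectly equal brood returns exactly 0.0 rather than
an O(1e−17) rounding residue.

## The singleton substitution

`P = 1 − w/N` is negative for broods smaller than `w`. For such species
(one offspring per breeding season under the default `w = 2`) `N` is replaced
by `n_substitute = 2.1` before computing `P`, giving a small positive
predation mortality, and the substitution is flagged in every result —
never applied silently. The trigger is `N < w` rather than `N == 1` so that
fractional averaged brood sizes below `w` (possible after multi-source
averaging) cannot produce negative probabilities either; this generalisation
follows directly from the rule's purpose. Outside this rule, out-of-range
values always raise: `P` is never clamped into [0, 1], because a negative
`P` indicates a data problem that should surface. `S > 1` (offspring
heavier than the breeder) is accepted with a logged warning rather than
rejected, since it usually indicates an averaging artefact worth inspecting
but not discarding; in that case `C = P·S` is still reported although it is
no longer interpretable as a joint probability.

## Trait-table handling

Life-history compilations mix sources, so trait cells may be plain numbers,
printed ranges `a-b` (hyphen or en-dash; averaged to the midpoint), or
multi-source lists `x|y|z` (arithmetic mean), with thousands separators
accepted. Rows failing validation are skipped and itemised with row numbers
rather than aborting the run — dirty rows are the norm in this kind of
data — and skipped + kept always equals the row count read. Missing
`brood_masses` means `G` is unavailable and is written as an empty cell,
never imputed or zero-filled. Units are the caller's responsibility; only
the ratio `m/M` within a row is ever used.

## The synthetic species generator

`generate_species` emulates the statistical shape of a broad cross-taxon
breeder-investment compilation: 87 species by default, split 30 predation /
35 scarcity / 10 weak / 12 convergent, matching the qualitative clustering
reported for such data (spawning fish, reptiles and marine invertebrates
under predation selection; birds and mammals under scarcity selection; a
small group of apex predators under weak selection; social insects and
social mammals under convergent selection). Per category, `N` is log-uniform
and `S` uniform inside bounds chosen strictly within that category's
set-point region (e.g. predation: `N` ∈ (30, 10⁶), `S` ∈ (10⁻⁴, 0.09)), so
the generated labels are recoverable by construction — the label-recovery
test is a check on the classifier's boundary logic, not on the generator's
realism. Breeder mass is log-normal (location 7.0, scale 2.5 on the natural
log scale, grams: median ≈ 1.1 kg with a heavy spread from insects to
megafauna), and offspring mass is `S·M`. Species with small integer broods
(2–60) carry per-offspring masses from a symmetric Dirichlet split so the
inequality index is exercised.

What the generator does *not* emulate: phylogenetic correlation between
species, measurement error in compiled traits, within-species variance
across breeding events, and any real joint distribution of `S` and `N`
within a category (they are sampled independently). Passing label-recovery
and partition tests therefore demonstrates the classifier's correctness, not
that real species are cleanly separable — real compilations have species
near the set points.

## The conjecture harness

The claim that joint predation-and-scarcity mortality favours unequal broods
is open. The harness operationalises the two mortality channels minimally,
as this package's own mechanism (no mechanism is given in the theory it
implements):

1. A brood of `n` offspring shares `total_mass` units of maternal capital by
   a symmetric Dirichlet(α) split; small α concentrates capital in few
   offspring (high `G`), large α approaches equality.
2. Every offspring independently survives predation with probability
   `1 − P`.
3. Predation survivors survive scarcity only if their dispersal mass is at
   least the regime's resource threshold (scarcity acts after predation
   because `m` is defined at dispersal, the later stage).
4. The brood *replaces* its breeder if at least `w` offspring survive both.
   Offspring are not sexed; the one-daughter-one-son refinement of the
   replacement criterion is out of scope.

For each regime `(P, threshold)` and each α, the harness reports the
replacement frequency, mean brood `G`, and realised scarcity mortality among
predation survivors. The across-regime association is summarised as the
Pearson correlation between each regime's realised `C = P·S` (with `S` the
realised scarcity mortality averaged over α cells) and the mean `G` of the
best-replacing α cell in that regime. A positive correlation means harsher
joint regimes favoured more unequal broods *under this mechanism*; it is a
measurement of the harness, not a confirmation of the conjecture.

All randomness flows from a single integer seed through a `SeedSequence`
with one independent child stream per (regime × α) cell, so results are
bit-identical across runs and insensitive to cell ordering changes within a
run.

## Numerical and design choices

- Pure arithmetic throughout (no iterative fitting); the default equality
  tolerance in tests is 1e−12.
- `C = P·S` is computed for every species, after the singleton substitution,
  mirroring the classification pipeline order (plot, move axes, superimpose
  probabilities); whether the index is meaningful outside the convergent
  quadrant is a modelling question the package leaves to the user.
- Rank ties in `BroodProfile` are broken by input position (stable sort);
  the reported `G` never depends on the tie-break.
- Quadrant plots use a log₁₀ `N` axis by default — the data span singleton
  broods to ~10⁶-egg marine clutches — with a linear option; axis scaling in
  the figures this style imitates is not documented, so this is a
  readability choice of this package.
- The command-line layer is four subcommands (`classify`, `gini`,
  `simulate`, `plot`) over the library; flags override the config file,
  which overrides defaults; logs (including a full echo of the effective
  parameters) go to stderr, data to files/stdout.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at the scales the model is defined
for: 87-species tables for classification (the default generator output),
400 synthetic species for label recovery, 1,000 random broods of 2–50
offspring for the Gini identity, a 200×200 grid including both set-point
boundaries for the partition property, and 20,000 Monte-Carlo replicates per
cell against exact 2ⁿ enumeration for broods of up to 12 offspring. These
sizes were chosen as comfortably sufficient for the deterministic checks and
for 3-standard-error agreement in the stochastic ones.

## Known limitations

- The four-category assignment is threshold classification, not inference;
  no uncertainty is attached to a species' category, and species near a set
  point flip categories under small trait changes.
- `S` conflates provisioning strategy with allometry; comparing `S` across
  taxa of very different body plans inherits that conflation from the model.
- The harness's mortality mechanism is one minimal choice among many; its
  measured `G`–`C` association should not be quoted as a property of real
  broods.
- No phylogenetic correction: species are treated as independent points, as
  in the classification scheme the package implements.
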