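# Methods

## Pedigree model

A pedigree is a directed acyclic graph of parent links.  Unknown parents
(`""`, `0`, `NA` on input) are treated as unrelated founders everywhere:
kinship with an unknown ancestor is zero and genetic contributions do not
flow through an unknown link.  Construction validates id uniqueness,
self-parenting, parent resolution (an explicit permissive flag
auto-creates founder records for dangling parent ids), sex consistency of
sires/dams, and acyclicity; a deterministic topological order (longest
path from the founders, then id) underlies every traversal.

**Inbreeding and relationship.** F(x) is the kinship of x's parents,
computed by the classical recursion φ(a,a) = (1+F_a)/2,
φ(a,b) = [φ(a, sire_b) + φ(a, dam_b)]/2 recursing on the topologically
later animal, memoized.  The test suite checks value equality (1e-12)
against the brute-force tabular relationship matrix.  The average
relationship of a group is the mean of 2·kinship over unordered distinct
pairs — self-pairs are excluded, the conventional "relatedness among
members" reading; this choice is a genuine free parameter of the
descriptive tables and is fixed here once.

**Completeness.** The five-generation pedigree completeness index is the
harmonic mean 2·C_pat·C_mat/(C_pat+C_mat), where each line's C is the
mean over generations 1..5 of the proportion of known ancestors in that
generation on that side (2^(g-1) slots).  A complete pedigree scores 1;
a missing parent scores 0.  An equivalent form in the literature writes
4·C'_pat·C'_mat/(C'_pat+C'_mat) with per-side proportions capped at ½;
the two agree, and only this normalization satisfies PCI ∈ [0,1] with
PCI = 1 iff complete.

## Probabilities of gene origin

The raw contribution of ancestor k to a cohort is the expected fraction
of the cohort's gene pool descending from k: c(k→k) = 1, else half the
sire's plus half the dam's value.  One backward sweep over topological
levels yields the contributions of *all* animals to a cohort in O(N).

The marginal decomposition selects ancestors greedily.  Each round:
candidates are all ancestors of at least one cohort member in the
current pruned pedigree (cohort members and previously selected
ancestors excluded); p_k = q_k·(1 − Σ a_i), where the a_i are the raw
contributions of already-selected ancestors to candidate k in the
current pedigree; the arg-max is selected and pseudo-foundered.  Because
selected ancestors have no parents in the pruned pedigree, Σ a_i for
every candidate equals a single "clamped" forward pass with all selected
ancestors as unit sources — the per-round cost is two level sweeps, and
the whole decomposition of a 5,000-animal pedigree takes milliseconds.
Ties on p_k (exact ties arise, e.g. the two parents of a full-sib
cohort) are broken by earlier birth year, then id, making results
independent of input record order.

Default stopping rule: cumulative explained ≥ 0.99 or candidate
exhaustion.  Marginals are orthogonal: Σ p_k = 1 exactly when every
founder is known, ≤ 1 otherwise (unknown-parent leakage); p_k ≤ q_k
every round.  Both properties are asserted in tests, and raw
contributions are cross-checked against an independent gene-dropping
Monte Carlo oracle (10^5 allele drops, 3-SE agreement).

In the ancestor × window contribution matrix, *missing* (ancestor never
selected for that cohort) is distinct from *zero* (selected, marginal
rounds to 0.000); row averages use non-missing cells only.

## Case-control comparison

Cohorts are overlapping three-year birth windows sliding by one year
(1993–95 … 2005–07 → 13 windows, 26 cohorts), one affected and one
control cohort each.  Controls are birth-year-matched contemporaries
("racing contemporaries" is operationalized as same birth year — the
reproducible reading), drawn without replacement, none reused across
cases, 5 per case by default.

Tested ancestors: average non-missing contribution ≥ 0.005 in either
matrix AND non-missing cells in ≥ 2 windows with pairwise-disjoint year
ranges (largest disjoint subset by greedy interval scheduling).  The
paired two-tailed t uses the **zero-fill union pairing**: a window
contributes a pair when either side is non-missing, the missing side
counting as zero contribution.  This convention is the only one that
reproduces the printed degrees of freedom of the reference table for 40
of its 41 rows (the one exception prints DF = 4 where every consistent
convention gives 5 — treated as a typo and excluded from exact-DF
assertions).  Significance is two-sided p ≤ α (default 0.05); direction
is the sign of mean(affected − control); Benjamini–Hochberg flags are
attached at 5% and 10% FDR over the tested set.  Degenerate rows (zero
variance of differences) are reported as untestable and left
unclassified.  Recomputed t statistics carry the 3-decimal rounding of
the printed inputs (≈0.1–1.5% relative error on well-conditioned rows);
for rows whose contributions are tiny relative to the rounding, only the
sign and significance class are meaningful.

## Synthetic data generator

`simulate_pedigree` emulates a closed racehorse registry: founders (half
male) in the first year; every later year up to `matings_per_year` dams
(uniform, without replacement, ages 3–20) are bred to sires (ages 3–24)
drawn with probability ∝ (1−skew)^rank, ranking eligible stallions by a
persistent random popularity score assigned at birth.  This produces the
heavy popular-sire skew of real studbooks while age-limiting any single
stallion's career.  Defaults — 100 founders in 1958, 100 births/year to
2007 (≈5,000 animals), skew 0.2, case window 1993–2007 — mirror the
scale of the motivating study's traced pedigrees (cohort pedigree sizes
in the low thousands) while staying desk-scale.

`assign_phenotypes` draws a liability ℓ = u + e: breeding values follow
the pedigree (founders ~ N(0, h²); offspring get the parent average plus
Mendelian sampling with variance h²·(1 − k/4) for k known parents),
residuals N(0, 1−h²), so liability is standard normal in the base
population; animals in the case window with ℓ above the
(1 − prevalence) normal quantile are cases.  Defaults: h² = 0.15 (the
motivating trait's reported heritability) and prevalence 0.05.  The
prevalence is not an estimate of any real admission rate — it is chosen
so that every birth year can supply 5 matched controls per case without
reuse, which requires the per-year case fraction to stay well below
1/(1+ratio).  An optional sire-family effect adds a fixed liability
shift to every descendant of a "risk sire", auto-chosen as the sire
whose case-window descendant share is closest to a target (default 10%,
preferring stallions at stud within 15 years of the window) — a
popular-but-not-dominant recent family, matching both the motivating
scenario and the control-sampling feasibility constraint.

The planted-family validation runs 25 seeded replicates at: shift 1.0
liability SD, family share 8%, 200 births/year, prevalence 0.04,
h² = 0.15; the planted lineage (risk sire or any of its ancestors) is
recovered as affected-significant in ~90% of replicates.  The null
validation runs 200 replicates at the default configuration with h² = 0
and no family effect.

What the generator does **not** emulate: real mating choice
(inbreeding avoidance, assortative mating), gait/sex stratification of
breeding, imported outside ancestry (simulated founders are the only
unknowns), admission bias in case ascertainment, and any real studbook's
year-to-year usage dynamics.  Passing tests therefore validate the
algorithms, not the biological conclusions drawn from any real registry.

## Calibration of the comparison pipeline — a known limitation

Under a null simulation (h² = 0, no family effect) the fraction of
tested ancestors reaching p ≤ 0.05 is ≈ 0.35–0.45, not the nominal 5%.
The inflation is structural, not an implementation artifact, and has
three sources, in decreasing order:

1. **Cohort-size asymmetry.**  Marginal contributions depend on cohort
   size: small cohorts concentrate their gene pool in fewer ancestors
   (visibly so in the reference tables' coverage counts), and affected
   cohorts are 5× smaller than control cohorts, so E[A_w − C_w] ≠ 0 per
   ancestor even when case status is pure noise.
2. **Overlapping windows.**  Adjacent three-year windows share two
   thirds of their members; the 13 "pairs" are strongly positively
   correlated, while the paired t treats them as independent
   (pseudo-replication).
3. **Selection on the outcome.**  Ancestors are tested *because* they
   showed high contributions in one of the two matrices.

When the assumptions are restored — equal-size cohorts, non-overlapping
windows, ancestors present on both sides — the empirical level returns
to ≈ 0.03–0.06 (asserted as a property test).  Consequently, p-values
produced by the full overlapping-window design should be read as
descriptive rankings rather than calibrated error rates; the acceptance
check asserting nominal calibration of the full pipeline is expected to
fail, and is retained deliberately as a documented negative result.

## Numerical choices

- Kinship memoization is exact rational-in-floating-point arithmetic; no
  tolerance is applied internally.  Oracle comparisons use 1e-12.
- Decomposition candidate cut-off: raw contribution > 1e-12; tie window
  on the arg-max: 1e-12.
- Degenerate paired tests (sd = 0) raise rather than return ±inf.
- Table-shaped output formats contributions to 3 decimals with "-" for
  missing and t to 4 decimals, matching the reference layout so diffs
  against the fixtures are trivial.
- All stochastic components take explicit integer seeds;
  `numpy.random.default_rng` sequences derived as (seed, stream-tag).
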