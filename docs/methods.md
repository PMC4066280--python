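# Methods

## The comparison model

The package quantifies similarity between two differential-expression
signatures drawn from independent two-group studies over a shared (or
ortholog-translatable) gene universe. A signature is the set of genes passing
|fold change| > `fc_cut` and *t*-test *P* < `p_cut`, ranked by ascending *P*
(ties: descending |display fold change|, then lexicographic gene id — the
ranking key is fixed so the rank-based overlap test is deterministic). The
measured background is every gene the study tested, not the genome; for
cross-species comparisons it is the set of background genes that survive
ortholog translation, the only choice under which the hypergeometric
population is well defined.

### Two-group statistics

Fold change is computed on anti-logged means of log2 data: FC =
2^(mean₁ − mean₂), with group 1 the young/disease-style numerator. The
*P*-value is a two-sided Student's pooled-variance two-sample *t*-test —
pooled rather than Welch, the classic microarray-era default, stated
explicitly so the test oracle is unambiguous. Degenerate genes (zero variance
in both groups) get *P* = 1 when means coincide and the smallest
representable positive double otherwise, flagged in `group_stats`. Both
filter inequalities are strict: a display fold change of exactly −1.2 is
excluded at `fc_cut = 1.2`.

### Running Fisher overlap

The scan walks cumulative cutoffs *k* down the ranked query signature A and
computes the exact upper-tail hypergeometric P(X ≥ |top_k(A) ∩ B|) with
|B| successes in a population of size *N* (the common background) and *k*
draws. The cutoff grid is every rank for |A| < 50 and the ten decile
boundaries otherwise; the summary is min_k P_k multiplied by the number of
cutoffs (Bonferroni over the scan), capped at 1. The grid-plus-correction
design keeps the test rank-sensitive while admitting an exact brute-force
oracle; the correction makes the null calibration conservative (measured
rejection at 0.05 stays at or below nominal), which is the safe side for an
overlap claim.

Direction is handled two ways, and both are reported: the joint scan over the
full signatures (`running_p`), and four direction-restricted sub-tests
(up-up, down-down, up-down, down-up), each a running Fisher on the
direction-filtered sub-signatures against the same background. The
significance ledger carries two Bonferroni levels: 0.05 divided by the number
of dataset pairs compared in the run, and 0.05/4 = 0.0125 for the four
direction pairings.

### Numerics of extreme tails

Hypergeometric tails are computed in exact big-integer arithmetic: the tail
numerator Σᵢ C(K, i)·C(N−K, n−i) is summed over Python integers and divided
by C(N, n) as a single rational. This is exact at any magnitude, so the
min-over-cutoffs comparison is immune to floating-point ties and the brute
force oracle matches bit for bit. Conversion to double happens only at the
boundary: values below ~5·10⁻³²⁴ are floored to the smallest subnormal
(P-values are never 0), and every overlap result also carries the exact
log₁₀ P, which stays informative down to the 10⁻⁶⁰⁰ range reached by strong
signatures over large backgrounds.

### Concordance chi-square

The positive-correlation count (same-direction shared genes, uu + dd) versus
the negative-correlation count is tested against an expected 50/50 split with
a 1-df Pearson chi-square and no continuity correction — with the correction,
published-scale splits such as 654:232 would not reproduce their printed
statistics (2·211²/443 = 201.00 exactly).

### Ortholog translation

Identifier matching is exact, case-sensitive string equality; aliasing
belongs in the map input. The collapse policy for ambiguous mappings is a
deterministic best-evidence rule: a 1:many fan-out keeps the source's single
best pairing (statistics tie within a source, so the lexicographically first
target wins); a many:1 collision keeps the source with the smallest *P*,
ties broken by larger |display FC|, then lexicographic id. When the
signature carries its background membership, the translated background is
the set of distinct first-targets of mappable background genes; when only a
count is known (bare signature tables), the background is bounded by the
mappable universe (distinct map sources) — a conservative stand-in recorded
in the translation log.

### Contribution and enrichment

The Venn partition over at most three reference signatures assigns every
bioset gene to exactly one membership region (or to the unexplained
remainder) by gene identity only; per-reference direction agreement is
tallied alongside but does not gate membership — shared-gene counts and
direction-matched counts are distinct quantities, and reports emit both.
More than three references are rejected rather than generalised, keeping the
region enumeration auditable. Percentages are half-up rounded to one decimal.

Enrichment is a one-sided (over-representation) Fisher exact test per set,
against the measured background; under-representation is out of scope.
Benjamini–Hochberg is implemented as the literal step-up definition
(p·n/rank, suffix minimum, cap at 1) so it can be validated exactly against
the definition; statsmodels serves as an independent cross-check in the test
suite.

## The synthetic generator

`generate_paired_studies` emulates the statistical structure of a paired
meta-analysis, not microarray physics. Per gene: a baseline log2 level
~ N(8, 1.5²) per study, an additive true effect in group 1, and i.i.d.
Gaussian noise per sample. A fraction `frac_de` of genes is differential in
study A; effect magnitudes are Gamma(shape 4, scale `effect_size`/4) — mean
`effect_size`, CV 0.5, chosen so magnitudes concentrate near the nominal
effect rather than piling up at zero — and signs are negative with
probability `down_bias` (default 0.6), reproducing the down-regulation-
dominated concordance seen in cortical maturation data. Of the A-DE genes, a
`concordance` fraction carries a same-sign (redrawn-magnitude) effect in
study B and the remainder an opposite-sign effect, so the pipeline estimate
(uu+dd)/overlap targets `concordance` directly; the A-only/B-only ground-
truth labels exist in the vocabulary but the default generator emits none.

Defaults — the study conditions used throughout the tests and the acceptance
script — are 2000 genes, 10 samples per group, `frac_de` 0.2, `concordance`
0.8, `effect_size` 1.0, `noise_sd` 0.5 (log2 units), `down_bias` 0.6: a
moderately powered microarray-scale design.

What the generator does **not** model: probe-level artifacts, batch effects,
normalisation (RMA/MAS5), correlated noise across genes, age as a continuous
covariate. Passing tests therefore demonstrate correctness of the statistics
and the estimator's behaviour under clean Gaussian noise, not robustness to
those real-data features.

### Estimator behaviour

(uu+dd)/overlap is a consistent estimator of the generator's concordance: as
samples per group grow, the fold-change filter eliminates null genes and the
bias shrinks monotonically (checked over n ∈ {3, 10, 30}). At finite n its
error is not purely binomial: genes with no true effect can pass the joint
filter in both studies (~0.049² jointly at the default design), and such
double false positives enter the overlap with independent random directions.
This contamination is negligible for interior concordance values but
dominates at the boundary: with concordance 1.0 the binomial band of the
estimate is the single point {overlap}, and roughly two contaminant genes
per run land on the discordant side, so boundary recovery at the default
noise level fails a degenerate band even though the estimate itself sits
within a few parts per thousand of 1.0. This is a property of uncorrected
P < 0.05 threshold extraction, shared by any pipeline built on it.

## Reference signatures and ortholog maps

`generate_reference_signature` builds a signature overlapping a designated
bioset at an exact requested fraction (37.4% of a 561-gene bioset shares
exactly 210 genes), with controllable direction agreement, optional
mouse-style identifiers (a deterministic `m` prefix) and a matching
generated ortholog map with adjustable dropout and 1:2 fan-out — enough to
exercise every translation code path without real nomenclature.

## Problem sizes

Test-suite simulations use 500–2000 genes, 3–30 samples per group, up to 500
null replicates for scan calibration, 1000 random instances for oracle
equivalence, and 100 seeded runs for end-to-end recovery; the whole suite
runs in well under a minute on one core, and `scripts/acceptance.py` in a
few seconds.

## Known limitations

- The running-Fisher cutoff grid and its min-scan correction are this
  package's declared design; proprietary implementations of rank-scanned
  overlap tests use unpublished grids and corrections, so absolute P-values
  are comparable only within this package.
- Input rows are treated as genes; probe-to-gene collapsing is the caller's
  responsibility.
- Enrichment ranks sets by Fisher P only; composite "enrichment scores"
  blending significance with consistency are not modelled.
- With membership-unknown backgrounds, translated background sizes are a
  bounded approximation (see above), logged per run.
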