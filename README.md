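# sigoverlap

Rank-based comparison of differential-expression signatures across studies,
built for transcriptomic maturity meta-analyses: given two two-group
expression studies (for example a developmental contrast in cortex and a
disease-versus-control contrast), how similar are their transcriptome-wide
changes, in which direction, and which cell types can account for the shared
genes?

The package implements, as a tested library plus a thin CLI:

- **Signature extraction** ("biosets"): genes with |fold change| > 1.2 and a
  two-sided pooled-variance *t*-test *P* < 0.05 (both cuts strict, no
  multiple-testing correction at this stage), with fold changes computed as
  2^(Δ of log2 group means) and displayed in the signed negative-reciprocal
  convention (a ratio of 0.5 prints as −2.0).
- **Running Fisher overlap**: scan cumulative cutoffs *k* down the ranked
  query signature; at each cutoff compute the upper-tail hypergeometric
  P(X ≥ |top_k(A) ∩ B|) over the common measured background *N*; summarise as
  min_k P_k × (number of cutoffs), capped at 1. Tails are evaluated in exact
  big-integer arithmetic, so extreme overlaps (10⁻⁷⁵ and beyond) are reported
  via log₁₀ rather than underflowing.
- **Directional concordance**: each shared gene falls in a quadrant (up-up,
  down-down, up-down, down-up); the positive-correlation count *c* versus the
  negative-correlation count *d* is tested against an expected 50/50 split by
  a Pearson chi-square with 1 df and no continuity correction,
  χ² = (c − n/2)²/(n/2) + (d − n/2)²/(n/2), n = c + d.
- **Ortholog translation** for cross-species comparisons, with a
  deterministic best-evidence collapse rule for 1:many and many:1 mappings.
- **Cell-type contribution**: Venn decomposition of a concordant bioset over
  up to three reference signatures (membership by gene identity, direction
  agreement tallied alongside), with half-up one-decimal percentages.
- **Gene-set enrichment**: one-sided Fisher exact tests against a GMT
  collection over the measured background, Benjamini–Hochberg adjusted.
- **Synthetic paired-study generator** so every stage is testable without
  external data: two studies share a latent axis with a controllable
  concordant fraction, Gamma-distributed effect magnitudes, a down-regulation
  bias, and Gaussian log2 noise.

## Worked example

```python
import sigoverlap as so

cfg = so.SyntheticConfig(seed=1)           # 2000 genes, 10/group, concordance 0.8
mat_a, mat_b, truth = so.generate_paired_studies(cfg)
sig_a = so.extract_signature(mat_a, name="development")
sig_b = so.extract_signature(mat_b, name="disease")
res = so.compare_signatures(sig_a, sig_b)
print(res.overlap, res.concordant, res.discordant)
print(round(res.chi2, 2), round(res.running_log10_p, 2))
```

prints

```
311 249 62
112.44 -172.02
```

Of the 311 genes recovered in both studies, 249 change in the same direction
(the estimated concordant fraction 249/311 ≈ 0.80 recovers the generator's
setting); the 249:62 split is far from 50/50 (χ²(1) = 112.44), and the
rank-scanned overlap P-value is ~10⁻¹⁷², i.e. the two signatures share far
more top-ranked genes than independent draws from a 2000-gene background
would. `so.make_bioset(res)` returns those 249 positive-correlation genes as
a new signature for the contribution and enrichment stages.

The same flow is available from the shell:

```sh
sigoverlap simulate --seed 1 --out-dir sim
sigoverlap extract --matrix sim/study_a.tsv --labels sim/study_a.labels.tsv --out a.tsv
sigoverlap extract --matrix sim/study_b.tsv --labels sim/study_b.labels.tsv --out b.tsv
sigoverlap overlap --sig-a a.tsv --sig-b b.tsv --background-n 2000
sigoverlap run --config run.yaml     # full declarative pipeline
```

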