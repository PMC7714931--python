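# Methods

## The testing problem

A summary-level TWAS tests, gene by gene, whether genetically predicted
expression is associated with a trait. Stage one (outside this package's
scope) estimates cis-SNP weights `w` from a reference transcriptome panel;
stage two, implemented here, combines those weights with GWAS marginal
z-scores `z` and a reference LD correlation matrix `R`:

    Z_t = z wᵀ / sqrt(w R wᵀ).

Under the null, `z ~ MVN(0, R)`, so `Z_t` is asymptotically N(0, 1) and its
p-value is the two-sided normal tail. The statistic is invariant to rescaling
`w`, equivariant under sign flips of `z`, and invariant to any common
permutation of the SNP order.

With `T` candidate tissues a gene yields up to `T` p-values that share the
same GWAS signal and overlapping eQTLs, hence are strongly positively
correlated with an unknown structure: expression reference panels are too
small to estimate the inter-tissue correlation `C` of the `Z_t` reliably.
The package's combiner of record is the Cauchy aggregation test (SCAT):

    T_SCAT = Σ_t ϖ_t tan((½ − p_t) π),
    P      = ½ − arctan(T_SCAT / Σ_t ϖ_t) / π.

Each tangent term is standard Cauchy under its null; the heavy Cauchy tail
makes the weighted average's null distribution insensitive to the dependence
among terms. Under independence the combined p-value is *exactly* uniform;
under dependence the guarantee is asymptotic as the level α → 0 (see
Calibration below). Fisher's method and the known-`C` chi-square oracle
`Q = Z C⁻¹ Zᵀ ~ χ²_T` are included as comparators, and a Bonferroni-calibrated
min-p helper as an internal benchmark. Gene calling uses Benjamini–Hochberg
with a strict `q < 0.05` rule.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `ϖ_t` | equal over observed tissues | combination weights; only their ratios matter (the formula divides by Σϖ) |
| `ridge` (single-tissue test) | 0, fallback 1e-6 | added to the LD diagonal when `w R wᵀ ≤ 1e-10`; finite reference panels can make `R` rank-deficient |
| p clipping | [1e-300, 1 − 1e-16] | keeps incoming p-values inside the open unit interval in double precision |
| tangent asymptote | p < 1e-15 | `tan((½−p)π)` is evaluated as `1/(pπ)`; elsewhere the cotangent identity `cot(pπ)` is used, which is accurate over all of (0,1) where the naive formula loses ~10 digits for p ≈ 1e-10 |
| Cauchy tail switch | x > 1e15 | combined p computed as `1/(πx)` to avoid cancellation in `½ − arctan(x)/π` |
| FDR threshold | 0.05 | strict inequality `q < 0.05` |

When one p-value `p_j` dominates (is tiny), the combined p-value approaches
`p_j · Σϖ / ϖ_j` — at equal weights, `T · min p` — so SCAT never pays more
than a Bonferroni-like factor for aggregation.

## Simulation design

The Monte-Carlo engine works directly on the z-score scale, the level at
which the multi-tissue dependence lives:

1. draw `z = μ + MVN(0, C)` with `C` independent, exchangeable(ρ), AR1(ρ), or
   a user matrix (default `T = 13`, matching the 13 brain reference panels);
2. per-tissue two-sided normal p-values;
3. power runs only: set a uniformly chosen set of `k` tissues missing,
   `k` uniform on {5, …, 11} — mimicking that most genes are cis-heritable in
   only a subset of reference tissues;
4. combine the remaining p-values per method; reject when combined p < α
   (α = 0.05 by default; the per-replicate rejection rule is a config field).

Under the null `μ = 0`; under the alternative each `μ_t` is drawn iid
N(0, 2.5), resampled every replicate (a fixed-`μ` mode is available via
`resample_per_replicate=false`; with it, the estimated power is conditional
on the single realised mean vector and varies widely across seeds). All
methods are evaluated on the same replicate draws, so method contrasts are
paired. Defaults: 10⁵ replicates for size runs in the test suite (scaled
from 10⁶; the MC standard error at α = 0.05 is then 7e-4, ample for
calibration checks at desk scale), 10³ for the headline power scenarios and
10⁴ where a dominance contrast needs tighter error.

The packaged "empirical-style" 13×13 correlation matrix
(`empirical_style_correlation`) is a synthetic stand-in for an empirical
inter-tissue z-score correlation: three anatomical blocks with within-block
0.6–0.9 and between-block 0.3–0.45. It reproduces the qualitative regime
(strong, heterogeneous positive dependence) but no real panel produced it;
`CorrelationSpec(kind="matrix")` and the `simulate --config` matrix_file key
accept a real matrix.

### What the generator does and does not emulate

It emulates the joint null/alternative distribution of per-tissue TWAS
z-scores given a correlation structure, Gaussian effect heterogeneity across
tissues, and tissue missingness. It does not simulate genotypes, eQTL
architectures, weight-estimation noise, LD mismatch between GWAS and
reference panels, or allele-coding errors — so passing tests demonstrate the
statistical behaviour of the combiners, not robustness of the full two-stage
pipeline to reference-data problems.

## Calibration of the Cauchy combination at moderate levels

Measured at 10⁵ replicates, SCAT's empirical size is indistinguishable from
nominal under independence (exact uniformity), but mildly anti-conservative
at conventional levels under strong exchangeable correlation: about 0.056 at
α = 0.05 for ρ = 0.3, 0.061 for ρ = 0.6, 0.055 for ρ = 0.9 (and ~0.012 at
α = 0.01). This is a real property of the method — its dependence-robustness
guarantee is asymptotic in small α — and the acceptance checks that demand
3-MC-SE agreement at those levels under exchangeable dependence therefore
fail by design rather than being loosened. At genome-wide-relevant levels
(α ≤ 1e-4) the approximation is far tighter, which is the regime the method
is intended for. Fisher's method, by contrast, is grossly inflated under the
same dependence (size ≈ 0.16 at ρ = 0.6, α = 0.05).

## Power under exchangeable correlation

With the documented design (iid per-tissue means of variance 2.5 resampled
per replicate, 5–11 tissues missing, α = 0.05, 1,000 replicates), SCAT's
power is roughly 0.55–0.65 and nearly flat in the exchangeable ρ — the iid
mean vector supplies fresh independent signal in every tissue regardless of
the noise correlation. Published values for this experiment decline steeply
with ρ, a pattern none of the design variants we examined (shared scalar
mean, correlated mean vector, variance 1–3.5, α 0.01–0.05, missingness
on/off) reproduces simultaneously at all four ρ values; a mean vector drawn
once per scenario — whose realisation cannot be recovered — would produce
exactly such irregular conditional powers. The package reports what the
documented design computes; the ρ = 0 setting agrees with the published
0.572 within Monte-Carlo tolerance, the positive-ρ settings do not, and the
corresponding acceptance checks are left failing with this analysis rather
than the generator being tuned to match.

## Numerical and design choices

* SNP alignment uses the intersection of GWAS/weight/LD ids in the weight
  file's order; missing weights mean an absent SNP, not a zero weight.
* Allele harmonisation flips the z sign for swapped A1/A2 and drops
  irreconcilable SNPs; strand-ambiguous (A/T, C/G) SNPs are dropped only on
  request, since summary files rarely carry strand information.
* The oracle statistic solves `C x = Z` rather than inverting `C`.
* BH ties share an adjusted value (any tie rule gives identical q); missing
  p-values are excluded from the number of tests.
* Scenario runs embed seed, config hash and package version in their output
  headers; identical (config, seed) runs are byte-identical.
* The minimum-p combiner is deliberately a Bonferroni-calibrated internal
  helper only: a permutation-calibrated version would need resampling the
  whole pipeline, which the summary-data setting does not support.

## Known limitations

* The Cauchy combination's mild moderate-α inflation under strong positive
  dependence (quantified above).
* Weights are inputs; nothing here validates how they were estimated.
* The genomic-inflation diagnostic of a real analysis (λ of the gene-level
  p-values) requires a full GWAS and is out of scope.
* Single-tissue "method" rows in the simulator report tissue 1 (all tissues
  are marginally identical under the exchangeable designs); use
  `per_tissue_rejection_rates` for per-tissue curves under asymmetric `C`.
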