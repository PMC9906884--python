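# Methods

This note records the statistical models behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical choices a maintainer would want written
down.

## TWAS from summary statistics

The gene-level statistic is the standard summary-based TWAS form
`z = wᵀz_snp / √(wᵀΣw)`, where `w` are per-SNP expression weights and `Σ`
the SNP correlation (LD) matrix from a reference panel. A ridge term
ε = 1e-4 is added to the diagonal of Σ before the quadratic form; reference
LD matrices estimated from finite panels can be numerically non-positive
definite, and the ridge keeps the denominator positive without materially
changing well-conditioned cases. The statistic is invariant to positive
rescaling of `w`, and the ridge preserves that invariance exactly: the
numerator and the denominator's quadratic form `wᵀ(Σ+εI)w` both scale
with the weight scale, so the ratio is unchanged.

Allele harmonization matches SNPs by identifier, flips the GWAS Z sign
when effect/other alleles are swapped, and drops strand-ambiguous (A/T,
C/G) SNPs outright — allele frequencies are not part of the input
contract, so frequency-based strand resolution is impossible. A gene whose
SNPs all drop out is skipped with a warning rather than crashing the scan.

Two-sided p-values use the normal distribution, never t: summary-based
TWAS statistics are asymptotically normal. Benjamini–Hochberg q-values are
computed by the step-up definition `q_(i) = min_{j≥i} p_(j)·m/j`, capped
at 1, in input order. BH is applied within each tissue panel by default
(`fdr_scope="panel"`), with a global option; the multi-panel design makes
per-panel correction the interpretable default when panels are reported
separately. The significance filter is `FDR q < 0.05` (strict) and
`cv-R² ≥ 0.01` (non-strict), matching the stated thresholds exactly at
their boundaries. The best GWAS SNP per gene is the harmonized SNP with
the largest |Z|, ties broken by lexicographic SNP id.

## Batch adjustment and moderated t

Batch adjustment is the parametric empirical-Bayes location/scale model
(ComBat): genes are standardized under a design that includes the batch
one-hots plus the case/control label, per-batch additive and
multiplicative effects are shrunk via normal/inverse-gamma priors with
method-of-moments hyperparameters, and the shrunken effects are removed.
The implementation delegates to `scanpy.pp.combat`; the group label is
passed as a numeric indicator covariate because a one-hot categorical
covariate would make the combined design rank-deficient. A single-batch
study is returned unchanged, and a batch with one sample raises an error
(its variance is undefined). Protecting the group label matters: without
it, unbalanced designs let the adjustment absorb part of the case/control
contrast.

The moderated t follows the empirical-Bayes variance-shrinkage scheme:
per-gene pooled variances `s²_g` with `d_g = n₁+n₂−2` degrees of freedom;
prior `(d₀, s₀²)` fit by matching the mean and variance of
`log s²_g` (digamma/trigamma-corrected), with the trigamma equation
inverted by Newton iteration; posterior variance
`s̃² = (d₀s₀² + d_g s²)/(d₀+d_g)`; and p-values from t with `d₀+d_g`
degrees of freedom. When the moment estimate finds no excess dispersion
(all genes sharing one variance, as in the homoscedastic simulations),
`d₀ = ∞` is used — every variance collapses to `s₀²` and the reference
distribution is normal — with a logged notice. `prior_df=0` recovers the
ordinary two-sample t exactly, which the tests use as a limit-case oracle.
DEG thresholds `|log₂FC| > 1`, `adj.P < 0.05` are both strict.

Probe-level data are assumed pre-collapsed to genes; the generators work
at gene level, and no probe-collapsing rule ships with the package.

## Over-representation

The ORA p-value is the hypergeometric upper tail `P[X ≥ k]` with the
universe defaulting to the genes carrying TWAS weights — the background
against which the study list was actually selectable — overridable by the
caller. Sets are intersected with the universe first and sets smaller than
5 after restriction are not tested (configurable). BH runs across all
tested sets of a catalog.

## CGSEA

The ranking statistic is the signed TWAS Z pooled across panels, keeping
each gene's largest-|Z| entry (`pooling="max_abs"`; `"mean"` available).
Ties in the ranking break by lexicographic gene id, so runs are
deterministic. The running sum increments by `|stat|^weight_exp`
(normalized over set members) at member genes and by `1/(N−|S|)` at
non-members; ES is the signed maximum deviation, in [−1, 1]. The default
`weight_exp = 1` is the standard weighted variant; 0 reduces exactly to
the classic two-sample Kolmogorov–Smirnov statistic, which the tests
verify against an independent implementation. If every member's statistic
is exactly zero under positive weighting, hit increments fall back to
uniform with a logged warning rather than dividing by zero.

Only summary statistics exist at this stage, so the null is gene-label
permutation — uniform random member subsets of the same size — matching
preranked-GSEA practice; phenotype permutation is impossible without
individual-level data. Null samples are cached per set size within a run
(seeded from the run seed and the size), so chemicals with equal effective
sizes share a null.

The empirical p is the upper tail on the signed ES against the full null,
`p = max(#{null ≥ ES}, 1)/n_perm`, floored at 1/n_perm. The choice of
tail deserves a note. With the ranking signed so that risk-increasing
association sorts to the top, enrichment of trait-associated genes
appears as a large positive ES, and the upper-tail p is exactly uniform
on the permutation grid under the null — the property that makes the
reported type-I level nominal. The superficially natural alternative,
mirroring the tail to the side of the observed score's sign, is *not*
null-uniform: its null CDF rises at twice the nominal rate and is capped
at the same-sign null mass, so a calibration check against Uniform(0,1)
must fail by construction. That variant is retained as
`empirical_p(..., side="signed")` for two-direction screening, with the
caveat documented here. NES divides the observed ES by the mean magnitude
of same-sign null scores (an interpretation choice — no canonical
normalization is mandated by the enrichment-score definition itself);
when no same-sign null score exists, NES is reported missing with a
warning. BH-FDR runs across all surviving sets.

## MCODE

Vertex weight is `k × density` of the highest k-core of the vertex's
closed neighborhood; modules grow greedily from the highest-weighted
unvisited seed, admitting neighbors with weight ≥ (1−vwp)·seed weight,
each vertex joining at most one module core. Defaults mirror the
published plugin defaults: vwp 0.2, haircut on (iteratively removing
members with fewer than two in-module neighbors), fluff off, max depth
100, minimum module size 3. Edge filtering at combined score 0.15 is
inclusive (≥); "requiring a confidence level of 0.15" is read as
admitting edges at the level. Density is loopless, `2|E|/(|V|(|V|−1))`;
multi-edges collapse to the maximum score; scores on the 0–1000 integer
convention are auto-detected and rescaled. Module order (score desc, size
desc, smallest member id) and within-expansion neighbor order are fixed,
so the module list is deterministic. If haircut disconnects a module, the
seed's component is kept.

## Synthetic data: what it emulates, what it does not

LD is first-order autoregressive within a gene (`Σ_ij = ρ^|i−j|`, default
ρ = 0.5 over 5 SNPs) and independent across genes — the simplest structure
that exercises the `wᵀΣw` denominator. Real genomes have long-range LD,
varying block sizes, and cross-gene correlation; none of that is emulated,
so passing tests say nothing about, e.g., TWAS signal spreading across
neighboring genes. GWAS Z-scores are drawn `N(Σw·β, Σ)` per gene, giving
the TWAS statistic noncentrality `β·√(wᵀΣw)` for causal genes and an
exactly standard-normal null — effect-size architecture in real data is
unknown, and this parameterization is a stand-in chosen to make power
calculations closed-form. Default standardized effect 6.0 with 2% causal
genes gives a mix of detectable and borderline genes.

Expression is Gaussian on the log2-intensity scale (array-like), not
count-based: baseline ~N(7, 1), unit gene-level noise, batch b shifted by
`b·batch_shift` (default 2) and scaled by `1 + 0.25b`, groups balanced
within batches. Defaults (30 per group, two batches) mirror a two-cohort
case/control study of the published size. RNA-seq overdispersion,
probe-level artifacts and missingness are not modeled. Planted log2
fold-changes are exact mean shifts, so the DEG-recovery tests measure the
estimator, not normalization.

Chemical catalogs draw set sizes uniformly over 10–500 from the gene
universe; planted sets oversample the top of a supplied ranking (fraction
`rank_bias` from the top `n_top` genes). Networks plant fully connected
cliques (scores in the top fifth of the score range) over an Erdős–Rényi
background (default edge probability 0.02).

A single study seed expands to per-component child streams through
`SeedSequence` spawn keys, so adding a generator never perturbs existing
streams, and byte-identical reruns are a tested property end-to-end.
In the orchestrated pipeline, planted causal genes are drawn from the
genes passing the cv-R² filter (an undetectable causal gene teaches
nothing about the downstream chain), eight of them are also planted as
DEGs to create a recoverable TWAS/DEG overlap, and the chemical-catalog
ranking is ordered by expected TWAS signal.

## Problem sizes

The test suite and acceptance script run at desk scale: 2000 genes × 5
SNPs for TWAS calibration and power, 2000 genes × 60 samples for DEG
recovery, 200 chemical sets at 2000 permutations for CGSEA type-I (the
full 10,000-permutation default is exercised where only one null sample
is needed, e.g. the empirical-p floor), and 500 random graphs of ≤ 12
vertices for the MCODE weight oracle. These sizes make every property
measurable with tight Monte-Carlo error while each stage completes in
seconds to a couple of minutes.

## Known limitations

- No weight training (weights are inputs), no conditional/joint
  fine-mapping after the scan, no genotype-level simulation or imputation.
- The expression model is array-like Gaussian; count models are out of
  scope.
- GO-graph propagation and pathway topology are not modeled; catalogs are
  flat sets.
- The published study's headline counts (numbers of significant genes,
  DEGs, enriched terms, chemicals, clusters) depend on external
  database versions and are not reproduction targets of the synthetic
  pipeline; the package reproduces the *methods* and their calibration,
  plus the self-contained worked examples.
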