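# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `transqtl`.

## Association model

Expression is prepared by (1) removing genes with fewer than a configured
number of nonzero samples, (2) quantile normalization across samples (every
sample is mapped onto the mean of the per-sample sorted values; ties within
a sample receive the mean of the reference values they span, which makes the
operation idempotent), and (3) a per-gene rank-based inverse normal
transform, Φ⁻¹((k − c)/(n − 2c + 1)) with the Blom offset c = 3/8 by default
(the offset is an argument). The transform is applied per gene across
samples — the standard eQTL orientation; the per-sample alternative is not
implemented.

The scan fits, for every in-window (variant, gene) pair, the OLS model
`expression ~ dosage + covariates + intercept` and t-tests the dosage
coefficient. It is computed through the Frisch–Waugh projection: expression
and dosage are residualized once against the covariates, after which each
pair reduces to a simple regression with df = n − n_covariates − 2. This is
algebraically identical to refitting the full model per pair and is exact,
not an approximation. Monomorphic variants (and variants constant after
residualization) are skipped and counted. cis means |variant − TSS| ≤ 1 Mb
on the same chromosome; trans means a different chromosome or > 5 Mb from
the TSS. Pairs between 1 and 5 Mb are deliberately tested in neither mode.

Covariates are hidden expression factors (top principal components of the
normalized expression matrix — an intentional surrogate for PEER factors,
which capture the same inter-sample covariance structure at a fraction of
the cost), genotype principal components of the standardized dosage matrix,
and centered indicator expansions of categorical sample columns. The
pipeline caps the factor count at n_samples/10 to avoid overfitting small
cohorts. Rank deficiency of the assembled matrix is an error that names the
collinear columns.

## Multiple testing

Three schemes operate on the scan output:

* **Pooled FDR**: Benjamini–Hochberg over the nominal p of the LD-pruned
  record list; records with q < α are the candidate list. α = 0.25 is the
  working threshold (deliberately permissive — the list is a screening set,
  so roughly a quarter of retained records are expected false positives,
  which downstream stages must tolerate); α = 0.05 gives the confirmatory
  list.
* **Hierarchical gene-level FDR**: per gene, the minimum nominal p is
  Šidák-corrected for the gene's number of tests, 1 − (1 − p_min)^m
  (evaluated as −expm1(m·log1p(−p)) for numerical precision), then BH across
  genes.
* **Permutation gene-level FDR**: per gene, the covariate-residualized
  expression vector is permuted n_perm times (one shared permutation set
  across genes keeps the cost linear) and the min-p recomputed; the
  empirical gene p is (1 + #{perm ≤ obs})/(n_perm + 1), BH across genes.
  For significant genes, associations are reported at the gene's nominal
  threshold, defined as the α-quantile of its permutation min-p
  distribution.

LD pruning is greedy at the variant level: variants are visited in order of
their best record's p (ties by id); a variant is kept unless its squared
dosage correlation with an already-kept same-chromosome variant exceeds
0.6. All records of a kept variant survive together — an independent eSNP
may retain several target genes, which is what makes hotspots observable
downstream. Cross-mappability filtering removes records whose variant and
gene TSS fall into the two intervals of a blacklist pair, in either
orientation.

Split-half replication splits the samples into two disjoint halves,
re-applies the inverse normal transform within each half (a rank transform
does not restrict to subsamples), rescans, prunes and thresholds each half
independently, and reports |pairs in both| / |smaller list|. The overlap at
desk scale is substantially below what a 1000+-sample cohort would show,
because per-fold power (and the stability of which LD proxy is pruned)
drops with n.

## Colocalization

Per variant, the Wakefield approximate Bayes factor against the null is
log ABF = ½log(1 − r) + ½z²r with r = W/(W + se²) and z = beta/se. The
prior effect variance is W = 0.15² for quantitative traits on the
standardized scale — inverse-normal expression has unit variance, so no
rescaling is needed; GWAS inputs are expected on a standardized scale, and
W is an argument everywhere. Five-hypothesis posteriors (no association /
trait-1 only / trait-2 only / two distinct causal variants / one shared
causal variant) are combined with per-variant priors p1 = p2 = 1e-4,
p12 = 1e-5 and computed entirely in log space (log-sum-exp; the H3 term is
the cross-product sum minus the same-variant sum, computed with a guarded
log-difference so a single-variant region gives PP3 = 0 exactly).

For cis–trans pairing, the region around each independent trans-eSNP is its
LD-partner set (r² > 0.6), matching how overlapping cis signals are
defined; a fixed-window mode exists for callers that prefer symmetric
regions. Pairs with fewer than two shared variants are skipped — a
one-variant colocalization cannot separate H3 from H4.

## Mediation

For a (SNP g, cis gene M, trans gene Y) triple: mediator model
M ~ g + covariates, outcome model Y ~ g + M + covariates, both OLS, no
exposure–mediator interaction. Inference is quasi-Bayesian: n_sims
coefficient vectors are drawn from each model's asymptotic multivariate
normal (SVD-based sampling for robustness to near-singular covariance);
each draw yields ACME = a·b, ADE = c′ and total = ACME + ADE, so the effect
decomposition holds exactly draw-wise. Point estimates are means over
draws, intervals are 2.5/97.5 percentiles, p-values are fraction-based and
floored at 1/(n_sims + 1). Exposure–mediator collinearity (|r| > 0.999) is
an error: the direct and mediated paths are not identifiable there. The
screen applies no multiple-testing correction to per-pair mediation
p-values (the p < 0.05 flag is a per-pair label); callers can BH the
`acme_p` column if they need set-level control.

The co-expression contrast compares |Pearson r| of mediated pairs against
colocalized-but-not-mediated pairs (acme_p > 0.1) and against random pairs
matched to each mediated pair's two genes by mean-expression decile, with
two-sided rank-sum tests. The effect-size contrast compares |beta|
distributions between gene groups with two-sample Kolmogorov–Smirnov tests.

## Hotspots

A hotspot is an independent trans-eSNP with ≥ 3 distinct trans target genes
in the significant list. The co-regulation statistic is the mean absolute
pairwise Pearson correlation of the targets; the null resamples gene sets
matching the targets' mean-expression deciles (10 bins by default;
configurable), excluding the targets themselves, without replacement within
a set, and asserts the decile composition of every draw. Empirical p uses
the +1 correction. Both per-hotspot p-values and a pooled summary (mean of
hotspot statistics vs the draw-wise null mean) are reported, since either
summary is defensible.

## Hi-C enrichment

Positions map to 0-based half-open 100-kb bins (bin = floor(bp/resolution));
genes are anchored at the TSS. Same-chromosome pairs are excluded and
counted. Because interchromosomal contact frequencies are often zero, only
non-zero frequencies enter the comparison, on both sides. The null draws
`n_random` replicates of the observed chromosome-pair composition with bins
uniform over the bins covered by the contact matrix, so the null
chromosome-pair multiset equals the observed multiset in every replicate.
The test is the one-sided Wilcoxon rank-sum (observed > null) — rank-based
because normalized contact distributions are heavy-tailed; a one-sided KS
alternative is available.

## GWAS integration

Loci are built by iterative clumping of genome-wide significant variants
(p < 5e-8 by default): the smallest-p unassigned variant becomes an index
and claims every significant same-chromosome variant with r² > 0.6, so each
significant variant lands in exactly one locus. Genes enter a locus when
they have a QTL record with p < 1e-5 on a member variant (the trans list is
screened at this relaxed threshold because trans signals are
systematically weaker); the colocalization then uses the gene's full trace
over the shared member variants, and PP4 > 0.6 calls a risk gene. Gene-set
enrichment uses the exact two-sided Fisher p on the raw 2×2 table, a sample
odds ratio with the Haldane–Anscombe 0.5 correction when any cell is zero,
and a Woolf log-odds normal 95% CI. Centrality contrasts are two-sided
Wilcoxon rank-sum tests on externally supplied kME values (co-expression
module membership); network construction itself is out of scope.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, not
human genetics in detail:

* **Genotypes**: per-variant MAF uniform in `maf_range`; each haplotype
  allele is the indicator of a latent Gaussian below the MAF quantile;
  within an LD block all variants share a latent haplotype signal with
  weight `ld_within_block_r` (0.95 by default). Thresholding attenuates the
  realized dosage correlation below the latent target (median within-block
  r² ≈ 0.5–0.8 depending on MAF), which is deliberate: it yields a mix of
  partners above and below the 0.6 pruning threshold, as real blocks do.
  Blocks that come out monomorphic are redrawn deterministically.
* **Expression**: shared hidden factors (loadings ~ N(0, factor_sd²),
  scores ~ N(0,1)) plus Gaussian noise give every gene a correlated
  background, so covariate correction has real work to do. Planted effects
  add a·g to a cis gene, b·y_cis + c·g to a mediated trans gene (reading
  the realized cis expression, so the implied SNP→trans path is a·b), and
  c·g to a direct trans gene. Chained paths (a trans target mediating
  another path) are not supported.
* **Hi-C**: Poisson baseline contacts (the analyses only compare normalized
  frequencies, so any overdispersed marginal would do; Poisson has a
  tractable law-of-large-numbers oracle), with planted pairs redrawn at
  `hic_enrichment_factor` times the mean. Only interchromosomal pairs are
  generated.
* **GWAS**: causal variants get a latent standardized effect of magnitude
  `gwas_effect_size` (expected z = effect·√n); other variants inherit the
  causal z scaled by their empirical dosage correlation — the standard
  single-causal-variant summary-statistic approximation — plus unit noise.
* All randomness flows from one root seed through named CRC32-keyed
  substreams, so regenerating one artifact never perturbs another and every
  pipeline stage is bit-reproducible.

The reference planted cohort (`planted_cohort_config`) uses n = 500
samples, 4 chromosomes × 150 genes × 750 variants, 5 hidden factors
(factor_sd 0.3) and unit noise, and plants 20 cis effects (a = 1.0), 20
mediated trans paths — 5 hotspots of 3 targets sharing one mediator
(b = ±0.9) plus 5 singletons (b = ±0.65) — and 10 direct trans effects
(c = ±0.7) whose variants double as cis-eSNPs and as the GWAS causal
variants for 5 loci. Planted variants are restricted to MAF ≥ 0.2, one per
LD block, so each trans path explains ≥ ~5% of its target's variance and
planted eSNPs are mutually independent. The hotspot coupling is set higher
than the singleton coupling because a hotspot's scientific premise is a
single strong shared regulator: its targets' mutual correlation must stand
above the hidden-factor background, and the permissive FDR-0.25 list
attaches occasional spurious targets that dilute the observed mean |r|.
The architecture is laid out against a genotype preview drawn from the same
seed, which is sound because genotype generation does not depend on the
effects list. Pure-null cohorts (`null_cohort_config`) use n = 200, 500
genes, 2000 variants, factors and noise but no effects.

What passing on these cohorts does not show: robustness to non-Gaussian
expression (counts, zero inflation), realistic human LD and allele-frequency
spectra, population structure, batch effects beyond additive factors, or
multi-causal loci. The colocalization model is single-causal-variant by
construction; regions with allelic heterogeneity will distribute posterior
mass across H3/H4.

## Numerical choices and problem sizes

Correlations are clipped to [−1, 1]; p-values floored at the smallest
positive double; hypothesis sums and Šidák corrections computed in log
space; ties broken by (p, variant id, gene id) sorts with a stable
mergesort throughout, so outputs are order-deterministic. The test suite
and acceptance script run the reference cohort at n = 500 and nulls at
n = 200 with 1.3M and 0.8M trans tests respectively — sizes chosen so the
full validation chain (50 null cohorts, a full planted recovery run, and a
double run for bit-level determinism) completes on a single CPU in a few
minutes while keeping every planted effect at ≥ ~5% explained variance.

## Evaluation conventions

Recovery against planted truth is scored at the locus level: a planted
(variant, gene) pair counts as recovered when the called eSNP is the
planted variant or an LD proxy (r² > 0.6) of it, because greedy pruning may
legitimately retain a proxy in place of the planted variant. Mediated paths
are matched by their (cis gene, trans gene) pair — the cis scan already
constrains the anchoring eSNP to the planted mediator's 1-Mb window — and
hotspots by target-set inclusion plus chromosome identity, at empirical
co-regulation p ≤ 0.01.
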