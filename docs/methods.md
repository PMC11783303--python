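# Methods

`immusel` reimplements, at desk scale, a comparative-genomics analysis of
positive selection on immune-gene categories: gene-wide codon-model tests
with model averaging, within-species selective constraint (pN/pS),
expression-derived covariates (mean expression and tissue specificity τ),
and the category-level statistics that separate a *function* effect from
an indirect *constraint* effect. A synthetic-data generator produces every
input with the statistical structure the analysis assumes, so the whole
stack is testable without any sequence download.

## Codon substitution model

The substitution process runs on the 61 sense codons of the universal
code. For codons *i* ≠ *j* differing at *d* positions, the instantaneous
rate is

    d = 1:  q_ij = π_j · κ^{ts} · (s if synonymous else ω)
    d = 2:  q_ij = δ · π_j · (ω if nonsynonymous else s)
    d = 3:  q_ij = ψ · π_j · (ω if nonsynonymous else s)

with κ the transition/transversion ratio, π the codon frequencies
(fixed at F3x4: average nucleotide frequencies per codon position), ω the
nonsynonymous/synonymous rate ratio, *s* a synonymous-rate multiplier, and
δ, ψ the double-/triple-hit (multinucleotide) rates. Q is normalized by
the expected substitution rate of the *base* model (ω = s = 1, current
δ/ψ), computed once and shared across mixture components, so one unit of
branch length is one expected substitution per codon under the base
model. The chain is reversible (π is stationary), which the likelihood
engine exploits: the π-symmetrized generator is diagonalized once per
mixture component and P(t) = exp(Qt) for all branches comes from the
shared eigendecomposition.

Site-to-site heterogeneity enters as a discrete mixture: K ω classes
(default 3, ascending) and M synonymous-rate classes (default 3,
renormalized so Σ q_m s_m = 1, keeping branch lengths identifiable). The
site likelihood is the weighted sum over the K × M components of a
Felsenstein-pruning likelihood, with site patterns compressed and
per-pattern rescaling against underflow. Gap codons (`---`), `NNN` and
partially ambiguous codons are missing data (partial likelihood of ones).

## Tests for positive selection

Three nested model variants are fitted per gene: `base` (ω mixture only),
`S` (adds the synonymous-rate mixture), and `S_MH` (adds δ and ψ).
Ignoring synonymous-rate variation and multi-hit substitutions is known to
inflate evidence for positive selection; the `S_MH` variant exists to
absorb exactly that signal. For each variant, the null caps the largest ω
class at 1 and the alternative frees it; the statistic is
LRT = max(0, 2(ℓ_alt − ℓ_null)) referred to χ²₂. The true null
distribution at this boundary is a mixture with more mass at zero, so χ²₂
is conservative — type-I error below the nominal level is expected and is
what the calibration tests check (≤ 0.08 at α = 0.05).

The three alternative fits are combined through Akaike weights
w_i ∝ exp(−ΔAIC_i/2) over the converged variants, and the reported
model-averaged p is Σ w_i p_i, so a variant that fits the data poorly
contributes little. Genes are flagged at Benjamini–Hochberg q < 0.2.
An M1a-vs-M2a site-model comparison (ω₀ < 1 plus ω = 1, versus an added
free ω > 1 class; χ²₂) and a single-ω estimator for whole-CDS dN/dS are
provided for benchmarking against the older test tradition.

### Optimization

Parameters are mapped to a bounded vector: log κ, log tree-scale, the top
ω and descending ratios (which enforces class ordering), stick-breaking
logits for mixture weights, log synonymous rates (one fixed at 0 before
mean-1 renormalization), and log δ/ψ. L-BFGS-B with finite differences
does the work; the FD step is 1e-5, large enough to dominate the
eigendecomposition's numerical noise (the default 1e-8 step produced
spurious early convergence). Defaults use 3 deterministic seed-derived
restarts and a budget of 400 evaluations; a supplied warm start counts
against the restart budget. Relative branch lengths are taken from the
input tree with one free scale factor — full per-branch optimization is
out of scope at desk scale.

Two structural warm starts matter for calibration. The alternative starts
from the fitted null with the top ω lifted to 2 (a positive-selection
probe), so nesting holds up to optimizer noise. When the raw LRT exceeds
1, a symmetric refinement round runs: the null is refit from the
alternative's solution (top ω clipped to 1) so an under-optimized null
cannot inflate the statistic, and if that improves the null, the
alternative is re-probed from it. Without the first half of this
round, null fits systematically lag the alternative on candidate genes
and the test becomes anti-conservative; without the second half it
becomes powerless, because the refined null inherits background-parameter
improvements the alternative never saw. The engine caches per-component
eigendecompositions and per-structure pattern likelihoods, which makes
finite-difference steps on weight parameters nearly free.

`FitSettings.fast()` (K = 2, one restart, 35 evaluations) is the screening
configuration used for the large replicate-world simulations; it is a
deliberate power/runtime trade verified on its own calibration runs, not
a general-purpose default.

## Selective constraint (pN/pS)

Per coding position, fold degeneracy counts how many of the four
nucleotides (including the reference) encode the same amino acid;
mutations to stop codons are never synonymous. Site totals follow the
standard opportunity formulas

    S = f2/3 + 2·f3/3 + f4        N = f0 + 2·f2/3 + f3/3

so S + N equals the number of counted positions exactly. SNPs are
classified against the reference codon background (minus-strand alleles
complemented first; stop gain/loss counts as nonsynonymous). Then
pN = n_nonsyn/N and pS uses a pseudo-count, p(S+1): pS = (n_syn + 1)/S,
keeping pN/pS defined for genes without synonymous polymorphism. The
cross-species constraint covariate is the arithmetic mean of the two
species' pN/pS, requiring both by default.

The variant-filter cascade retains biallelic SNPs with QUAL > 30, both
strand supports positive (SAF, SAR > 0), read-position supports RPL > 1
and RPR > 1, allele balance in [0.3, 0.7], a one-sided exact
(Levene–Haldane) heterozygote-excess Hardy–Weinberg p > 1e-4, and fewer
than 5 missing genotypes; repeats are subtracted as 0-based half-open BED
intervals; a minor-allele-frequency floor (0.0625 for the 31-diploid
species) equalizes detectability between unequal sample sizes. Coverage
hygiene: per-sample masks remove sites below one third or above 1.5× the
sample median depth (thresholds halved for males on X-linked scaffolds);
scaffolds are called X when female:male mean normalized coverage falls in
[1.7, 2.5] — a numeric criterion chosen so the call is automatic and testable; sites where total coverage reaches
twice the mean merge into excessive-coverage intervals.

## Expression covariates

TMM normalization follows the published procedure: the reference sample
has the upper quartile (of counts scaled by library size) closest to the
mean upper quartile; per sample, the factor is the weighted mean of
gene-wise log2 fold changes after trimming 30% of M and 5% of A values,
with inverse asymptotic-variance weights; factors renormalize to
geometric mean 1 (cross-checked against edgeR in the test suite).
TMM–FPKM divides CPM on TMM-adjusted library sizes by the effective
length in kb (lengths of 0 remapped to 0.01). Tissue specificity is

    τ = Σ_i (1 − x_i/x_max) / (N − 1)

on untransformed per-tissue mean TMM–FPKM (no log transform — the index
is defined on the means themselves); all-zero genes get a missing τ. Mean expression is
the arithmetic mean of tissue means. A log2(CPM+1) PCA (after requiring
≥ 4 reads in ≥ 3 samples) is a QC view only — it deliberately replaces a
variance-stabilizing transform, which changes distances but not the
qualitative grouping of samples by organ.

## Category statistics

dN/dS is square-root transformed; mean expression, PPI + 1, and length are
log10; τ is arcsine-square-root; continuous predictors are Z-scaled.
Positive-selection status is modeled by a binomial GLM with type-3
likelihood-ratio tests (full vs term-dropped refits); sqrt dN/dS by OLS
with type-3 partial F. Per-category contrasts against the control level
use treatment coding, and the Dunnett-style family-wise adjustment is
P(max_j |T_j| ≥ |t_obs|) under the joint normal (GLM) or t (LM) null with
the correlation from the coefficient covariance, evaluated by Monte Carlo
with a fixed seed (200,000 draws, ±0.002 on p). pN/pS resists
normalizing transforms, so category differences use a tie-corrected
Kruskal–Wallis test with Dunn z-tests vs control and BH correction over
those comparisons. Partial Spearman correlations rank-transform all
variables, residualize on the control ranks, and use the t approximation
with df = n − 2 − k. The 2×2 G-test is the binomial likelihood-ratio
statistic on χ²₁, and the headline "rate ratio range" is the min/max of
per-row immune:control proportion ratios rounded to one decimal.

## Synthetic data: what it does and does not emulate

The generator writes every pipeline input: two-clade pure-birth
(Yule) trees joined by a stem, ultrametric with the requested root-to-tip
depth in substitutions per codon; codon alignments evolved site-by-site
with exact per-branch transition matrices (no Gillespie simulation —
deterministic given the seed, and exact for a time-homogeneous chain);
variant tables whose expected pN/pS before the pseudo-count equals the
target, with allele counts following a 1/i neutral-SFS law and
site annotations built to pass the filter cascade; negative-binomial
expression counts (dispersion 0.1, a typical bulk-RNA-seq value; the noise model is this package's choice)
around profiles whose noiseless τ equals the target exactly (one peak
tissue at μ, the rest at (1 − τ)μ); and 1-kb coverage tracks with X
scaffolds at half male depth plus injected high-coverage spikes.

Deliberately absent: demography, linkage and recombination (variants are
parametric, not coalescent), indels, alignment error, annotation error,
read-level noise, branch-length heterogeneity between genes (worlds share
one tree). Passing tests therefore demonstrate that the *statistical
machinery* behaves as claimed under its own assumptions — calibration,
power ordering, recovery — not that real rodent data would give the same
per-gene answers.

In a "world", each gene draws a pN/pS target lognormally around its
category mean (sd 0.3 by default) and carries a positive-selection ω
class with a category-specific probability. With
`constraint_coupling` > 0 that probability scales with
(pN/pS_gene / mean)^coupling, creating the gene-level mediation pathway
— low constraint → more positive selection — whose statistical signature
(category term attenuated by the pN/pS covariate) the end-to-end test
checks. Per-category fractions and effect sizes are calibration choices of
the generator, not estimates of real-data values.

## Study conditions for the calibration and end-to-end checks

A full-scale comparative study of this kind involves ~30 genomes and
thousands of genes of ~10³ codons; a single-CPU test suite cannot. Sizes here were fixed once, after profiling
and then frozen:

* **Calibration** (type-I, power, multi-hit pattern): 12 taxa, 150
  codons; 25 null genes per variant, 12 power genes (ω₃ = 5, weight 0.1),
  12 multi-hit-null genes (δ = 0.25, ψ = 0.05); fits with K = 3, M = 2,
  one restart, 150 evaluations.
* **Recovery**: 50 genes per ω level for the single-ω estimator; 200
  genes for τ; 20 replicates for the GLM effect.
* **End-to-end worlds**: 20 replicates × 150 genes/category (control,
  cytokines), 4-taxon 90-codon genes at depth 0.8, fast fit settings,
  base variant. Within-world effect sizes: positive class ω = 8 at weight
  0.15 in 25% of cytokine vs 3% of control genes before coupling; pN/pS
  targets 0.12 vs 0.32 with gene sd 0.5 and coupling 1.5; θ = 0.2.

Deeper trees were tried and rejected for the worlds: beyond ~1
substitution per codon root-to-tip, saturation at four taxa erodes the
test's power faster than the extra substitutions add signal.

## Numerical choices and degenerate inputs

LRTs are clamped at 0; all-gap columns contribute 0 to the log-likelihood;
an alignment with no variable column makes the single-ω fit
unidentifiable (flagged, ω missing); an all-zero expression sample is
excluded from TMM with a warning; a zero male coverage mean labels the
scaffold X with a warning; empty coverage input yields no intervals;
complete separation in the GLM flags the term's p as missing. Coordinates
are 0-based half-open internally; VCF positions convert on read; BED stays
native. Codons with one or two ambiguous bases are treated as missing
throughout (a convention, stated here once); only one SNP per codon is assumed, and
multiple SNPs classify per-SNP against the reference background.

## Known limitations

No branch-specific ω (the mixture applies to the whole tree, matching the
gene-wide usage); no autocorrelation of synonymous rates; no MNP/complex
allele decomposition (input VCFs are assumed pre-decomposed); the Dunnett
adjustment is Monte Carlo rather than quadrature; the χ²₂ reference is
conservative at the boundary rather than the exact mixture; the fast fit
settings trade fine-grained ω estimation for runtime and should not be
used to report per-gene parameter estimates.
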