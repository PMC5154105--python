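# Methods

This note documents the models, parameter choices and deliberate
simplifications behind `netconverge`, in the order the pipeline runs.

## Synthetic study design

The generator emulates a multi-region brain expression study on one cohort:
the same individuals (sample IDs and covariates) are profiled in every
condition. Expression follows a latent-factor model

    x_gs = μ_g + Σ_m λ_gm f_ms + Σ_h b_gh u_hs + ε_gs,

with one latent factor per module and condition. Consensus modules are
driven in every condition; differential modules only in the first third of
conditions. Defaults: 2000 genes, 9 conditions, 50 samples, module sizes
320/100/80/60 with the last module differential, loading magnitude
(`module_signal_sd`) 2 and noise sd 1, giving an expected within-module
correlation of s²/(s²+σ²) = 0.8. The 320-gene first module is the designated
disease module, the size chosen to match the scale at which the integrative
gates (DNM + GWAS) operate in real brain-network studies. Loadings carry a
random sign with P(positive) = 0.95: mostly-coherent modules keep
directional readouts (seizure anti-correlation, downregulation)
recoverable, while the minority of negative loadings still exercises the
unsigned-network decisions.

Hidden batch factors are rank-one terms across *all* genes with loading sd
1.5× the noise sd, i.e. batch structure dominates global variance. This is
deliberate: hidden-factor surrogates (here, principal components) can only
stand in for technical nuisance if the top components capture batch and not
the largest biological module; with weaker batch loadings PC1 is the disease
module itself and residualising it destroys the signal. Per-gene mean levels
come from a 0.4/0.6 mixture of N(3,1) and N(8,1) on the log2 scale (module
genes always from the high component), which is what the EM expression
filter is designed to separate.

Other generators: DNM counts are Poisson with per-gene rates proportional to
log-normal length weights, summing to `base_rate` (default 1) events per
trio; the disease module's *case, nonsynonymous* rate is multiplied by the
enrichment factor (default 5), synonymous counts never are (negative-control
class). Trio counts default to 356 cases / 1891 controls. GWAS P values are
U(0,1) in the background and 1−Φ(Z+shift) (default shift 0.5) in the
disease module; 5% of genes are flagged "no genotyped SNP" and excluded from
testing. The PPI graph draws endpoints with Pareto-distributed
attractiveness (degree-heterogeneous), default 3000 background edges over
2000 genes (mean degree 3, so a random 320-gene set connects ≈ 40% of its
nodes — leaving dynamic range for the planted 300 extra intra-module edges).
Disease DE gives module genes log2FC ≈ −1; the seizure phenotype is negative
binomial with log-mean 2 − 0.7 × (module factor), i.e. over-dispersed counts
anti-correlated with module expression — the realistic stress case for
rank-based scoring. The drug library holds one true drug whose up-set covers
60% of the disease module plus 149 decoys with 50 random DE genes each.

Each generator op draws from its own RNG stream (seed combined with a fixed
per-op tag), so adding a generator call never perturbs the others, and all
outputs are pure functions of (config, seed).

What the generator does **not** emulate: linkage disequilibrium, read-level
noise, probe-level microarray artifacts, correlated gene-gene noise beyond
the planted factors, and any coupling between PPI degree and DNM burden.
Passing tests therefore demonstrate the statistics' correctness and
calibration, not robustness to those real-data complications; in particular
the hub-vs-DNM analyses have no planted effect and act as implemented
machinery, not a recovery test.

## Preprocessing

Quantile normalisation forces every sample onto the vector of row means of
the column-sorted matrix; ties receive the mean of the target values they
span (the conventional policy, made explicit). Hidden factors are the top-k
principal-component scores of the gene-standardised matrix, scaled to unit
variance; k defaults to 10, and which factors to regress out is a config
list (default F1, F2), mirroring the manual selection such studies make from
factor-vs-covariate plots. Residualisation fits each gene on an intercept,
the covariates (categoricals expanded to indicators) and the selected
factors; rank-deficient designs go through the pseudo-inverse (equivalent
to dropping redundant columns) with a warning.

The EM expression filter fits a two-component univariate Gaussian mixture
(deterministic 1-D k-means initialisation from the data quartiles;
convergence at log-likelihood change < 1e-8 or 1000 iterations). The
expressed threshold is low_mean + Φ⁻¹(0.95)·low_sd. Degenerate fits
(component weight < 1e-3 or sd < 1e-6) and fits whose components are not
separated (Ashman's D = |μ₂−μ₁|/√((σ₁²+σ₂²)/2) < 2) are rejected as
"unimodal input" — the D criterion is needed because EM on a single
Gaussian happily converges to two overlapping half-components that the
weight/sd rule alone would accept. Note an unavoidable property of the
threshold definition: ~5% of genuinely low-expressed genes fall above the
95th-percentile cut.

Orthologue mapping keeps only strictly one-to-one pairs (a source with two
targets, or a target hit twice, is dropped with its rows).

## Network inference

Correlation is the biweight midcorrelation (tuning constant 9); genes with
zero MAD fall back to Pearson weighting for their pairs. The network is
unsigned, `a = |cor|^β` — the historical default and the reading consistent
with "raising the correlation to the β power"; a signed variant is out of
scope. β is selected as the smallest candidate whose scale-free fit index
(r² of log10 p(k) on log10 k, signed by slope) exceeds 0.8; the index bins
connectivity on the *linear* scale with ten equal-width bins, because
log-scale bins isolate single low-degree nodes into their own bin and break
the fit even for genuine preferential-attachment graphs. A single fixed
candidate (e.g. β = 7) is returned as given, with a warning if it misses the
criterion.

Consensus: each condition's TOM is calibrated to the first condition by a
single-quantile power transform (exponent log q_ref / log q_c at the 0.95
off-diagonal quantile — exact for power-law-related TOMs, identity for equal
ones), then the element-wise minimum is taken. The differential
(DiffCoEx-style) path computes the per-pair standard deviation of adjacency
across conditions, rescales it by its maximum, raises it to β/2 (the
original differential-co-expression soft threshold; without it, adjacency
sampling noise of strong consensus modules sits too close to genuine
condition-dependent signal and background genes chain into the clusters)
and clusters 1 − TOM of the result.

Module detection cuts the average-linkage dendrogram at 99% of its height;
clusters of at least `min_module_size` (default 40) become branches, smaller
ones are absorbed into the nearest branch when their mean dissimilarity
stays below the cut, otherwise unassigned. Modules whose eigengenes (first
PC of the gene-standardised submatrix, unit variance, sign-oriented to
correlate positively with the module, tie-break positive first loading)
have dissimilarity 1 − cor < 0.25 are merged iteratively, using the minimum
correlation across conditions in multi-condition runs. This is a simplified
hybrid dynamic cut without the PAM-like reassignment stage; the contract is
planted-module recovery, not bit-equivalence with any reference tool.
Blockwise decomposition is not implemented (synthetic scale fits one
block); the block-size parameter is accepted and ignored with a warning.

## Preservation

Four statistics span the density/connectivity contract: mean within-module
test adjacency and test eigengene variance explained (density); Spearman
correlations of intramodular connectivity and of within-module correlation
entries between reference and test (connectivity). The null draws random
same-size gene sets without replacement from the shared gene universe
(matching "no relationship between module assignment and test data"; not
degree-matched). Z per statistic, Z_density and Z_connectivity as means,
Z_summary as their mean, classified < 2 / 2–10 / > 10. The permutation count
defaults to 200 (the conventional choice; it is configurable and the
stability test checks doubling it moves Z_summary only within noise).

## Genetic enrichment

The DNM test builds the 2×2 table of DNM *events* (case/control ×
in/outside module) for one mutation class and applies the two-tailed Fisher
exact test; counts enter unnormalised, reflecting the assumption that all
genes' coding sequence is fully covered in all trios. Counting events (not
distinct genes) follows from testing mutation *rates*; a per-gene mode
exists behind a flag. Odds ratios use the Haldane–Anscombe 0.5 correction
when a cell is zero, with Woolf 95% log-OR intervals. Multiple testing:
Bonferroni over modules × phenotypes for the DNM gate, BH FDR for the GWAS
screen (gates: Bonferroni P < 0.05 and FDR < 5% jointly select the
prioritised module).

The GWAS test scores each gene Z_g = Φ⁻¹(1 − p_g) (mean −log10 P available
as an option), takes the module mean over genes with ≥ 1 genotyped SNP, and
standardises it against bootstrap same-size gene sets from the testable
background (default 100,000 draws; the pipeline uses 5,000 for desk-scale
runtime). One-sided P from the normal tail; an empirical bootstrap P with a
+1 pseudocount is reported alongside. A gene-exclusion list supports
leave-one-out sensitivity (e.g. dropping a single dominant gene).

## PPI and directional enrichment

PPI node-count enrichment compares the number of module genes with ≥ 1
intra-module edge to uniform random same-size gene sets (empirical P with
pseudocount; degree-matched sampling exists behind a flag but is not the
default, matching the stated null). The GSEA engine ranks by descending
score with deterministic gene-ID tie-breaks; hits advance by |s|^w/Σ|s|^w
(w = 1 default, w = 0 for the unweighted degree analysis), misses retreat by
1/(N−N_hit); ES is the signed extremum. The null permutes set membership
(the only null admissible for a precomputed ranked list); P is the
sign-matched tail with pseudocount, NES divides ES by the mean |null ES| of
matching sign, FDR q is the null-tail fraction on the NES scale. Gene sets
need ≥ 2 scored members. Permutations default to 10,000 (100,000 available
by flag); the pipeline uses 2,000.

## Drug screen

Signatures become up/down sets at adjusted P < 0.10; eligibility requires
≥ 10 significant genes. The screen is directional by default — one-tailed
(greater) Fisher of module × up-set — because the therapeutic logic is
reversal of a *downregulated* disease module; a flag generalises to
matching the disease direction. BH correction pools all eligible
(drug, cell line, concentration) entries. The included Welch-style DE
simulation in the generator exists only so the synthetic pipeline runs end
to end; it is not a moderated-statistics DE implementation. The replication
direction test reports the fractions of mapped module genes moved up and
down with one-tailed Fisher tests in each direction.

## Numerical and testing choices

Resampling sizes in the shipped pipeline configuration (bootstrap 5,000;
PPI 2,000; GSEA 2,000; preservation 100) are chosen so a full run completes
in ~15 s while leaving empirical P floors (1/(n+1)) well below the decision
thresholds; all are configurable up to the reference sizes. Calibration
tests use 500 null replicates and accept type-I error inside the 95%
binomial interval around 0.05; note that exact conditional tests are
intrinsically conservative at small counts, so those checks run at the
default cohort scale where the tables are near-continuous. All randomness
flows from named, seed-derived RNG streams; rerunning any stage or the whole
pipeline with the same configuration and seed reproduces outputs
byte-identically (wall-clock timing is kept out of the serialised report
for that reason).

## Known limitations

- The dynamic tree cut is a simplified hybrid; very close or nested modules
  may be resolved differently than by the reference implementation.
- The preservation module computes 4 statistics, not the reference tool's
  ~20; Z_summary and its thresholds are the supported contract.
- The unsigned network cannot distinguish a module from its anti-correlated
  counterpart; eigengene orientation handles reporting but signed-network
  biology is out of scope.
- Uniform (not degree-matched) nulls in the PPI test can overstate
  enrichment for modules of systematically high-degree genes; the
  degree-matched flag exists for sensitivity analysis.
- The single-set FDR q in GSEA reduces to a normalised tail probability;
  batch-level ratio-of-tails FDR across many sets is not implemented.
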