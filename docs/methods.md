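# Methods

## Estimation models

All genomic models are linear mixed models for genotype means `g` of
testcross hybrids,

    g ~ N(W b,  Σ_c σ_c² K_c + σ_ε² I),

fitted by restricted maximum likelihood. The fixed design `W` always
contains an intercept and the first three principal components of a
reference inbred panel; the directional model appends genomic inbreeding
`F` and `F²`, and the genotype-by-panel model replaces the intercept with
panel indicators. Kernels are built from noncentered marker matrices:
`G = XX'/m` from minor-allele counts and `D = ZZ'/m` from heterozygosity
indicators, with per-bin variants `K_k = M_k M_k'/m_k` when variance is
partitioned by a functional feature. Because hybrids descend from
homozygous parents, `Z = 1{X = 1}` exactly; the additive and dominance
kernels are therefore correlated, and separating them relies on the
panel's kinship contrast (see *Synthetic data*).

PC coordinates of any panel are projections with the reference model,
`P = (X − M) V`, where `M` holds reference column means and `V` the top
right singular vectors of the centered reference matrix; loadings are
sign-fixed by forcing the largest-|loading| entry of each column
positive. Minor alleles are defined by reference-panel frequency, ties at
0.5 broken by keeping the simulated allele orientation.

### REML

The optimizer takes average-information (AI) steps on the variance
components, halving the step until the restricted likelihood does not
decrease and falling back to an expectation–maximization update when no
AI step is acceptable (EM never decreases the restricted likelihood).
Components driven to zero are clamped there and flagged as boundary
estimates; a clamped component with an inward-pointing score re-enters
the active set. Convergence is |Δ restricted log-likelihood| < 1e−8 or
200 iterations, with non-convergence flagged rather than silent. Starting
values split the OLS residual variance equally across components. The
reported restricted log-likelihood subtracts log|W'W| so that it is
invariant to the basis of the fixed design; likelihood-ratio tests
require identical fixed designs and use χ² with df equal to the
difference in component counts (a ½–½ mixture option exists for
boundary-null tests, the plain χ² being the conservative default). Fixed
effects are GLS at the optimum, `b̂ = (W'V̂⁻¹W)⁻¹ W'V̂⁻¹ y`, with
covariance `(W'V̂⁻¹W)⁻¹` used by Wald tests.

### Variance partition and derived statistics

Shares of phenotypic variance use kernels adjusted for the fixed design,
`K̃ = (I−H) K (I−H)` with `H = W(W'W)⁻¹W'`; the share of component *c* is
the average over individuals of `K̃_c,ii σ_c² / (Σ_d K̃_d,ii σ_d² + σ_ε²)`,
so all shares including the residual sum to one. SNP enrichment of bin
*k* is its share of the genomic (non-residual) variance over `m_k / Σ m`;
SNP-share-weighted enrichments average to one by construction. The degree
of dominance is `√(share_D / share_G)` — the residual cancels, so it is a
ratio of genomic SDs (a 35/65 dominance/additive split gives 0.73, 41/59
gives 0.83). A second enrichment summary, the per-SNP variance fold
`(σ_k²/m_k)` relative to its SNP-weighted average, estimates the ratio of
per-SNP effect variances between bins and is the quantity compared with
generative folds in recovery experiments (a 10× bin covering 20% of SNPs
has share-based enrichment ≈ 3.6 even with perfect estimation, but a
per-SNP fold ratio of 10).

### GWAS

The per-SNP scan fixes variance components at the null-model REML
estimates, whitens data by `V̂^{-1/2}` (eigendecomposition), and runs GLS
of `g` on `[Q, x_j]` (or `[Q, x_j, z_j]`) per SNP with residual-rescaled
t-tests — exact under the null if the null components were known, and
calibrated in practice (checked by KS uniformity on permuted traits).
SNPs whose dominance column is collinear with `[Q, x_j]` (fewer than
three genotype classes) fall back to the additive-only test; fully
collinear SNPs are flagged NaN. FDR control is Benjamini–Hochberg
step-up. PIPs from a sparse Bayesian model are treated as input; windows
are anchored at position 0, half-open `[start, start+500kb)` with 250-kb
steps, and a SNP's WPIP is the maximum over windows covering it.
High-confidence selection keeps SNPs with q ≤ 0.05 and WPIP ≥ 0.5, then
greedily prunes, in ascending-p order (ties to the lower coordinate),
SNPs within 1 Mb of a kept SNP on the same chromosome.

### Prediction

New-panel predictions combine the fixed part from projected reference PCs
(never refit, which also prevents leakage) with BLUPs through
cross-kernels built from each training kernel's own SNP columns and
scaling, `û_new = Σ_c σ̂_c² C_c V̂⁻¹(y − Wb̂)`. Validation schemes:
leave-one-population-out over biparental families, and random subsets
stratified by tester × k-means cluster (k = 4, k-means++ with 10
restarts, fixed seed) with cell-balanced dealing. Accuracies are Pearson
correlations; significance by one-sample and validation-set-paired
t-tests (raw correlations by default; a Fisher-z option is a flag).

### Plot-level model

Plot records are modeled as `y_ij = g_i + env_j + e_ij` with i.i.d.
random genotype, environment and error terms — a deliberate
simplification without spatial autocorrelation, which the estimators
downstream do not need. `H² = σ_g²/(σ_g² + σ_e²)`; entry-mean
reliability is `1 − mean(PEV)/σ_g²` from the prediction-error variances
of the random genotype effects; genotype means come from the
fixed-genotype variant (optional fixed covariate, e.g. flowering time for
yield).

## Synthetic data

The generator emulates two panel types: a diverse inbred panel crossed to
two testers from different subpopulations, and biparental RIL populations
sharing a common parent, crossed to the tester the two panels share (the
non-common parents are also crossed to that tester, giving check hybrids
present in both panels for ρ_R).

**Founders.** Ancestral allele frequencies are Uniform(0.05, 0.95);
subpopulation frequencies follow Balding–Nichols with parameter
`divergence` (default 0.15, verified by a Hudson-estimator check), and
within each subpopulation founders come in pedigree families
(`family_size` = 6 lines) whose frequencies diverge further
(`family_divergence` = 0.4). The family level matters: with i.i.d.
founders a ~500-hybrid panel has almost no kinship contrast and the
information matrix makes additive and dominance components practically
inestimable, whereas germplasm collections in reality contain many
closely related accessions. All founders are fully homozygous. A
designated third of them (every third line) acts as the external
reference panel for allele-frequency orientation, π, and PCs; SNPs
monomorphic in that subset are dropped.

**RILs.** Each RIL is one recombinant gamete of the F1, doubled to
homozygosity: crossover counts per chromosome are Poisson with mean the
map length in Morgans, crossover positions uniform on the genetic scale.
This doubled-gamete idealization gives exactly one meiosis per
transmitted gamete (≈1 crossover per Morgan) and avoids
residual-heterozygosity bookkeeping; it understates the map expansion of
selfed RILs, which none of the estimators under test depend on.

**Annotations.** Gene intervals are placed to hit a target proximal-SNP
fraction (default 0.35 at the "< 1 kb of a gene" rule; an inclusive-≤
flag exists because the boundary convention is ambiguous in common
usage); MNase peaks sit near genes with configurable association; GERP
scores are a signed exponential mixture with configurable positive
fraction; MAF is π; the genetic map is a smooth deterministic oscillation
around 1.5 cM/Mb so recombination tertiles are non-degenerate. The
recombination-rate feature is estimated from the map by a GCV-penalized
smoothing spline and a 1-Mb finite difference divided by the (clamped)
window span, negatives clamped to zero.

**Phenotypes.** `g = structure + Σ_k X_k a_k + Z d + τ₁F + τ₂F² +
panel-deviation + ε`. Variance targets are on the phenotypic scale: each
genetic component is rescaled so its realized variance *orthogonal to the
panel indicators and PCs* equals its target exactly — this is the
variance the mixed models can see, and recovery is judged by comparing
`σ̂_c² · mean(diag K̃_c)` against the target. Per-SNP additive variances
are proportional to enrichment folds (global rescaling preserves the fold
ratios); dominance effects are exchangeable; panel deviations redraw the
polygenic effect independently per panel, matching the `G ∘ EE'`
covariance. The residual is left as drawn, so its recovery also tests
noise estimation. One master seed drives deterministic per-stage child
generators; identical configurations reproduce byte-identical output.

**What the generator does not emulate.** No coalescent realism and no
LD fine structure beyond family/RIL cosegregation — SNPs are exchangeable
given ancestry, so passing tests demonstrate estimator correctness under
the models' own assumptions, not robustness to real-genome LD. No
genotyping error, missingness or imputation noise (imputation-accuracy
scores are simulated only to exercise the filtering rule). Trait scales
are SD units, not crop units.

## Experiment design choices

* **Recovery experiments** use ~500-hybrid panels and 2,000–5,000 SNPs,
  20 replicates; these sizes keep a full sweep near ten minutes on one
  CPU while leaving Monte-Carlo error well inside the stated bands.
* **Enrichment recovery** runs on the single-tester RIL panel with an
  additive-only partition and a high-reliability trait (residual 0.15),
  and the enriched bin is a contiguous fifth of the genome (two of ten
  chromosomes). Scattered random bins produce bin kernels that are nearly
  identical in expectation, so their components are identified only
  through 1/√m kernel noise and estimates are wildly heavy-tailed;
  contiguous bins segregate differently across RIL families and are
  genuinely distinguishable.
* **Directional effects** use τ₁ = −0.5 for coverage and a purely
  quadratic τ₂ = −4 (trait SD per unit F²) for power, on a
  high-reliability trait. The Wald SE of the quadratic term is ≈1 in
  these panels — F is strongly entangled with the dominance kernel's
  leading direction — so the power arm uses inbreeding-depression
  curvature large enough for the test to operate at its nominal power;
  maize yield loses several trait SDs under complete inbreeding, so the
  magnitude is not biologically outlandish.
* **GWAS null calibration** checks KS uniformity of 5,000 p-values on a
  permuted pure-noise trait in a single-tester panel of independent
  founders. Each EMMAX test is exactly calibrated there; the restrictive
  conditions exist because the KS check also needs the tests to be nearly
  independent — with two testers every female appears in two hybrids and
  the pair contrasts become common factors across all tests, and a
  genetically structured trait makes the permutation null exchangeable
  but slightly non-Gaussian, both of which the KS statistic detects at
  this many tests even though each single test stays valid.
* **Interaction model experiments** use two joint panels of ~240 hybrids
  each; ρ_G targets of 1.0 and 0.5 follow from setting the panel-specific
  variance to 0 or to the main variance.
* The quadratic-inbreeding design uses raw `F` and `F²` (a centering flag
  exists); the Wald test of the quadratic coefficient is invariant to
  centering.

## Numerical notes and limitations

* Kernels are dense; PSD is verified by jittered Cholesky
  (tolerance 1e−8·trace/n). Desk-scale n (≤ ~1,000) keeps every REML
  iteration at O(n³) milliseconds-to-seconds.
* Tertiles use type-7 (linear-interpolation) sample quantiles; all-equal
  values raise a degenerate-bin error.
* The smoothing spline can fail GCV selection on noise-free maps; the
  estimator then falls back to a linear interpolant, which is exact
  there. Flat maps short-circuit to zero rates.
* EMMAX p-values are approximate under strong single-SNP signal (variance
  components are not refitted per SNP); agreement with exact per-SNP
  REML refits is monitored by a Spearman check in the tests.
* Epistatic kernels are out of scope: additive × additive relationships
  are nearly collinear with additive ones in panels like these, and
  centering conventions make epistatic partitions arbitrary.
* The plot-level model omits the spatial autocorrelation real trials
  exhibit; genotype means fed to the genomic models are correspondingly
  clean.
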