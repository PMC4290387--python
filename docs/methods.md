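# Methods

This note documents the models, estimators, and numerical choices behind
`epimarks`, and what the synthetic-data experiments do and do not establish.

## The synthetic cohort model

The generator emulates a three-species comparative design (default 3 species
× 8 individuals, five marks, one individual missing for H3K27ac in the third
species, emulating a real-world incomplete design; all downstream code
tolerates N = 7).

**Latent marks.** Per gene g, a 5-vector of latent "mark enrichment levels"
(sqrt-RPKM-fold units) is drawn once from N(μ, Σ) and shared by all
individuals; values are clipped at 0 (levels are non-negative by
definition). Defaults: μ ≈ 1 (levels fluctuate around the genome-wide
average), per-mark SD 0.4, active-mark correlations +0.55, H3K27me3
correlations −0.35 — the qualitative pattern seen near TSSs in
lymphoblastoid data, where the repressive mark opposes the active four.

**Latent expression.** log2-scale expression is linear in the latent levels,

    y_gi = b0 + Σ_j β_j x_gij + ε_g + η_{g,s(i)},

with β = (0.2, 0.8, 0.7, −0.6, 0.9): H3K4me3, H3K27ac and Pol II carry most
of the signal, H3K4me1 little, H3K27me3 a negative effect — the relative
importance ordering expected for these marks. ε_g is gene-level structural
noise shared by all species; η_{g,s} is a per-species component present
**only at shifted genes** (see below).

**Species shifts (DE ground truth).** A fraction f (default 0.1) of genes
receives species-level mark shifts u_{g,s}·w with loadings
w = (½, ½, ½, −½, ½): active marks move with expression, H3K27me3 against
it, so the direction-consistency rule is genuinely satisfiable. Expression
shifts follow through β plus the mark-independent η. Non-shifted genes have
no species component at all and are exact nulls for differential testing.
Two shift-size distributions are available: `normal` (sizes N(0, s²); the
default, used for variance-partitioning studies) and `signed` (±s with
random sign; used where "shifted" must mean "large effect", since a
N(0, s²) draw can be arbitrarily close to zero). For a species pair, the
ground truth is `GroundTruth.pair_de_genes`: genes whose shift differs
between the two species (a gene shifted identically in both is null for
that pair).

**Calibration.** The two structural-noise SDs are solved in closed form so
that the latent variance explained is 0.58 within species and 0.40 between
species on the shifted subset (the scale of these analyses in comparative
LCL data):

    R²_within  = B / (B + σ_struct² + f σ_spec²),   B = β'Σβ + f·(w'β·s)²
    R²_between = A / (A + σ_spec²),                 A = (w'β·s)²

Zero-clipping of latent levels shrinks β'Σβ slightly, so realized latent
R² is ≈ 0.57/0.395; cross-validated estimates land within ±0.02 of the
targets.

**Measurement layer.** Observed mark signal is latent fold (level²) plus
Gaussian noise of SD 0.15 on the input-subtracted-RPKM scale, floored at 0;
expression is latent log2 level plus Gaussian noise of SD 0.15. Counts are
emitted as real-valued read counts consistent with these targets (input at
a flat 0.5 RPKM, libraries 10⁷/4×10⁷/10⁷ reads) so that the zero-noise
configuration reproduces the latent values *exactly* after quantification —
integer rounding would break those identities, and nothing downstream
depends on integrality. `simulate_observed_matrices` produces the same
values as the count tables → quantification round trip (verified by test)
without materializing tables, for large-G studies.

**Peak calls.** Per individual×mark, genes with any latent signal emit a
peak (±1 kb of the TSS, jittered); confidence is an FDR for narrow marks
(Beta(1, 40) for strong signal — concentrated below the 5% stringent
cutoff; Beta(1.5, 12) for weak signal — concentrated below the relaxed
cutoffs) or an RSEG-style domain score for H3K27me3 (20 + Gamma for strong,
Uniform(1, 20) for weak). These distributions are a modelling convenience;
no claim is made that real peak-caller FDRs follow them.

**What the generator does not emulate.** Raw reads, duplicates, mappability
structure in sequence space, gene-length variation, phylogenetic structure
among the species (shifts are exchangeable across species), inter-gene
correlation, or peak-caller internals. Passing tests therefore demonstrate
the correctness and calibration of the *statistical machinery* under its
stated assumptions, not robustness to alignment artifacts or model
misspecification in real data.

## Quantification

* `normalized_peak_rpkm` scales input reads by the ChIP/input library ratio
  before subtraction (raw-count subtraction across different depths is not
  meaningful) and floors negative values at 0, since the square-root
  transform requires non-negativity.
* TSS windows run from 2 kb upstream to the earlier of 2 kb downstream or
  the start of the second orthologous exon, strand-aware; the half-width is
  configurable (±1/2/5/10 kb) with ±2 kb the default.
* The log2 offset is 0.25 RPKM, recorded in the matrix metadata; any
  strictly positive constant would serve.
* The TSS fold-enrichment test uses an exact one-sided Mann-Whitney for
  small samples (≤ 25 pooled values) and the asymptotic form otherwise;
  all-tied input yields p = 0.5 with a warning rather than an error.

## Two-step classification

Threshold comparisons are inclusive (FDR ≤ cutoff, score ≥ cutoff). Step 2
requires ≥ 1 shared base between a relaxed-pass call and a stringent seed
from **another individual** (any species), with cross-genome positions
resolved through the ortholog map; it is evaluated in a single pass against
the union of step-1 seeds — a relaxed call never licenses further relaxed
calls. The H3K27me3 relaxed rule is mere presence of a domain call. The
mappability filter retains calls overlapping ≥ 1 retained 200-bp window and
drops calls whose best ortholog-map aligned fraction is below 0.20
(boundary inclusive; a call with no map entry failed to lift over and is
dropped).

## Permutation differential test

Genes with median value ≤ 0 across the pair's individuals are excluded
(strictly above zero). Values are quantile-transformed to normal scores
twice — across genes within each individual (rank r ↦ Φ⁻¹(r/(G+1)),
average ranks for ties), then across the pair's individuals within each
gene. The per-gene statistic is the t-statistic of the species coefficient
from OLS on intercept + sex + species; if a label assignment makes sex
collinear with species (possible under permutation in a balanced design),
sex is dropped for that assignment.

The null is the **exhaustive** enumeration of species-label assignments
(lexicographic order, observed labelling included). Per gene,
p = #{assignments with |t| ≥ |t_obs|}/K. |t| values are quantized to
float32 before comparison: an assignment and its species-swapped complement
have identical |t| in exact arithmetic but can differ by an ulp, and the
quantization makes such exact-math ties count as ties. A consequence worth
knowing: in a *balanced* design the complement of the observed labelling is
itself enumerated, so the smallest attainable two-sided p is 2/K, not 1/K.

The empirical FDR at threshold t is
(mean over assignments of #{perm p ≤ t}) / #{observed p ≤ t}, evaluated at
each observed p, monotonized by a running maximum from smallest to largest
p, and clipped to [0, 1] in the reported table. No π₀ correction is
applied.

**Known limitation — rank leakage.** The stage-1 cross-gene transform
couples genes: strongly shifted genes displace the ranks of other genes
between species, most visibly at the distribution tails where normal scores
are steep. Under strong, frequent shifts this manufactures species
differences at truly null genes that the permutation null cannot absorb, so
the FDR measured against *generator* ground truth can exceed the nominal
level even though the estimator is internally consistent. On null data the
procedure is exactly calibrated (verified by a chi-square goodness-of-fit
test of the p-value distribution and a zero false-discovery count at the
5% threshold).

A related subtlety affects calibration checks themselves: after the
transform, every gene's p-value is drawn from the same *atomic*
distribution (the enumeration over one shared score multiset has heavy
irregular ties), so goodness-of-fit must be assessed against that exact
discrete null — `permutation_null_pvalues` computes it from a single
transformed gene — rather than against a flat uniform on [0, 1], which
would be rejected spuriously at scale.

## BVSR

Model: y = X_γ β_γ + e with e ~ N(0, σ²I), β_γ|σ² ~ N(0, σ²τI). σ² carries
a Jeffreys prior and β is integrated analytically, so the chain runs over
the inclusion vector γ alone (add/remove/swap Metropolis-Hastings with
boundary-adjusted proposal probabilities) plus an optional random-walk
update of log τ (log-uniform hyperprior on [0.01, 100]). The model-size
prior integrates a log-uniform hyperprior on the inclusion probability over
[1/p, 1) — standard BVSR practice. With ≤ ~80 covariates each
marginal-likelihood evaluation is a small Cholesky, so mixing is fast.

PIP = fraction of posterior samples including the covariate; coefficient
estimates are Rao-Blackwellized conditional means; PVE samples are drawn as
var(X_γ β_draw)/(var + σ²_draw) per iteration. Defaults are 10,000 burn-in
and 100,000 sampling iterations; the test suite and acceptance script run
1,000/10,000, which this problem size mixes comfortably within (the
split-chain PIP heuristic warns above a 0.1 disagreement). A chance null
covariate with sample |z| ≈ 3 legitimately earns a moderate PIP; null
calibration is therefore a statement about the ensemble, not each draw.

## Cross-validated R²

Folds are stratified by response decile; per replicate, R² is pooled as
1 − ΣSSE/ΣSST across the 10 test folds (SST about each fold's own mean) —
pooling stabilizes small-fold variance relative to averaging fold-wise
R² — and the mean/SD are taken across the 20 split replicates. Feature
sets: 5 marginal levels; +26 interaction products of the (already
sqrt-transformed) levels; or +state-restricted levels (`state:mark`
columns), which reduce exactly to the marginals when one state covers
everything.

## Maximal R²

The corrected ratio is implemented exactly as displayed (symmetric solve
with a positive-definiteness check at tolerance 1e-10 on the smallest
eigenvalue; explicit errors name the violated condition when noise
estimates are too large for the data). The replicate noise estimator
divides by N²G, which makes it a (N−1)/N-scaled estimate of the noise
variance of the per-individual measurement — i.e. it under-corrects the
variance of the N-individual *mean* by a factor (N−1)/N, a bias of order
τ²/N² that is negligible at N = 8 relative to the signal. The estimator
needs only the *average* noise variance across genes, so mildly
heteroscedastic noise (as produced by the sqrt transform) is tolerated.
The returned value is never clipped; the pipeline's reporting layer adds a
[0, 1]-clipped column.

## Bayesian network

The BGe score uses the reference prior with ν = sample mean, α_μ = 1,
α_w = d + 2, T = t·I, t = α_μ(α_w − d − 1)/(α_μ + 1); a Gaussian-BIC score
is available as an alternative. The edge prior contributes
log(p/(1−p)) per edge (default p = 0.01). Hill climbing is single-start
greedy by default with lexicographic (move type, source, target)
tie-breaking, making runs deterministic. Greedy search can mis-orient a
collider and stall in a local optimum; `restarts > 0` alternates seeded
perturbations of the incumbent with fresh random-DAG starts and keeps the
best score — with 32 restarts the search matches exhaustive enumeration on
hundreds of random 3-node datasets. The RNA blacklist (no RNA→mark edges)
is enforced at every move, including perturbation and random starts.

## Problem sizes

The test suite and acceptance script use: G = 2,000 for permutation-null
calibration (full 12,870-assignment enumeration), G = 20,000 for CV-R²
recovery, G = 50,000 × N = 8 for maximal-R² recovery, n = 2,000 × 10
covariates for BVSR, 200 random 3-node datasets for the structure-search
oracle, and G = 150–400 cohorts for end-to-end pipeline runs. These sizes
give sampling error comfortably inside the assertion tolerances while
keeping a full run to a few minutes on one CPU.
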