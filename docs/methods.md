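# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `ewaskit`.

## The adjusted association scan

Each probe is fit by OLS on the beta scale.  The "GLM" of array EWAS
practice is linear in beta, and beta-scale estimation keeps coefficients
directly interpretable as case-minus-control methylation differences; an
M-value analysis can be run by passing logit-transformed values, but beta
is the default.  Two-sided p-values use the t distribution with residual
degrees of freedom, not the normal, which matters at the modest sample
sizes (~100–800) the pipeline targets.

Confounding control is two-staged:

1. **Control-probe PCs.**  PCA of log(intensity + 1) control-probe rows,
   per-probe centered.  Control probes measure assay steps, not biology,
   so their leading PCs span batch and technical variation.  Default: 30
   PCs (`n_control_pcs`), configurable down to 0.
2. **Residual PCs.**  Beta is first regressed on the nuisance covariates
   (age, smoking, alcohol score, adherence, log10 viral load, WBC, six
   cell fractions) plus the control PCs, *without* the phenotype term;
   PCA of the residual matrix yields scores capturing residual global
   structure (unmeasured biology, e.g. a hidden exposure).  Default: 5
   PCs (`n_residual_pcs`), 0 skips the stage.

PC signs are fixed by making each component's largest-magnitude loading
positive, so results are identical across platforms and runs.  Aliased
design columns are dropped (first-come-first-kept QR-style scan) with a
warning naming them; samples missing any model term are dropped listwise
with a logged count.  The significance threshold for a discovery scan
defaults to p < 5e-7 with BH FDR reported alongside; replication scans
conventionally use nominal 0.05.  Both are config constants.

### Residual PCs and widespread true signal

Residual PCA cannot distinguish a disease factor from a technical one: if
case/control effects are spread over enough probes, the leading residual
PC aligns with the group contrast and absorbs part of the effect.  The
strength of that factor scales with (number of affected probes) ×
(Δbeta)² × n, while the PCA noise bulk it must exceed grows with the
probe/sample ratio.  At genome scale (hundreds of thousands of probes, a
handful of associated CpGs) the factor is far below the bulk and the
adjustment is safe; in a desk-scale simulation with thousands of probes
and dozens of strongly spiked CpGs it is not, and coefficients shrink
markedly.  The package's standard study conditions therefore spike few
probes (≈0.05% of a 20k-probe scan) at effect sizes in the realistic
1–6% range, where residual shrinkage stays within ~15%.  This is a
documented property of the method, not a defect of the implementation:
analysts applying CPACOR-style adjustment to small custom panels should
expect the same behavior on real data.

## Synthetic cohorts

`generate_cohort` builds beta as the inverse logit of a sum of effects:

* **Baseline**: per-probe logit drawn from a three-component mixture
  (means −2.2 / 0 / +2.2, SD 0.4; weights 0.35/0.30/0.35), reproducing
  the bimodal beta distribution of real arrays.  10% of probes get
  per-cell-type logit offsets (SD 0.5) so cell composition is a genuine
  global confounder; reference marker probes use the purified profiles
  directly.
* **Cell mixture**: per-sample fractions from a Dirichlet with mean
  (CD4T .03, CD8T .18, NK .07, B .09, Mono .12, Gran .51) and
  concentration 14, giving a granulocyte SD ≈ 0.13 — typical of
  estimated whole-blood compositions.
* **Covariate effects**: age (standardized) and smoking load on 20% of
  probes (loadings N(0, 0.05) and N(0, 0.08) on the logit scale).  Cases
  are older and smoke/drink more, so these are real confounders the
  model must absorb.
* **Batch**: a per-sample factor b ~ N(shift·case, batch_sd²) with
  per-probe loadings N(0, 0.15); the same factor multiplies control-probe
  intensities (base·exp(0.3 b)), so control-probe PCA can recover it.
  `batch_group_shift > 0` turns batch into a group confounder for the
  rescue experiments.
* **Noise**: i.i.d. N(0, 0.15) on the logit scale — heteroscedastic on
  the beta scale (SD ≈ 0.037 mid-range, smaller near the bounds), as in
  real data.
* **Group effect**: Δbeta added on the beta scale for cases at spiked
  probes and at all probes of spiked genes, then clipped to (1e-4,
  1−1e-4).  Spiked probes are given mid-range baselines so the additive
  shift is not distorted by the bounds.  Region truth is recorded per
  contiguous run (a gene label may recur on distant runs).
* **Frailty index**: the burden score is the Δ-weighted sum of realized
  beta over spiked probes; the index is round(32 + 16·(r·z_burden +
  √(1−r²)·ε)) clipped to [0, 120].  A clipped normal was chosen over a
  skewed transform because a monotone nonlinearity would attenuate the
  Pearson coupling below the requested `score_index_r`.  With the
  default cuts, ~13% of samples are high-frailty (> 50) and ~16%
  low-frailty (< 16).

Total intensities (for detection-p/call-rate QC) are N(5000, 800) with a
0.1% failure rate dropping to background N(500, 100); negative-control
probes sit at the background level, giving the pipeline its detection
reference.  All randomness flows through one
`numpy.random.default_rng(seed)`; a fixed seed reproduces the study
bit for bit.

What the generator does **not** emulate: probe-type chemistry (design
type is a flag only), spatial/array-position artifacts, SNP-driven
trimodality, correlated probe noise within CpG islands, real
VACS-index component structure, and platform differences between
cohorts beyond probe-set overlap.  Passing tests therefore demonstrate
correctness of the statistical machinery under the stated generative
model, not performance on any real cohort.

## QC

Filter precedence is control → sex-chromosome → SNP-proximal → detection
failure, so each probe has exactly one removal reason and the report
reconciles to the input count exactly.  Sample call rate is the fraction
of probes detected at p < 1e-12; samples strictly below 98% are removed
(a sample at exactly the threshold is retained).  Detection p is the
upper-tail normal probability of a probe's intensity under a background
estimated per sample from a caller-designated probe set; the pipeline
uses negative-control probes, and any set (e.g. Y-chromosome probes in an
all-male cohort, a convention some pipelines use) can be passed instead —
the mechanism behind that convention is ambiguous, so neither mode is
asserted as canonical.  Sex is called from mean Y-probe beta by a 1-D
two-means split, with absolute thresholds (male if in [0.2, 0.8]) for
one-cluster cohorts; mismatches against self-report are flagged, never
auto-dropped.  Quantile normalization maps each sample's sorted values to
the across-sample mean of order statistics within probe strata (default
single stratum; design-type strata supported), ties by average rank.

Deconvolution defaults to `w ≥ 0, Σw ≤ 1` (reported whole-blood fractions
need not sum to 1); `sum_to_one=True` imposes the equality.  NNLS solves
the unconstrained-sum case; SLSQP refines when the sum constraint binds.

## DMR calling

Defaults: max_gap 500 bp, window 3, cutoff at the 0.99 quantile of
|smoothed coefficient|, min 3 probes, 100 permutations — all exposed as
config.  Coefficients fed to smoothing come from the *adjusted* final
model, so regions inherit covariate adjustment.  The cutoff is computed
once from the observed smoothed values and held fixed during label
permutations (the original bump-hunting scheme); null candidate areas are
pooled across permutations and clusters, because per-region nulls at
B=100 would have resolution no finer than ~0.01 anyway.  Region p =
(1 + #{null area ≥ observed}) / (1 + pool size); an empty pool floors p
at 1/(B+1) with a warning.  BED output converts the 1-based inclusive
records to 0-based half-open at the writer boundary only.

## Meta-analysis

Fixed-effect only; random-effects pooling is deliberately out of scope.
Inverse-variance is the default scheme (it produces pooled coefficients
and SEs); sample-size-weighted z pooling is provided for cross-check.
Probes present in a single cohort are passed through flagged `unpooled`
rather than silently mixed — different array generations overlap on only
part of their probe sets, and `probe_overlap` reports the asymmetry.
I² = max(0, 100·(Q − (k−1))/Q).

## Panel, score and frailty prediction

Panel selection keeps probes at p < 1e-3 with EWAS coefficients as
weights; per gene, the smallest-p probe is the representative.  The
residualization recipe is fitted on training samples only and re-applied
verbatim to held-out samples (stored design columns and coefficients; no
re-aliasing at transform time), so a held-out sample identical to a
training sample gets the identical residual.  The cumulative score is the
weighted mean over panel probes of residual methylation by default; raw
beta is supported, matching both conventions seen in practice.  Because
residualization removes covariate components that the generator's burden
retains, the score–index correlation is mildly attenuated relative to the
generator coupling; the generator contract (burden vs index within the
Fisher-z band of the target r) and the pipeline property (score–index
correlation strongly positive) are asserted separately.

The classifier is a linear SVM with inverse-frequency class weights
(positive classes are ~13–20% of samples; an unweighted margin
concentrates on the majority class and discards most of the attainable
AUC), hyperparameter C chosen by stratified 10-fold CV over
{0.01, 0.1, 1, 10} on ROC AUC; an RBF kernel with a gamma grid is
available by flag.  Training uses the binary tasks directly (high vs
rest, low vs rest); the five index bands (≤16, 16–24, 24–34, 34–50, >50,
boundaries assigned to the lower band by convention — only the binary
cuts are asserted) are retained for stratification.  AUC CIs are
stratified bootstrap (default 2000 replicates), resampling positives and
negatives separately.  The random-panel null draws panels of the observed
size without replacement and runs the full residualize → train → test
pass per panel with a fixed-C linear SVM, applied identically to the
observed panel, so the permutation p isolates the probe choice; p =
(1 + #{null AUC ≥ observed}) / (B + 1).

## Pipeline

`run-all` executes simulate → qc → ewas → dmr → meta → panel → predict
from one YAML config (flags override; `show-config` prints the merged
result).  Each stage records a parameter/input hash and the SHA-256 of
its outputs in `run_manifest.json`; re-running with an unchanged config
skips completed stages, and two fresh runs of the same config are
byte-identical (floats written with a fixed format, JSON keys sorted, no
timestamps in hashed outputs).  Exit codes: 0 success, 2 validation
error, 3 stage failure, with the failing stage named.

## Problem sizes and runtime choices

The bundled demo config simulates three cohorts (discovery 60+60,
replication 40+80, test 40+80) over 3k autosomal probes; the acceptance
script uses 5k-probe scans for calibration experiments, a 20k-probe scan
for effect-recovery and frailty experiments (sized so the residual-PCA
noise bulk dominates sparse spikes, per the scaling argument above), 10
DMR seeds at B=100 permutations, and B=200 random panels for the
prediction null.  These sizes were chosen to keep a complete desk run in
minutes while preserving the statistical regimes of an array-scale study.

## Known limitations

* Fixed-effect meta-analysis only; no mixed models or robust SEs in the
  scan; no surrogate-variable alternatives (SVA/RUV) to the PC bases.
* The detection-p background model is a per-sample normal; arrays with
  heavy-tailed backgrounds would need a rank-based variant.
* The bump hunter uses a running-mean smoother, not loess with genomic
  weights, and a pooled permutation null, not per-region bootstrap.
* Classifier choices beyond the linear/RBF SVM, and feature selection
  beyond the p-threshold rule, are out of scope.
* The generator's cell-reference panel is idealized (0.85/0.15
  contrasts); real reference libraries have weaker, correlated markers,
  so real-data deconvolution error will exceed the synthetic RMSE.
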