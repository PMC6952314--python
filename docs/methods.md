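# Methods

This note documents the models implemented in `hrmwas`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Censored lognormal regression (`censored_regression`)

**Model.** For one feature with intensity *T* over samples,

log *T*ᵢ = μ + β₁·dxᵢ + β₂·sexᵢ + β₃·ageᵢ (+ medication indicators) + σεᵢ,

with ε standard normal — an accelerated failure time model with lognormal
errors. A detected sample contributes the normal density of its log
intensity; a non-detected sample contributes Φ((log LOD − x'β)/σ), where
the LOD is that feature's lowest detected intensity (one common value per
feature). β₁ is interpreted as the change in log mean intensity for cases
versus controls. Natural logs throughout.

**Estimation.** The likelihood is maximized over (β, log σ) by BFGS from
an OLS start (censored rows imputed at the LOD for initialization only),
with analytic gradients and a gradient-norm target of 1e-8. Non-intercept
design columns are centered and scaled internally purely for conditioning
(age in years next to an intercept makes the Hessian badly scaled); the
optimum is mapped back exactly, so reported coefficients are on the raw
scale. Standard errors come from the observed information (central-
difference Hessian of the analytic gradient) propagated through the same
back-transformation; p-values are two-sided normal (the usual AFT
convention — a t reference would be an alternative; the choice is
documented here rather than inferred). A fit is flagged non-convergent if
the gradient inf-norm at the optimum exceeds 1e-5; a stalled line search
triggers one derivative-free polish plus a re-climb before flagging.
Rank-deficient designs and all-censored groups fail loudly; constant
medication indicators are dropped with a warning.

With zero censoring the MLE reduces to OLS with σ̂² = RSS/n; this and a
brute-force likelihood maximization on tiny instances serve as oracles in
the tests, with an independent AFT implementation (lifelines) as a
cross-check.

## Meta-analysis and selection (`meta_mwas`)

Fixed effects with inverse-variance weights: estimate Σwᵢeᵢ/Σwᵢ, SE
(Σwᵢ)^(−1/2), wᵢ = 1/SEᵢ². FDR is Benjamini-Hochberg (the procedure is
named in every run manifest because "FDR" alone underdetermines it),
computed over exactly the features common to both studies — the analysis
set is the matched intersection, not the union. Selection: meta-FDR <
0.20 AND per-study p < 0.10 in every study AND sign concordance (a zero
estimate fails concordance). Both thresholds are configurable (a relaxed
p < 0.20 variant is supported the same way). Cochran's Q and I² are
reported but play no role in selection.

**Medication sensitivity.** The attenuation criterion is operationalized
as: exclude when in at least one study |β₁| shrinks by ≥ 20% after adding
the three medication-detection indicators, or the sign flips; the
fraction is a parameter and appears in every report. A non-convergent
adjusted fit yields "indeterminate", never an automatic exclusion. Note
this rule is deliberately conservative: because only cases take the
medications, the indicators correlate strongly with diagnosis and the
adjusted coefficient is noisier, so chance attenuation past 20% occurs at
small n (visible in `examples/06_full_pipeline.py`).

## Matching (`matching`)

ppm difference uses the symmetric denominator (mean of the two masses);
candidates must satisfy both |ppm| ≤ 5 and |Δrt| ≤ 30 s; among a
feature's candidates the closest retention time wins. To make the map
well-defined and one-to-one, all candidate pairs are resolved greedily in
order of |Δrt|, then |ppm|, then ids (the per-feature closest-RT rule
alone does not define a global matching; mutual-best was the alternative
and the greedy choice is recorded in run metadata). The production
matcher works on m/z-sorted arrays with window search; an exhaustive
brute-force implementation with identical rules is kept as the testing
oracle.

## Annotation (`annotation`, `chem`)

Monoisotopic element masses are hard-coded at 6 dp with the proton
(1.007276 Da) and electron (0.000549 Da) masses; every adduct offset is
computed from these constants, so identities like (protonation) −
(water-loss protonation) = mass(H₂O) hold exactly. The adduct set is
[M+H]⁺, [M+Na]⁺, [M+K]⁺, [M+H−H₂O]⁺, [M+H−2H₂O]⁺, [M+ACN+H]⁺,
[M+ACN+Na]⁺, [M+2Na−H]⁺; fragments are limited to the water losses — no
bond-level fragmentation and no halogen isotope-pattern scoring (those
require MS² or isotope-envelope data the feature table does not carry).

Pseudospectra are connected components of the graph whose edges join
features with |Δrt| ≤ 5 s and Pearson correlation ≥ 0.7 of log₂
intensities over co-detected samples, requiring ≥ 10 shared detections
per edge to bound spurious correlation. The original study's thresholds
for its clustering application are not published; these defaults are
explicit parameters, not claims about that tool.

**Role assignment.** Every member × ion-hypothesis pair implies a
candidate neutral mass; the candidate explaining the most members wins.
Two refinements make the winner well-defined and chemically sensible:
(1) a ¹³C label is only credible when its monoisotopic partner ion is in
the cluster (a cluster cannot consist solely of isotope peaks); (2) score
ties are broken by adduct simplicity — position in the configured adduct
set — before the final lower-neutral-mass tie-break. Without these, the
hypothesis table is degenerate under translation (the ACN pair reproduces
the H/Na mass difference, and a global ¹³C shift reproduces every
difference), and a pure lowest-mass rule would systematically pick the
translated interpretation.

Compound lookup inverts each adduct hypothesis and returns compounds
within 5 ppm of the implied neutral mass, sorted by |ppm error|; when a
role was predicted, only that adduct is searched. The packaged table of
~60 common plasma metabolites (plus the three AD medications) stands in
for a full metabolite database and is validated against its formulas at
load; any user CSV of (name, formula) pairs can be substituted.

## Batch correction (`feature_table.correct_batches`)

Parametric empirical-Bayes location/scale adjustment of detected log₂
intensities: per-feature batch means/variances are standardized against
the pooled feature mean and residual variance, shrunk across features
toward normal/inverse-gamma priors (moment-matched, solved by the usual
fixed-point iteration), and the standardized data are adjusted and mapped
back. Non-detects carry no value and are untouched; batch parameters are
estimated from detected values only, avoiding the imputation the modeling
approach is designed to avoid. Whether to correct on the log or raw scale
is not externally specified; log₂ was chosen and is documented here. The
per-feature LOD after correction is recomputed as the minimum detected
value of the corrected table, keeping the LOD definition and the
"detected ≥ LOD" invariant self-consistent. A single batch is returned
unchanged; batches with < 2 samples, or with no detections at all, fail
loudly. EB shrinkage leaves a small per-feature residual batch difference
of order (shrinkage × batch-mean sampling error); with realistic feature
variances this is well under 5% of an injected shift.

## Correlations (`correlations`)

Partial Spearman: midranks for x, y and continuous covariates (binary
covariates enter as 0/1 unranked), rank vectors regressed on the
covariate design, Pearson correlation of residuals; with no covariates
this is exactly classical Spearman. If the covariates explain a variable
completely the partial correlation is reported as 0. Study results are
combined on the Fisher-z scale with weights n − k − 3 (k covariates; the
n − 3 variant would differ negligibly at these n; the choice is recorded
in output metadata). Non-detects are excluded pairwise and every estimate
reports its n; censoring-aware correlation is out of scope. Plasma-CSF
correlation is unadjusted Spearman over samples detected in both fluids,
flagged (no estimate) below 4 shared detections.

## Synthetic data (`synthetic_data`)

The generator emulates the structure the pipeline assumes: two studies
with 45 samples per diagnosis group (study 1 also gets an MCI group),
log-intensities μ_f + β₁dx + β₂sex + β₃age + batch shift + batch scale ×
noise, per-feature censoring, ~42% of features shared between studies
(with ≤ 2 ppm mass and ≤ 10 s retention-time jitter between studies;
study-specific features sit on a 0.1 Da grid so they are far beyond 5 ppm
from the other study), planted adduct clusters driven by one latent
abundance per metabolite, and optional medication features detected only
in cases. Censoring draws complete intensities and masks values below the
closed-form normal quantile of each feature's marginal distribution that
targets the configured non-detect fraction; the LOD is then *recomputed*
as the minimum detected value, mirroring the analysis-side LOD rule
rather than leaking the generator's threshold. CSF biomarkers are drawn
from diagnosis-specific normal distributions calibrated to the cohort
descriptives (e.g. Aβ42 340 ± 137 in controls vs 203 ± 76 in AD) and
respect the enrollment rule (t-Tau/Aβ42 ≥ 0.39 for AD, < 0.39 for
controls); ages are uniform 55-85 y and sex Bernoulli(0.5) — realistic
ranges without claiming the cohorts' exact distributions.

Defaults: effect size 0.3 on the natural-log scale (the magnitude of the
replicated per-study coefficients), residual σ 0.5 (implied by per-study
SEs ≈ 0.11 at n ≈ 84), 4 batches per study (batches of ~20 injections),
batch shift SD 0.3 / scale SD 0.1 and a 10% censoring target — the last
three are not published quantities and are configurable parameters, not
calibrated claims. The default feature count (500) is a deliberate
scale-down of the original thousands of features: the statistical
behavior per feature is unchanged and every stage still has real work.

Not emulated: chromatographic peak shapes, mass-accuracy drift over time,
replicate injections (tables are one column per sample; a median
summarization helper exists but is off by default), missingness that is
not LOD-driven, and correlated metabolite networks beyond the planted
adduct clusters. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated generative model, not robustness
to every failure mode of real LC-MS data.

Reproducibility: one global seed; per-study and per-component generators
are spawned deterministically from it, so identical (config, seed) gives
byte-identical tables. Batch-shift draws are shared by all features in a
batch, so the *realized* censoring fraction of a single run can sit a few
points from the target even though the average over seeds is unbiased.

## Pipeline (`pipeline`, `cli`)

Stage order: simulate/load → medication-ion detection on the unfiltered
tables → RT filter (drop rt < 30 s, strict) → presence filter (keep
detection fraction strictly > 80% of that study's samples) → batch
correction → per-study MWAS → cross-study matching → meta-analysis over
the common set → FDR + replication rule → medication sensitivity →
annotation → biomarker correlations. Every threshold is a config field
(YAML) and CLI flag; outputs are TSVs plus a JSON manifest with versions,
thresholds, seed and per-stage feature counts; runs are deterministic
given the seed. The pipeline aborts with a stage-named error if more than
5% of fits fail to converge (configurable). Exit codes: 0 ok, 2 config
error, 3 data validation error, 4 excess non-convergence. The test and
acceptance suites run the heavy simulations at 500-1000 features and
90 samples per group, which keeps full-suite runtime around a minute on
one core; these sizes are stated here as the package's own choice of
problem scale.
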