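# Methods

`grsanhedonia` re-implements, as a tested library, the analysis chain
linking a depression genetic risk score (GRS) to anhedonia-related
phenotypes across units of analysis — self-report, behavior, and brain
circuits — together with a calibrated synthetic-cohort generator that
stands in for the access-controlled study data.

## Genetic risk scoring

The GRS for individual *i* is the weighted risk-allele sum
`GRS_i = Σ_j w_j d_ij`, where `d_ij ∈ [0, 2]` counts copies of SNV *j*'s
effect allele and `w_j` is the GWAS effect size.  Scoring is preceded by:

* **QC** — SNVs removed when missingness > 5% or imputation INFO ≤ 0.8
  (retention requires INFO strictly above 0.8), then individuals removed
  when their missingness over retained SNVs > 2%.  SNV-level filtering
  runs before individual-level filtering; the order is fixed for
  reproducibility.  On the default 22-SNV synthetic panel 14 SNVs
  survive, emulating the study panel.
* **Allele harmonization** — dosages counting the record's other allele
  are complemented (`d → 2 − d`); unambiguous pairs may match via strand
  complement; strand-ambiguous pairs (A/T, C/G) are flagged and resolved
  by direct allele match only.
* **Weight transform** — `identity` (default) uses the linear-regression
  beta as the weight.  A `log` mode (natural log, for odds-ratio-scale
  inputs) is provided but deliberately errors on non-positive values:
  applying a logarithm to signed linear betas would silently fabricate
  weights.
* **Missing dosages** — mean-imputed as twice the observed effect-allele
  frequency (the default of standard scoring tools); a `skip` policy is
  available for sensitivity analysis.  Both agree exactly on complete
  data.  The score is reported as a sum, with a per-SNV average column
  alongside.

Ancestry is summarized by PCs of the standardized dosage matrix
(centered at `2p̂`, scaled by `sqrt(2p̂(1−p̂))`, monomorphic SNVs
dropped), sign-fixed by making each component's largest-magnitude SNV
loading positive and standardized to unit variance.  By default PCs come
from the scored panel itself; 14 SNVs are a weak ancestry proxy, so
`ancestry_pcs` also accepts any external genotype panel — the synthetic
cohort's two-population structure is recovered (|r| > 0.9 with the true
labels) when a few hundred SNVs are supplied.

## PRT response bias

The probabilistic reward task presents 80-trial blocks with 40 "rich"
and 40 "lean" stimuli; correct rich responses are rewarded three times
as often (24 vs 8 per block, 32 total).  Reward learning is quantified
by the signal-detection response bias

    log b = 0.5 · log10[ (RC + 0.5)(LI + 0.5) / (RI + 0.5)(LC + 0.5) ],

with 0.5 added to every cell so the statistic is finite for empty cells
(the convention of the task's originating literature; the log base is
configurable).  The behavioral outcome is the stress-induced double
difference `(B2 − B1)_post − (B2 − B1)_pre`; subjects missing any of the
four session-blocks are dropped from the behavioral unit only.  No
behavioral outlier rule is applied by default.

## Q-learning / softmax model

Each stimulus pair (gain, loss, neutral) carries values `Qa`, `Qb`
initialized at 0 per stress condition.  The chosen value updates as
`Q ← Q + α(R − Q)` with `R ∈ {+1, −1, 0}` for win, loss and neutral
outcomes; choices follow `P(A) = exp(Qa/β) / (exp(Qa/β) + exp(Qb/β))`
with β a divisor temperature (packages using an inverse-temperature
multiplier correspond to `1/β`).  Published group parameters
(α 0.28 gain / 0.46 loss; β 2.24 / 5.23) drive RPE-regressor generation,
per the population-parameter convention for fMRI modeling.  Whether Q
resets between runs within a condition is configurable; the default
resets per condition only.

Maximum-likelihood fitting is per subject and valence: a 100-point α
grid × 31-point log-spaced β grid locates the basin (ties broken toward
smaller α, then smaller β), then Nelder–Mead refines.  The search box is
α ∈ [0.01, 1], β ∈ [0.1, 10], bracketing the published values by at
least 2× on each side.  Estimates pinned at the box edge are flagged
`at_bound`, not raised: a near-random sequence legitimately drives β to
the bound.  Group summaries (mean/median) are taken over interior fits,
since boundary fits mark degenerate likelihoods; all-fit summaries and a
pooled fixed-effects fit (one (α, β) maximizing the summed likelihood
across subjects) are reported alongside.

**Identifiability caveat.**  At the published temperatures the softmax
probabilities stay close to chance (loss pairs never leave
[0.45, 0.55]), so a single subject's 72–144 trials carry little
information.  The recovery studies in `grsanhedonia.calibration`
quantify this: with 144 trials/subject the mean of per-subject α
estimates carries an upward small-sample bias of ≈ +0.05–0.08 for gain
pairs, and the median per-subject loss-pair β estimate sits near 2.5–3
regardless of the generating 5.23.  The pooled fixed-effects estimator
is approximately unbiased for both valences (it recovers β_loss ≈ 5 from
200 × 144 trials), which is the recommended group-level estimate when
the scientific question is the population parameter.  Recovery bias
shrinks with trials per subject, as the test suite checks at 48 vs 144.

## Hierarchical association

Predictor blocks enter ordinary least squares in sequence (ancestry PCs
first, GRS last; the incremental-validity variant inserts SHAPS and the
behavioral change score between them).  Each step reports the
incremental variance ΔR² and the F-change test
`ΔF = (ΔR²/q) / ((1 − R²_full)/df2)`, `df2 = n − p_cum − 1`, with the
upper-tail central-F p-value.  Rows are deleted listwise per outcome
(never imputed), so each measure has its own N.  Volumes are
head-size-corrected before fitting — by default the residual of volume
on intracranial volume plus the sample mean (ratio adjustment is
available but distorts when the volume–ICV slope is not proportional).
Outcome values with |z| > 3 can be flagged as outliers (on by default,
logged per row, configurable) since the study excluded one activation
outlier without stating its criterion.  Bonferroni control is applied
per circuit pair (0.05/2 = 0.025).

Because the sample ΔR² of a single added predictor is inflated by
roughly `(1 − R²)/df2`, a bias-adjusted increment is reported: the
difference of Olkin–Pratt shrinkage estimates
`1 − ((n−3)/(n−p−1))(1−R²)·₂F₁(1, 1; (n−p+1)/2; 1−R²)` of the full- and
reduced-model population R² (an Ezekiel adjusted-R² difference is also
available).  Over ≥ 2000 replicate cohorts of n = 73 this estimator's
mean is within ±0.01 of the generating increment.

## Synthetic cohort

The generator supplies every input under one seed, with ground truth in
a sidecar the analysis never reads.

* **Genotypes** — Balding–Nichols-style structure: each SNV has an
  ancestral frequency; per-population frequencies are drawn from
  `Beta(p(1−F)/F, (1−p)(1−F)/F)` with divergence F (default 0.05, two
  populations), and dosages are Binomial(2, p), so Hardy–Weinberg holds
  within population.  This is the simplest structure that makes genotype
  PCs meaningful.  QC-flagged SNVs (8 of 22) carry sub-threshold INFO,
  every second one also ~10% missingness, so both removal rules are
  exercised; passing SNVs are complete by default, emulating
  post-imputation dosage data (and keeping every individual under the 2%
  rule — with a 14-SNV panel a single missing call would otherwise
  exceed it).  A third of SNVs are stored counting the other allele to
  exercise harmonization.
* **Phenotypes** — for each measure with target increment `r2_u`, the
  phenotype is `s·sqrt(r2_u)·z + c·(PC1 + PC2) + e`, where `z` is the
  in-sample standardized residual of the GRS on the PCs, `s = −1` (the
  published direction: higher risk, smaller volumes / larger RPE
  reduction), the PC terms carry 0.10 of the unit total variance, and
  the noise makes total variance 1.  Because `z ⊥ PCs` by construction
  the population incremental R² beyond the PCs equals `r2_u` exactly.
  Default targets are the published per-measure values (0.017, 0.035,
  0.065, 0.074, 0.064, 0.095; the 0.064/0.095 pair follows the printed
  table, whose structural-unit average 7.95% confirms it over the
  conflicting 0.095/0.095 in the running text).  Volumes are emitted in
  mm³ (bilateral NAc 1300 ± 130, putamen 10500 ± 1050) with an ICV
  loading of 0.7 SD for the adjustment stage; per-measure missingness
  reproduces the study's listwise Ns (82, 59, 62, 63, 73, 73 of 83).
* **PRT sessions** — responses come from a static logistic model,
  `P(respond rich) = σ(bias_b + discrim·s)` with `s = ±1` for rich/lean;
  the reward controller is quota-based (reward positions drawn without
  replacement among correct responses) because the task fixes reward
  counts per block rather than reward probabilities.  If a block lacks
  enough correct responses for its quota, all available are rewarded and
  the shortfall logged.
* **RL choices** — simulated directly from the Q-learning model at the
  published parameters (6 runs × 36 trials; 12 per pair type).

What the generator does **not** emulate: linkage disequilibrium between
panel SNVs (treated as independent, as the published panel effectively
is after clumping), voxelwise BOLD data (ROI-level phenotypes are
generated directly), task learning dynamics inside the PRT response
model, and any coupling between the trial-level task simulations and the
calibrated phenotype columns beyond a monotone link in the pipeline's
PRT stage.  Passing tests therefore demonstrate the statistical
machinery and its calibration, not the psychometrics of real task data.

## Pipeline

`run_pipeline` executes simulate → QC/score/PCA → phenotypes → PRT → RL
→ associate from one flat YAML config.  One master seed is fanned out
per stage via `SeedSequence.spawn`; every output file's SHA-256 digest
is recorded in a manifest, and identical config + seed reproduces
identical digests.  The association table is computed on the calibrated
phenotype columns; the PRT and RL stages write their own per-subject
outputs (response-bias table, RPE regressors, fitted parameters) as
parallel products — trial-level simulation cannot hit an exact
population ΔR² target, so the calibrated columns are the ones carrying
the designed effect sizes.

## Numerical choices and degenerate inputs

Softmax probabilities are computed in overflow-safe log-sigmoid form.
OLS uses `numpy.linalg.lstsq` with an explicit rank check (rank
deficiency raises, naming the offending block); zero residual variance
reports ΔF = ∞ with p = 0 and a warning rather than dividing by zero.
PCA sign and grid tie-breaks are deterministic, so every fit is
reproducible bit-for-bit given the data.  Adjusted-R² estimates are not
clipped at zero: small negative values are informative about null
increments.

## Problem sizes

Default simulation scales — 100–200 subjects × 144 trials/valence for RL
recovery, 2000 replicate cohorts of n = 73 for incremental-R² recovery,
1000 null cohorts for p-uniformity — were chosen so Monte-Carlo error is
comfortably below the effect sizes being checked while a full run of the
suite and the recovery scripts completes in a few minutes on one core.
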