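# Methods

This note documents the statistical models, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and the
design decisions taken where more than one defensible convention exists.

## Study design assumed by the pipeline

The pipeline targets repeated-measures around-the-clock designs: `P`
participants, each sampled in `S` multi-day sessions at `K` clock times
spanning 24 h (defaults: 20 participants, sessions BDC1, BDC2, HDT1,
HDT2, HDT3, R; clock times 15:00, 19:00, 23:00, 03:00, 07:00, 11:00 at
4-h spacing). Samples that wrap past midnight are unwrapped so consecutive
draws keep their true spacing. All rhythm models run on times expressed
relative to each participant's melatonin offset, the internal circadian
phase reference.

## Melatonin offset

Salivary melatonin is sampled hourly 07:00–23:00. The threshold is the
mean + 2·SD of three designated baseline samples; the offset is the
linearly interpolated clock time of the first downward threshold crossing
after the profile's morning maximum. Two conventions are supported for
the baseline designation. The default uses the midday plateau
(12:00–14:00): with a profile that starts at 07:00, the first samples sit
on the morning *decline*, so using them as "baseline" would place the
threshold above the entire profile and make every offset undetectable;
the midday samples are the low daytime plateau that the threshold method
assumes. `baseline="first3"` (the first three samples) remains available
for profiles whose recording begins after the decline. A profile is
flagged undetectable when its pre-baseline maximum does not clear the
threshold by at least the assay detection limit (0.85 pg/ml) — without
this margin, noise wiggles in a flat profile could masquerade as a
crossing — or when no downward crossing exists. Offsets may be used per
participant × session (default) or averaged per participant.

Participant × session series without a usable offset are dropped from all
aligned analyses, and the drops are logged.

## The mixed-effects cosinor

The 24-h cosinor `y = mes + amp·sin(2π(t − φ)/τ)` is linearized as
`y = mes + β1·x1 + β2·x2` with `x1 = cos(2πt/τ)`, `x2 = sin(2πt/τ)` and
fixed τ = 24 h, and fitted per transcript × session in two variants:

* **slopes** — `y ~ 0 + x1 + x2 + (0 + x1 + x2 | participant)` on data
  z-scored within participant × session (sample SD, n−1; constant series
  become zeros and are flagged). The 2×2 random-slope covariance is
  unstructured.
* **intercept** — `y ~ x1 + x2 + (1 | participant)` on raw data; the
  fixed intercept is the MESOR.

Derived parameters: `amp = √(β1² + β2²)`;
`φ = (τ/2π)·atan2(β1, β2) mod τ`; acrophase `= (τ − φ + τ/4) mod τ`. The
two-argument arctangent is used instead of an arctangent with quadrant
corrections: it agrees on all non-degenerate quadrants, remains defined
on the axes (β2 = 0), and makes the acrophase identically equal to the
argmax of the fitted sinusoid — a property the test suite verifies
against a 1-minute grid search. `(β1, β2) = (0, 0)` yields amplitude 0
with phase and acrophase flagged undefined (NaN).

**Classification.** Per session, BH-FDR is applied separately to the β1
and β2 p-value vectors across transcripts; a transcript is rhythmic when
`min(FDR_β1, FDR_β2) < 0.05`. NA p-values are excluded from the
correction and flagged non-rhythmic. Taking the minimum of two FDRs
inflates the realized false-positive proportion slightly above 0.05; the
acceptance suite measures it under a global null (200 replicates × 2,000
transcripts at the study design) and requires ≤ 0.10 — in practice it
sits near 0.03–0.05 because the random-slope boundary makes the slope
tests mildly conservative.

**Estimation.** All mixed models are fitted by profiled REML. The
likelihood is expressed through per-participant sufficient statistics
(`Z'Z`, `Z'X`, `Z'y`, `X'X`, `X'y`, `y'y`), with the random-effect
covariance parameterized by its log-Cholesky factor relative to the
residual variance and the residual variance profiled out. One evaluation
costs O(participants · q²), so thousands of transcripts sharing one
design are fitted as a single vectorized batch by a lock-step
Nelder–Mead (relative tolerance 1e-9 on the objective, up to 400
iterations, method-of-moments starting values; single-response ANOVA
fits tighten to 1e-13). Log-scale variance parameters are clamped at
e⁻⁸, so a boundary (singular) fit degrades gracefully to the
fixed-effects model; boundary ANOVA fits are flagged and warned as the
documented fixed-effects fallback. The engine reproduces statsmodels
MixedLM estimates to ~1e-5 and lmerTest fixed effects to 1e-15 in the
cross-check tests.

**Inference.** Fixed-effect t-tests use Satterthwaite denominator
degrees of freedom computed numerically: the df of a contrast is
`2·Var(c'β̂)² / (g' W g)` with `g` the finite-difference gradient of the
contrast variance in the variance parameters and `W` twice the inverse
finite-difference Hessian of the REML deviance. Multi-df term F-tests
combine eigen-contrast dfs by the Fai–Cornelius formula, as in lmerTest,
which the tests confirm on unbalanced panels (F, df, p and LS means all
match lmerTest's Type-III table to ~4 decimals). A Wald-normal
alternative is available via `df_method="wald"`.

**Uncertainty.** Bootstrap SEs (default R = 200) resample participants
with replacement (cluster bootstrap, respecting the repeated measures;
row resampling available by flag). Replicates are represented as
group-multiplicity weight vectors over the shared sufficient statistics,
so an ensemble refits in one batch. Linear SEs are the SD of replicate
estimates; the acrophase SE is the circular standard deviation
(√(−2 ln R̄) scaled to hours) of the replicate acrophases. Ensembles with
more than 50% failed replicates are flagged unreliable.

**Conditional R².** `(σ²_fixed + σ²_random) / (σ²_fixed + σ²_random +
σ²_residual)` with σ²_fixed the variance of the fixed-effect predictions
over the observed design points and σ²_random the mean over observations
of `z_i' G z_i` (the random-slopes extension of the
Nakagawa–Schielzeth formulation).

## Session comparisons

Counts of rhythmic transcripts across sessions are compared by a χ²
homogeneity test on the S × 2 table, without continuity correction (a
multi-category homogeneity test). Overlap is reported both as Jaccard
percentages (|A∩B|/|A∪B|) and column-conditional percentages (|A∩B|/|B|),
since figure conventions differ; the always-rhythmic set is the
intersection. Amplitude and conditional-R² distributions of rhythmic
transcripts are compared pairwise by two-sample KS tests with BH
correction over the pairwise family. Acrophase distributions are binned
into 24 half-open one-hour bins in clock time — the session-mean
melatonin offset is added back before binning — and compared pairwise by
χ² with zero-total bins pooled into their right neighbour.

Session effects on participant-level rhythm parameters (fixed effects +
conditional modes): amplitude uses the mixed ANOVA
`amplitude ~ session + (1|participant)`; acrophase uses per-session
circular means with 95% participant-cluster bootstrap percentile
intervals, and two sessions are declared different when their intervals
do not overlap (interval arithmetic on the circle, so a 23.5 h vs 0.5 h
pair is 1 h apart, not 23). This bootstrap interval replaces a Bayesian
projected-normal circular mixed model: the published decision rule —
non-overlap of 95% intervals of the circular means — is preserved while
avoiding an MCMC implementation; the acceptance suite verifies ≥ 90%
empirical coverage of the intervals. Rhythmic peak times are classed
into four half-open clock windows: day 11:00–18:00, evening 18:00–21:00,
night 21:00–07:00, morning 07:00–11:00 (boundaries belong to the later
window).

## Differential expression

Per transcript: `expression ~ session + time + group + leg +
session:time + (1|participant)` on quantile-normalized (not
batch-adjusted) data, with time a categorical factor and sum-coded
effects so the term F-tests are Type-III-style. Main-effect p-values are
BH-corrected across transcripts; the 15 pairwise session contrasts of LS
means are BH-corrected within each transcript. A transcript is called in
a pair when both FDRs are below 0.01; direction is the sign of the
LS-mean difference, which on log2 input is a log2 fold change. LS means
are equal-weight marginal predictions over the factorial grid. Group and
leg are covariates only; their contrasts are not classified.

## PCA and rotated components

The matrix used for components is batch-adjusted (per-transcript
batch-mean alignment to the grand mean — a deliberately simple, exactly
testable stand-in for empirical-Bayes correction, applied only here) and
then zero-centered within participant. PCA is a covariance
decomposition (no variable scaling) with samples as observations;
component signs are fixed by making each component's largest-magnitude
loading positive. The first k = 4 components are varimax-rotated: the
rotation matrix is found on Kaiser row-normalized loadings (the R
`varimax` default) and applied to the raw loadings and to the scores, so
rotated scores are `scores × rotation` and the total variance of the
first k components is preserved exactly. Rotated scores are then passed
through the same mixed ANOVA (`score ~ session + time + session:time +
(1|participant)`) and the slopes-variant cosinor. Eigenvalues are
reported without imposing a retention threshold. Note that scores of a
participant-centered matrix carry almost no between-participant
variance, so their ANOVA fits typically sit at the random-intercept
boundary and reduce to fixed-effects ANOVA — expected, and warned once.

## Preprocessing rules

Samples are retained when median replicate-probe CV < 10%, flagged-probe
fraction < 35% and RIN > 6 (all strict; missing QC rows exclude the
sample with a log entry). Quantile normalization forces every column
onto the mean of the per-column sorted values; ties receive the mean of
the reference quantiles they span. Transcripts flagged in < 20% of the
*retained* samples are kept (the filter counts flags after sample
exclusion).

## The synthetic cohort generator

Per transcript: a Bernoulli(frac_rhythmic = 0.25) rhythmic indicator;
baseline MESOR ~ N(8, 1.5²) log2 units; amplitude ~ lognormal(log 0.4,
0.5) log2 units for rhythmic transcripts (0 otherwise); acrophase from a
von Mises mixture with a night mode (mean 03:00, κ = 3, weight 0.55) and
a day mode (14:00, κ = 3, weight 0.45), reproducing the bimodal
day/night peak structure of diurnal blood transcriptomes. Per session,
(MESOR shift, amplitude scale, phase shift) defaults trace the protocol
qualitatively: amplitudes highest in late baseline (×1.1), an earlier
night peak entering bed rest (−2 h), a deep amplitude trough mid bed
rest (×0.45), partial return (×0.8) and the lowest amplitudes at
recovery (×0.35). Participants carry a random intercept (SD 0.5) and,
for rhythmic transcripts only, jointly Gaussian (β1, β2) slope
deviations (default diag(0.01)) — matching the random-slopes estimator's
assumed structure and keeping a non-rhythmic transcript's marginal
variance exactly `re_intercept_sd² + noise_sd²`. Residual noise is
Gaussian (SD 0.35); samples drop out uniformly at random (rate 0.09,
the study's attrition); melatonin offsets are N(8.0 h, 0.6 h) clipped
into the morning window, with 2% of profiles undetectable. Optional
differential expression plants per-session MESOR offsets of ±`de_effect`
in a random subset of transcripts, with the pattern recorded in the
truth table. A single `numpy` Generator seeded from `seed` drives every
draw, so cohorts are bit-reproducible.

What the generator does *not* emulate: probe-level microarray artifacts
(dye effects, saturation), cell-type composition shifts, non-Gaussian
heavy-tailed noise, informative missingness, period deviations from
24 h, and harmonics beyond the fundamental. Passing tests therefore
demonstrate correctness of the estimators under the design's
correlation structure, not robustness to those real-data features.
Amplitude and acrophase distribution shapes are conventions (lognormal /
von Mises), not inferences from any particular dataset.

## Problem sizes and tolerances in the test suite

The acceptance suite runs at the sizes the checks are stated for: 1,000
random parameter draws for exactness (1e-6), 1,000 slope pairs for the
argmax identity (1/120 h), 200 replicates × 2,000 transcripts for null
calibration, 500 transcripts / 20 participants for recovery, 600
transcripts for the DE error rates with 500 balanced null replicates per
term, 200 simulated sessions for circular-interval coverage, and a
150-transcript pipeline for byte-identical determinism. Unit tests use
smaller draws. The whole suite completes in a few minutes on one CPU;
the single long test is the null-calibration study (~3–4 min).

## Known limitations

* τ is fixed at 24 h; no period estimation or multi-harmonic fits.
* The Satterthwaite machinery is numerical; at variance boundaries the
  df falls back to the residual df (the fixed-effects answer).
* The simplified batch adjustment equalizes batch means only; it does
  not shrink batch-specific variances.
* Circular intervals assume interval half-widths well below τ/2; with
  3 or fewer participants per session they are flagged unreliable.
* The DE call rule classifies only session contrasts; group and leg are
  adjustment covariates.
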