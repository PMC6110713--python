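# Methods

## Choice model and estimation

A lottery pays one of three equiprobable outcomes (JPY). Utility is the
quasi-maximin combination U = α·min + (1−α)·EV with maximin weight
α ∈ [0, 1]; choices between two lotteries follow a logit rule
P(a) = σ(λ·(U(a) − U(b))) with sensitivity λ > 0 in 1/JPY. Because utilities
are kept in raw JPY, λ absorbs the currency scale (λ = 0.02 means a 100 JPY
utility advantage maps to ≈ 0.88 choice probability); rescaling money would
rescale λ inversely.

Per subject and condition, (α, λ) is the maximizer of the Bernoulli
likelihood under box bounds α ∈ [0, 1], λ ∈ [1e−6, 1]. The likelihood is
convex in the reparametrization (λα, λ(1−α)) — it is a logistic regression
on the signed min- and EV-differences — so the landscape in (α, λ) has no
spurious interior optima. Estimation evaluates the negative log-likelihood
on a 5×5 start grid (α equispaced, λ log-spaced), polishes the best three
starts with L-BFGS-B using the analytic gradient, and reports the overall
minimum, which is therefore never above the value at any start point. An
exhaustive grid evaluator (`grid_fit_oracle`) provides an independent check
and agrees with the optimizer to |Δα| ≤ 0.01 on simulated subjects.

Degenerate inputs: trials with identical utilities contribute ln 2
regardless of the choice; perfectly separable data (a deterministic agent)
drive λ to its upper bound, which is capped and flagged (`lam_capped`)
rather than treated as an error, since deterministic agents are legitimate
test inputs. λ is estimated per condition (the simplest reading of
condition-wise fitting); a shared-λ variant would be a one-line change in
the per-subject loop and was not needed for any analysis here.

## Synthetic study generator

No participant data ship with this package; the generator produces data with
the statistical structure the analyses assume, and every pipeline stage is
validated by recovering the generating parameters.

**Choice sets.** 36 pairs of three-outcome lotteries, integer amounts in
[0, 2000] JPY rounded to 10 JPY, rejection-sampled so that no pair is
stochastically dominated (rank-ordered outcomes compared exhaustively), both
minima and both EVs differ, and 75% of pairs place the larger minimum and
the larger EV on opposite options. Such min-vs-EV conflicts are what make α
identifiable; without them every α fits equally well. The finished set must
keep |corr(ΔMin, ΔEV)| < 0.5 (checked at generation) so the two modulators
are separable in the mixed models and the GLM.

**Agents and cohorts.** Subject-level maximin weights are Beta-distributed
(mean 0.45, sd 0.15); the Other-minus-Self contrast is Gaussian (sd 0.15)
and linked to a trait empathic-concern score (7-point scale, mean 3.5,
sd 0.8) through a Gaussian copula with correlation ρ (default 0.4), so the
generating corr(empathy, α_other − α_self) is exact in expectation up to
boundary clipping (≤ 0.06 attenuation at ρ = 0.4, measured at n = 4000).
Response times are truncated lognormal with condition-specific means
(Self 9.49 s vs Other 8.41 s under the 30 s behavioral deadline; 2.59 s vs
2.51 s under the 5 s scanner deadline), reproducing the slower-for-Self
pattern.

**Mouselab view logs.** Views alternate between the two options from a
random starting side; the first view's cell is the minimum (L) box with a
condition-specific probability (defaults 0.75 Self / 0.60 Other, with a
subject-level deviate on the logit scale shared across conditions so the
condition contrast is a fixed effect over a subject random intercept — the
structure the first-view GLMM assumes). View durations are gamma weights
rescaled so total dwell on the larger-minimum option exceeds the other
option by gain·ΔMin + noise (gain defaults: 2 ms/JPY in Self, 0 in Other;
trial noise sd 0.4 s; subject-level bias sd 0.15 s), the linear structure
the dwell mixed model recovers. Views never overlap and fit inside [0, RT].

**Gaze streams.** 500 Hz piecewise traces: fixations at AOI centers (± a
0.3° per-fixation scatter) joined by minimum-jerk saccades (default 20
samples ≈ 40 ms; ~375°/s peak for a 10° amplitude). Fixation time is
allocated with the same dwell-bias structure as the Mouselab generator.
Ground-truth events (the strictly moving interval for saccades) are emitted
alongside samples. With jitter enabled, fixational noise is low-pass
filtered tremor (200 ms window) scaled to sd 0.2° plus 0.02° white
measurement noise; white noise of the full amplitude at 500 Hz would by
itself exceed a 30°/s velocity threshold, which no real fixation does.

**BOLD.** y = Xβ + iid Gaussian noise on a 1-D ROI series; event schedules
follow the scanner task (1 s cue, 2/4/6 s SOA, 5 s option window with RT
durations, 2/4/6 s ITI, conditions in blocks of 12). The generator does not
model autocorrelated MRI noise, head motion, or spatial structure; GLM
t-calibration results therefore speak to the estimator, not to serial
correlation in real scanner data.

What passing recovery tests does *not* show: real participants have
sequential dependencies, learning, lapses, and gaze calibration error that
the generator omits; the pipeline's statistical calibration holds under the
generator's independence assumptions.

## Process tracing

Quartile view shares split each trial's decision time (options onset to
response) into four equal sub-intervals and apportion each view by exact
overlap; a brute-force per-0.1 ms discretization agrees to < 0.1%. Averaging
is trials-first within subject, then across subjects. Views spanning a
quartile boundary are split proportionally.

First views are modeled as P(first view = L) with a random-intercept
logistic model (L vs H; first views on M are excluded but counted), fixed
effects for condition and the L/M/H vs H/M/L layout dummy. Estimation is
maximum likelihood with 30-node Gauss–Hermite quadrature over the subject
intercept — statsmodels has no ML binomial mixed model, so this is
implemented in `mixed.py` and cross-checked against lme4::glmer (nAGQ = 25)
on a frozen fixture, agreeing to ~1e−6 in coefficients, standard errors,
σ_u and log-likelihood. Inference is Wald-z (the normal approximation is
named in the output); exact integration beyond quadrature is not attempted.
Near-separation (any |coef| reaching 15) triggers a lightly ridge-penalized
refit, flagged in the result. If the information matrix is singular the
model falls back to a fixed-effects logit with a warning.

Dwell differences (larger-minimum minus smaller-minimum option, positive =
more viewing of the larger-minimum option; tied-minimum trials dropped) are
modeled per condition with a random-intercept linear mixed model
(statsmodels MixedLM, REML) on ΔMin, ΔEV and the layout dummy; p-values are
Wald normal. Subjects are the only random effect; no random slopes.

## Gaze-event classification

Positions are smoothed with a 5-sample moving average; speed and its rate of
change come from central finite differences (the thresholds are standard,
the differentiation scheme is this package's convention). A sample is a
saccade when speed > 30°/s or |acceleration| > 9500°/s²; maximal non-saccade
runs of ≥ 100 ms become fixations, shorter runs are left unclassified, so
stationary runs under the threshold can never yield fixations. Invalid gaps
≤ 75 ms are linearly interpolated; longer gaps split the trace into
independently classified segments. Fixation centroids use the raw
(unsmoothed) samples. AOIs are two non-overlapping rectangles (one per
option) with a central gap; a centroid on the gap belongs to neither.
Saccade samples are never counted as dwell. On noiseless generator output
the classifier reproduces every ground-truth event with boundaries within
one sample.

## fMRI design and connectivity

The canonical HRF is the double-gamma form (response peak 6 s, undershoot
16 s, peak:undershoot 6, 32 s support), peak-normalized, sampled at
TR/16 = 0.125 s. Condition regressors are boxcars with trial-RT durations
(cue: 1 s; response: zero-duration impulse), convolved at microtime
resolution and sampled at the middle microtime bin of each TR. Parametric
modulators (ΔU for GLM1 — using condition-mean α; ΔMin and ΔEV for GLM2)
are mean-centered within condition before convolution and are **not**
serially orthogonalized (configurable choice; centering alone matches
modern practice). Drift is handled by discrete-cosine nuisance regressors
with a 128 s cutoff. Estimation is OLS with classical t statistics; rank
deficiency is an error naming the collinear columns.

The ROI summary series is the first eigenvariate: the leading left singular
vector of the column-centered time × voxel matrix, scaled by s₁/√(n_voxels)
and sign-aligned to the ROI mean, so a single-voxel ROI returns its own
centered series. gPPI interactions are formed at the BOLD level — centered
seed × (HRF-convolved, centered) condition regressor — without neural-level
deconvolution; this is a documented simplification, adequate here because
the synthetic target is generated at the BOLD level too.

## Group statistics

t tests are classical (zero-variance inputs are errors, not silent NaNs).
The robust correlation is the percentage-bend coefficient with bend = 0.2:
deviations from the percentage-bend location are scaled by the (1 − bend)
quantile of absolute deviations from the median and winsorized at ±1 before
correlating; the test statistic is r·√((n−2)/(1−r²)) on n−2 df. It is
invariant under positive affine maps and moves < 0.02 under a single gross
outlier where the product-moment r moves an order of magnitude more.

The 2×2 within-subject ANOVA (condition × parameter on modulator betas)
tests each effect as a single-df per-subject contrast, so every F equals the
squared paired t of its contrast with df (1, n−1) — verified to 1e−10 and
against pingouin. Reports of such designs sometimes quote pooled error
degrees of freedom (e.g. 2 and 2(n−1)); this package reports the single-df
convention and makes no attempt to emulate pooled-df output. Bonferroni
adjustment is min(1, m·p). All p-values are two-sided.

## Problem sizes and seeds

All generators take an explicit seed and are reproducible byte-for-byte.
The validation suite runs the recovery studies at their natural scales (20
subjects for the oracle check; 200 subjects for α recovery at 36/108/360
trials; 200 replicate cohorts of 60 subjects for the correlation and
information-search power studies, with matched null generators; 500 GLM and
200 gPPI replicates). The reproduction script reports the same quantities
with 100 cohort and 60 tracing replicates per arm, recording each n in its
output.
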