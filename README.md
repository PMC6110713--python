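# maximin-choice

Analysis pipeline for risky decision making **for oneself vs. for an
anonymous other**: model-based estimation of maximin concern from binary
lottery choices, process-tracing (Mouselab) information-search analysis,
gaze-event classification, model-derived fMRI regressors (parametric
modulation and gPPI connectivity), and the group-level statistics — together
with a synthetic-data generator that makes every stage verifiable by
parameter recovery.

## The model

Each choice option is a lottery over three equiprobable monetary outcomes
(π₁, π₂, π₃ in JPY). A decision maker's utility for option *x* follows the
quasi-maximin form

    Uᵢ(x) = αᵢ · min(π₁, π₂, π₃) + (1 − αᵢ) · EV(x),

where the **maximin weight** αᵢ ∈ [0, 1] measures concern about the worst
outcome: α = 0 is pure risk-neutral EV maximization, α = 1 pure maximin.
Binary choices follow a softmax (logit) rule,
P(choose a) = 1 / (1 + exp(−λ·(U(a) − U(b)))), with sensitivity λ (1/JPY),
and (α, λ) are estimated per participant and condition (Self / Other) by
bound-constrained maximum likelihood with multi-start quasi-Newton search.

Trial-level quantities derived from the model — ΔMin, ΔEV, and ΔU (absolute
between-option differences in minimum, expected value, and utility at the
group-mean α) — drive the downstream analyses: the dwell-difference mixed
model in the process-tracing stage and the parametric-modulation regressors
(ΔU in GLM1; ΔMin and ΔEV in GLM2) in the fMRI design stage.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic data
(each prints what it found and writes its tables under `results/`):

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_fit_choice_model.py
python analysis/03_information_search.py
```

Output of the run above:

```
cohort: 60 subjects, 4320 choices, 34493 box views
generating maximin weights: alpha_self mean 0.454, alpha_other mean 0.448
mean RT: Self 9.37 s vs Other 8.37 s (Self slower)

fitted 120 subject x condition cells
alpha recovery MAE: Self 0.052, Other 0.052
alpha_Self_vs_0: stat=23.433, df=59, p=1.408e-31
alpha_Other_vs_0: stat=21.658, df=59, p=9.119e-30
alpha_self_vs_other_paired: stat=0.274, df=59, p=0.7853
pbcor_empathy_vs_alpha_contrast: stat=0.487, df=58, p=7.863e-05

first-quartile view shares: L 54.3%, M 10.0%, H 35.7%
first-view condition effect (Self vs Other, logit): 0.528 (z = 7.61, p = 2.8e-14)
dwell-difference slope on dMin, Self: 2.009 ms/JPY (p = 0)
dwell-difference slope on dMin, Other: 0.004 ms/JPY (p = 0.93)
```

Reading the numbers: the estimated maximin weights are recovered to ±0.05
per subject; both condition means are far from zero (strong maximin concern)
while Self and Other do not differ at the decision level; the percentage-bend
correlation between trait empathic concern and the α(Other) − α(Self)
contrast recovers the generating linkage (ρ = 0.4); information search is
biased toward the minimum-outcome boxes early in the trial, more strongly
when deciding for oneself; and the injected Self-only dwell sensitivity to
ΔMin (2 ms per JPY) is recovered with the Other condition flat.

Scripts `04`–`06` continue with the scanner-side analyses: gaze-event
classification and option-dwell tests, the GLM1/GLM2 parametric-modulation
fits with the condition × parameter repeated-measures ANOVA, and gPPI
seed-by-condition connectivity recovery.

The same stages are available as a CLI
(`maximin-choice simulate|fit|trace|gaze|design|stats|recover`, each taking
`--seed`/`--config`/`--out`) over tab-separated interchange files.

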