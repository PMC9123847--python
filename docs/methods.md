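# Methods

## The natural-history model

The core object is a linear mixed model on longitudinal pairs of
delta-power measurements,

    δ_sub = β₀ + β₁ δ_init + β₂ log₁₀(age_init)·IVI + b_subject + ε,

with a subject random intercept `b ~ N(0, σ_b²)` and residual
`ε ~ N(0, σ_e²)`. Age and IVI share one unit within a dataset (years for
the human arm, weeks for the mouse arm); the unit is carried in the fit
object and echoed in reports. Estimation is maximum likelihood by default
(REML available); Wald t statistics use residual degrees of freedom
`n_pairs − 3`, and 95% CIs are `estimate ± t₀.₉₇₅,df·SE`. The in-sample
RMSE is computed on *population-level* residuals (random effect set to
zero), because every downstream treatment-effect computation scores new
observations against the population prediction.

Residual sign convention: residual = **predicted − observed**. Delta
power is pathologically elevated in this disorder and effective treatment
is expected to lower it, so under this convention treatment pushes
residuals positive. The opposite convention is more common in regression
texts; it is deliberately not used here.

Two numerical fallbacks make the fit total on degenerate inputs:

- Noise-free data (OLS residuals at machine precision) are returned as an
  exact deterministic fit with zero variance components, since no mixed
  likelihood exists at σ_e = 0.
- When the random-intercept variance is at or near zero the MixedLM
  optimiser may fail to converge; after a BFGS and a Powell attempt the
  fit falls back to the boundary solution (plain least squares with
  σ_b = 0), which is the ML solution there.

Cross-validation refits the model per fold (subjects, or
subsequent-visit weeks for the regularly sampled mouse design) and pools
held-out population-level residuals into one RMSE.

## Spectral estimation

Human EEG: posterior channels (O1, O2, P3, Pz, P4) are re-referenced to
their instantaneous group average; power spectra are computed on
non-overlapping 1 s Hann-tapered windows (1 Hz resolution), each window
demeaned before tapering. Relative delta power per interval is the summed
2–4 Hz power averaged over channels divided by the summed 1–50 Hz power
averaged over channels (ratio of channel averages; a mean-of-per-channel-
ratios variant is available), and the recording-level estimate is the
mean over intervals. With 1 Hz bins, "2–4 Hz" is taken as the three bins
{2, 3, 4} and "1–50 Hz" as the fifty bins {1..50}, all inclusive.
Intervals with zero total power are dropped and counted. Spectra use
one-sided density scaling, so for broadband signals the summed power times
the bin width approximates the window variance; per-window demeaning
removes DC leakage at the cost of a dent in the 1 Hz bin (DC removal
bleeds through the Hann main lobe), which is inside the total band but
outside the delta band and negligible for the 50-bin denominator.

Mouse LFP: DPSS multitaper spectra (5 tapers, time–bandwidth product 3)
on 5 s windows with 1 s overlap, averaged over windows and then across
hemispheres, restricted to the trailing 10 minutes of the session;
absolute delta activity is the peak of the averaged spectrum between 1 and
5 Hz inclusive, in mV²/Hz. The multitaper normalisation matches the rest
of this package (unit-energy tapers, density scaling); absolute values are
therefore comparable within this implementation but not against other
toolboxes, whose normalisation conventions differ.

Noisy-channel exclusion (the recording hardware occasionally damages an
electrode) flags a channel when the robust z-score of its log total power
(1.4826·MAD scaling around the cohort median) exceeds a threshold
(default 3), or when the signal sits at a rail value for at least 0.1 s.
The rule is a documented, configurable stand-in for a lab-specific
procedure; exclusions are reported, and estimates fall back to a single
hemisphere with a warning rather than failing.

## Stability by resampling

The precision of a relative delta estimate as a function of data amount
is quantified empirically: per-second interval values are resampled
either as random epochs (without replacement) or as contiguous stretches
with uniformly random start times (no wraparound), 1000 repetitions per
size by default, and the SEM is the standard deviation of the resampled
means (empirical 2.5/97.5 percentiles give the CI). The empirical SEM is
used rather than s/√n deliberately: under slow temporal drift the
contiguous-epoch SEM exceeds the iid prediction, and that excess is the
quantity of interest.

## Trial power simulation

A two-arm trial is simulated by drawing pairs with replacement from a
pair pool for each arm, subtracting a fixed offset from the treatment
arm's subsequent-visit delta (clamped at zero and counted — relative
power cannot be negative), scoring both arms against one pre-fitted
model, and comparing arm residuals with a one-sided pooled-variance
t-test (H₁: treatment residuals exceed control). The model is fitted once
on the untreated pool and held fixed across simulations: the natural
history model is the measurement instrument, and refitting per simulated
trial would answer a different design question (a per-simulation refit
flag is available). Power per (offset, arm size) cell is the rejection
fraction over 2000 simulations; the default grid spans offsets 0–0.1 in
0.002 steps with arms of 25/50/100/150. For Gaussian residuals the
noncentral-t closed form (`analytic_power`, noncentrality
offset/(σ√(2/n))) provides an independent check; simulation and closed
form agree within Monte-Carlo tolerance in the test suite.

## Mouse treatment-effect detection

Electrode implantation precludes pre-treatment recordings, so treated
mice lack an initial visit. For each target visit a *surrogate baseline*
is drawn uniformly from the week-2 control-ASO observations (a control
mouse never draws its own), a pair is formed (IVI = age difference), and
the population-level residual computed. The per-week treatment effect is
median(treated residuals) − median(control residuals); redrawing all
baselines 10,000 times yields the effect distribution and its 2.5–97.5%
bounds. Week-2 observations serve as initial visits only, so effects
start at week 3. Prediction for treated mice is population-level (random
effect zero): treated animals are unseen by the control-fitted model, so
no subject-specific intercept exists for them; an empirical-Bayes variant
conditioned on the drawn baseline mouse is available behind a flag.

Significance comes from a permutation null: control and treated mice are
pooled and relabelled into pseudo-groups of the original sizes (each
mouse keeps one pseudo-label across all weeks; the pseudo-control group
supplies the baseline pool), and the effect computation is repeated per
relabelling. The default p-value is the empirical tail probability of the
mean observed effect under the null, `(1 + #{null ≥ observed})/(n + 1)`.
A one-sided t-test between the observed and null effect *distributions*
is provided as an option for fidelity with the procedure as originally
described, but it treats resampling replicates as independent samples and
inflates significance; it is not the default. The null machinery is fully
vectorised when every mouse is observed at the relevant weeks and falls
back to an explicit loop otherwise.

Because the model adjusts for the log₁₀(age)·IVI drift, treated and
control groups can be contrasted at *different* weeks
(`cross_age_contrast`); a raw-delta t-test is reported alongside for
comparison. Such cross-age contrasts additionally carry the working
model's per-week lack of fit (see below), which same-week contrasts
cancel.

## Expression slopes

Week-7 residuals (surrogate baselines redrawn each repetition) are
regressed by OLS, with intercept and no weighting, on relative *Ube3a*
mRNA for the mice with expression data (the study design: 8 control + 4
treated; control and treated pooled into one regression by default, with
a control-only option). The 12 mice are fixed; all resampling variability
comes from the baseline draws, and the summary is the slope distribution
(mean, SD, SE, fraction positive) over 1000 repetitions. mRNA is encoded
relative to the wild-type control mean (1.0 = WT); slopes scale inversely
under affine re-encoding of the mRNA axis (asserted in tests).

## Synthetic data: what it emulates and how it is calibrated

**EEG.** Channels are independent random-phase multisines: band-limited
components on the delta band (2–4 Hz) and on the remainder of 1–50 Hz,
with fixed per-component amplitudes (so every realisation carries exactly
the programmed band power; sums of thousands of components are Gaussian
to excellent approximation). The two band variances are solved
analytically with the Hann-kernel leakage matrix so that the *measured*
band ratio matches the target, and a final one-step correction against
the estimator's expectation (measured on an internal fixed-seed probe
signal) absorbs the small negative bias of averaging per-interval ratios.
Targets are restricted to the reachable range; taper leakage across the
band edges caps the maximum ratio below 1, and infeasible targets raise.
The generator emulates band-power statistics only — no spindles,
artifacts, or topography — so passing spectral tests demonstrates
estimator correctness, not robustness to real-world artifact.

**Human cohort.** 56 subjects, 204 visits. Each subject receives an
initial visit (age log-uniform on 0.89–32.5 years; baseline delta from a
truncated normal with mean 0.55 − 0.15·log₁₀(age), SD 0.12, clipped to
[0.05, 0.95] — parameters chosen to span the plausible range of relative
delta in this population while keeping clipping rare) and 1+ subsequent
visits at log-uniform IVIs (2 days–7 years) generated from the model with
defaults β = (0.25, 0.43, −0.03), σ_e = 0.09 (anchored to the
cross-validated RMSE) and σ_b = 0.05 (not separately reported anywhere;
an assumption, flagged as such). Subsequent deltas are clipped to [0, 1]
with events counted (< 1% under defaults). All subsequent visits anchor
to the subject's initial visit: this keeps the initial-delta regressor
independent of the random intercept and the noise, so the fitted model is
correctly specified and parameter recovery is unbiased — chained or
all-combination pairing of *generated* human visits would make the lagged
regressor endogenous.

**Mouse cohort.** Three arms (WT control 28, AS control 26, AS ASO 15),
weekly recordings at post-treatment weeks 2–8 (ages 7–13 weeks; treatment
at P35 ≈ 5 weeks of age). Here the downstream fit deliberately follows
the experimental procedure — *all* pair combinations of each control
mouse's weekly visits — which re-uses noisy observations as regressors,
so no generative trajectory satisfies the pair model exactly for every
pair, and naive trajectory generation substantially biases the recovered
coefficients. The generator therefore solves for the shared mean weekly
trajectory (quadratic in week) such that the *large-sample estimand* of
the all-pairs working-model fit — available in closed form from the
population normal equations, measurement error included — equals the
requested coefficients exactly. Defaults: β = (3.08e-3, 0.06, −8.07e-5),
σ_e = 4.5e-4 mV²/Hz (anchored to the full-model RMSE of the original
mouse fit), σ_b = 0. A true per-mouse random intercept would make the
lagged-delta regressor endogenous and shift the estimand; between-mouse
spread therefore enters only through per-visit noise, and the recovered
random-intercept variance on synthetic mouse cohorts is correctly ~0.
Consequences worth knowing: β₂ recovery is excellent (mean −7.9e-5 over
200 cohorts against −8.07e-5), while β₁ estimates at n = 26 are noisy and
attenuated — consistent with the original mouse analysis, where the
initial-delta coefficient was itself not significant (P = 0.1). The
calibrated trajectory also leaves a small per-week lack of fit
(`E[control residual] ≠ 0` week by week, a few times 1e-4), which
same-week contrasts cancel and cross-age contrasts inherit. The AS-ASO
arm subtracts an additive `treatment_effect` (default 1e-3 mV²/Hz, the
scale detectable against σ_e) from week 2 onward; WT mice are offset
−1.2e-3 (delta is higher in AS than WT at every week).

**Expression.** mRNA = group baseline + coupling·(control-trajectory
value − observed delta at week 7) + Gaussian noise, clipped at 0. Group
baselines 1.0 / 0.22 / 0.50 (WT control / AS control / AS ASO) follow the
reported qPCR normalisations; coupling defaults to 250 relative-mRNA
units per mV²/Hz with noise SD 0.05, giving the qualitative
all-slopes-positive outcome at the study's 8+4 sample size. Note the
original slope summaries are consistent with mRNA expressed in percent
(WT = 100); with the 1.0 = WT encoding used here slopes are ~100× larger,
and the affine-rescaling invariance test covers the conversion.

## Problem sizes and determinism

Every stochastic routine takes a seed (or a numpy Generator) and is
bit-reproducible under it. The validation experiments use 200 replicate
cohorts for parameter recovery, 2000 simulations per power cell, 500
replicates at 1000 resamples for permutation-null calibration, and
10,000/1000 resamples for the mouse-effect and expression distributions
in production use; these sizes put Monte-Carlo error well below the
effect scales being checked while keeping each experiment in the
seconds-to-minutes range.

## Known limitations

- Wake/sleep staging is an input (sidecar intervals), never computed.
- Human EEG artifact rejection is deliberately absent (the posterior
  electrodes are used unclean, matching the upstream measurement
  protocol); the synthetic EEG contains no artifacts to reject.
- Absolute mouse delta values are internally consistent only; comparing
  them against other spectral toolboxes requires matching normalisations.
- The mouse generator encodes between-animal heterogeneity as per-visit
  noise (σ_b = 0); mouse-arm variance components are design choices, not
  reported quantities.
- The permutation p-value, not the distribution-versus-distribution
  t-test, is the calibrated default; the t-test variant exists for
  procedural fidelity and is anticonservative.
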