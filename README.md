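# deltatrack

Longitudinal natural-history modelling of EEG delta power for Angelman
syndrome (AS) trials, for biostatisticians and translational
neurophysiologists planning or analysing delta-power biomarker studies.

Delta-band (2–4 Hz) EEG power is elevated in AS and tracks disease
severity, but it varies widely between individuals and across development,
so single cross-sectional measurements cannot resolve a treatment effect.
The approach implemented here instead models the *natural history* of the
biomarker — how a person's (or mouse's) delta power at one visit predicts
its value at a later visit — and scores treatment as a deviation from that
prediction.

## The model

For a longitudinal pair of recordings (initial → subsequent), relative
delta power at the subsequent visit is modelled as

```
δ_subsequent = β₀ + β₁ δ_initial + β₂ log₁₀(age_initial)·IVI + b_subject + ε
b_subject ~ N(0, σ_b²),   ε ~ N(0, σ_e²)
```

where IVI is the inter-visit interval (same unit as age: years for humans,
weeks for mice), and `b_subject` is a random intercept absorbing stable
inter-individual differences. Fitting is by maximum likelihood
(statsmodels `MixedLM`; REML optional).

A *residual* throughout this package is **predicted − observed**, so a
treatment that lowers delta power produces positive residuals.

Around that core the package provides:

- `deltatrack.spectral` — relative delta power from scalp EEG
  (non-overlapping 1 s Hann windows; ratio of channel-averaged 2–4 Hz to
  1–50 Hz band power on average-referenced posterior channels O1, O2, P3,
  Pz, P4) and absolute delta activity from mouse visual-cortex LFP (DPSS
  multitaper, 5 tapers, NW = 3, 5 s windows / 1 s overlap; peak of the
  hemisphere-averaged spectrum in 1–5 Hz, mV²/Hz), plus noisy-channel
  exclusion.
- `deltatrack.stability` — SEM-versus-data-amount curves by epoch
  resampling (random 1 s epochs or contiguous stretches).
- `deltatrack.model` — pair building (consecutive or all combinations),
  the mixed-model fit, prediction, residuals, leave-one-subject-out and
  leave-one-week-out cross-validation.
- `deltatrack.trialpower` — bootstrap two-arm trial power: resample pairs,
  subtract a delta offset in the treatment arm, compare arm residuals with
  a one-sided t-test; includes the noncentral-t closed form for checking.
- `deltatrack.mouse_effect` — surrogate-baseline residuals for treated
  mice without pre-treatment recordings, per-week median-residual
  treatment effects with resampled CIs, and a mouse-level permutation
  null with empirical p-values.
- `deltatrack.expression` — resampled OLS slopes relating week-7 model
  residuals to relative *Ube3a* mRNA.
- `deltatrack.synthetic` — generators for every input (EEG with
  programmed relative delta power, the 56-subject/204-visit human cohort,
  the 28/26/15 three-arm weekly mouse cohort, coupled mRNA values), each
  deterministic under a seed and emitting its ground truth.
- `deltatrack.io` / `deltatrack.cli` — EDF reading (MNE), CSV/JSON/YAML
  schemas, and a `deltatrack` command-line tool
  (`delta`, `stability`, `fit`, `cv`, `power`, `mouse-effect`,
  `mrna-slope`, `simulate`, `run`).

## Worked example

```python
import numpy as np
from deltatrack import synthetic, model, trialpower

cohort = synthetic.make_human_cohort(synthetic.HumanCohortSpec(seed=3))
fit = model.fit_natural_history(cohort.pairs, units="years")
print(f"beta (intercept, delta_initial, log10(age):IVI) = "
      f"({fit.beta0:.3f}, {fit.beta1:.3f}, {fit.beta2:.3f})")
print(f"sigma_b = {fit.sigma_b:.3f}, sigma_e = {fit.sigma_e:.3f}, "
      f"in-sample RMSE = {fit.rmse:.3f}")
cv = model.cross_validate(cohort.pairs, "leave_one_subject_out")
print(f"leave-one-subject-out RMSE = {cv.rmse:.3f}")
curve = trialpower.power_curve(
    cohort.pairs, fit, offsets=np.arange(0.0, 0.101, 0.002),
    group_sizes=[50], n_sims=2000, seed=0,
)
print(f"smallest offset with >=80% power at n=50: "
      f"{curve.offset_for_80_power[50]:.3f}")
```

prints

```
beta (intercept, delta_initial, log10(age):IVI) = (0.270, 0.380, -0.032)
sigma_b = 0.042, sigma_e = 0.093, in-sample RMSE = 0.102
leave-one-subject-out RMSE = 0.104
smallest offset with >=80% power at n=50: 0.052
```

One synthetic cohort of 56 subjects was generated at coefficients
(0.25, 0.43, −0.03) with residual SD 0.09; the single-cohort fit recovers
them within sampling error, the cross-validated RMSE matches the residual
scale, and a two-arm trial with 50 subjects per arm would need roughly a
0.05 reduction in relative delta power for 80% detection power at this
cohort's residual spread (this pool also carries the 0.042
random-intercept spread, which is why the threshold sits slightly above
the 0.046 obtained at a pure 0.09 residual SD).

The same pipeline runs end to end from the shell:

```sh
deltatrack run --seed 1 --out out/
```

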