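"""Synthetic data with known ground truth for every pipeline stage.

Nothing in the human arm of the study is publicly deposited, so the test
bed is fully synthetic: EEG with programmed relative delta power, a human
longitudinal cohort obeying the natural-history model, a weekly three-arm
mouse cohort, and mRNA values coupled to the deviation from natural
history.  Every generator is deterministic under a fixed seed and returns
its ground truth alongside the data.

Two design points deserve note (details in the methods note):

* Human cohort: each subject has one initial visit; all later visits are
  generated from — and paired with — that anchor.  This keeps the
  initial-delta regressor independent of the random intercept and the
  noise, so the fitted mixed model is correctly specified and parameter
  recovery is unbiased.

* Mouse cohort: the fitted model pairs *all* combinations of weekly
  visits, re-using noisy observations as regressors, so no generative
  trajectory can satisfy the pair model exactly for every pair.  The
  shared mean trajectory (quadratic in week) is instead solved so that the
  large-sample limit of the fitted coefficients — the working-model
  estimand, available in closed form for the pooled estimator — equals the
  requested coefficients exactly.  The generated cohort therefore "has"
  those coefficients in the only sense an all-pairs fit can recover them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import root

from .spectral import TimeSeriesRecording

# Human natural-history coefficients used as generating defaults
# (intercept, delta_initial, log10(age):IVI), ages in years.
HUMAN_BETA = (0.25, 0.43, -0.03)
# Mouse counterparts, ages in weeks, delta in mV²/Hz.
MOUSE_BETA = (3.08e-3, 0.06, -8.07e-5)
#: ASO treatment at P35 ≈ 5 weeks of age; post-treatment week w ↦ age w+5.
MOUSE_AGE_OFFSET = 5.0


# --------------------------------------------------------------------------
# synthetic EEG with programmed relative delta power
# --------------------------------------------------------------------------

def _hann_tone_weights(fs: int, n_total: int, freq_idx: np.ndarray,
                       bins: np.ndarray) -> np.ndarray:
    """Expected windowed-periodogram weight of unit tones in integer bins.

    ``weights[m, k]`` is proportional to the expected (phase-averaged)
    power a unit-variance tone at grid frequency ``freq_idx[m]·fs/n_total``
    contributes to the integer-Hz bin ``bins[k]`` of a Hann-tapered 1 s
    window.  The Hann transform is evaluated on the fine frequency grid by
    zero-padded FFT, so leakage across band edges is exact on that grid.
    """
    n_win = int(fs)
    w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n_win) / n_win)
    wmag2 = np.abs(np.fft.fft(w, n_total)) ** 2
    bin_idx = np.rint(bins * n_total / fs).astype(int)
    minus = (bin_idx[None, :] - freq_idx[:, None]) % n_total
    plus = (bin_idx[None, :] + freq_idx[:, None]) % n_total
    return 0.25 * (wmag2[minus] + wmag2[plus])


def programmed_delta_variances(
    target: float,
    fs: int,
    duration_s: float,
    band_delta=(2.0, 4.0),
    band_total=(1.0, 50.0),
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Band variances making the *expected measured* delta ratio = target.

    The delta component is band-limited noise on ``band_delta``; the rest
    component covers ``band_total`` minus the delta band.  Taper leakage
    across band edges is accounted for with the Hann kernel, so the
    expectation of the 1 s-window estimator equals ``target``.  Returns
    (delta variance, rest variance, delta grid freqs, rest grid freqs)
    with the rest variance fixed at 1.
    """
    n_total = int(round(duration_s * fs))
    df = fs / n_total
    grid_idx = np.arange(1, int(np.floor((band_total[1] + band_delta[1]) / df)))
    grid = grid_idx * df
    in_delta = (grid >= band_delta[0]) & (grid <= band_delta[1])
    in_rest = (
        (grid >= band_total[0]) & (grid <= band_total[1]) & ~in_delta
    )
    f_d, f_r = grid[in_delta], grid[in_rest]
    bins = np.arange(1.0, band_total[1] + 0.5)
    delta_bins = (bins >= band_delta[0]) & (bins <= band_delta[1])
    wd = _hann_tone_weights(fs, n_total, grid_idx[in_delta], bins)
    wr = _hann_tone_weights(fs, n_total, grid_idx[in_rest], bins)
    add, adt = wd[:, delta_bins].sum() / len(f_d), wd.sum() / len(f_d)
    ard, art = wr[:, delta_bins].sum() / len(f_r), wr.sum() / len(f_r)
    denom = add - target * adt
    v_d = (target * art - ard) / denom
    if not np.isfinite(v_d) or v_d <= 0:
        raise ValueError(
            f"target relative delta {target} infeasible for bands "
            f"{band_delta}/{band_total}"
        )
    return float(v_d), 1.0, f_d, f_r


def make_synthetic_eeg(
    target_relative_delta: float,
    duration_s: float = 60.0,
    fs: int = 256,
    n_channels: int = 5,
    seed: int | np.random.Generator = 0,
    rms_uv: float = 20.0,
    channel_labels: list[str] | None = None,
    calibrate: bool = True,
) -> TimeSeriesRecording:
    """EEG-like noise whose expected relative delta power equals the target.

    Each channel is an independent sum of band-limited Gaussian noise in
    the delta band (2–4 Hz) and in the remainder of 1–50 Hz, with
    variances solved analytically (taper leakage included) so the
    band-power partition matches the target; channels are independent, so
    average re-referencing rescales but does not annihilate the signal.

    The per-interval ratio estimator carries a small negative bias (the
    mean of ratios is below the ratio of means, and the delta numerator
    averages only three bins), so by default the target is additionally
    corrected by one fixed-point step against the estimator's expectation,
    measured on an internal fixed-seed calibration signal.
    """
    if not 0 < target_relative_delta < 1:
        raise ValueError("target must lie strictly inside (0, 1)")
    if fs < 128:
        raise ValueError("fs must be >= 128 to cover the 1-50 Hz band")
    rng = np.random.default_rng(seed)
    target = target_relative_delta
    if calibrate:
        probe = make_synthetic_eeg(
            target, duration_s=max(duration_s, 600.0), fs=fs,
            n_channels=n_channels, seed=987654321, calibrate=False,
        )
        from .spectral import relative_delta_power, rereference_average

        measured = relative_delta_power(
            rereference_average(probe, probe.channel_labels)
        ).value
        target = float(np.clip(2 * target - measured, 1e-3, 1 - 1e-3))
    v_d, v_r, f_d, f_r = programmed_delta_variances(target, fs, duration_s)
    n = int(round(duration_s * fs))
    grid = np.fft.rfftfreq(n, d=1 / fs)
    spec_var = np.zeros(len(grid))
    for freqs, v in ((f_d, v_d), (f_r, v_r)):
        idx = np.rint(freqs * duration_s).astype(int)
        spec_var[idx] = v / len(freqs)
    # random-phase multisine: each grid component carries its programmed
    # power exactly (no realisation-level power fluctuation), and the sum
    # of thousands of components is Gaussian to excellent approximation
    chans = []
    for _ in range(n_channels):
        theta = rng.uniform(0.0, 2 * np.pi, len(grid))
        coef = n * np.sqrt(spec_var / 2.0) * np.exp(1j * theta)
        coef[0] = 0.0
        x = np.fft.irfft(coef, n=n)
        chans.append(x)
    x = np.array(chans)
    x *= rms_uv / np.sqrt(np.mean(x**2))
    labels = channel_labels or [f"ch{i}" for i in range(n_channels)]
    if channel_labels is None and n_channels == 5:
        labels = ["O1", "O2", "P3", "Pz", "P4"]
    return TimeSeriesRecording(samples=x, fs=float(fs), channel_labels=labels)


# --------------------------------------------------------------------------
# human longitudinal cohort
# --------------------------------------------------------------------------

@dataclass
class HumanCohortSpec:
    """Generating parameters for the synthetic human cohort.

    Defaults mirror the study design: 56 subjects with 204 visits in
    total, ages log-uniform on 0.89–32.5 years, inter-visit intervals
    log-uniform from 2 days to 7 years, natural-history coefficients at
    the published point estimates, residual SD anchored to the
    cross-validated RMSE of 0.09 and a 0.05 random-intercept SD (the
    latter is not separately reported; it is an assumption).  The baseline
    (initial-visit) delta marginal is a truncated normal declining in
    log10(age): mean 0.55 − 0.15·log10(age), SD 0.12, clipped to
    [0.05, 0.95].
    """

    n_subjects: int = 56
    n_visits_total: int = 204
    age_range: tuple[float, float] = (0.89, 32.5)
    ivi_range: tuple[float, float] = (2.0 / 365.25, 7.0)
    beta: tuple[float, float, float] = HUMAN_BETA
    sigma_b: float = 0.05
    sigma_e: float = 0.09
    baseline_mean: tuple[float, float] = (0.55, -0.15)  # a + b·log10(age)
    baseline_sd: float = 0.12
    baseline_clip: tuple[float, float] = (0.05, 0.95)
    seed: int | np.random.Generator = 0

    def __post_init__(self) -> None:
        if self.n_visits_total < self.n_subjects + 1:
            raise ValueError("need at least one subsequent visit overall")


@dataclass
class SyntheticHumanCohort:
    visits: pd.DataFrame
    pairs: pd.DataFrame
    truth: dict = field(default_factory=dict)


def make_human_cohort(spec: HumanCohortSpec | None = None) -> SyntheticHumanCohort:
    """Generate a longitudinal human cohort obeying the natural-history model.

    Each subject receives an initial visit (age and baseline delta drawn
    from the spec's marginals) and one or more subsequent visits whose
    delta is b0 + b1·delta_initial + b2·log10(age_initial)·ivi +
    b_subject + eps, clipped to [0, 1] (clip events counted in the truth
    record).  Pairs link every subsequent visit to the subject's initial
    visit.
    """
    spec = spec or HumanCohortSpec()
    rng = np.random.default_rng(spec.seed)
    b0, b1, b2 = spec.beta
    n_extra = spec.n_visits_total - 2 * spec.n_subjects
    counts = 1 + np.bincount(
        rng.integers(0, spec.n_subjects, n_extra), minlength=spec.n_subjects
    )
    visits, pairs = [], []
    intercepts = {}
    n_clipped = 0
    for s in range(spec.n_subjects):
        sid = f"S{s:03d}"
        age0 = 10 ** rng.uniform(*np.log10(spec.age_range))
        b = rng.normal(0.0, spec.sigma_b)
        intercepts[sid] = b
        d0 = np.clip(
            rng.normal(
                spec.baseline_mean[0] + spec.baseline_mean[1] * np.log10(age0),
                spec.baseline_sd,
            ),
            *spec.baseline_clip,
        )
        visits.append((sid, age0, float(d0), "AS", 0))
        for _ in range(counts[s]):
            ivi = 10 ** rng.uniform(*np.log10(spec.ivi_range))
            d = (
                b0 + b1 * d0 + b2 * np.log10(age0) * ivi
                + b + rng.normal(0.0, spec.sigma_e)
            )
            if d < 0 or d > 1:
                n_clipped += 1
                d = float(np.clip(d, 0.0, 1.0))
            visits.append((sid, age0 + ivi, float(d), "AS", 1))
            pairs.append((sid, float(d0), float(d), age0, ivi, "AS"))
    visits_df = pd.DataFrame(
        visits, columns=["subject_id", "age", "delta", "group", "is_subsequent"]
    ).sort_values(["subject_id", "age"], ignore_index=True)
    pairs_df = pd.DataFrame(
        pairs,
        columns=[
            "subject_id", "delta_initial", "delta_subsequent",
            "age_initial", "ivi", "group",
        ],
    )
    truth = {
        "beta": list(spec.beta),
        "sigma_b": spec.sigma_b,
        "sigma_e": spec.sigma_e,
        "random_intercepts": intercepts,
        "n_clipped": n_clipped,
        "clip_fraction": n_clipped / len(pairs_df),
    }
    return SyntheticHumanCohort(visits_df, pairs_df, truth)


# --------------------------------------------------------------------------
# mouse cohort
# --------------------------------------------------------------------------

def _allpairs_plim(mu: np.ndarray, weeks: np.ndarray, age_offset: float,
                   sigma_b: float, sigma_e: float) -> np.ndarray:
    """Large-sample fitted coefficients for an all-pairs working-model fit.

    For visits delta_w = mu_w + b + eps_w, the pooled estimator of
    (intercept, delta_initial, log10(age):IVI) converges to the solution
    of the population normal equations below; eps in the regressor enters
    as classical measurement error, which these moments capture exactly.
    """
    k = len(weeks)
    I, J = np.triu_indices(k, 1)
    z = np.log10(weeks[I] + age_offset) * (weeks[J] - weeks[I])
    mi, mj = mu[I], mu[J]
    n = len(I)
    s2 = sigma_b**2 + sigma_e**2
    A = np.array(
        [
            [n, mi.sum(), z.sum()],
            [mi.sum(), (mi**2).sum() + n * s2, (mi * z).sum()],
            [z.sum(), (mi * z).sum(), (z**2).sum()],
        ]
    )
    c = np.array(
        [
            mj.sum(),
            (mi * mj).sum() + n * sigma_b**2,
            (z * mj).sum(),
        ]
    )
    return np.linalg.solve(A, c)


def solve_mouse_trajectory(
    beta: tuple[float, float, float],
    weeks: np.ndarray,
    age_offset: float,
    sigma_b: float,
    sigma_e: float,
) -> np.ndarray:
    """Mean weekly trajectory whose all-pairs estimand equals ``beta``.

    Parametrises the trajectory as quadratic in post-treatment week and
    solves the three moment conditions (one per coefficient) exactly.
    """
    weeks = np.asarray(weeks, dtype=float)

    def eqs(c):
        u = weeks - weeks[0]
        mu = c[0] + c[1] * u + c[2] * u**2
        return _allpairs_plim(mu, weeks, age_offset, sigma_b, sigma_e) - beta

    sol = root(eqs, x0=[abs(beta[0]) + 1e-4, beta[2], 0.0], tol=1e-14)
    resid = np.abs(eqs(sol.x)).max()
    if resid > 1e-10 * max(abs(beta[0]), 1e-6):
        raise RuntimeError(
            f"trajectory calibration failed (residual {resid:.3g}); "
            "the requested coefficients may be infeasible for this design"
        )
    u = weeks - weeks[0]
    return sol.x[0] + sol.x[1] * u + sol.x[2] * u**2


@dataclass
class MouseCohortSpec:
    """Generating parameters for the weekly three-arm mouse cohort.

    Group sizes follow the experiment (WT control 28, AS control 26,
    AS ASO 15) with recordings at post-treatment weeks 2–8 (ages 7–13
    weeks; treatment at P35).  Coefficients default to the published mouse
    natural-history estimates; the per-visit noise SD is anchored to the
    full-model RMSE of 4.5e-4 mV²/Hz.  ``sigma_b`` defaults to 0 — a true
    random intercept would make the lagged-delta regressor endogenous and
    shift the all-pairs estimand away from the requested coefficients (see
    module docstring).  The treatment effect is an additive delta
    reduction applied to AS-ASO mice from week 2 onward; the genotype
    offset shifts the WT trajectory downward.
    """

    n_wt_control: int = 28
    n_as_control: int = 26
    n_as_aso: int = 15
    weeks: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    beta: tuple[float, float, float] = MOUSE_BETA
    sigma_b: float = 0.0
    sigma_e: float = 4.5e-4
    treatment_effect: float = 1.0e-3
    wt_offset: float = -1.2e-3
    age_offset: float = MOUSE_AGE_OFFSET
    seed: int | np.random.Generator = 0


@dataclass
class SyntheticMouseCohort:
    visits: pd.DataFrame
    truth: dict = field(default_factory=dict)


def make_mouse_cohort(spec: MouseCohortSpec | None = None) -> SyntheticMouseCohort:
    """Generate weekly mouse LFP delta trajectories for the three arms.

    AS control mice follow the calibrated mean trajectory plus per-mouse
    intercept and per-visit noise; WT controls are shifted by the genotype
    offset; AS ASO-treated mice have ``treatment_effect`` subtracted from
    week 2 onward.  Delta values are floored at a small positive value
    (floor events counted in the truth record).
    """
    spec = spec or MouseCohortSpec()
    rng = np.random.default_rng(spec.seed)
    weeks = np.asarray(spec.weeks, dtype=float)
    mu = solve_mouse_trajectory(
        spec.beta, weeks, spec.age_offset, spec.sigma_b, spec.sigma_e
    )
    rows = []
    n_floored = 0
    arms = (
        ("WT_control", spec.n_wt_control, spec.wt_offset, 0.0),
        ("AS_control", spec.n_as_control, 0.0, 0.0),
        ("AS_ASO", spec.n_as_aso, 0.0, spec.treatment_effect),
    )
    m_idx = 0
    for group, n, offset, effect in arms:
        for _ in range(n):
            mid = f"M{m_idx:03d}"
            m_idx += 1
            b = rng.normal(0.0, spec.sigma_b) if spec.sigma_b > 0 else 0.0
            eps = rng.normal(0.0, spec.sigma_e, len(weeks))
            vals = mu + offset - effect + b + eps
            for w, v in zip(weeks, vals):
                if v <= 0:
                    n_floored += 1
                    v = 1e-6
                rows.append((mid, group, int(w), w + spec.age_offset, float(v)))
    visits = pd.DataFrame(
        rows, columns=["mouse_id", "group", "week", "age", "delta"]
    )
    truth = {
        "beta": list(spec.beta),
        "trajectory": {int(w): float(m) for w, m in zip(weeks, mu)},
        "sigma_b": spec.sigma_b,
        "sigma_e": spec.sigma_e,
        "treatment_effect": spec.treatment_effect,
        "wt_offset": spec.wt_offset,
        "n_floored": n_floored,
    }
    return SyntheticMouseCohort(visits, truth)


# --------------------------------------------------------------------------
# mRNA expression coupled to model deviations
# --------------------------------------------------------------------------

#: Relative *Ube3a* mRNA group means (1.0 = wild-type control mean),
#: matching the reported qPCR normalisations.
MRNA_BASELINE = {"WT_control": 1.0, "AS_control": 0.22, "AS_ASO": 0.50}


def make_expression(
    cohort: SyntheticMouseCohort,
    coupling_slope: float = 250.0,
    noise_sd: float = 0.05,
    seed: int | np.random.Generator = 0,
    week_residual: int = 7,
    mice: list[str] | None = None,
) -> pd.DataFrame:
    """Relative mRNA levels linearly coupled to natural-history deviations.

    mrna = group baseline + coupling·(control-trajectory value − observed
    delta at ``week_residual``) + noise, clipped at 0.  The treated
    baseline is higher than the AS control baseline, emulating paternal
    unsilencing; ``coupling_slope`` is in units of relative mRNA per
    mV²/Hz of deviation.
    """
    rng = np.random.default_rng(seed)
    mu_w = cohort.truth["trajectory"][week_residual]
    sub = cohort.visits[cohort.visits["week"] == week_residual]
    if mice is not None:
        sub = sub[sub["mouse_id"].isin(mice)]
    rows = []
    for r in sub.itertuples(index=False):
        deviation = mu_w - r.delta  # positive when delta below natural history
        mrna = (
            MRNA_BASELINE[r.group]
            + coupling_slope * deviation
            + rng.normal(0.0, noise_sd)
        )
        rows.append((r.mouse_id, r.group, max(mrna, 0.0), week_residual + 1))
    return pd.DataFrame(
        rows, columns=["mouse_id", "group", "mrna_relative", "week_measured"]
    )
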