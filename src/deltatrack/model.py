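"""Random-intercept natural-history model of longitudinal delta power.

The model predicts delta power at a subsequent visit from delta power at an
initial visit, the interaction of log10(age at the initial visit) with the
inter-visit interval (IVI), and a per-subject random intercept:

    delta_subsequent = b0 + b1 * delta_initial
                       + b2 * log10(age_initial) * ivi
                       + b_subject + eps,
    b_subject ~ N(0, sigma_b^2),   eps ~ N(0, sigma_e^2).

Age and IVI must share one unit within a dataset (years for the human
cohort, weeks for mice).  Fitting is by maximum likelihood (REML optional)
through statsmodels' MixedLM.

Sign convention: a *residual* is predicted minus observed, so a treatment
that lowers delta power produces positive residuals.  This is the
convention used throughout the treatment-effect machinery and is the
opposite of the more common observed-minus-predicted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning


class ModelFitError(RuntimeError):
    """Singular design or non-convergence, with diagnostics in the message."""


@dataclass
class VisitRecord:
    """One visit: subject, age at visit, delta-power value, group label."""

    subject_id: str
    age: float
    delta: float
    group: str = ""
    visit_time: float | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not np.isfinite(self.delta):
            raise ValueError(f"delta must be finite, got {self.delta}")


@dataclass
class LongitudinalPair:
    """One model observation: an (initial, subsequent) visit pair."""

    subject_id: str
    delta_initial: float
    delta_subsequent: float
    age_initial: float
    ivi: float
    group: str = ""

    def __post_init__(self) -> None:
        if self.ivi <= 0:
            raise ValueError(f"ivi must be positive, got {self.ivi}")
        if self.age_initial <= 0:
            raise ValueError(
                f"age_initial must be positive (log10), got {self.age_initial}"
            )
        for name in ("delta_initial", "delta_subsequent"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def pairs_to_frame(pairs: list[LongitudinalPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in pairs],
            "delta_initial": [p.delta_initial for p in pairs],
            "delta_subsequent": [p.delta_subsequent for p in pairs],
            "age_initial": [p.age_initial for p in pairs],
            "ivi": [p.ivi for p in pairs],
            "group": [p.group for p in pairs],
        }
    )


def frame_to_pairs(df: pd.DataFrame) -> list[LongitudinalPair]:
    return [
        LongitudinalPair(
            subject_id=str(r.subject_id),
            delta_initial=float(r.delta_initial),
            delta_subsequent=float(r.delta_subsequent),
            age_initial=float(r.age_initial),
            ivi=float(r.ivi),
            group=str(getattr(r, "group", "") or ""),
        )
        for r in df.itertuples(index=False)
    ]


def build_pairs(
    visits: list[VisitRecord], policy: str = "all_combinations"
) -> list[LongitudinalPair]:
    """Form longitudinal pairs from per-subject visit lists.

    ``policy="consecutive"`` pairs each visit with the next one;
    ``"all_combinations"`` forms every ordered pair (i, j), i < j — for a
    mouse observed over 7 weekly sessions that is C(7,2) = 21 pairs.  The
    IVI is the age difference.  Subjects with fewer than two visits
    contribute nothing; duplicate same-age visits for a subject raise.
    """
    if policy not in ("consecutive", "all_combinations"):
        raise ValueError(f"unknown pairing policy {policy!r}")
    by_subject: dict[str, list[VisitRecord]] = {}
    for v in visits:
        by_subject.setdefault(v.subject_id, []).append(v)
    pairs: list[LongitudinalPair] = []
    for sid, vs in by_subject.items():
        vs = sorted(vs, key=lambda v: v.age)
        ages = [v.age for v in vs]
        if len(set(ages)) != len(ages):
            raise ValueError(f"subject {sid!r} has duplicate same-time visits")
        if policy == "consecutive":
            combos = [(i, i + 1) for i in range(len(vs) - 1)]
        else:
            combos = [
                (i, j) for i in range(len(vs)) for j in range(i + 1, len(vs))
            ]
        for i, j in combos:
            pairs.append(
                LongitudinalPair(
                    subject_id=sid,
                    delta_initial=vs[i].delta,
                    delta_subsequent=vs[j].delta,
                    age_initial=vs[i].age,
                    ivi=vs[j].age - vs[i].age,
                    group=vs[i].group,
                )
            )
    return pairs


@dataclass
class NaturalHistoryFit:
    """Fitted natural-history model.

    ``beta`` holds (intercept, delta_initial, log10(age):ivi) coefficients;
    ``se``/``ci95``/``p`` are per-coefficient Wald summaries with t
    reference on ``df`` = n_pairs − 3 residual degrees of freedom;
    ``sigma_b``/``sigma_e`` are the random-intercept and residual SDs;
    ``rmse`` is computed on population-level residuals (random effect 0).
    """

    beta: np.ndarray
    se: np.ndarray
    ci95: np.ndarray  # (3, 2)
    p: np.ndarray
    sigma_b: float
    sigma_e: float
    rmse: float
    df: int
    n_pairs: int
    n_subjects: int
    aic: float
    units: str = "years"
    method: str = "ml"
    random_effects: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    @property
    def beta1(self) -> float:
        return float(self.beta[1])

    @property
    def beta2(self) -> float:
        return float(self.beta[2])

    def to_dict(self) -> dict:
        names = ["intercept", "delta_initial", "log10_age_x_ivi"]
        return {
            "coefficients": {
                n: {
                    "estimate": float(b),
                    "se": float(s),
                    "ci95": [float(lo), float(hi)],
                    "p": float(pv),
                }
                for n, b, s, (lo, hi), pv in zip(
                    names, self.beta, self.se, self.ci95, self.p
                )
            },
            "sigma_b": self.sigma_b,
            "sigma_e": self.sigma_e,
            "rmse": self.rmse,
            "df": self.df,
            "n_pairs": self.n_pairs,
            "n_subjects": self.n_subjects,
            "aic": self.aic,
            "units": self.units,
            "method": self.method,
            "converged": self.converged,
        }


def _design(df: pd.DataFrame, include_group: bool = False):
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["delta_initial"].to_numpy(float),
            np.log10(df["age_initial"].to_numpy(float))
            * df["ivi"].to_numpy(float),
        ]
    )
    names = ["intercept", "delta_initial", "log10_age_x_ivi"]
    if include_group:
        levels = sorted(df["group"].unique())
        for lev in levels[1:]:
            X = np.column_stack([X, (df["group"] == lev).astype(float)])
            names.append(f"group[{lev}]")
    return X, names


def fit_natural_history(
    pairs: list[LongitudinalPair] | pd.DataFrame,
    method: str = "ml",
    units: str = "years",
    include_group: bool = False,
) -> NaturalHistoryFit:
    """Fit the random-intercept natural-history model by maximum likelihood.

    Requires at least two subjects and three pairs with a full-rank design.
    Wald 95% CIs use estimate ± t(0.975, df)·SE with df = n_pairs − 3.
    Degenerate noise-free inputs (OLS residuals at machine precision) are
    returned exactly with zero variance components, since a mixed model
    cannot be maximised on zero-variance data.
    """
    df = pairs if isinstance(pairs, pd.DataFrame) else pairs_to_frame(pairs)
    n = len(df)
    n_subj = df["subject_id"].nunique()
    if n < 3 or n_subj < 2:
        raise ModelFitError(
            f"need >= 3 pairs and >= 2 subjects, got {n} pairs / {n_subj} subjects"
        )
    X, _ = _design(df, include_group)
    y = df["delta_subsequent"].to_numpy(float)
    cond = np.linalg.cond(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ModelFitError(
            f"singular design matrix (condition number {cond:.3g})"
        )

    k = X.shape[1]
    dof = max(n - k, 1)
    ols_beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ols_resid = y - X @ ols_beta
    if float(np.std(ols_resid)) < 1e-10:
        # noise-free: exact deterministic relation
        beta = ols_beta
        se = np.zeros(k)
        ci = np.column_stack([beta, beta])
        p = np.zeros(k)
        fit = NaturalHistoryFit(
            beta=beta[:3] if not include_group else beta,
            se=se[:3] if not include_group else se,
            ci95=ci[:3] if not include_group else ci,
            p=p[:3] if not include_group else p,
            sigma_b=0.0,
            sigma_e=0.0,
            rmse=float(np.sqrt(np.mean(ols_resid**2))),
            df=dof,
            n_pairs=n,
            n_subjects=n_subj,
            aic=float("nan"),
            units=units,
            method=method,
        )
        return fit

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        mod = MixedLM(y, X, groups=df["subject_id"].to_numpy())
        res = None
        for opt in ("bfgs", "powell"):
            try:
                res = mod.fit(reml=(method == "reml"), method=opt)
            except Exception:
                res = None
            if res is not None and res.converged:
                break
    if res is None or not res.converged:
        # near-zero random-intercept variance puts the MLE on the boundary;
        # there the mixed model degenerates to OLS, which we return
        boundary = (
            res is not None
            and float(np.asarray(res.cov_re)[0, 0]) < 1e-3 * res.scale
        )
        if res is None or boundary:
            return _ols_boundary_fit(
                df, X, y, ols_beta, ols_resid, n, n_subj, dof,
                units, method, include_group,
            )
        raise ModelFitError(
            f"mixed-model optimiser did not converge "
            f"(design condition number {cond:.3g})"
        )

    beta = np.asarray(res.fe_params, dtype=float)
    se = np.asarray(res.bse_fe, dtype=float)
    tq = stats.t.ppf(0.975, dof)
    ci = np.column_stack([beta - tq * se, beta + tq * se])
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    p = 2 * stats.t.sf(np.abs(tvals), dof)
    pop_resid = y - X @ beta
    ranef = {
        str(key): float(np.asarray(val).ravel()[0])
        for key, val in res.random_effects.items()
    }
    return NaturalHistoryFit(
        beta=beta[:3] if not include_group else beta,
        se=se[:3] if not include_group else se,
        ci95=ci[:3] if not include_group else ci,
        p=p[:3] if not include_group else p,
        sigma_b=float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0))),
        sigma_e=float(np.sqrt(res.scale)),
        rmse=float(np.sqrt(np.mean(pop_resid**2))),
        df=dof,
        n_pairs=n,
        n_subjects=n_subj,
        aic=float(res.aic),
        units=units,
        method=method,
        random_effects=ranef,
    )


def _ols_boundary_fit(
    df, X, y, beta, resid, n, n_subj, dof, units, method, include_group
) -> NaturalHistoryFit:
    """ML solution at the sigma_b = 0 boundary (plain least squares)."""
    k = X.shape[1]
    rss = float(resid @ resid)
    sigma_e2 = rss / n  # ML variance
    se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) * (rss / dof))
    tq = stats.t.ppf(0.975, dof)
    ci = np.column_stack([beta - tq * se, beta + tq * se])
    p = 2 * stats.t.sf(np.abs(beta / se), dof)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma_e2) + 1)
    aic = 2 * (k + 2) - 2 * loglik  # k betas + sigma_b (at boundary) + sigma_e
    sl = slice(None) if include_group else slice(0, 3)
    return NaturalHistoryFit(
        beta=beta[sl], se=se[sl], ci95=ci[sl], p=p[sl],
        sigma_b=0.0, sigma_e=float(np.sqrt(sigma_e2)),
        rmse=float(np.sqrt(np.mean(resid**2))),
        df=dof, n_pairs=n, n_subjects=n_subj, aic=float(aic),
        units=units, method=method,
        random_effects={str(s): 0.0 for s in df["subject_id"].unique()},
    )


def predict(
    fit: NaturalHistoryFit,
    delta_initial,
    age_initial,
    ivi,
    subject: str | None = None,
):
    """Predicted delta at the subsequent visit.

    Population mode (``subject=None``) uses a zero random effect; passing a
    subject id adds that subject's empirical-Bayes intercept (unknown ids
    raise).  Vectorised over array inputs.
    """
    delta_initial = np.asarray(delta_initial, dtype=float)
    age_initial = np.asarray(age_initial, dtype=float)
    ivi = np.asarray(ivi, dtype=float)
    if (age_initial <= 0).any():
        raise ValueError("age_initial must be positive")
    if (ivi < 0).any():
        raise ValueError("ivi must be non-negative")
    out = (
        fit.beta0
        + fit.beta1 * delta_initial
        + fit.beta2 * np.log10(age_initial) * ivi
    )
    if subject is not None:
        if subject not in fit.random_effects:
            raise KeyError(
                f"subject {subject!r} unknown to the fit "
                f"({fit.n_subjects} subjects)"
            )
        out = out + fit.random_effects[subject]
    return out if out.ndim else float(out)


def residual(
    fit: NaturalHistoryFit,
    pair: LongitudinalPair,
    mode: str = "population",
) -> float:
    """Model residual, predicted − observed (treatment-lowered delta > 0)."""
    subject = pair.subject_id if mode == "subject" else None
    pred = predict(fit, pair.delta_initial, pair.age_initial, pair.ivi, subject)
    return float(pred - pair.delta_subsequent)


def population_residuals(
    fit: NaturalHistoryFit, pairs: list[LongitudinalPair] | pd.DataFrame
) -> np.ndarray:
    """Vectorised population-level residuals (predicted − observed)."""
    df = pairs if isinstance(pairs, pd.DataFrame) else pairs_to_frame(pairs)
    pred = predict(
        fit,
        df["delta_initial"].to_numpy(float),
        df["age_initial"].to_numpy(float),
        df["ivi"].to_numpy(float),
    )
    return np.asarray(pred) - df["delta_subsequent"].to_numpy(float)


@dataclass
class CrossValidationResult:
    """Per-fold held-out residuals and the pooled RMSE."""

    scheme: str
    fold_residuals: dict[str, np.ndarray]
    rmse: float
    skipped_folds: list[str] = field(default_factory=list)

    @property
    def n_folds(self) -> int:
        return len(self.fold_residuals)


def cross_validate(
    pairs: list[LongitudinalPair] | pd.DataFrame,
    scheme: str = "leave_one_subject_out",
    method: str = "ml",
) -> CrossValidationResult:
    """Leave-one-subject-out or leave-one-week-out cross-validation.

    Folds are subjects, or (for regularly sampled rodent data) the age at
    the subsequent visit rounded to the nearest week.  Each fold is refit
    on the remainder and population-level residuals computed on the
    held-out pairs; the pooled RMSE is reported.  Folds whose removal
    leaves fewer than three training pairs are skipped with a warning.
    """
    df = pairs if isinstance(pairs, pd.DataFrame) else pairs_to_frame(pairs)
    if scheme in ("leave_one_subject_out", "loso"):
        keys = df["subject_id"].astype(str)
    elif scheme in ("leave_one_week_out", "loweek"):
        keys = (
            (df["age_initial"] + df["ivi"]).round().astype(int).astype(str)
        )
    else:
        raise ValueError(f"unknown cross-validation scheme {scheme!r}")
    folds = sorted(keys.unique())
    if len(folds) < 3:
        raise ModelFitError(f"need >= 3 folds, got {len(folds)}")
    fold_res: dict[str, np.ndarray] = {}
    skipped: list[str] = []
    for f in folds:
        train = df[keys != f]
        test = df[keys == f]
        if len(train) < 3 or train["subject_id"].nunique() < 2:
            warnings.warn(
                f"fold {f!r} leaves too little training data; skipped",
                RuntimeWarning, stacklevel=2,
            )
            skipped.append(f)
            continue
        fit = fit_natural_history(train, method=method)
        fold_res[f] = population_residuals(fit, test)
    pooled = np.concatenate(list(fold_res.values()))
    return CrossValidationResult(
        scheme=scheme,
        fold_residuals=fold_res,
        rmse=float(np.sqrt(np.mean(pooled**2))),
        skipped_folds=skipped,
    )


def group_effect_delta_aic(
    pairs: list[LongitudinalPair] | pd.DataFrame, method: str = "ml"
) -> float:
    """AIC(with group fixed effect) − AIC(without).

    Negative values favour including the group (genotype/arm) term; in the
    human data adding genotype did not improve fit, and cohorts generated
    without group effects should change AIC by less than 2 in most
    replicates.
    """
    base = fit_natural_history(pairs, method=method)
    ext = fit_natural_history(pairs, method=method, include_group=True)
    return float(ext.aic - base.aic)
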