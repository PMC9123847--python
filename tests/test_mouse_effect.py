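"""Surrogate-baseline treatment-effect detection in the mouse cohort."""

import numpy as np
import pandas as pd
import pytest

from deltatrack import synthetic
from deltatrack.model import build_pairs, fit_natural_history, VisitRecord
from deltatrack.mouse_effect import (
    MouseCohort,
    cross_age_contrast,
    permutation_null,
    surrogate_residuals,
    treatment_effect_by_week,
)


def _cohort(treatment_effect, seed):
    spec = synthetic.MouseCohortSpec(
        treatment_effect=treatment_effect, seed=seed
    )
    return synthetic.make_mouse_cohort(spec)


def _fit_controls(cohort):
    ctrl = cohort.visits[cohort.visits["group"] == "AS_control"]
    visits = [
        VisitRecord(r.mouse_id, r.age, r.delta, r.group)
        for r in ctrl.itertuples(index=False)
    ]
    return fit_natural_history(build_pairs(visits), units="weeks")


class TestSurrogateResiduals:
    def test_targets_on_model_prediction_have_zero_residual(self, mouse_fit):
        pool = pd.DataFrame(
            {
                "mouse_id": ["a", "b", "c"],
                "delta": [3.0e-3, 3.2e-3, 3.4e-3],
                "age": [7.0, 7.0, 7.0],
            }
        )
        # every pool value predicts the same target when the target equals
        # the prediction from each possible baseline -> impossible unless
        # beta1 = 0; instead check draw-by-draw
        rng = np.random.default_rng(0)
        targets = pd.DataFrame(
            {"mouse_id": ["t1"], "delta": [0.0], "age": [12.0]}
        )
        res = surrogate_residuals(targets, pool, mouse_fit, seed=rng,
                                  n_resamples=200)
        preds = (
            mouse_fit.beta0
            + mouse_fit.beta1 * pool["delta"].to_numpy()
            + mouse_fit.beta2 * np.log10(7.0) * 5.0
        )
        assert set(np.round(res.ravel(), 12)) <= set(np.round(preds, 12))

    def test_shifted_targets_shift_residuals_positively(self, mouse_cohort, mouse_fit):
        pool = mouse_cohort.visits[
            (mouse_cohort.visits["group"] == "AS_control")
            & (mouse_cohort.visits["week"] == 2)
        ]
        targets = mouse_cohort.visits[
            (mouse_cohort.visits["group"] == "AS_control")
            & (mouse_cohort.visits["week"] == 6)
        ]
        base = surrogate_residuals(targets, pool, mouse_fit, True, 1, 500)
        shifted = targets.copy()
        shifted["delta"] -= 1.0e-3
        moved = surrogate_residuals(shifted, pool, mouse_fit, True, 1, 500)
        assert np.allclose(moved - base, 1.0e-3)

    def test_control_self_consistency_median_near_zero(self, mouse_cohort, mouse_fit):
        pool = mouse_cohort.visits[
            (mouse_cohort.visits["group"] == "AS_control")
            & (mouse_cohort.visits["week"] == 2)
        ]
        targets = mouse_cohort.visits[
            (mouse_cohort.visits["group"] == "AS_control")
            & (mouse_cohort.visits["week"] == 5)
        ]
        res = surrogate_residuals(targets, pool, mouse_fit, True, 2, 2000)
        med = np.median(res, axis=1)
        assert abs(med.mean()) < 2.0e-4

    def test_single_mouse_pool_with_self_exclusion_raises(self, mouse_fit):
        pool = pd.DataFrame(
            {"mouse_id": ["a"], "delta": [3e-3], "age": [7.0]}
        )
        targets = pd.DataFrame(
            {"mouse_id": ["a"], "delta": [3e-3], "age": [10.0]}
        )
        with pytest.raises(ValueError):
            surrogate_residuals(targets, pool, mouse_fit, exclude_self=True)


class TestTreatmentEffect:
    def test_injected_additive_effect_recovered(self):
        effects = []
        for k in range(12):
            cohort = _cohort(1.0e-3, seed=100 + k)
            fit = _fit_controls(cohort)
            res = treatment_effect_by_week(
                MouseCohort(cohort.visits), fit, n_resamples=800, seed=k
            )
            effects.extend(r.effect_mean for r in res)
        mean_eff = np.mean(effects)
        assert mean_eff == pytest.approx(1.0e-3, rel=0.10)

    def test_week2_serves_as_initial_visit_only(self, mouse_cohort, mouse_fit):
        res = treatment_effect_by_week(
            MouseCohort(mouse_cohort.visits), mouse_fit, 200, seed=0
        )
        assert [r.week for r in res] == [3, 4, 5, 6, 7, 8]

    def test_no_effect_cohort_effects_small_and_not_significant(self):
        # the baseline-draw CI is conditional on the realised cohort, so the
        # calibrated statement is about the effect scale and the permutation
        # p-values, not the narrow draw CI
        cohort = _cohort(0.0, seed=55)
        fit = _fit_controls(cohort)
        res = permutation_null(MouseCohort(cohort.visits), fit, 1500, seed=1)
        # 3x the sampling SD of a median difference (15 vs 26 mice)
        sigma = 4.5e-4
        scale = 3 * sigma * np.sqrt(np.pi / 2 * (1 / 15 + 1 / 26))
        assert all(abs(r.effect_mean) < scale for r in res)
        assert sum(r.p_value > 0.05 for r in res) >= len(res) - 2


class TestPermutationNull:
    def test_null_distribution_centred_near_zero(self, mouse_cohort, mouse_fit):
        res = permutation_null(
            MouseCohort(mouse_cohort.visits), mouse_fit, 2000, seed=3
        )
        for r in res:
            assert abs(np.mean(r.null_distribution)) < 2.0e-4
            assert 0 <= r.p_value <= 1

    def test_strong_effect_detected(self):
        cohort = _cohort(2.0e-3, seed=77)  # ~4x residual SD
        fit = _fit_controls(cohort)
        res = permutation_null(MouseCohort(cohort.visits), fit, 2000, seed=4)
        assert all(r.p_value < 1e-2 for r in res)

    def test_row_order_invariance(self, mouse_cohort, mouse_fit):
        visits = mouse_cohort.visits
        shuffled = visits.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = permutation_null(MouseCohort(visits), mouse_fit, 500, seed=5)
        b = permutation_null(MouseCohort(shuffled), mouse_fit, 500, seed=5)
        for ra, rb in zip(a, b):
            assert ra.effect_mean == pytest.approx(rb.effect_mean, abs=5e-5)

    def test_type_one_error_roughly_calibrated(self):
        rejections = 0
        n_rep = 60
        for k in range(n_rep):
            cohort = _cohort(0.0, seed=5000 + k)
            fit = _fit_controls(cohort)
            res = permutation_null(
                MouseCohort(cohort.visits), fit, 400, seed=k, weeks=[6]
            )
            rejections += res[0].p_value < 0.05
        # binomial 99.7% envelope around 0.05 at 60 replicates
        assert rejections / n_rep < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_t_distribution_variant_runs(self, mouse_cohort, mouse_fit):
        res = permutation_null(
            MouseCohort(mouse_cohort.visits), mouse_fit, 300, seed=6,
            weeks=[7], method="t_distributions",
        )
        assert res[0].p_method == "t_distributions"
        assert 0 <= res[0].p_value <= 1


class TestCrossAgeContrast:
    def test_constant_effect_recovered_across_age_gap(self):
        cohort = _cohort(1.5e-3, seed=88)
        fit = _fit_controls(cohort)
        out = cross_age_contrast(4, 8, MouseCohort(cohort.visits), fit,
                                 2000, seed=7)
        # plug-in oracle on the realised deltas: the model adjusts for the
        # log10(age)*IVI drift between the two weeks, so the contrast is the
        # median residual difference computed at the mean baseline (the
        # small beta1 makes the median nearly linear in the baseline draw)
        v = cohort.visits
        ctrl = v[v["group"] == "AS_control"]
        pool_mean = ctrl.loc[ctrl["week"] == 2, "delta"].mean()
        b0, b1, b2 = fit.beta
        la = np.log10(7.0)

        def med_resid(deltas, ivi):
            return np.median(b0 + b1 * pool_mean + b2 * la * ivi - deltas)

        t4 = v[(v["group"] == "AS_ASO") & (v["week"] == 4)]["delta"]
        c8 = ctrl[ctrl["week"] == 8]["delta"]
        expected = med_resid(t4.to_numpy(), 2.0) - med_resid(c8.to_numpy(), 6.0)
        assert out["effect_mean"] == pytest.approx(expected, abs=5e-5)
        # and it is recognisably the injected effect despite the age gap
        # (up to per-week working-model lack-of-fit and cohort noise)
        assert out["effect_mean"] == pytest.approx(1.5e-3, abs=6e-4)
        assert out["p_value"] < 0.05

    def test_no_effect_contrast_not_significant_usually(self):
        hits = 0
        for k in range(10):
            cohort = _cohort(0.0, seed=7000 + k)
            fit = _fit_controls(cohort)
            out = cross_age_contrast(4, 8, MouseCohort(cohort.visits), fit,
                                     400, seed=k)
            hits += out["p_value"] < 0.05
        assert hits <= 3
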