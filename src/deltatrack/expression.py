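"""Correlating natural-history residuals with relative *Ube3a* mRNA.

Week-7 model residuals (computed with surrogate week-2 baselines) are
regressed on relative *Ube3a* mRNA measured in the same mice at week 8.
The sample is tiny (8 control + 4 treated mice in the original design), so
instead of a single regression the slope is re-estimated under repeated
random baseline draws — the 12 mice stay fixed; all resampling variability
comes from the surrogate baselines.  The summary is the distribution of
ordinary-least-squares slopes (mV²/Hz per unit relative mRNA) and the
fraction of positive slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import NaturalHistoryFit
from .mouse_effect import surrogate_residuals


@dataclass
class ExpressionRecord:
    """Relative *Ube3a* mRNA for one mouse (1.0 = wild-type control mean)."""

    mouse_id: str
    group: str
    mrna_relative: float
    week_measured: int = 8

    def __post_init__(self) -> None:
        if self.mrna_relative < 0:
            raise ValueError("mrna_relative must be non-negative")


def expression_to_frame(records: list[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mouse_id": [r.mouse_id for r in records],
            "group": [r.group for r in records],
            "mrna_relative": [r.mrna_relative for r in records],
            "week_measured": [r.week_measured for r in records],
        }
    )


@dataclass
class SlopeDistribution:
    """Resampled OLS slopes of residual on relative mRNA."""

    slopes: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.slopes.mean())

    @property
    def sd(self) -> float:
        return float(self.slopes.std(ddof=1))

    @property
    def se(self) -> float:
        return float(self.sd / np.sqrt(len(self.slopes)))

    @property
    def frac_positive(self) -> float:
        return float(np.mean(self.slopes > 0))


def residual_mrna_slopes(
    week7_visits: pd.DataFrame,
    expression: pd.DataFrame | list[ExpressionRecord],
    baseline_pool: pd.DataFrame,
    fit: NaturalHistoryFit,
    n_resamples: int = 1000,
    seed: int | np.random.Generator = 0,
    pool_groups: bool = True,
) -> SlopeDistribution:
    """Distribution of OLS slopes relating model residuals to mRNA levels.

    Every expression record must match a visit in ``week7_visits`` by
    mouse id (unmatched ids raise, listing them); at least three matched
    mice are required.  Per resample, surrogate-baseline residuals are
    recomputed for the matched mice with fresh week-2 draws (control mice
    never draw their own baseline) and the slope of residual on
    ``mrna_relative`` recorded.  ``pool_groups=False`` restricts the
    regression to control mice only (a per-group variant; the default
    pools all matched mice into one regression).
    """
    expr = (
        expression
        if isinstance(expression, pd.DataFrame)
        else expression_to_frame(expression)
    )
    visits = week7_visits.set_index("mouse_id")
    unmatched = [m for m in expr["mouse_id"] if m not in visits.index]
    if unmatched:
        raise ValueError(
            f"expression records without a matching visit: {unmatched}"
        )
    if not pool_groups:
        expr = expr[expr["group"] != "AS_ASO"]
    if len(expr) < 3:
        raise ValueError(f"need >= 3 matched mice, got {len(expr)}")
    targets = visits.loc[expr["mouse_id"]].reset_index()
    exclude = np.isin(
        targets["mouse_id"].to_numpy(), baseline_pool["mouse_id"].to_numpy()
    )
    rng = np.random.default_rng(seed)
    # control mice must not draw their own week-2 baseline
    res = np.empty((n_resamples, len(targets)))
    if exclude.any():
        res[:, exclude] = surrogate_residuals(
            targets[exclude], baseline_pool, fit, True, rng, n_resamples
        ).reshape(n_resamples, -1)
    if (~exclude).any():
        res[:, ~exclude] = surrogate_residuals(
            targets[~exclude], baseline_pool, fit, False, rng, n_resamples
        ).reshape(n_resamples, -1)
    x = expr["mrna_relative"].to_numpy(float)
    xc = x - x.mean()
    denom = float((xc**2).sum())
    if denom == 0:
        raise ValueError("mRNA values are constant; slope undefined")
    slopes = (res - res.mean(axis=1, keepdims=True)) @ xc / denom
    return SlopeDistribution(slopes=slopes)
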