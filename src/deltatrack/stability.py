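"""Precision of a delta-power estimate as a function of data amount.

Relative delta power is an average of per-second interval values; how much
EEG is needed for a stable estimate is answered empirically by resampling:
draw subsets of the per-interval values (random 1 s epochs, or contiguous
stretches started at random positions), average each subset, and summarise
the spread of the subset means.  The SEM reported here is the standard
deviation across resampled means — under temporal drift (e.g. circadian
structure) this differs from the analytic s/√n, which is the point of the
contiguous variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class StabilityCurve:
    """SEM of the delta estimate versus amount of data.

    ``sample_sizes`` are epoch counts (random mode) or contiguous durations
    in seconds; ``sem[i]`` is the sample standard deviation (ddof=1) of the
    ``n_reps`` resampled means at ``sample_sizes[i]`` and ``ci95[i]`` their
    empirical 2.5/97.5 percentiles.
    """

    sample_sizes: np.ndarray
    sem: np.ndarray
    ci95: np.ndarray  # shape (n_sizes, 2)
    n_reps: int
    mode: str

    def __post_init__(self) -> None:
        self.sample_sizes = np.asarray(self.sample_sizes)
        self.sem = np.asarray(self.sem, dtype=float)
        self.ci95 = np.asarray(self.ci95, dtype=float)
        if not (len(self.sample_sizes) == len(self.sem) == len(self.ci95)):
            raise ValueError("sample_sizes, sem and ci95 lengths disagree")
        if (self.sem < 0).any():
            raise ValueError("sem must be non-negative")
        if (self.ci95[:, 0] > self.ci95[:, 1] + 1e-12).any():
            raise ValueError("ci95 lower bound exceeds upper bound")


def sem_random_epochs(
    per_interval: np.ndarray,
    sizes: list[int] | np.ndarray,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> StabilityCurve:
    """SEM curve from randomly sampled (without replacement) 1 s epochs.

    For each size ``n``, ``n_reps`` subsets of ``n`` distinct intervals are
    drawn and averaged; the curve summarises the spread of those means.
    """
    x = np.asarray(per_interval, dtype=float)
    sizes = np.asarray(sizes, dtype=int)
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 to estimate a spread")
    for n in sizes:
        if n < 1 or n > len(x):
            raise ValueError(
                f"epoch count {n} exceeds the {len(x)} available intervals"
            )
    rng = np.random.default_rng(seed)
    sem, ci = [], []
    for n in sizes:
        if n == len(x):
            means = np.full(n_reps, x.mean())
        else:
            draws = np.empty((n_reps, n))
            for r in range(n_reps):
                draws[r] = x[rng.choice(len(x), size=n, replace=False)]
            means = draws.mean(axis=1)
        sem.append(means.std(ddof=1))
        ci.append(np.percentile(means, [2.5, 97.5]))
    return StabilityCurve(sizes, np.array(sem), np.array(ci), n_reps, "random")


def sem_contiguous_epochs(
    per_interval: np.ndarray,
    durations_s: list[int] | np.ndarray,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> StabilityCurve:
    """SEM curve from contiguous epochs at random start positions.

    Per-interval values are assumed to be consecutive 1 s estimates; a
    draw of duration ``d`` averages ``d`` consecutive values starting at a
    uniform position in ``[0, span - d]`` (no wraparound — recordings are
    not circular).
    """
    x = np.asarray(per_interval, dtype=float)
    durations = np.asarray(durations_s, dtype=int)
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 to estimate a spread")
    for d in durations:
        if d < 1 or d > len(x):
            raise ValueError(
                f"duration {d} s exceeds the {len(x)} s recording span"
            )
    rng = np.random.default_rng(seed)
    csum = np.concatenate([[0.0], np.cumsum(x)])
    sem, ci = [], []
    for d in durations:
        starts = rng.integers(0, len(x) - d + 1, size=n_reps)
        means = (csum[starts + d] - csum[starts]) / d
        sem.append(means.std(ddof=1))
        ci.append(np.percentile(means, [2.5, 97.5]))
    return StabilityCurve(
        durations, np.array(sem), np.array(ci), n_reps, "contiguous"
    )
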