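"""Readers, writers, configuration and the end-to-end pipeline.

EDF recordings are read through MNE with case-insensitive 10–20 channel
selection; wake staging is always an *input* (a sidecar CSV of intervals),
never computed.  A minimal EDF writer is included so synthetic recordings
can be round-tripped through the standard format (16-bit, 1 s records).
Tabular data (visits, pairs, expression, curves) travel as CSV with fixed
schemas; fit and effect reports as JSON; configuration as YAML.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectral import TimeSeriesRecording

VISITS_COLUMNS = ["subject_id", "age", "delta", "group"]
PAIRS_COLUMNS = [
    "subject_id", "delta_initial", "delta_subsequent", "age_initial", "ivi",
]
MOUSE_COLUMNS = ["mouse_id", "group", "week", "age", "delta"]
EXPRESSION_COLUMNS = ["mouse_id", "group", "mrna_relative"]


# --------------------------------------------------------------------------
# EDF
# --------------------------------------------------------------------------

def read_eeg(
    path: str | Path,
    channels: list[str] | None = None,
    wake_sidecar: str | Path | None = None,
    units: str = "uV",
) -> TimeSeriesRecording:
    """Read an EDF recording into a :class:`TimeSeriesRecording`.

    Channel selection is case-insensitive on the 10–20 labels; a missing
    channel raises listing the available labels.  ``units`` selects the
    output scale ("uV" for scalp EEG, "mV" for LFP).  The optional sidecar
    is a headerless or headed CSV of ``start,end`` second intervals marked
    wake.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    except Exception as exc:
        raise OSError(f"could not parse {path} as EDF: {exc}") from exc
    available = raw.ch_names
    if channels is None:
        picks = list(range(len(available)))
        labels = list(available)
    else:
        lowered = {c.lower(): i for i, c in enumerate(available)}
        picks, labels = [], []
        for ch in channels:
            if ch.lower() not in lowered:
                raise KeyError(
                    f"channel {ch!r} not found; available: {available}"
                )
            picks.append(lowered[ch.lower()])
            labels.append(available[lowered[ch.lower()]])
    data = raw.get_data(picks=picks)  # Volts
    scale = {"uV": 1e6, "mV": 1e3, "V": 1.0}[units]
    mask = read_wake_sidecar(wake_sidecar) if wake_sidecar else None
    return TimeSeriesRecording(
        samples=data * scale,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        wake_mask=mask,
    )


def read_wake_sidecar(path: str | Path) -> list[tuple[float, float]]:
    """Wake intervals from a CSV with (start, end) seconds per row."""
    df = pd.read_csv(path, header=None, comment="#")
    if isinstance(df.iloc[0, 0], str):  # headed file
        df = pd.read_csv(path, comment="#")
    arr = df.iloc[:, :2].to_numpy(float)
    return [(float(a), float(b)) for a, b in arr]


def write_edf(
    rec: TimeSeriesRecording, path: str | Path, physical_dim: str = "uV"
) -> None:
    """Write a recording as 16-bit EDF (1 s data records).

    A deliberately minimal writer for synthetic recordings and round-trip
    tests; it requires an integer sampling rate and truncates a trailing
    partial second.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    ns = rec.n_channels
    n_records = rec.samples.shape[1] // fs
    if n_records == 0:
        raise ValueError("recording shorter than one data record")

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    pmin = rec.samples.min(axis=1)
    pmax = rec.samples.max(axis=1)
    span = np.where(pmax - pmin > 0, pmax - pmin, 1.0)
    dmin, dmax = -32768, 32767

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate X X X X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (ns + 1)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )
    fields = [
        ("label", 16, list(rec.channel_labels)),
        ("transducer", 80, [""] * ns),
        ("dim", 8, [physical_dim] * ns),
        ("pmin", 8, [f"{v:.6g}"[:8] for v in pmin]),
        ("pmax", 8, [f"{v:.6g}"[:8] for v in pmax]),
        ("dmin", 8, [str(dmin)] * ns),
        ("dmax", 8, [str(dmax)] * ns),
        ("prefilter", 80, [""] * ns),
        ("nsamp", 8, [str(fs)] * ns),
        ("reserved", 32, [""] * ns),
    ]
    for _, width, values in fields:
        header += b"".join(pad(v, width) for v in values)

    pmin_f = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_f = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    span = np.where(pmax_f - pmin_f > 0, pmax_f - pmin_f, 1.0)
    digital = np.rint(
        (rec.samples[:, : n_records * fs] - pmin_f[:, None]) / span[:, None]
        * (dmax - dmin) + dmin
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


# --------------------------------------------------------------------------
# tabular schemas
# --------------------------------------------------------------------------

def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_visits(path: str | Path) -> pd.DataFrame:
    return _read_table(path, VISITS_COLUMNS)


def read_pairs(path: str | Path) -> pd.DataFrame:
    return _read_table(path, PAIRS_COLUMNS)


def read_mouse_visits(path: str | Path) -> pd.DataFrame:
    return _read_table(path, MOUSE_COLUMNS)


def read_expression(path: str | Path) -> pd.DataFrame:
    return _read_table(path, EXPRESSION_COLUMNS)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


# --------------------------------------------------------------------------
# configuration and pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated end-to-end pipeline settings.

    Every stochastic stage derives its stream from ``seed``; ``units``
    must be consistent across stages ("years" for the human arm, "weeks"
    for the mouse arm — the human power simulation runs in years, the
    mouse effect detection in weeks).
    """

    seed: int = 0
    outdir: str = "deltatrack_out"
    units_human: str = "years"
    units_mouse: str = "weeks"
    channel_subset: tuple[str, ...] = ("O1", "O2", "P3", "Pz", "P4")
    alpha: float = 0.05
    n_power_sims: int = 2000
    power_group_sizes: tuple[int, ...] = (25, 50, 100, 150)
    power_offsets: tuple[float, float, float] = (0.0, 0.1, 0.002)  # lo, hi, step
    n_effect_resamples: int = 10_000
    n_slope_resamples: int = 1000
    stages: tuple[str, ...] = ("human", "power", "mouse", "expression")

    def validate(self) -> None:
        if self.units_human not in ("years",) or self.units_mouse not in ("weeks",):
            raise ValueError(
                "units mismatch: human stages run in years, mouse stages in "
                f"weeks (got {self.units_human!r}/{self.units_mouse!r})"
            )
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("n_power_sims", "n_effect_resamples", "n_slope_resamples"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        unknown = set(self.stages) - {"human", "power", "mouse", "expression"}
        if unknown:
            raise ValueError(f"unknown pipeline stages {sorted(unknown)}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    for key in ("channel_subset", "power_group_sizes", "power_offsets", "stages"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Synthetic end-to-end run: simulate, fit, validate, and test.

    Executes the configured stages (human fit + CV, trial power, mouse
    treatment effect, expression slopes) on synthetic cohorts, writing CSV
    and JSON artifacts plus a run log capturing the seed, configuration
    and library versions.  Any stage failure aborts with the stage name;
    artifacts already written are left in place.
    """
    from . import __version__, model, synthetic, trialpower
    from .expression import residual_mrna_slopes
    from .mouse_effect import MouseCohort, permutation_null

    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    stage = "setup"
    try:
        stage = "human"
        human = synthetic.make_human_cohort(
            synthetic.HumanCohortSpec(seed=config.seed)
        )
        write_table(human.visits, out / "human_visits.csv")
        write_table(human.pairs, out / "human_pairs.csv")
        fit = model.fit_natural_history(human.pairs, units=config.units_human)
        write_json(fit.to_dict(), out / "human_fit.json")
        cv = model.cross_validate(human.pairs, "leave_one_subject_out")
        write_json(
            {"scheme": cv.scheme, "rmse": cv.rmse, "n_folds": cv.n_folds},
            out / "human_cv.json",
        )
        report["human"] = {"fit": fit.to_dict(), "cv_rmse": cv.rmse}

        if "power" in config.stages:
            stage = "power"
            lo, hi, step = config.power_offsets
            curve = trialpower.power_curve(
                human.pairs, fit,
                offsets=np.arange(lo, hi + step / 2, step),
                group_sizes=config.power_group_sizes,
                n_sims=config.n_power_sims,
                alpha=config.alpha,
                seed=np.random.default_rng([config.seed, 1]),
            )
            surface = pd.DataFrame(
                curve.power, index=curve.group_sizes, columns=curve.offsets
            )
            surface.index.name = "n_per_group"
            surface.to_csv(out / "power_surface.csv")
            write_json(
                {
                    "alpha": curve.alpha,
                    "n_sims": curve.n_sims,
                    "offset_for_80_power": curve.offset_for_80_power,
                    "clamp_fraction": curve.clamp_fraction,
                },
                out / "power_thresholds.json",
            )
            report["power"] = curve.offset_for_80_power

        if "mouse" in config.stages or "expression" in config.stages:
            stage = "mouse"
            mouse = synthetic.make_mouse_cohort(
                synthetic.MouseCohortSpec(seed=config.seed)
            )
            write_table(mouse.visits, out / "mouse_visits.csv")
            ctrl = mouse.visits[mouse.visits["group"] == "AS_control"]
            m_visits = [
                model.VisitRecord(r.mouse_id, r.age, r.delta, r.group)
                for r in ctrl.itertuples(index=False)
            ]
            m_pairs = model.build_pairs(m_visits, "all_combinations")
            m_fit = model.fit_natural_history(m_pairs, units=config.units_mouse)
            write_json(m_fit.to_dict(), out / "mouse_fit.json")
            report["mouse_fit"] = m_fit.to_dict()

        if "mouse" in config.stages:
            cohort = MouseCohort(mouse.visits)
            effects = permutation_null(
                cohort, m_fit,
                n_resamples=config.n_effect_resamples,
                seed=np.random.default_rng([config.seed, 2]),
            )
            eff_report = [
                {
                    "week": e.week,
                    "effect_mean": e.effect_mean,
                    "ci95": list(e.ci95),
                    "p_value": e.p_value,
                }
                for e in effects
            ]
            write_json({"effects": eff_report}, out / "mouse_effects.json")
            report["mouse_effects"] = eff_report

        if "expression" in config.stages:
            stage = "expression"
            ctrl_ids = sorted(
                mouse.visits.loc[
                    mouse.visits["group"] == "AS_control", "mouse_id"
                ].unique()
            )[:8]
            aso_ids = sorted(
                mouse.visits.loc[
                    mouse.visits["group"] == "AS_ASO", "mouse_id"
                ].unique()
            )[:4]
            expr = synthetic.make_expression(
                mouse, seed=np.random.default_rng([config.seed, 3]),
                mice=ctrl_ids + aso_ids,
            )
            write_table(expr, out / "expression.csv")
            week7 = mouse.visits[
                (mouse.visits["week"] == 7)
                & mouse.visits["mouse_id"].isin(expr["mouse_id"])
            ]
            pool = mouse.visits[
                (mouse.visits["group"] == "AS_control")
                & (mouse.visits["week"] == 2)
            ]
            slopes = residual_mrna_slopes(
                week7, expr, pool, m_fit,
                n_resamples=config.n_slope_resamples,
                seed=np.random.default_rng([config.seed, 4]),
            )
            write_json(
                {
                    "mean": slopes.mean,
                    "sd": slopes.sd,
                    "se": slopes.se,
                    "frac_positive": slopes.frac_positive,
                },
                out / "mrna_slopes.json",
            )
            report["mrna_slope"] = {
                "mean": slopes.mean, "frac_positive": slopes.frac_positive
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    log = {
        "config": asdict(config),
        "versions": {
            "deltatrack": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    write_json(log, out / "run_log.json")
    report["log"] = log
    return report
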