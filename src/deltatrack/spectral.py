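"""Band-power estimation for scalp EEG and intracranial LFP.

Two estimators are provided, matching the two arms of the Angelman syndrome
delta-power analysis:

* :func:`relative_delta_power` — human scalp EEG.  Non-overlapping 1 s
  Hanning-tapered power spectra (1 Hz resolution) on average-referenced
  posterior channels; per interval, the summed 2–4 Hz power averaged over
  channels is divided by the summed 1–50 Hz power averaged over channels,
  and the per-interval ratios are averaged into a single unitless value in
  [0, 1].

* :func:`absolute_delta_peak` — mouse visual-cortex LFP.  DPSS multitaper
  spectra (5 tapers, time–bandwidth product 3, 5 s windows with 1 s
  overlap), averaged over windows and hemispheres; the estimate is the peak
  of the averaged spectrum between 1 and 5 Hz, in mV²/Hz.

Spectra use one-sided density scaling, so for broadband signals the summed
power across bins times the bin width approximates the signal variance
(Parseval, up to taper normalisation).  Each window is demeaned before
tapering to keep DC from bleeding into the 1 Hz bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal


class ChannelNotFoundError(KeyError):
    """A requested channel label is not present in the recording."""


class InsufficientDataError(ValueError):
    """The recording is too short (or too masked) for the requested windows."""


@dataclass
class TimeSeriesRecording:
    """Multichannel signal with sampling rate and optional wake mask.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal, µV for scalp EEG or mV for LFP.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names (10–20 labels for EEG, hemisphere labels for
        LFP).
    wake_mask : list of (start, end) or None
        Half-open ``[start, end)`` intervals in seconds marked as wake.
        When present, only wake data enter spectral estimates.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    wake_mask: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        dur = self.duration_s
        if self.wake_mask is not None:
            for lo, hi in self.wake_mask:
                if not (0 <= lo < hi <= dur + 1e-9):
                    raise ValueError(
                        f"wake interval [{lo}, {hi}) outside recording "
                        f"of duration {dur:.3f} s"
                    )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel_index(self, label: str) -> int:
        """Case-insensitive channel lookup."""
        lowered = [c.lower() for c in self.channel_labels]
        try:
            return lowered.index(label.lower())
        except ValueError:
            raise ChannelNotFoundError(
                f"channel {label!r} not in {self.channel_labels}"
            ) from None


#: Posterior electrodes used for the human relative delta estimate.
POSTERIOR_CHANNELS = ("O1", "O2", "P3", "Pz", "P4")


@dataclass
class SpectralConfig:
    """Windowing and band parameters for delta-power estimation.

    ``taper`` is either ``"hann"`` or ``("dpss", NW, K)``; band edges are
    inclusive in the bin-selection sense documented on the estimators.
    """

    window_s: float = 1.0
    overlap_s: float = 0.0
    taper: object = "hann"
    band_delta: tuple[float, float] = (2.0, 4.0)
    band_total: tuple[float, float] = (1.0, 50.0)
    channel_subset: tuple[str, ...] | None = None
    #: "ratio_of_means" divides channel-averaged band sums (default, the
    #: published word order); "mean_of_ratios" averages per-channel ratios.
    channel_combine: str = "ratio_of_means"

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_s < self.window_s:
            raise ValueError(
                f"need 0 <= overlap ({self.overlap_s}) < window ({self.window_s})"
            )


#: Default config for the human relative delta estimate.
HUMAN_EEG_CONFIG = SpectralConfig(
    window_s=1.0, overlap_s=0.0, taper="hann",
    band_delta=(2.0, 4.0), band_total=(1.0, 50.0),
    channel_subset=POSTERIOR_CHANNELS,
)

#: Default config for the mouse absolute delta-peak estimate.
MOUSE_LFP_CONFIG = SpectralConfig(
    window_s=5.0, overlap_s=1.0, taper=("dpss", 3, 5),
    band_delta=(1.0, 5.0), band_total=(1.0, 5.0),
)


@dataclass
class DeltaEstimate:
    """A scalar delta-power value with its per-interval support.

    ``mode`` is ``"relative"`` (unitless, in [0, 1], mean over intervals of
    the per-interval band ratio) or ``"absolute_peak"`` (mV²/Hz, peak of the
    window- and hemisphere-averaged spectrum in the delta band).
    """

    value: float
    per_interval: np.ndarray
    mode: str
    n_dropped: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def n_intervals(self) -> int:
        return len(self.per_interval)

    @property
    def sem(self) -> float:
        if self.n_intervals < 2:
            return float("nan")
        return float(
            np.std(self.per_interval, ddof=1) / np.sqrt(self.n_intervals)
        )


def rereference_average(
    rec: TimeSeriesRecording, subset: list[str] | tuple[str, ...]
) -> TimeSeriesRecording:
    """Re-reference a channel subset to its instantaneous group average.

    Returns a recording containing only ``subset``, with the mean across
    the subset subtracted from every channel at every sample; the output
    channels sum to zero at each sample.
    """
    idx = [rec.channel_index(c) for c in subset]
    sub = rec.samples[idx]
    ref = sub - sub.mean(axis=0, keepdims=True)
    return TimeSeriesRecording(
        samples=ref,
        fs=rec.fs,
        channel_labels=[rec.channel_labels[i] for i in idx],
        wake_mask=rec.wake_mask,
    )


def _wake_segments(rec: TimeSeriesRecording) -> list[np.ndarray]:
    """Split samples into contiguous analysis segments (whole file, or the
    wake intervals when a mask is present)."""
    if rec.wake_mask is None:
        return [rec.samples]
    segs = []
    for lo, hi in rec.wake_mask:
        i0, i1 = int(round(lo * rec.fs)), int(round(hi * rec.fs))
        segs.append(rec.samples[:, i0:i1])
    return segs


def _dpss_spectra(seg: np.ndarray, fs: float, cfg: SpectralConfig):
    """Multitaper spectra of one segment: (n_windows, n_channels, n_freqs)."""
    _, nw, n_tapers = cfg.taper
    nper = int(round(cfg.window_s * fs))
    step = nper - int(round(cfg.overlap_s * fs))
    n_win = 1 + (seg.shape[1] - nper) // step if seg.shape[1] >= nper else 0
    if n_win == 0:
        return None, None
    tapers = signal.windows.dpss(nper, nw, n_tapers)  # (K, nper), sum w^2 = 1
    starts = np.arange(n_win) * step
    frames = np.stack([seg[:, s:s + nper] for s in starts])  # (W, C, nper)
    frames = frames - frames.mean(axis=-1, keepdims=True)
    # (K, W, C, nfreq): per-taper eigenspectra, then average over tapers
    spec = np.fft.rfft(frames[None, :, :, :] * tapers[:, None, None, :], axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=0) / fs
    psd[..., 1:-1] *= 2.0  # one-sided
    freqs = np.fft.rfftfreq(nper, d=1 / fs)
    return freqs, psd


def windowed_power_spectrum(rec: TimeSeriesRecording, cfg: SpectralConfig):
    """Per-window, per-channel one-sided power spectra.

    Returns ``(freqs, psd)`` with ``psd`` of shape
    ``(n_windows, n_channels, n_freqs)`` in density scaling (power per Hz;
    bin spacing is ``1 / window_s``).  Windows are demeaned before
    tapering; partial trailing windows are discarded; when a wake mask is
    present, windows are drawn only from within wake intervals.
    """
    nper = int(round(cfg.window_s * rec.fs))
    noverlap = int(round(cfg.overlap_s * rec.fs))
    segs = _wake_segments(rec)
    chunks = []
    freqs = None
    for seg in segs:
        if seg.shape[1] < nper:
            continue
        if cfg.taper == "hann":
            f, _, p = signal.spectrogram(
                seg, fs=rec.fs, window="hann", nperseg=nper,
                noverlap=noverlap, detrend="constant",
                scaling="density", mode="psd",
            )
            chunks.append(np.moveaxis(p, -1, 0))  # (W, C, F)
            freqs = f
        elif isinstance(cfg.taper, tuple) and cfg.taper[0] == "dpss":
            f, p = _dpss_spectra(seg, rec.fs, cfg)
            if p is not None:
                chunks.append(p)
                freqs = f
        else:
            raise ValueError(f"unknown taper {cfg.taper!r}")
    if not chunks:
        raise InsufficientDataError(
            f"no complete {cfg.window_s} s window in a recording of "
            f"{rec.duration_s:.3f} s (wake-masked)"
        )
    return freqs, np.concatenate(chunks, axis=0)


def _band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    return (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)


def relative_delta_power(
    rec: TimeSeriesRecording, cfg: SpectralConfig = HUMAN_EEG_CONFIG
) -> DeltaEstimate:
    """Relative delta power: mean over intervals of (delta power)/(total power).

    With 1 s windows the delta band 2–4 Hz covers the three bins
    {2, 3, 4} Hz and the total band 1–50 Hz the fifty bins {1..50} Hz, both
    inclusive.  Per interval the band sums are averaged over channels first
    and the ratio taken second (``cfg.channel_combine`` switches to
    per-channel ratios).  Intervals with zero total power are dropped and
    counted; an all-dropped recording raises :class:`InsufficientDataError`.
    """
    freqs, psd = windowed_power_spectrum(rec, cfg)
    delta = psd[:, :, _band_bins(freqs, cfg.band_delta)].sum(axis=2)
    total = psd[:, :, _band_bins(freqs, cfg.band_total)].sum(axis=2)
    if cfg.channel_combine == "ratio_of_means":
        num, den = delta.mean(axis=1), total.mean(axis=1)
    elif cfg.channel_combine == "mean_of_ratios":
        with np.errstate(invalid="ignore", divide="ignore"):
            per_chan = np.where(total > 0, delta / np.where(total > 0, total, 1), np.nan)
        num, den = np.nanmean(per_chan, axis=1), np.ones(delta.shape[0])
    else:
        raise ValueError(f"unknown channel_combine {cfg.channel_combine!r}")
    ok = den > 0
    if cfg.channel_combine == "mean_of_ratios":
        ok = np.isfinite(num)
    n_dropped = int((~ok).sum())
    if not ok.any():
        raise InsufficientDataError("every interval had zero total power")
    ratios = num[ok] / den[ok]
    return DeltaEstimate(
        value=float(ratios.mean()),
        per_interval=ratios,
        mode="relative",
        n_dropped=n_dropped,
    )


def absolute_delta_peak(
    rec: TimeSeriesRecording,
    cfg: SpectralConfig = MOUSE_LFP_CONFIG,
    last_minutes: float | None = 10.0,
    z_thresh: float | None = None,
) -> DeltaEstimate:
    """Absolute delta activity: peak of the averaged LFP spectrum in 1–5 Hz.

    Multitaper spectra per hemisphere are averaged over windows, then
    across hemispheres, and the maximum over frequency bins in
    ``cfg.band_delta`` (inclusive) is returned, in mV²/Hz.  Analysis is
    restricted to the trailing ``last_minutes`` of the recording.  When
    ``z_thresh`` is given, noisy channels are excluded first via
    :func:`exclude_noisy_channels`; losing one hemisphere warns, losing all
    raises.
    """
    notes: list[str] = []
    if z_thresh is not None:
        rec, report = exclude_noisy_channels(rec, z_thresh)
        notes.extend(report)
        if rec.n_channels == 1:
            warnings.warn(
                "one hemisphere excluded as noisy; single-hemisphere estimate",
                RuntimeWarning, stacklevel=2,
            )
    if last_minutes is not None:
        n_keep = int(round(last_minutes * 60 * rec.fs))
        if rec.samples.shape[1] > n_keep:
            rec = TimeSeriesRecording(
                rec.samples[:, -n_keep:], rec.fs, list(rec.channel_labels)
            )
    freqs, psd = windowed_power_spectrum(rec, cfg)
    mean_spec = psd.mean(axis=(0, 1))  # windows, then hemispheres
    inband = _band_bins(freqs, cfg.band_delta)
    per_window = psd.mean(axis=1)[:, inband].max(axis=1)
    return DeltaEstimate(
        value=float(mean_spec[inband].max()),
        per_interval=per_window,
        mode="absolute_peak",
        notes=notes,
    )


def exclude_noisy_channels(
    rec: TimeSeriesRecording,
    z_thresh: float = 3.0,
    saturation_s: float = 0.1,
) -> tuple[TimeSeriesRecording, list[str]]:
    """Drop channels with outlying broadband power or rail saturation.

    A channel is excluded when the robust z-score of its log total power
    (deviation from the cohort median, scaled by 1.4826·MAD) exceeds
    ``z_thresh`` in absolute value, or when it sits at its extreme (rail)
    value for at least ``saturation_s`` consecutive seconds.  Returns the
    cleaned recording and a report of exclusions with reasons.  If every
    channel would be excluded the original recording is returned with the
    report (downstream estimators decide whether that is fatal).
    """
    logp = np.log(np.mean(rec.samples**2, axis=1) + np.finfo(float).tiny)
    dev = logp - np.median(logp)
    scale = 1.4826 * np.median(np.abs(dev))
    if scale > 0:
        z = dev / scale
    else:
        z = np.where(dev == 0, 0.0, np.where(dev > 0, np.inf, -np.inf))
    n_sat = max(1, int(round(saturation_s * rec.fs)))
    report, keep = [], []
    for i, label in enumerate(rec.channel_labels):
        reasons = []
        if abs(z[i]) > z_thresh:
            reasons.append(f"log-power robust z = {z[i]:.2f} > {z_thresh}")
        x = rec.samples[i]
        for rail in (x.min(), x.max()):
            run = _longest_run(x == rail)
            if run >= n_sat:
                reasons.append(
                    f"saturated at {rail:g} for {run / rec.fs:.3f} s"
                )
                break
        if reasons:
            report.append(f"{label}: excluded ({'; '.join(reasons)})")
        else:
            keep.append(i)
    if not keep:
        return rec, report + ["all channels flagged; none removed"]
    if len(keep) == rec.n_channels:
        return rec, report
    return (
        TimeSeriesRecording(
            rec.samples[keep], rec.fs,
            [rec.channel_labels[i] for i in keep], rec.wake_mask,
        ),
        report,
    )


def _longest_run(mask: np.ndarray) -> int:
    if not mask.any():
        return 0
    padded = np.concatenate([[0], mask.astype(int), [0]])
    edges = np.flatnonzero(np.diff(padded))
    return int((edges[1::2] - edges[::2]).max())
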