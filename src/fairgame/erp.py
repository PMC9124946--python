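"""ERP preprocessing and peak measurement.

Implements the stimulus-locked ERP chain: zero-phase Butterworth band-pass,
epoching with pre-stimulus baseline correction, amplitude-threshold artifact
rejection, per-condition averaging, and windowed peak detection for the four
analyzed components (fronto-central N1/P2/MFN, posterior-parietal LPC).

Epoch containers are plain numpy arrays shaped ``(n_trials, n_channels,
n_samples)`` in microvolts, with an accompanying time axis in milliseconds.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "FilterSpec",
    "EpochSpec",
    "ComponentWindow",
    "COMPONENT_WINDOWS",
    "SITE_GROUPS",
    "PeakMeasurement",
    "bandpass",
    "extract_epochs",
    "baseline_correct",
    "epoch_and_baseline",
    "reject_artifacts",
    "average_condition",
    "detect_peak",
    "measure_components",
    "measurement_capacity",
    "default_times_ms",
]

#: Midline electrodes entering the quantitative analysis, by scalp region.
SITE_GROUPS = {
    "fronto-central": ("Fz", "FCz"),
    "posterior-parietal": ("Pz", "CPz"),
}


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass IIR Butterworth, applied forward-backward (zero phase).

    The default 6th order corresponds to a -36 dB/octave roll-off per pass.
    """

    low_hz: float = 0.1
    high_hz: float = 32.0
    order: int = 6


@dataclass(frozen=True)
class EpochSpec:
    """Epoch window and baseline relative to the stimulus marker."""

    tmin_ms: float = -200.0
    tmax_ms: float = 800.0
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    reject_threshold_uv: float = 100.0

    def __post_init__(self):
        b0, b1 = self.baseline_ms
        if not (self.tmin_ms <= b0 < b1 <= self.tmax_ms):
            raise ValueError("baseline must lie inside the epoch window")
        if self.reject_threshold_uv <= 0:
            raise ValueError("rejection threshold must be positive")


@dataclass(frozen=True)
class ComponentWindow:
    """Analysis window for one ERP component."""

    component: str
    polarity: str  # "negative" or "positive"
    tmin_ms: float
    tmax_ms: float
    site_group: str

    def __post_init__(self):
        if self.tmin_ms >= self.tmax_ms:
            raise ValueError("tmin must precede tmax")
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")

    @property
    def electrodes(self) -> tuple[str, ...]:
        return SITE_GROUPS[self.site_group]


#: The four analyzed components and their default windows (ms post-stimulus).
COMPONENT_WINDOWS = {
    "N1": ComponentWindow("N1", "negative", 110.0, 160.0, "fronto-central"),
    "P2": ComponentWindow("P2", "positive", 180.0, 240.0, "fronto-central"),
    "MFN": ComponentWindow("MFN", "negative", 260.0, 400.0, "fronto-central"),
    "LPC": ComponentWindow("LPC", "positive", 430.0, 630.0, "posterior-parietal"),
}


@dataclass
class PeakMeasurement:
    participant: str
    condition: str
    component: str
    electrode: str
    replicate: int
    identified: bool
    latency_ms: float | None = None
    amplitude_uv: float | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_times_ms(sfreq: float = 1024.0, tmin_ms: float = -200.0,
                     tmax_ms: float = 800.0) -> np.ndarray:
    """Sample times (ms) of an epoch [tmin, tmax) at ``sfreq``."""
    n = int(round((tmax_ms - tmin_ms) / 1000.0 * sfreq))
    return tmin_ms + np.arange(n) * 1000.0 / sfreq


# ---------------------------------------------------------------------------
# filtering / epoching
# ---------------------------------------------------------------------------

def bandpass(data: np.ndarray, sfreq: float, spec: FilterSpec = FilterSpec(),
             axis: int = -1) -> np.ndarray:
    """Zero-phase band-pass filter along ``axis``.

    Forward-backward application (``sosfiltfilt``) doubles the effective
    roll-off and cancels the group delay, so peak latencies are unbiased.
    """
    nyq = sfreq / 2.0
    if spec.high_hz >= nyq:
        raise ValueError(f"high cutoff {spec.high_hz} Hz >= Nyquist {nyq} Hz")
    if sfreq < 256:
        raise ValueError("sampling rate must be >= 256 Hz")
    sos = signal.butter(spec.order, [spec.low_hz, spec.high_hz],
                        btype="bandpass", fs=sfreq, output="sos")
    data = np.asarray(data, dtype=float)
    # maximal padding: the 0.1 Hz pole settles over seconds, so epoch-length
    # segments need far more padding than scipy's default to avoid edge bias
    padlen = max(data.shape[axis] - 1, 0)
    return signal.sosfiltfilt(sos, data, axis=axis, padlen=padlen)


def extract_epochs(continuous: np.ndarray, event_samples: np.ndarray,
                   sfreq: float, spec: EpochSpec = EpochSpec()):
    """Cut stimulus-locked epochs out of a continuous record.

    ``continuous`` is (n_channels, n_samples); events are sample indices of
    the stimulus markers.  Events too close to either recording edge are
    dropped and reported.

    Returns ``(epochs, kept_events, dropped_events)`` with epochs shaped
    (n_events_kept, n_channels, n_epoch_samples), not yet baseline corrected.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    n_before = int(round(-spec.tmin_ms / 1000.0 * sfreq))
    n_after = int(round(spec.tmax_ms / 1000.0 * sfreq))
    n_total = continuous.shape[1]
    kept, dropped, chunks = [], [], []
    for ev in np.asarray(event_samples, dtype=int):
        if ev - n_before < 0 or ev + n_after > n_total:
            dropped.append(int(ev))
            continue
        kept.append(int(ev))
        chunks.append(continuous[:, ev - n_before: ev + n_after])
    epochs = (np.stack(chunks) if chunks
              else np.empty((0, continuous.shape[0], n_before + n_after)))
    return epochs, kept, dropped


def baseline_correct(epochs: np.ndarray, times_ms: np.ndarray,
                     baseline_ms: tuple[float, float] = (-200.0, 0.0)) -> np.ndarray:
    """Subtract the mean over the baseline interval, per epoch and channel."""
    epochs = np.asarray(epochs, dtype=float)
    mask = (times_ms >= baseline_ms[0]) & (times_ms < baseline_ms[1])
    if not mask.any():
        raise ValueError("baseline interval contains no samples")
    return epochs - epochs[..., mask].mean(axis=-1, keepdims=True)


def epoch_and_baseline(data: np.ndarray, sfreq: float,
                       spec: EpochSpec = EpochSpec(),
                       event_samples: np.ndarray | None = None):
    """Epoch (if continuous) and baseline-correct.

    If ``event_samples`` is given, ``data`` is a continuous (n_channels,
    n_samples) record; otherwise it is an already-cut (n_trials, n_channels,
    n_samples) array.  Returns ``(epochs, times_ms, dropped_events)``.
    """
    times = default_times_ms(sfreq, spec.tmin_ms, spec.tmax_ms)
    if event_samples is not None:
        epochs, _, dropped = extract_epochs(data, event_samples, sfreq, spec)
    else:
        epochs, dropped = np.asarray(data, dtype=float), []
        if epochs.shape[-1] != times.size:
            raise ValueError("epoch length does not match the epoch window")
    return baseline_correct(epochs, times, spec.baseline_ms), times, dropped


# ---------------------------------------------------------------------------
# artifact rejection / averaging
# ---------------------------------------------------------------------------

def reject_artifacts(epochs: np.ndarray, threshold_uv: float = 100.0,
                     channel_names: list[str] | None = None):
    """Remove epochs whose absolute amplitude exceeds ``threshold_uv``.

    Returns ``(clean_epochs, kept_index, log)`` where ``log`` is a list of
    dicts (trial, channel, peak_uv) for every rejected epoch.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    epochs = np.asarray(epochs, dtype=float)
    peak = np.abs(epochs).max(axis=-1)  # (n_trials, n_channels)
    bad = peak > threshold_uv
    log = []
    for t in np.where(bad.any(axis=1))[0]:
        ch = int(np.argmax(peak[t]))
        name = channel_names[ch] if channel_names else str(ch)
        log.append({"trial": int(t), "channel": name,
                    "peak_uv": float(peak[t, ch])})
    keep = ~bad.any(axis=1)
    return epochs[keep], np.where(keep)[0], log


def average_condition(epochs: np.ndarray, n_min: int = 10):
    """Pointwise mean over trials.

    Returns ``(average, n, usable)``; ``usable`` is False when fewer than
    ``n_min`` trials entered the average (the average is still returned when
    at least one trial exists, else None).
    """
    epochs = np.asarray(epochs, dtype=float)
    n = epochs.shape[0]
    if n == 0:
        return None, 0, False
    return epochs.mean(axis=0), n, n >= n_min


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def _smooth(y: np.ndarray, times_ms: np.ndarray, sigma_ms: float) -> np.ndarray:
    if sigma_ms <= 0:
        return y
    dt = float(times_ms[1] - times_ms[0])
    half = int(math.ceil(4 * sigma_ms / dt))
    k = np.exp(-0.5 * ((np.arange(-half, half + 1) * dt) / sigma_ms) ** 2)
    k /= k.sum()
    # reflect padding keeps edges unbiased for smooth signals
    ypad = np.pad(y, half, mode="reflect")
    return np.convolve(ypad, k, mode="valid")


def detect_peak(waveform: np.ndarray, times_ms: np.ndarray,
                window: ComponentWindow, smoothing_ms: float = 8.0,
                prominence_factor: float = 0.5,
                participant: str = "", condition: str = "",
                electrode: str = "", replicate: int = 1) -> PeakMeasurement:
    """Find the component's extremum inside its analysis window.

    Candidates are strict local extrema of the stated polarity (sign change
    of the first difference of the smoothed waveform).  The most extreme
    candidate wins; exact ties go to the earliest peak for the early
    components and to the latest for the LPC (the representative late peak
    is the second of the extended positivity).  A peak counts as identified
    only when its prominence exceeds ``prominence_factor`` times the
    pre-stimulus standard deviation of the (smoothed) waveform.
    """
    waveform = np.asarray(waveform, dtype=float)
    if times_ms[0] > window.tmin_ms or times_ms[-1] < window.tmax_ms:
        raise ValueError("waveform does not cover the analysis window")
    y = _smooth(waveform, times_ms, smoothing_ms)
    sgn = -1.0 if window.polarity == "negative" else 1.0
    z = sgn * y  # peaks of interest become maxima

    mask = (times_ms >= window.tmin_ms) & (times_ms <= window.tmax_ms)
    idx = np.where(mask)[0]
    d = np.diff(z)
    # strict local maxima of z over the whole trace, then restrict to window
    interior = np.where((d[:-1] > 0) & (d[1:] < 0))[0] + 1
    cand = interior[(interior >= idx[0]) & (interior <= idx[-1])]

    not_found = PeakMeasurement(participant, condition, window.component,
                                electrode, replicate, identified=False)
    if cand.size == 0:
        return not_found

    vals = z[cand]
    best = vals.max()
    ties = cand[np.isclose(vals, best, rtol=0.0, atol=1e-12)]
    pick = ties[-1] if window.component == "LPC" else ties[0]

    prominences = signal.peak_prominences(z, [pick])[0]
    baseline_sd = float(np.std(y[times_ms < 0.0])) if (times_ms < 0).any() else 0.0
    if prominences[0] < prominence_factor * baseline_sd:
        return not_found

    return PeakMeasurement(participant, condition, window.component,
                           electrode, replicate, identified=True,
                           latency_ms=float(times_ms[pick]),
                           amplitude_uv=float(y[pick]))


def measurement_capacity(n_participants: int, n_sets: int,
                         n_electrodes: int = 2, n_replicates: int = 3) -> int:
    """Theoretical maximum number of measurements for one ERP wave."""
    return n_participants * n_sets * n_electrodes * n_replicates


def measure_components(epochs_by_condition: dict, times_ms: np.ndarray,
                       channels: list[str],
                       windows: dict[str, ComponentWindow] | None = None,
                       replicates: int = 3, bootstrap: bool = True,
                       seed: int | np.random.SeedSequence = 0,
                       smoothing_ms: float = 8.0,
                       prominence_factor: float = 0.5,
                       participant: str = "", n_min: int = 10) -> pd.DataFrame:
    """Replicate peak measurements for every condition of one participant.

    ``epochs_by_condition`` maps condition label -> (n_trials, n_channels,
    n_samples) baseline-corrected epochs.  Each replicate measures the
    average of a seeded bootstrap resample (same n, with replacement) of the
    condition's trials, standing in for one independent human observer; with
    ``bootstrap=False`` every replicate reads the plain average.

    Returns a tidy DataFrame with one row per (condition, component,
    electrode, replicate).
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    windows = windows or COMPONENT_WINDOWS
    rng = np.random.default_rng(seed)
    rows = []
    for condition, epochs in epochs_by_condition.items():
        epochs = np.asarray(epochs, dtype=float)
        n = epochs.shape[0]
        if n == 0:
            continue
        for r in range(1, replicates + 1):
            if bootstrap and n > 1:
                draw = rng.integers(0, n, size=n)
                avg = epochs[draw].mean(axis=0)
            else:
                avg = epochs.mean(axis=0)
            for comp, win in windows.items():
                for el in win.electrodes:
                    if el not in channels:
                        continue
                    ci = channels.index(el)
                    m = detect_peak(avg[ci], times_ms, win,
                                    smoothing_ms=smoothing_ms,
                                    prominence_factor=prominence_factor,
                                    participant=participant,
                                    condition=condition, electrode=el,
                                    replicate=r)
                    row = m.as_dict()
                    row["n_trials"] = n
                    row["low_n"] = n < n_min
                    rows.append(row)
    return pd.DataFrame(rows)
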