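"""Tail-beat rhythmicity metrics for fictive-swimming recordings.

The central statistic is *Peak_20–40*: an epoch of recorded swimming is
called rhythmic when the autocorrelation function of the (1–200 Hz
band-passed) signal, fitted with a second-order polynomial

    acf_fit(tau) = a0 + a1*tau + a2*tau**2

over the 20–50 ms lag window, is concave down (a2 < 0) with its vertex
-a1/(2*a2) strictly inside the 25–50 ms lag range — i.e. a periodicity in
the 20–40 Hz tail-beat band.  A recording's rhythm score is the fraction
of ten 200-ms epochs passing this test; the attenuation of the score by a
glycine-receptor blocker quantifies how strongly the rhythm depends on
synaptic inhibition.

Note the asymmetry between the fit window (from 20 ms) and the acceptance
interval (from 25 ms); it is deliberate and preserved exactly.  The
detector's power is highest for beat frequencies in the middle of the
20–40 Hz band; see docs/methods.md for its measured power band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .trace import TimeSeriesTrace

__all__ = [
    "EpisodeInterval",
    "AutocorrFunction",
    "AutocorrPolyFit",
    "RhythmScore",
    "SpectrogramMatrix",
    "bandpass_filter",
    "detect_episodes",
    "extract_epochs",
    "autocorrelation",
    "fit_autocorr_poly",
    "detect_peak_20_40",
    "rhythm_score",
    "attenuation",
    "apply_rejection_rule",
    "stft_heatmap",
]

logger = logging.getLogger(__name__)

FIT_WINDOW_MS = (20.0, 50.0)     # lag window of the polynomial fit (inclusive)
ACCEPT_WINDOW_MS = (25.0, 50.0)  # vertex acceptance interval (strict)
EPOCH_MS = 200.0
MIN_EPISODE_S = 0.2


@dataclass(frozen=True)
class EpisodeInterval:
    """One swimming episode, [start_s, end_s] in trace time."""

    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class AutocorrFunction:
    """Normalized autocorrelation: values[0] == 1, lags in ms."""

    lags_ms: np.ndarray
    values: np.ndarray


@dataclass
class AutocorrPolyFit:
    """Least-squares quadratic fit of an ACF on the 20–50 ms lag window."""

    a0: float
    a1: float
    a2: float
    fit_window_ms: tuple[float, float] = FIT_WINDOW_MS

    @property
    def vertex_ms(self) -> float | None:
        """Lag of the parabola's extremum; undefined for a2 == 0."""
        if self.a2 == 0.0:
            return None
        return -self.a1 / (2.0 * self.a2)

    @property
    def concave_down(self) -> bool:
        return self.a2 < 0.0


@dataclass
class RhythmScore:
    """Fraction of analyzed epochs with a detected 20–40 Hz peak."""

    n_epochs: int
    n_detected: int
    fits: list[AutocorrPolyFit] = field(default_factory=list)

    @property
    def score(self) -> float:
        return self.n_detected / self.n_epochs


@dataclass
class SpectrogramMatrix:
    """Magnitude spectra of consecutive non-overlapping epochs.

    ``magnitude`` has shape (n_epochs, n_freqs); ``epoch_times_s`` are the
    epoch centers.
    """

    epoch_times_s: np.ndarray
    freqs_hz: np.ndarray
    magnitude: np.ndarray


# --------------------------------------------------------------------------


def bandpass_filter(trace: TimeSeriesTrace, low_hz: float = 1.0,
                    high_hz: float = 200.0, order: int = 4) -> TimeSeriesTrace:
    """Zero-phase Butterworth band-pass (default 1–200 Hz).

    The filter is applied forward and backward (``sosfiltfilt``) so the
    passband has unit gain and zero phase shift.
    """
    nyq = trace.rate_hz / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=trace.rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.samples)
    meta = dict(trace.meta)
    meta["bandpass_hz"] = (low_hz, high_hz)
    return TimeSeriesTrace(filtered, trace.rate_hz, trace.units, meta)


def detect_episodes(trace: TimeSeriesTrace, threshold_k: float = 3.0,
                    smooth_ms: float = 20.0, merge_gap_ms: float = 50.0,
                    min_dur_s: float = MIN_EPISODE_S) -> list[EpisodeInterval]:
    """Find swimming episodes as sustained elevations of the signal envelope.

    The envelope is the rectified signal smoothed over ``smooth_ms``.
    Samples above ``median + threshold_k * sigma`` (sigma estimated robustly
    from the median absolute deviation, so episodes do not inflate the
    baseline) mark activity; gaps shorter than ``merge_gap_ms`` are merged
    and runs shorter than ``min_dur_s`` dropped — swimming episodes are by
    definition longer than 200 ms.
    """
    x = trace.samples
    if np.ptp(x) == 0.0:
        warnings.warn("flat trace: no episodes detectable", stacklevel=2)
        return []
    win = max(int(round(smooth_ms / 1e3 * trace.rate_hz)), 1)
    env = signal.convolve(np.abs(x), np.ones(win) / win, mode="same")
    med = np.median(env)
    sigma = 1.4826 * np.median(np.abs(env - med))
    if sigma == 0.0:
        warnings.warn("degenerate envelope: no episodes detectable", stacklevel=2)
        return []
    above = env > med + threshold_k * sigma

    # run-length encode the boolean mask
    runs: list[list[int]] = []
    idx = np.flatnonzero(above)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > 1)
        seg_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
        seg_ends = np.concatenate([idx[breaks], [idx[-1]]])
        runs = [[s, e] for s, e in zip(seg_starts, seg_ends)]

    merge_gap = merge_gap_ms / 1e3 * trace.rate_hz
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    out = []
    for s, e in merged:
        start_s, end_s = s / trace.rate_hz, (e + 1) / trace.rate_hz
        if end_s - start_s >= min_dur_s:
            out.append(EpisodeInterval(start_s, end_s))
    logger.debug("detected %d episodes", len(out))
    return out


def extract_epochs(trace: TimeSeriesTrace,
                   episodes: list[EpisodeInterval],
                   n: int = 10,
                   epoch_ms: float = EPOCH_MS,
                   strategy: str = "sequential",
                   seed: int | None = None) -> list[TimeSeriesTrace]:
    """Extract ``n`` fixed-length epochs lying fully inside episodes.

    ``strategy="sequential"`` (default) takes the earliest non-overlapping
    windows across episodes in temporal order; ``"random"`` places ``n``
    non-overlapping windows uniformly at random (seeded) over the eligible
    capacity.  Raises if the episodes cannot hold ``n`` disjoint epochs,
    naming the shortfall.
    """
    if not episodes:
        raise ValueError("no episodes to extract epochs from")
    epoch_s = epoch_ms / 1e3
    caps = [int(ep.duration_s / epoch_s) for ep in episodes]
    capacity = sum(caps)
    if capacity < n:
        raise ValueError(
            f"episodes hold only {capacity} disjoint {epoch_ms:.0f}-ms epochs, "
            f"{n} requested ({n - capacity} short)")

    starts: list[float] = []
    if strategy == "sequential":
        for ep, cap in zip(episodes, caps):
            for k in range(cap):
                if len(starts) == n:
                    break
                starts.append(ep.start_s + k * epoch_s)
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        slots = [(i, k) for i, cap in enumerate(caps) for k in range(cap)]
        chosen = rng.choice(len(slots), size=n, replace=False)
        for j in sorted(chosen):
            i, k = slots[j]
            starts.append(episodes[i].start_s + k * epoch_s)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    return [trace.slice_s(s, s + epoch_s) for s in starts[:n]]


def autocorrelation(epoch: TimeSeriesTrace, max_lag_ms: float = 100.0
                    ) -> AutocorrFunction:
    """Normalized (biased-estimator) autocorrelation of one epoch.

    The mean is removed; values are scaled so the zero-lag value is one.
    The biased estimator keeps |acf| <= 1 at every lag.
    """
    if np.ptp(epoch.samples) == 0.0:
        raise ValueError("zero-variance epoch has no autocorrelation")
    x = epoch.samples - epoch.samples.mean()
    max_lag = int(round(max_lag_ms / 1e3 * epoch.rate_hz))
    max_lag = min(max_lag, x.size - 1)
    c = signal.correlate(x, x, mode="full")[x.size - 1: x.size + max_lag]
    values = c / c[0]
    lags_ms = np.arange(max_lag + 1) / epoch.rate_hz * 1e3
    return AutocorrFunction(lags_ms, values)


def fit_autocorr_poly(acf: AutocorrFunction,
                      fit_window_ms: tuple[float, float] = FIT_WINDOW_MS
                      ) -> AutocorrPolyFit:
    """Least-squares quadratic on the ACF's 20–50 ms lag samples (inclusive)."""
    lo, hi = fit_window_ms
    m = (acf.lags_ms >= lo) & (acf.lags_ms <= hi)
    if m.sum() < 3:
        raise ValueError(
            f"only {int(m.sum())} lag samples in [{lo}, {hi}] ms; need >= 3")
    a2, a1, a0 = np.polyfit(acf.lags_ms[m], acf.values[m], 2)
    return AutocorrPolyFit(a0=float(a0), a1=float(a1), a2=float(a2),
                           fit_window_ms=fit_window_ms)


def detect_peak_20_40(fit: AutocorrPolyFit) -> bool:
    """True iff the fitted parabola peaks strictly inside 25–50 ms.

    The two printed conditions, exactly: a2 < 0 (concave down) and
    25 ms < -a1/(2 a2) < 50 ms.  a2 == 0 (no vertex) is no peak; a vertex
    at exactly 25 or 50 ms is no peak.
    """
    if fit.a2 >= 0.0:
        return False
    vertex = fit.vertex_ms
    lo, hi = ACCEPT_WINDOW_MS
    return lo < vertex < hi


def rhythm_score(trace: TimeSeriesTrace,
                 episodes: list[EpisodeInterval] | None = None,
                 n: int = 10,
                 epoch_ms: float = EPOCH_MS,
                 strategy: str = "sequential",
                 seed: int | None = None,
                 prefilter: bool = True,
                 low_hz: float = 1.0,
                 high_hz: float = 200.0) -> RhythmScore:
    """Peak_20–40 score of a recording: detected epochs / analyzed epochs.

    Runs the full chain — band-pass, episode detection (unless intervals
    are supplied), epoch extraction, autocorrelation, quadratic fit, peak
    test — and reports the detection fraction as an exact n/N ratio.
    """
    work = bandpass_filter(trace, low_hz, high_hz) if prefilter else trace
    if episodes is None:
        episodes = detect_episodes(work)
    epochs = extract_epochs(work, episodes, n=n, epoch_ms=epoch_ms,
                            strategy=strategy, seed=seed)
    fits = [fit_autocorr_poly(autocorrelation(ep)) for ep in epochs]
    detected = sum(detect_peak_20_40(f) for f in fits)
    return RhythmScore(n_epochs=len(epochs), n_detected=detected, fits=fits)


def attenuation(score_ctrl: float, score_str: float) -> float:
    """Attenuation of the Peak_20–40 score by a blocker: 1 - str/ctrl."""
    ctrl = score_ctrl.score if isinstance(score_ctrl, RhythmScore) else score_ctrl
    blk = score_str.score if isinstance(score_str, RhythmScore) else score_str
    if ctrl == 0:
        raise ZeroDivisionError("attenuation undefined for a zero control score")
    return 1.0 - blk / ctrl


def apply_rejection_rule(control_scores: dict,
                         exempt_flags: dict | None = None,
                         cutoff: float = 0.5):
    """Discard arrhythmic animals: control score < 50% unless exempt.

    ``control_scores`` maps animal id -> control-condition score (0–1);
    ``exempt_flags`` maps animal id -> bool (e.g. the somite-1 recordings
    at 5 dpf, which are kept despite sub-50% scores).  Returns
    ``(kept, discarded, discard_fraction)`` with kept/discarded as dicts.
    """
    exempt_flags = exempt_flags or {}
    kept, discarded = {}, {}
    for animal, score in control_scores.items():
        sc = score.score if isinstance(score, RhythmScore) else score
        if sc < cutoff and not exempt_flags.get(animal, False):
            discarded[animal] = sc
        else:
            kept[animal] = sc
    frac = len(discarded) / len(control_scores) if control_scores else 0.0
    return kept, discarded, frac


def stft_heatmap(trace: TimeSeriesTrace, epoch_ms: float = 375.0,
                 max_freq_hz: float = 200.0) -> SpectrogramMatrix:
    """Short-time Fourier magnitudes over consecutive 375-ms epochs.

    The trace is cut into floor(duration/epoch) non-overlapping epochs;
    each epoch's FFT magnitude is kept up to ``max_freq_hz``.  Intended to
    be applied after :func:`bandpass_filter`, mirroring the 30-s heat maps
    of spinal-cord activity.
    """
    nper = int(round(epoch_ms / 1e3 * trace.rate_hz))
    n_epochs = trace.n_samples // nper
    if n_epochs < 1:
        raise ValueError(
            f"trace ({trace.duration_s:.3f} s) shorter than one "
            f"{epoch_ms:.0f}-ms epoch")
    seg = trace.samples[: n_epochs * nper].reshape(n_epochs, nper)
    freqs = np.fft.rfftfreq(nper, d=1.0 / trace.rate_hz)
    keep = freqs <= max_freq_hz
    mag = np.abs(np.fft.rfft(seg, axis=1))[:, keep]
    centers = (np.arange(n_epochs) + 0.5) * nper / trace.rate_hz
    return SpectrogramMatrix(epoch_times_s=centers, freqs_hz=freqs[keep],
                             magnitude=mag)
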