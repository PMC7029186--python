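"""Seeded generators for every input class the analysis consumes.

Three generators emulate the raw data of a larval-zebrafish fictive-swimming
experiment, with ground truth attached so every downstream stage is testable
offline:

* :func:`generate_fictive_trace` — ventral-root-like voltage traces carrying
  swimming episodes (>200 ms) in four modes: 3-dpf-like ``burst`` (long,
  infrequent episodes) vs 5-dpf-like ``bg`` (beat-and-glide: short, frequent
  episodes), each either ``ctrl`` (20–40 Hz tail-beat carrier) or ``str``
  (strychnine-like: slow voltage deflections without the rhythmic carrier).
* :func:`generate_ipsc_trace` — trains of stereotyped postsynaptic-current
  kernels, either jittered-periodic (rhythmic) or homogeneous-Poisson
  (arrhythmic).
* :func:`generate_swim_video` — a head-embedded swimming fish as a binary
  silhouette whose midline is a traveling sine wave with caudally growing
  amplitude, imaged at 500 fps.

All randomness flows from one ``numpy`` Generator seeded per call, so an
identical spec + seed reproduces bit-identical output.  Units of the traces
are arbitrary ("a.u."): the source recordings' amplifier gain and
digitization scale are not part of the emulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .trace import GroundTruth, TimeSeriesTrace

__all__ = [
    "MODES",
    "SyntheticTraceSpec",
    "generate_fictive_trace",
    "generate_ipsc_trace",
    "generate_swim_video",
    "save_frames",
    "load_frames",
]

#: mode -> (mean episode duration s, episode occurrence rate 1/s,
#:          default trace duration s, carrier retained, residual-rhythm prob)
MODES = {
    "burst_ctrl": (2.0, 0.10, 30.0, True, 1.0),
    "burst_str": (2.0, 0.10, 30.0, False, 0.6),
    "bg_ctrl": (0.30, 0.80, 20.0, True, 1.0),
    "bg_str": (0.30, 0.80, 20.0, False, 0.0),
}

RAMP_S = 0.020  # raised-cosine on/off ramp of the episode envelope


@dataclass(frozen=True)
class SyntheticTraceSpec:
    """Parameters of one synthetic fictive-swimming recording.

    ``snr`` is the amplitude of the oscillatory (or deflection) component
    in units of the background-noise SD.  ``residual_rhythm_prob`` is the
    per-episode probability that a strychnine-mode episode keeps the
    20–40 Hz carrier; it defaults to the mode table (0.6 for 3-dpf-like
    ``burst_str``, matching the observation that oscillations persist in
    more than half of 3-dpf episodes under strychnine, and 0.0 for
    5-dpf-like ``bg_str``).
    """

    mode: str = "bg_ctrl"
    tailbeat_hz: float = 30.0
    episode_dur_s: float | None = None
    episode_rate_hz: float | None = None
    snr: float = 5.0
    rate_hz: float = 10_000.0
    duration_s: float | None = None
    seed: int = 0
    noise_sd: float = 1.0
    residual_rhythm_prob: float | None = None

    def resolved(self) -> "SyntheticTraceSpec":
        """Fill mode-dependent defaults and validate."""
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; one of {sorted(MODES)}")
        dur, rate, total, _, resid = MODES[self.mode]
        out = replace(
            self,
            episode_dur_s=dur if self.episode_dur_s is None else self.episode_dur_s,
            episode_rate_hz=rate if self.episode_rate_hz is None else self.episode_rate_hz,
            duration_s=total if self.duration_s is None else self.duration_s,
            residual_rhythm_prob=(resid if self.residual_rhythm_prob is None
                                  else self.residual_rhythm_prob),
        )
        if not 20.0 <= out.tailbeat_hz <= 40.0:
            raise ValueError("tailbeat_hz must lie in [20, 40] Hz")
        if out.episode_dur_s <= 0.2:
            raise ValueError("episode_dur_s must exceed the 0.2 s episode minimum")
        if out.snr <= 0 or out.rate_hz <= 0 or out.episode_rate_hz <= 0:
            raise ValueError("snr, rate_hz and episode_rate_hz must be positive")
        return out


def _place_episodes(spec: SyntheticTraceSpec, rng: np.random.Generator
                    ) -> list[tuple[float, float]]:
    """Draw sorted, non-overlapping episode intervals.

    Inter-episode gaps are exponential with a 0.2 s floor so that episodes
    stay separable by an envelope detector with a 50 ms gap-merge.
    """
    min_gap = 0.2
    mean_gap = max(1.0 / spec.episode_rate_hz - spec.episode_dur_s - min_gap, 0.05)
    intervals: list[tuple[float, float]] = []
    t = min_gap + rng.exponential(mean_gap)
    while True:
        dur = float(np.clip(rng.normal(spec.episode_dur_s, 0.2 * spec.episode_dur_s),
                            max(0.25, 0.5 * spec.episode_dur_s),
                            1.8 * spec.episode_dur_s))
        if t + dur + min_gap > spec.duration_s:
            break
        intervals.append((t, t + dur))
        t += dur + min_gap + rng.exponential(mean_gap)
    if not intervals:
        # an unlucky long first gap must not leave a recording empty when
        # the duration can hold an episode; only a truly short duration errs
        dur = min(spec.episode_dur_s, spec.duration_s - 2 * min_gap)
        if dur < 0.25:
            raise ValueError(
                f"duration_s={spec.duration_s} too short to hold one "
                f"~{spec.episode_dur_s:.2f} s episode")
        intervals.append((min_gap, min_gap + dur))
    return intervals


def _episode_envelope(t: np.ndarray, start: float, end: float) -> np.ndarray:
    """Unit envelope with raised-cosine ramps, zero outside [start, end]."""
    env = np.zeros_like(t)
    inside = (t >= start) & (t <= end)
    env[inside] = 1.0
    for edge, rising in ((start, True), (end, False)):
        lo, hi = (edge, edge + RAMP_S) if rising else (edge - RAMP_S, edge)
        m = (t >= lo) & (t <= hi)
        phase = (t[m] - lo) / RAMP_S
        env[m] = 0.5 - 0.5 * np.cos(np.pi * (phase if rising else 1 + phase))
    return env


def generate_fictive_trace(spec: SyntheticTraceSpec
                           ) -> tuple[TimeSeriesTrace, GroundTruth]:
    """Synthesize a ventral-root-like trace plus its ground truth.

    Control-mode episodes are amplitude-enveloped sinusoids at
    ``spec.tailbeat_hz`` (amplitude ``snr × noise_sd``) on Gaussian
    background noise.  Strychnine-mode episodes replace the carrier with a
    slow (0.5–4 Hz) unipolar deflection plus a broadband noise boost,
    emulating long-duration voltage changes without the tail-beat rhythm;
    a ``residual_rhythm_prob`` fraction of them keeps the carrier.
    """
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed)
    intervals = _place_episodes(spec, rng)

    n = int(round(spec.duration_s * spec.rate_hz))
    t = np.arange(n) / spec.rate_hz
    x = rng.normal(0.0, spec.noise_sd, size=n)
    amp = spec.snr * spec.noise_sd

    rhythmic: list[bool] = []
    for start, end in intervals:
        is_rhythmic = bool(rng.random() < spec.residual_rhythm_prob)
        phase = rng.uniform(0, 2 * np.pi)
        # slow "voltage change" of the strychnine condition: a zero-mean
        # gated sine (at least one full cycle per episode) so its energy
        # stays inside the 1-200 Hz analysis band instead of exciting the
        # band edge
        f_slow = float(np.clip(max(rng.uniform(0.5, 4.0),
                                   1.2 / (end - start)), 0.5, 4.5))
        env = _episode_envelope(t, start, end)
        if is_rhythmic:
            x += amp * env * np.sin(2 * np.pi * spec.tailbeat_hz * t + phase)
        else:
            x += amp * env * np.sin(2 * np.pi * f_slow * (t - start))
            x += 0.5 * amp * env * rng.normal(0.0, 1.0, size=n)
        rhythmic.append(is_rhythmic)

    trace = TimeSeriesTrace(
        x, spec.rate_hz, units="a.u.",
        meta={"generator": "fictive", "mode": spec.mode, "seed": spec.seed,
              "tailbeat_hz": spec.tailbeat_hz, "snr": spec.snr})
    truth = GroundTruth(
        episode_intervals=intervals,
        tailbeat_hz=[spec.tailbeat_hz] * len(intervals),
        rhythmic=rhythmic)
    return trace, truth


# --------------------------------------------------------------------------
# IPSC event trains
# --------------------------------------------------------------------------

def _psc_kernel(rate_hz: float, rise_ms: float, decay_ms: float, amp: float
                ) -> np.ndarray:
    """Difference-of-exponentials postsynaptic-current kernel, peak = amp."""
    if rise_ms <= 0 or decay_ms <= rise_ms:
        raise ValueError("need 0 < rise_ms < decay_ms")
    tr, td = rise_ms / 1e3, decay_ms / 1e3
    t = np.arange(0.0, 8 * td, 1.0 / rate_hz)
    k = np.exp(-t / td) - np.exp(-t / tr)
    return amp * k / k.max()


def generate_ipsc_trace(rate_hz_events: float,
                        rhythmic: bool,
                        jitter_sd_ms: float = 0.0,
                        kernel_params: dict | None = None,
                        rate_hz: float = 10_000.0,
                        duration_s: float = 10.0,
                        seed: int = 0,
                        noise_sd: float = 0.02,
                        ) -> tuple[TimeSeriesTrace, GroundTruth]:
    """Synthesize an IPSC train as a sum of stereotyped kernels.

    ``rhythmic=True`` places events periodically at ``rate_hz_events`` with
    independent Gaussian timing jitter of SD ``jitter_sd_ms``; ``False``
    draws a homogeneous Poisson process at the same mean rate, emulating
    the arrhythmic glycinergic input of younger larvae.
    """
    if rate_hz_events <= 0:
        raise ValueError("rate_hz_events must be positive")
    if jitter_sd_ms < 0:
        raise ValueError("jitter_sd_ms must be non-negative")
    rng = np.random.default_rng(seed)
    kp = {"rise_ms": 1.0, "decay_ms": 5.0, "amp": 1.0, **(kernel_params or {})}

    if rhythmic:
        period = 1.0 / rate_hz_events
        nominal = np.arange(rng.uniform(0, period), duration_s, period)
        times = nominal + rng.normal(0.0, jitter_sd_ms / 1e3, size=nominal.size)
        times = np.sort(times[(times >= 0) & (times < duration_s)])
    else:
        gaps = rng.exponential(1.0 / rate_hz_events,
                               size=int(rate_hz_events * duration_s * 2) + 20)
        times = np.cumsum(gaps)
        times = times[times < duration_s]

    n = int(round(duration_s * rate_hz))
    x = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    kernel = _psc_kernel(rate_hz, kp["rise_ms"], kp["decay_ms"], kp["amp"])
    for tk in times:
        i0 = int(round(tk * rate_hz))
        seg = min(kernel.size, n - i0)
        if seg > 0:
            x[i0:i0 + seg] += kernel[:seg]

    trace = TimeSeriesTrace(
        x, rate_hz, units="a.u.",
        meta={"generator": "ipsc", "rhythmic": rhythmic, "seed": seed,
              "rate_hz_events": rate_hz_events, "jitter_sd_ms": jitter_sd_ms})
    truth = GroundTruth(event_times_s=times,
                        rhythmic=[rhythmic] * len(times))
    return trace, truth


# --------------------------------------------------------------------------
# Swim video
# --------------------------------------------------------------------------

def default_amp_envelope(s: np.ndarray) -> np.ndarray:
    """Rostro-caudally growing relative bend amplitude (rostral floor 0.1)."""
    return 0.1 + 0.9 * np.asarray(s) ** 2


def _analytic_midline(s: np.ndarray, t_s: float, wave_hz: float,
                      amp_px: float, amp_envelope, n_waves: float,
                      x0: float, body_len_px: float, y_center: float
                      ) -> np.ndarray:
    """Midline points for body coordinate s∈[0,1] (0 = rostral) at time t."""
    x = x0 + body_len_px * s
    y = y_center + amp_px * amp_envelope(s) * np.sin(
        2 * np.pi * (n_waves * s - wave_hz * t_s))
    return np.column_stack([x, y])


def _segment_angles_from_points(points: np.ndarray, n_segments: int
                                ) -> np.ndarray:
    """Arc-length resample to n_segments+1 points; arctan slope per segment."""
    d = np.diff(points, axis=0)
    arclen = np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])
    targets = np.linspace(0.0, arclen[-1], n_segments + 1)
    xs = np.interp(targets, arclen, points[:, 0])
    ys = np.interp(targets, arclen, points[:, 1])
    return np.arctan2(np.diff(ys), np.diff(xs))


def generate_swim_video(wave_hz: float,
                        n_frames: int,
                        fps: float = 500.0,
                        amp_envelope=None,
                        img_shape: tuple[int, int] = (120, 260),
                        seed: int = 0,
                        amp_px: float = 12.0,
                        n_waves: float = 1.0,
                        head_halfwidth_px: float = 7.0,
                        tail_halfwidth_px: float = 2.0,
                        n_segments: int = 30,
                        ):
    """Render a swimming-fish silhouette video with attached ground truth.

    Returns ``(frames, midlines, angles, positions)`` where ``frames`` is a
    uint8 array (n_frames, H, W) with the body at 255, ``midlines`` is an
    (n_frames, 101, 2) array of analytic midline x-y coordinates (rostral
    to caudal), ``angles`` the (n_segments, n_frames) ground-truth local
    bend angles (radians, relative to the straight rest posture) and
    ``positions`` the normalized body coordinate of each segment center
    with the extreme caudal segment at 1.0.

    The silhouette is the set of pixels within a tapered half-width of the
    midline, so the body has rounded caps and a thickness decreasing from
    head to tail.  ``seed`` is accepted for interface symmetry; rendering
    is deterministic.
    """
    del seed  # rendering has no stochastic component
    if fps <= 2 * wave_hz:
        raise ValueError(f"fps={fps} must exceed twice wave_hz={wave_hz}")
    if 2 * min(head_halfwidth_px, tail_halfwidth_px) < 3:
        raise ValueError("body thickness under 3 px leaves the skeleton undefined")
    if amp_envelope is None:
        amp_envelope = default_amp_envelope

    h, w = img_shape
    x0, x1 = 12.0, w - 14.0
    body_len = x1 - x0
    y_center = h / 2.0
    if amp_px + head_halfwidth_px + 2 > h / 2:
        raise ValueError("img_shape too small for the requested amplitude")

    s_dense = np.linspace(0.0, 1.0, max(int(2 * body_len), 64))
    halfwidth = head_halfwidth_px + (tail_halfwidth_px - head_halfwidth_px) * s_dense
    s_mid = np.linspace(0.0, 1.0, 101)

    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)

    frames = np.zeros((n_frames, h, w), dtype=np.uint8)
    midlines = np.zeros((n_frames, s_mid.size, 2))
    angles = np.zeros((n_segments, n_frames))
    for i in range(n_frames):
        t_s = i / fps
        pts = _analytic_midline(s_dense, t_s, wave_hz, amp_px, amp_envelope,
                                n_waves, x0, body_len, y_center)
        dist, idx = cKDTree(pts).query(pix, k=1)
        mask = dist <= halfwidth[idx]
        frames[i] = (mask.reshape(h, w) * 255).astype(np.uint8)
        midlines[i] = _analytic_midline(s_mid, t_s, wave_hz, amp_px,
                                        amp_envelope, n_waves, x0, body_len,
                                        y_center)
        angles[:, i] = _segment_angles_from_points(midlines[i], n_segments)

    centers = (np.arange(n_segments) + 0.5) / n_segments  # caudal end = 1.0
    return frames, midlines, angles, centers


def save_frames(frames: np.ndarray, path: str | Path) -> None:
    """Write frames as a multi-page TIFF (``.tif``) or a PNG directory."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, frames)
    else:
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)


def load_frames(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF or a directory of numbered PNG frames."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG frames in {path}")
        return np.stack([iio.imread(f) for f in files])
    import tifffile

    return tifffile.imread(path)
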