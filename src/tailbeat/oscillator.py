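"""Coupled-oscillator model of the pacemaker-to-network-oscillator transition.

The spinal rhythm generator is reduced to two coupled abstract oscillators:
a harmonic *pacemaker* (the IC-interneuron kernel) driving a damped
*half-center network* oscillator with the same natural frequency.  The
network output x solves

    x'' + 2*zeta*omega0*x' + omega0**2 * x = F0*sin(omega0*(t - t1)) + F1(t)

with omega0 = 2*pi*omega0_hz rad/s.  The pacemaker is not integrated: its
output is exactly the sinusoidal drive F0*sin(omega0*(t - t1)) during the
descending "go signal" gate [t1, t2], and both drive terms are zero outside
the gate.  zeta encodes the strength of reciprocal (glycinergic) inhibition
— high zeta plays the role of strychnine — and F0 the pacemaker-to-network
coupling, which weakens as newly integrated neurons lose direct contact
with the pacemaker kernel.

Four canonical (F0, zeta) regimes are studied: strong coupling F0 = 0.5,
weak coupling F0 = 0.01, strong reciprocal inhibition zeta = 0.1 and weak
reciprocal inhibition zeta = 0.5.  Integration is fixed-step classical
Runge–Kutta (RK4).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .rhythm import (AutocorrFunction, autocorrelation, detect_peak_20_40,
                     fit_autocorr_poly)
from .trace import TimeSeriesTrace

__all__ = [
    "OscillatorParams",
    "OscillatorOutput",
    "REGIMES",
    "drive_signal",
    "simulate",
    "regime_outputs",
    "resonant_steady_amplitude",
    "static_deflection",
    "model_autocorr_analysis",
]

#: the four (F0, zeta) parameter regimes of the developmental 2x2
REGIMES = ((0.5, 0.1), (0.5, 0.5), (0.01, 0.1), (0.01, 0.5))


@dataclass(frozen=True)
class OscillatorParams:
    """Model parameters.

    omega0_hz : natural frequency of both oscillators, ordinary Hz.
    zeta      : damping ratio (reciprocal-inhibition strength).
    f0        : pacemaker->network coupling coefficient.
    f1        : go-signal amplitude (tonic descending excitation).
    t1_s,t2_s : go-signal gate; both drives act only inside it.
    dt_s      : RK4 step; must satisfy dt <= 1/(100*omega0_hz).
    """

    omega0_hz: float = 20.0
    zeta: float = 0.1
    f0: float = 0.5
    f1: float = 1.0
    t1_s: float = 0.5
    t2_s: float = 2.5
    dt_s: float = 1e-4
    duration_s: float = 3.0
    x0: float = 0.0
    v0: float = 0.0

    def validate(self) -> None:
        if self.omega0_hz <= 0:
            raise ValueError("omega0_hz must be positive")
        if self.zeta < 0:
            raise ValueError("zeta must be non-negative")
        if not self.t1_s < self.t2_s <= self.duration_s:
            raise ValueError("need t1_s < t2_s <= duration_s")
        if self.dt_s > 1.0 / (100.0 * self.omega0_hz):
            raise ValueError(
                f"dt_s={self.dt_s} too large for omega0_hz={self.omega0_hz}; "
                f"need dt_s <= {1.0 / (100.0 * self.omega0_hz):.2e}")

    @property
    def omega0_rad(self) -> float:
        return 2.0 * np.pi * self.omega0_hz


@dataclass
class OscillatorOutput:
    """Integrated network output: time grid and oscillating variable x."""

    t_s: np.ndarray
    x: np.ndarray
    params: OscillatorParams

    def gated(self) -> np.ndarray:
        m = (self.t_s >= self.params.t1_s) & (self.t_s <= self.params.t2_s)
        return self.x[m]

    def as_trace(self) -> TimeSeriesTrace:
        return TimeSeriesTrace(self.x, 1.0 / self.params.dt_s, units="a.u.",
                               meta={"generator": "oscillator"})


def drive_signal(t, params: OscillatorParams):
    """(periodic drive, go signal) at time(s) t; both zero outside the gate."""
    t = np.asarray(t, dtype=float)
    gate = (t >= params.t1_s) & (t <= params.t2_s)
    periodic = np.where(
        gate, params.f0 * np.sin(params.omega0_rad * (t - params.t1_s)), 0.0)
    go = np.where(gate, params.f1, 0.0)
    return periodic, go


def _total_drive(t: float, params: OscillatorParams) -> float:
    if params.t1_s <= t <= params.t2_s:
        return (params.f0 * np.sin(params.omega0_rad * (t - params.t1_s))
                + params.f1)
    return 0.0


def simulate(params: OscillatorParams) -> OscillatorOutput:
    """Integrate the driven damped oscillator with fixed-step RK4."""
    params.validate()
    om = params.omega0_rad
    two_zw = 2.0 * params.zeta * om
    om2 = om * om
    dt = params.dt_s
    n = int(round(params.duration_s / dt)) + 1
    t = np.arange(n) * dt
    x = np.empty(n)
    v = np.empty(n)
    x[0], v[0] = params.x0, params.v0

    def acc(ti: float, xi: float, vi: float) -> float:
        return _total_drive(ti, params) - two_zw * vi - om2 * xi

    for i in range(n - 1):
        ti, xi, vi = t[i], x[i], v[i]
        k1x, k1v = vi, acc(ti, xi, vi)
        k2x = vi + 0.5 * dt * k1v
        k2v = acc(ti + 0.5 * dt, xi + 0.5 * dt * k1x, vi + 0.5 * dt * k1v)
        k3x = vi + 0.5 * dt * k2v
        k3v = acc(ti + 0.5 * dt, xi + 0.5 * dt * k2x, vi + 0.5 * dt * k2v)
        k4x = vi + dt * k3v
        k4v = acc(ti + dt, xi + dt * k3x, vi + dt * k3v)
        x[i + 1] = xi + dt / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        v[i + 1] = vi + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
    return OscillatorOutput(t_s=t, x=x, params=params)


def regime_outputs(base: OscillatorParams | None = None
                   ) -> dict[tuple[float, float], OscillatorOutput]:
    """Simulate the four (F0, zeta) regimes on one common gate and grid."""
    base = base or OscillatorParams()
    return {(f0, z): simulate(replace(base, f0=f0, zeta=z))
            for f0, z in REGIMES}


def resonant_steady_amplitude(params: OscillatorParams) -> float:
    """Closed-form steady-state amplitude under resonant drive: F0/(2*zeta*omega0^2)."""
    return params.f0 / (2.0 * params.zeta * params.omega0_rad ** 2)


def static_deflection(params: OscillatorParams) -> float:
    """Static response to the go signal alone: F1/omega0^2."""
    return params.f1 / params.omega0_rad ** 2


def model_autocorr_analysis(output: OscillatorOutput,
                            window_ms: float = 200.0,
                            noise_sd: float = 0.0,
                            seed: int | None = None,
                            ) -> tuple[AutocorrFunction, bool]:
    """Autocorrelation readout of the model output, as for recordings.

    The gated output (optionally with seeded additive observation noise)
    is cut into consecutive ``window_ms`` windows; each window gets the
    same autocorrelation + quadratic-fit peak test applied to recorded
    epochs.  Returns the ACF of the full gated segment (for plotting) and
    True when a peak is detected in at least half of the windows.
    """
    p = output.params
    if (p.t2_s - p.t1_s) * 1e3 < window_ms:
        raise ValueError("go-signal gate shorter than one analysis window")
    rate = 1.0 / p.dt_s
    xg = output.gated()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        xg = xg + rng.normal(0.0, noise_sd, size=xg.size)
    gated_trace = TimeSeriesTrace(xg, rate)
    full_acf = autocorrelation(gated_trace)

    nper = int(round(window_ms / 1e3 * rate))
    detections = []
    for i in range(xg.size // nper):
        win = TimeSeriesTrace(xg[i * nper:(i + 1) * nper], rate)
        if np.ptp(win.samples) == 0.0:
            detections.append(False)
            continue
        fit = fit_autocorr_poly(autocorrelation(win))
        detections.append(detect_peak_20_40(fit))
    detected = sum(detections) >= max(len(detections) / 2.0, 1)
    return full_acf, bool(detected)
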