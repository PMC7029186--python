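"""Uniformly sampled single-channel time series and its on-disk formats.

A :class:`TimeSeriesTrace` holds one channel of a voltage/current recording
(or a simulated stand-in) together with its sampling rate and a free-form
metadata mapping.  Traces round-trip through either a two-column CSV
(``time_s,value``) or a ``.npz`` array container; both carry a JSON sidecar
with the sampling rate, units and any generator metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["TimeSeriesTrace", "GroundTruth"]


@dataclass
class TimeSeriesTrace:
    """One channel of uniformly sampled signal.

    Parameters
    ----------
    samples : ndarray
        Signal values, finite, arbitrary units unless stated.
    rate_hz : float
        Sampling rate in samples per second (> 0).
    units : str
        Unit label for the samples (synthetic traces use ``"a.u."``).
    meta : dict
        Free-form provenance (generator mode, seed, ...).
    """

    samples: np.ndarray
    rate_hz: float
    units: str = "a.u."
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate_hz

    def slice_s(self, start_s: float, end_s: float) -> "TimeSeriesTrace":
        """Return the sub-trace covering [start_s, end_s)."""
        i0 = int(round(start_s * self.rate_hz))
        i1 = int(round(end_s * self.rate_hz))
        if not (0 <= i0 < i1 <= self.n_samples):
            raise ValueError(f"slice [{start_s}, {end_s}) s outside trace")
        return TimeSeriesTrace(self.samples[i0:i1], self.rate_hz, self.units,
                               dict(self.meta))

    # ---- IO ------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write ``time_s,value`` CSV plus a ``.json`` metadata sidecar."""
        path = Path(path)
        arr = np.column_stack([self.times_s, self.samples])
        np.savetxt(path, arr, delimiter=",", header="time_s,value",
                   comments="")
        self._write_sidecar(path)

    def to_npz(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, samples=self.samples, rate_hz=self.rate_hz)
        self._write_sidecar(path)

    def _write_sidecar(self, path: Path) -> None:
        side = path.with_suffix(path.suffix + ".json")
        side.write_text(json.dumps(
            {"rate_hz": self.rate_hz, "units": self.units, "meta": self.meta},
            indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, rate_hz: float | None = None) -> "TimeSeriesTrace":
        """Read a two-column CSV; the rate comes from the sidecar, the time
        column, or the explicit argument (in that order of preference)."""
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        units, meta = "a.u.", {}
        side = path.with_suffix(path.suffix + ".json")
        if side.exists():
            d = json.loads(side.read_text())
            rate_hz = d.get("rate_hz", rate_hz)
            units = d.get("units", units)
            meta = d.get("meta", meta)
        if rate_hz is None:
            dt = np.median(np.diff(arr[:, 0]))
            rate_hz = 1.0 / dt
        return cls(arr[:, 1], float(rate_hz), units, meta)

    @classmethod
    def from_npz(cls, path: str | Path) -> "TimeSeriesTrace":
        path = Path(path)
        d = np.load(path)
        units, meta = "a.u.", {}
        side = path.with_suffix(path.suffix + ".json")
        if side.exists():
            s = json.loads(side.read_text())
            units, meta = s.get("units", units), s.get("meta", meta)
        return cls(d["samples"], float(d["rate_hz"]), units, meta)


@dataclass
class GroundTruth:
    """Generator-attached truth for a synthetic trace.

    ``episode_intervals`` are non-overlapping, sorted (start_s, end_s) pairs.
    ``tailbeat_hz`` and ``rhythmic`` are per-episode; event-train generators
    fill ``event_times_s`` instead of episodes.
    """

    episode_intervals: list[tuple[float, float]] = field(default_factory=list)
    tailbeat_hz: list[float] = field(default_factory=list)
    rhythmic: list[bool] = field(default_factory=list)
    event_times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        iv = self.episode_intervals
        for (s0, e0), (s1, e1) in zip(iv, iv[1:]):
            if s1 < e0:
                raise ValueError("episode intervals overlap or are unsorted")
        for s, e in iv:
            if e <= s:
                raise ValueError("empty episode interval")

    def to_json(self, path: str | Path) -> None:
        d = {
            "episode_intervals": [list(map(float, iv))
                                  for iv in self.episode_intervals],
            "tailbeat_hz": [float(f) for f in self.tailbeat_hz],
            "rhythmic": [bool(r) for r in self.rhythmic],
        }
        if self.event_times_s is not None:
            d["event_times_s"] = [float(t) for t in self.event_times_s]
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        ev = d.get("event_times_s")
        return cls(
            episode_intervals=[tuple(iv) for iv in d["episode_intervals"]],
            tailbeat_hz=d["tailbeat_hz"],
            rhythmic=d["rhythmic"],
            event_times_s=None if ev is None else np.asarray(ev, dtype=float),
        )
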