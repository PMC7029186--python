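"""The coupled-oscillator model across its four developmental regimes.

A harmonic pacemaker drives a damped half-center oscillator (both at
20 Hz) during a descending go signal.  Strong coupling (F0=0.5) stands
for the young, pacemaker-driven network; weak coupling (F0=0.01) for the
older network; low damping (zeta=0.1) for intact reciprocal inhibition
and high damping (zeta=0.5) for strychnine.  The printed amplitude shows
how much 20 Hz rhythm survives in each regime.
"""

import numpy as np

import tailbeat as tb
from tailbeat.oscillator import OscillatorParams

outputs = tb.regime_outputs(OscillatorParams())
print(f"{'F0':>5} {'zeta':>5} {'FFT peak':>9} {'20 Hz amplitude':>16}")
for (f0, zeta), out in outputs.items():
    xg = out.gated()
    freqs = np.fft.rfftfreq(xg.size, out.params.dt_s)
    mag = np.abs(np.fft.rfft(xg - xg.mean()))
    amp_20 = 2 * mag[np.abs(freqs - 20.0).argmin()] / xg.size
    print(f"{f0:>5} {zeta:>5} {freqs[mag.argmax()]:>7.2f}Hz {amp_20:>15.2e}")

p = OscillatorParams(f0=0.5, zeta=0.1, f1=0.0)
print(f"\nclosed-form resonant amplitude F0/(2 zeta omega0^2) = "
      f"{tb.resonant_steady_amplitude(p):.3e} (compare the strong-coupling, "
      "low-damping row)")
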