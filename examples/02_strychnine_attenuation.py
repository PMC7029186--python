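"""Attenuation of rhythmicity by glycine blockade, 3-dpf-like vs 5-dpf-like.

For each synthetic "fish", a control and a strychnine-like recording share
one seed (same episode layout, same tail-beat frequency), mirroring paired
recordings before and after drug application.  The attenuation
1 - Peak_20-40(strychnine)/Peak_20-40(control) is near zero when the
rhythm survives blockade (3-dpf-like bursts retain a residual rhythm) and
near one when blockade abolishes it (5-dpf-like beat-and-glide).

Tail-beat frequencies are drawn mid-band (25-35 Hz), where the quadratic
peak detector has full power (see docs/methods.md on its power band).
"""

import numpy as np

import tailbeat as tb

def paired_scores(mode_base, n_fish=5, seed0=11):
    rng = np.random.default_rng(seed0)
    ctrl, stry = [], []
    for _ in range(n_fish):
        f = float(rng.uniform(25.0, 35.0))
        fish_seed = int(rng.integers(2 ** 31))
        for cond, acc in (("ctrl", ctrl), ("str", stry)):
            spec = tb.SyntheticTraceSpec(mode=f"{mode_base}_{cond}",
                                         tailbeat_hz=f, seed=fish_seed)
            trace, _ = tb.generate_fictive_trace(spec)
            acc.append(tb.rhythm_score(trace).score)
    return np.array(ctrl), np.array(stry)

for label, mode in (("3-dpf-like (burst)", "burst"),
                    ("5-dpf-like (beat-and-glide)", "bg")):
    ctrl, stry = paired_scores(mode)
    att = tb.attenuation(ctrl.mean(), stry.mean())
    try:
        p = f"{tb.compare([ctrl, stry], 'paired').p_value:.3g}"
    except ValueError:
        p = "-- (constant difference across fish)"
    print(f"{label}: ctrl={ctrl.mean():.2f}  str={stry.mean():.2f}  "
          f"attenuation={att:.2f}  paired t p={p}")

print("\nA larger attenuation in the beat-and-glide group reproduces the"
      "\ntransition from a weakly to a strongly glycine-dependent rhythm.")
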