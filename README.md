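# tailbeat

Rhythmicity analysis of fictive swimming in developing larval zebrafish.

Between 3 and 5 days post-fertilization (dpf), zebrafish swimming matures
from long, infrequent *burst* episodes to short, frequent *beat-and-glide*
episodes, and the 20–40 Hz tail-beat rhythm shifts from a weakly
glycine-dependent rhythm (WGDR, pacemaker-driven) to a strongly
glycine-dependent rhythm (SGDR, half-center network). `tailbeat` provides
the complete analysis toolkit for studying this transition on
ventral-root-style recordings, motoneuron current recordings, and
high-speed swim videos — together with seeded synthetic-data generators so
every stage runs and is testable fully offline.

## The core statistic: Peak_20–40

An epoch of recorded swimming is called *rhythmic* when the
autocorrelation function of the (1–200 Hz band-passed) signal, fitted over
the 20–50 ms lag window with a second-order polynomial

```
acf_fit(τ) = a0 + a1·τ + a2·τ²
```

is concave down (`a2 < 0`) with vertex `−a1/(2a2)` strictly inside
25–50 ms — i.e. a periodicity in the 20–40 Hz tail-beat band. A
recording's **Peak_20–40 score** is the fraction of ten 200-ms epochs
(drawn from swimming episodes longer than 200 ms) that pass this test, and
the effect of a glycine blocker is quantified as

```
attenuation = 1 − score_strychnine / score_control.
```

Around this sit: an envelope-threshold episode detector, 375-ms-epoch STFT
heat maps, a video pipeline (silhouette → skeleton midline → 30 segment
bend angles → per-segment FFT), a coupled-oscillator model of the
pacemaker→network transition (a damped oscillator
`x'' + 2ζω₀x' + ω₀²x = F₀·sin(ω₀t) + F₁(t)` resonantly driven during a
descending "go signal"), and the study's statistics (paired/unpaired
Student t, one-way ANOVA, Bonferroni).

## Worked example

```python
import tailbeat as tb

spec = tb.SyntheticTraceSpec(mode="bg_ctrl", tailbeat_hz=30.0, snr=5.0, seed=7)
trace, truth = tb.generate_fictive_trace(spec)
score = tb.rhythm_score(trace)
print(f"Peak_20-40 score: {score.n_detected}/{score.n_epochs} = {score.score:.2f}")
```

prints

```
Peak_20-40 score: 10/10 = 1.00
```

— all ten 200-ms epochs of this 5-dpf-like control recording carry a
detectable 20–40 Hz peak (the quadratic fits have `a2 ≈ −7.5e-3` with
vertices near 33.9 ms ≈ one 30 Hz period). Running the paired
control/strychnine comparison (`examples/02_strychnine_attenuation.py`)
prints

```
3-dpf-like (burst):           ctrl=1.00  str=0.60  attenuation=0.40
5-dpf-like (beat-and-glide):  ctrl=1.00  str=0.00  attenuation=1.00
```

— blocking glycine barely dents the 3-dpf-like rhythm (a residual rhythm
persists) but abolishes the 5-dpf-like rhythm: the WGDR→SGDR direction.
The `examples/` directory has one short script per capability (scoring,
attenuation, STFT, kinematics, oscillator regimes, IPSC rhythmicity), each
printing the numbers it computes and what they mean.

A thin CLI wraps the same functions:

```
tailbeat simulate --mode bg_ctrl --seed 7 --out trace.csv
tailbeat score-rhythm --trace trace.csv --out scores.json
tailbeat stft --trace trace.csv --out spec.csv --png spec.png
tailbeat oscillator --f0 0.5 --zeta 0.1 --out sim.csv --acf acf.csv
tailbeat run --config examples/demo_config.yaml
```

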