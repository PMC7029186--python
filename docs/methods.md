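# Methods

## Signal model and the Peak_20–40 statistic

Fictive swimming appears on a ventral-root recording as episodes — bursts
of high-frequency electrical activity longer than 200 ms — carrying the
20–40 Hz tail-beat rhythm. The analysis chain is:

1. **Band-pass 1–200 Hz.** Butterworth (`scipy.signal.butter`, order 4)
   applied forward–backward (`sosfiltfilt`): unit passband gain, zero
   phase. The 1 Hz edge has a multi-second transient; tests and examples
   read steady-state behaviour away from trace edges.
2. **Episode detection.** The rectified signal is smoothed over 20 ms;
   samples above `median + k·σ` (k = 3, σ = 1.4826·MAD of the envelope, a
   robust scale estimate that episodes cannot inflate) mark activity; gaps
   under 50 ms are merged and runs under 200 ms dropped. The source
   workflow identified episodes by inspection; this detector is this
   package's own, and its parameters are exposed.
3. **Epoch extraction.** Ten 200-ms epochs lying fully inside episodes.
   Default placement is the earliest non-overlapping windows across
   episodes in temporal order (deterministic); seeded random placement is
   available. Ten epochs are used at all ages so that long-episode (3 dpf)
   and short-episode (5 dpf) recordings are analyzed identically.
4. **Autocorrelation.** Mean-removed, biased estimator (normalized by the
   zero-lag value), lags 0–100 ms. The biased estimator keeps |acf| ≤ 1;
   detection is invariant to amplitude rescaling by construction.
5. **Quadratic fit and peak test.** Least squares of
   `a0 + a1·τ + a2·τ²` on the lag samples in [20, 50] ms (inclusive). A
   peak is detected iff `a2 < 0` and `25 < −a1/(2a2) < 50` (strict; a
   vertex at exactly 25 or 50 ms, or `a2 = 0`, is no peak). The asymmetry
   — fitting from 20 ms but accepting from 25 ms — is part of the printed
   procedure and is preserved, not "corrected".

The **score** is the exact fraction n_detected/n_epochs. **Attenuation**
is `1 − score_str/score_ctrl` (undefined for a zero control score — an
explicit error). The **rejection rule** discards animals whose control
score is below 50%, with a per-animal exemption flag (used in the source
study for somite-1 recordings at 5 dpf).

### Measured power band of the detector

The printed conditions give the statistic a hard power band. On noise-free
signals the 20–50 ms window sees, for beat frequencies below ≈23 Hz, a
trough followed by a peak at/beyond 50 ms (the fit turns convex or the
vertex lands ≥ 50 ms), and above ≈36 Hz two full autocorrelation periods
(peak–trough–peak, so `a2 ≥ 0`). Detection is therefore essentially
certain for ≈24–34 Hz tail beats at snr ≥ 3 and essentially impossible
outside ≈23–36 Hz, for any waveform family we tried (sinusoids, tapered
sinusoids, Gaussian burst trains, stereotyped biphasic wavelet trains).
Consequently a population whose tail-beat frequencies span the full
20–40 Hz band uniformly averages a control detection rate near 0.6, while
mid-band populations score near 1.0. On featureless noise the test fires
on roughly one epoch in three (concave-down fits with an in-window vertex
are that common by chance), so arrhythmic recordings score near 0.3 —
which is why a 50% rejection cutoff on control recordings is meaningful.

A special case of the band edge: a signal at exactly 20 Hz has its
autocorrelation peak at exactly 50 ms, the open boundary of the acceptance
interval, and is never detected. This matters for the oscillator model
below, whose natural frequency is 20 Hz.

## STFT heat maps

30-s recordings are band-passed and cut into consecutive non-overlapping
375-ms epochs; each epoch's FFT magnitude (≤ 200 Hz) is one column of the
heat map. No windowing beyond the rectangular epoch is applied, matching
the plain per-epoch Fourier transform of the source workflow.

## Kinematics

Frames are thresholded (fixed value or Otsu), dilated one pixel, the holes
filled, and the largest connected component kept. The morphological
skeleton's longest geodesic path is the midline; spurs that medial axes
grow into blunt body ends are trimmed by walking in from each end while
the distance-to-background climbs steeply (≥ 0.5 per step) — a tapered
tail changes slowly and is untouched. The midline is ordered from the
embedded head (configurable image side), lightly smoothed against pixel
quantization, and resampled to 31 arc-length-uniform points bounding 30
segments. A segment's bend angle is the arctangent of its slope (folded
into (−π/2, π/2], so it is independent of traversal direction) minus the
same quantity on the rest posture (first frame by default). Per-segment
FFTs of the angle time series localize the tail-beat band along the body.

Body coordinate convention: the extreme caudal segment is 1.0 and the
rostral end 0.0 by default. The source descriptions of this convention
conflict with each other (the methods text states the reverse of the
figure legend); we follow the figure convention and expose
`caudal_is_one` as an option rather than hard-coding either.

## Coupled-oscillator model

Two coupled abstract oscillators: a harmonic pacemaker (the IC-interneuron
kernel) drives a damped half-center oscillator, both with natural
frequency ω₀ = 20 Hz (treated as ordinary frequency; ω₀ = 2π·20 rad/s in
the equations — the output must oscillate in the tail-beat band). The
network output solves

    x'' + 2ζω₀x' + ω₀²x = F₀·sin(ω₀(t − t₁)) + F₁(t)

with both drive terms gated by the descending go signal on [t₁, t₂]. The
printed source equation omits the x in the restoring term; it is restored
here, as the standard damped driven oscillator, since without it the
system has no natural frequency. The pacemaker is not integrated
separately — its output is exactly the sinusoidal drive during the gate.
ζ encodes reciprocal (glycinergic) inhibition, i.e. strychnine raises ζ;
F₀ encodes pacemaker→network coupling, which falls as the network matures.
Regimes: F₀ ∈ {0.5, 0.01} × ζ ∈ {0.1, 0.5}.

Defaults not stated by the source: F₁ = 1 (a.u.), gate [0.5 s, 2.5 s],
duration 3 s, dt = 10⁻⁴ s, x(0) = x'(0) = 0. Integration is fixed-step
classical RK4; a step larger than 1/(100·ω₀_Hz) is rejected before
integrating. Verified properties: halving dt changes the solution by
< 10⁻⁶ (max norm); the response is linear in (F₀, F₁) to 10⁻⁹; the
post-gate envelope decays at ζω₀ within 5%; the resonant steady state
matches the closed form F₀/(2ζω₀²) within 2%.

**Model readout.** The gated output (optionally with seeded additive
observation noise) is analyzed with the same autocorrelation + Peak_20–40
machinery as recordings, on 200-ms windows. Because the model output
oscillates at exactly 20 Hz in every regime, its autocorrelation peak sits
on the 50 ms boundary and the printed peak test cannot fire in *any*
regime — the band-edge degeneracy described above. The regime contrast the
model is meant to illustrate (rhythm everywhere except weak coupling with
high damping) does emerge from this readout when the natural frequency is
placed mid-band (e.g. 30 Hz) with a common observation-noise level; at the
canonical 20 Hz the readout should be taken from the plotted
autocorrelation functions (whose oscillation amplitude separates the
regimes cleanly), as the source study did.

## Synthetic data generators

The generators define the study conditions; all are bit-reproducible under
a fixed seed (one `numpy` Generator per call).

* **Fictive traces.** White Gaussian background (SD 1); episodes placed
  with exponential gaps (0.2 s floor) and truncated-normal durations
  around the mode mean (3-dpf-like burst: 2 s episodes at 0.1 /s over
  30 s; 5-dpf-like beat-and-glide: 0.3 s at 0.8 /s over 20 s). Episode
  envelopes have 20 ms raised-cosine ramps (no spectral splatter into the
  band-power oracles). Control episodes carry a sinusoid at the
  recording's tail-beat frequency with amplitude snr·SD (default snr 5).
  Strychnine-like episodes instead carry a zero-mean slow wave (0.5–4 Hz,
  at least one full cycle per episode so its energy stays inside the
  1–200 Hz band rather than exciting the filter edge) plus a broadband
  noise boost (half the carrier amplitude) — long-duration voltage
  changes with high-frequency but arrhythmic content. In the 3-dpf-like
  strychnine mode each episode keeps the rhythmic carrier with
  probability 0.6 (oscillations persist in more than half of 3-dpf
  episodes under blockade); in the 5-dpf-like mode, never. This residual
  rhythm is what produces the WGDR→SGDR attenuation contrast by
  construction.
* **IPSC trains.** Stereotyped difference-of-exponentials kernels (rise
  1 ms, decay 5 ms — kinetics are this package's choice, none were
  stated), at periodic-with-Gaussian-jitter times (rhythmic) or
  homogeneous-Poisson times (arrhythmic).
* **Swim videos.** A tapered, round-capped silhouette (half-width
  7 px → 2 px head to tail; thickness under 3 px is rejected since the
  skeleton is undefined) whose midline is a traveling sine
  `y(s, t) = A(s)·sin(2π(s − f·t))` with caudally growing amplitude
  `A(s) ∝ 0.1 + 0.9s²`, rendered at 500 fps, 120×260 px, with analytic
  midlines and segment angles attached as ground truth.

What the generators do *not* emulate: spike-level structure and motor-unit
composition of real ventral-root bursts, within-episode frequency
modulation, electrode drift, line noise, camera optics and illumination
gradients, or body-thickness variation between fish. Tests passing on this
synthetic data therefore validate the pipeline's numerics and logic — not
its robustness to every artifact of real recordings.

## Statistics

Two-tailed paired and unpaired Student t tests (`scipy.stats`; classic
equal-variance form, as an unqualified "Student's t test" implies) and
one-way ANOVA; on two groups F = t² exactly. Identical paired samples
return t = 0, p = 1 by convention rather than 0/0. The Bonferroni
threshold is exact (α/m) internally; displays truncate to four decimals,
reproducing the printed 0.0166 (m = 3) and 0.0125 (m = 4). Episode-duration
summaries pool episodes across animals (e.g. 10 per fish × 5 fish, SEM =
SD/√50) by default, with per-animal averaging as an option.

## Pipeline and reproducibility

One top-level seed expands into independent per-stage streams via
`numpy.random.SeedSequence.spawn`, so adding recordings to one stage never
perturbs another. Paired control/strychnine recordings of one synthetic
fish share a seed: identical episode layout and tail-beat frequency,
differing only in episode content — the synthetic analogue of recording
the same fish before and after drug application. Run manifests record the
package version, a SHA-256 of the canonical config and all derived seeds;
reruns are byte-identical. Problem sizes throughout (20–30 s recordings at
10 kHz, 250-frame videos, 100-seed Monte-Carlo ladders) keep any single
analysis in seconds on one core while leaving the Monte-Carlo estimates'
sampling error well inside the asserted margins.

## Known limitations

* The Peak_20–40 statistic's power band (≈23–36 Hz) is a property of the
  printed window and conditions, not of this implementation; studies whose
  frequencies hug the band edges will under-detect, and a 20 Hz signal is
  undetectable in principle.
* The episode detector is an envelope-threshold stand-in for expert
  inspection; heavily fragmented or drifting recordings may need its
  parameters adjusted.
* The kinematics midline is pixel-quantized; rostral segments with
  sub-pixel motion carry relatively large angle noise (the dominant
  frequency is still recovered).
* The oscillator model is linear, so coupling strength scales amplitude
  exactly; it cannot capture amplitude saturation or entrainment effects
  of real half-center circuits.
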