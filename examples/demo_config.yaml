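# End-to-end demo for `tailbeat run --config examples/demo_config.yaml`
# Two paired groups (3-dpf-like bursts, 5-dpf-like beat-and-glide), four
# synthetic fish each; outputs scores.json, attenuation.csv, report.json,
# an STFT heat map and the oscillator regime panel.
seed: 42
out_dir: tailbeat_demo
n_epochs: 10
groups:
  3dpf:
    mode: burst
    n_animals: 4
  5dpf:
    mode: bg
    n_animals: 4
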