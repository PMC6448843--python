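# provoc

Phase-vocoder randomization of the prosody/melody of speech and music
recordings, plus the reverse-correlation analysis used to map listeners'
mental representations from two-interval forced-choice responses.

`provoc` cuts a base recording into successive time segments and applies a
random parametric transformation of each segment's **pitch** (cents),
**duration** (stretch ratio) or **amplitude** (dB), driven by stochastic
breakpoint functions (BPFs) and realized with a phase-locked phase vocoder.
The analysis side computes first-order temporal kernels (mean chosen minus
mean non-chosen stimulus profile), within-subject and split-plot ANOVAs on
the kernels, double-pass agreement, and internal-noise estimates from a
signal-detection model with late additive noise and response bias.

## Layout

| module                | contents                                                         |
|-----------------------|------------------------------------------------------------------|
| `provoc.signal_core`  | WAV I/O, analysis windows, STFT / inverse STFT                   |
| `provoc.transforms`   | phase-locked phase propagation, time stretch, pitch shift, gain, resampling |
| `provoc.bpf`          | breakpoint functions, truncated-Gaussian sampling, f0 tracking, pitch flattening |
| `provoc.batch`        | config-driven batch generation, transformation chaining, case-study stimulus recipes |
| `provoc.revcorr`      | kernels, ANOVAs, double-pass agreement, internal-noise estimation, convergence curves |
| `provoc.synthetic`    | tones / glides / note sequences and simulated template observers |

## CLI

Generate a batch of randomized stimuli from a base sound (mono WAV):

```sh
provoc generate --input base.wav --config conf.yaml --seed 1234 --out stimuli/
```

with a YAML configuration such as

```yaml
numFiles: 10          # outputs to generate
outPath: ./out        # default output folder
chain: true           # apply transformations in series
transf: [stretch, pitch]
stretch: {numWin: 6, winUnit: n, std: 0.4, trunc: 1.6, BPFtype: square, trTime: 0.1}
pitch:   {numWin: 6, winUnit: n, std: 70,  trunc: 2.2, BPFtype: ramp}
```

Each output WAV is written with one 2-column BPF log per applied
transformation and a `manifest.csv`.  `provoc make-fixtures --out DIR`
writes deterministic synthetic WAVs and a simulated response table for
experimentation.

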