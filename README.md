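# vhfilter

Virtual hexagonal trellis (VHT) filtering for blood-smear (white blood
cell) image enhancement, with the full quality-metric suite used to
evaluate it and a seeded synthetic smear generator so everything is
testable without any dataset.

## What it does

- **Preprocessing** (`vhfilter.preprocess`): crop/resize, per-channel
  complement, dark-channel dehazing (`I = J*t + A*(1-t)` inverted with an
  estimated atmospheric light and transmission map), and BT.601 grayscale
  conversion. The default pipeline dehazes the *complemented* image so the
  dark-channel prior applies to the smear's bright background.
- **Kernel derivation** (`vhfilter.kernel`): the 3x3 VHT kernel
  `[[1,0,1],[2,6,2],[1,0,1]] / CFF` is derived symbolically — virtual
  pixels at the corner/centre midpoints, a seven-term hexagonal average,
  denominators cleared to integers — not hard-coded, so every coefficient
  is testable. CFF (the normalizing divisor) is free; 14 gives unit DC
  gain.
- **Convolution** (`vhfilter.convolve`): single-stride 3x3 filtering with
  exact integer arithmetic and explicit rounding (`floor` / `half_up` /
  `ceil`) and border (`replicate` / `reflect` / `zero`) contracts.
- **Quality metrics** (`vhfilter.metrics`): MSE, PSNR (100 dB cap), MAE,
  NAE, NCC, Gaussian-window SSIM, 256-bin Shannon entropy, blockwise EME
  contrast, Fourier-domain alpha rooting, and the classical comparator
  filters (histogram equalization, 3x3 mean, 3x3 adaptive Wiener).
- **Synthetic data** (`vhfilter.synth`): seeded WBC-like smears — bright
  stained background, elliptical cytoplasm, lobed nucleus, dark granules —
  with known clean/hazed pairs for round-trip testing.
- **Experiment drivers** (`vhfilter.experiments`): CFF sweep (PSNR/MSE per
  CFF in 7..19), four-method comparison table, and EME-vs-alpha sweeps.

A note on rounding: the in-paper worked example (`patch
[[3,0,1],[6,6,2],[2,4,1]]`, weighted sum 59, divisor 14) prints 5, which
only ceiling rounding reproduces (59/14 ≈ 4.21). `ceil` is therefore the
fidelity mode; `half_up` is the general-purpose default.

## CLI

The `vhf` entry point (or `python -m vhfilter.cli`) exposes:

```sh
vhf synth --n 5 --seed 7 --out fixtures/          # synthetic clean/hazed/mask triples
vhf enhance fixtures/hazed_000.png -o out.png --cff 14 --rounding ceil
vhf derive-kernel --cff 14                        # kernel grid as JSON
vhf metrics --ref a.png --test b.png --format csv
vhf sweep-cff fixtures/clean_000.png -o sweep.csv --plot sweep.png
vhf compare fixtures/clean_000.png -o compare.csv
vhf alpha-sweep --original clean.png --noisy hazed.png -o alpha.csv
```

Exit codes: 0 success, 2 bad input, 3 config-file error. A flat
`key = value` config file (`vhf --config run.cfg <cmd>`) pre-sets any
option; command-line flags win.

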