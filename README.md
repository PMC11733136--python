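# dropletpix

A desk-scale software stand-in for a droplet-microfluidics pixel-array
platform. The package covers the full computational chain of such a system:

- **`synthetic_data`** — synthetic photodetector voltage traces: Gaussian
  pulse trains over a noisy (optionally drifting) baseline, and mixed
  multi-group droplet populations in which each droplet transit yields three
  pulses (one per laser excitation point) on a single collected stream.
- **`peak_detection`** — a streaming peak detector with a drift-free adaptive
  baseline: a moving average over baseline-classified samples only (in-peak
  samples are excluded so pulse trains cannot drag the baseline), threshold
  at a multiple of the window SD, greedy group-time assembly of per-droplet
  three-channel signatures. Chunked streaming is byte-identical to a single
  pass.
- **`classification`** — the 8-color droplet palette (high/low levels of
  blue, green, red), unsupervised k-means population recovery, and a
  supervised per-channel threshold classifier for sorting decisions.
- **`component_models`** — empirically anchored surrogates: droplet
  generation envelope (95–176 µm, 4–368 Hz over the characterized flow
  rectangle), Poisson single-cell loading with OD-to-cell conversion,
  picoinjection volume change (−3 % to +50 %), the three sorting regimes
  (no deflection < 100 V < sorted < 400 V < failure at 1 mL/hr, scaled with
  flow), and anchor trapping outcome bands.
- **`pixel_compiler`** — image "dropletization" (block-average then snap to
  the nearest palette color), 5×5 tiling with unique-pattern deduplication,
  sort-instruction compilation that inverts the serpentine anchor FIFO
  (each sorted droplet knocks all occupants one anchor deeper), mosaic
  stitching, and rendering.
- **`workflow_simulator`** — an end-to-end run: generate a droplet stream as
  a raw trace, sense it with the peak detector, classify, sort against the
  instruction list (wait-for-color), push through the anchor FIFO, and
  verify the final grid pixel-by-pixel. Fault injection covers nonspecific
  sorting, anchor skips, and double occupancy; a built-in 35-pattern 5×5
  alphanumeric symbol library exercises the full chain.
- **`io_cli`** — CSV traces, PNG/PPM images, JSON artifacts, strict YAML
  configuration, and the `dropletpix` command-line interface.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the headline criteria: the exhaustive FIFO
law at 25 anchors, compile→replay→render round-trips on 1000 random tiles,
streaming/offline detector equivalence, ≥ 0.99 detector recall at SNR 10 on
400 droplets, drift-immunity contrast against an ablated detector, k-means
recovery of 8 populations (ARI ≥ 0.95), Poisson Monte-Carlo vs closed form,
the sorting-regime voltage scan, the picoinjection and generation envelope
endpoints, zero-fault simulator fidelity on 100 random targets, and the
35-symbol library.

## CLI

```sh
dropletpix synth-trace --config cfg.yaml --out trace.csv --truth truth.json
dropletpix detect      --trace trace.csv --config cfg.yaml --out sig.json
dropletpix classify    --sig sig.json --fit-k 8
dropletpix dropletize  --image img.png --width 10 --height 10 --out grid.json
dropletpix compile     --grid grid.json --out compiled.json
dropletpix stitch      --compiled compiled.json --out mosaic.json
dropletpix simulate    --target target.json --seed 7
dropletpix component   --which sorter --flow 1.0 --voltage 250
dropletpix verify      --grid out.json --target target.json
```

Exit codes: 0 clean, 2 mismatches found, 1 error.

## A note on detector timing

The adaptive threshold is a multiple of the SD of the baseline window, and
in-peak samples are excluded from that window — but sub-threshold pulse
*shoulders* are not. If pulses arrive faster than the window length, those
shoulders accumulate, inflate the SD, and the threshold chases the signal.
Keep the baseline window shorter than the pulse spacing (defaults here:
100-sample window at 10 kHz, ≥ 12 ms pulse spacing); `min_below_to_close`
adds a close-side debounce against noise-split peaks.
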