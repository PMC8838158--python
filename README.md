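# ecgcnn

A compact six-class ECG heart-beat classifier — a fixed 297-parameter CNN —
together with a **bit-accurate behavioral simulator of its resource-shared
fixed-point hardware datapath**, trainable and testable end-to-end on
synthetic beats (no data downloads required).

The network classifies single beats (2×24 input tensors derived from a
48-sample window at 360 Hz centered on the R peak) into six classes:
Normal (N), LBBB (L), RBBB (R), PVC (V), APB (A) and Paced (/). The
architecture is fixed and bias-free:

```
2×24 ─ conv 3×(1×7) ─ ReLU ─ maxpool 1×2 ─ conv 1×1 ─ ReLU
     ─ conv 3×(1×7) ─ ReLU ─ maxpool 1×3 ─ flatten(6) ─ fc 6→21 ─ ReLU ─ fc 21→6 ─ argmax
```

Per-layer parameter counts: 21 / 3 / 21 / 126 / 126 = **297**.

## Packages

| module | contents |
|---|---|
| `ecgcnn.model` | float reference network: layer ops, forward pass, weight container |
| `ecgcnn.datapath` | hardware simulator: 7-lane MAC PE, ReLU unit, max-pool unit, 54-register control buffer, argmax unit, mux schedule (S1–S6), fixed-point quantization, error bounds, float-vs-fixed comparison |
| `ecgcnn.training` | SGD-with-momentum training (hand-written backprop), calibration, weight quantization |
| `ecgcnn.synthetic` | seeded Gaussian P-QRS-T beat generator, six class-distinct morphologies |
| `ecgcnn.evaluation` | confusion matrix, per-class recall, overall accuracy, optional WFDB beat extractor |
| `ecgcnn.wfdb_io` | minimal WFDB header/signal (formats 16 and 212) and annotation I/O |

The synthetic morphologies are *caricatures* sufficient to exercise the
classifier — not clinical simulations.

## CLI

```sh
ecgcnn generate --seed 1 --out beats.tsv                  # 12,000 train + 3,000 test beats
ecgcnn train    --data beats.tsv --seed 1 --out w.json
ecgcnn quantize --weights w.json --out qw.json            # Q4.12 by default
ecgcnn infer    --weights qw.json --data beats.tsv --out preds.txt
ecgcnn evaluate --weights w.json --data beats.tsv --out eval.tsv
ecgcnn compare  --weights w.json --data beats.tsv --out cmp.tsv
```

`compare` runs every beat through both the float reference and the
fixed-point datapath simulator and reports per-beat agreement (the
hardware/software co-verification methodology; "pass" = identical class).

## Fixed-point model

Default format is 16-bit words with 12 fractional bits for weights and
activations; PE sums are carried at full product precision and requantized
(round-to-nearest-even, saturating) only at unit outputs. Word lengths are
configurable — the published design does not state them. Because the
network has no biases it is positively homogeneous, so
`training.calibrate_weights` rescales layers to fit the dynamic range
without changing any prediction.

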