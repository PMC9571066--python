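# hfomorph

Morphological spike rejection for ripple (high-frequency oscillation)
detection in intracranial EEG.

Sharp interictal spikes ring when passed through the 80–500 Hz band-pass
filter that every RMS-style ripple detector starts with, and the ringing is
indistinguishable from a real 80–250 Hz ripple to threshold rules. This
package implements:

- **`hfomorph.morphology`** — exact 1-D flat grayscale morphology
  (erosion / dilation / opening / closing) with an O(n) van Herk
  sliding-extrema fast path, edge replication, and a brute-force oracle the
  fast path must match sample-for-sample.
- **`hfomorph.preprocess`** — zero-phase FIR band-pass, rectification,
  rectified first difference, moving-average and RMS envelopes (centered
  odd windows, edge-replicated).
- **`hfomorph.staba`** — the classical RMS ripple detector: runs of the
  3 ms RMS envelope above mean + 5 SD lasting ≥ 6 ms (events < 10 ms apart
  clustered), confirmed by ≥ 6 rectified-signal peaks above mean + 3 SD.
- **`hfomorph.classifier`** — the spike-vs-ripple screen: per event, the
  smoothed (10 ms) rectified first difference is enveloped by a 1 ms
  closing and truncated by an opening (default 4 ms); the **dynamic
  threshold** is the maximum truncated level over a training set, and
  events whose envelope peak exceeds it are called spikes. A sweep over
  opening windows (1–8 ms) scores each size by sensitivity / false
  detection rate.
- **`hfomorph.evaluation`** — event-level confusion counts (spike =
  positive class), SE = TP/(TP+FN), FDR = FP/(FP+TP), Euclidean ROC
  distance to the ideal point (0 % FDR, 100 % SE), optimal-window
  selection, and seeded repeated stratified cross-validation.
- **`hfomorph.synthetic`** — a seeded generator of labeled recordings
  (1/f background, triangular spikes with a fast upstroke, Hann-windowed
  ripple bursts) so the whole pipeline is testable without patient data.
- **`hfomorph.io` / `hfomorph.cli`** — CSV and minimal EDF signal I/O,
  event tables, YAML run configuration, and the command-line surface.

## Command-line usage

The `hfomorph` entry point chains the whole pipeline:

```sh
# 1. a labeled synthetic recording (60 s at 5 kHz, 10 spikes, 20 ripples)
hfomorph simulate --seed 42 --out-signal signal.csv --out-events truth.csv

# 2. candidate ripple events from the RMS detector
hfomorph detect signal.csv --out candidates.csv

# 3. fit the dynamic spike threshold on labeled training events
hfomorph train signal.csv labeled.csv --open-ms 4 --out threshold.json

# 4. screen candidates: spike or ripple
hfomorph classify signal.csv candidates.csv threshold.json --out predicted.csv

# 5. score predictions against ground truth
hfomorph evaluate predicted.csv truth.csv --out metrics.json

# opening-window sweep + ROC operating-point selection
hfomorph sweep signal.csv labeled.csv --out sweep.json --out-csv sweep.csv
```

Signals are CSV (`# fs=<Hz>` header, `sample_index,value` rows) or EDF;
event tables are CSV with 0-based half-open sample intervals
(`start_sample,end_sample,start_s,end_s,label,score`). All outputs carry a
provenance header (tool version, config hash, seed). A YAML config file
(`--config`) can override any detector/morphology parameter; unknown keys
are rejected.

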