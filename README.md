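# cardioset

Interpretable, set-based analysis of multichannel heart-sound recordings:

1. **synthetic** — generates 4-channel phonocardiogram fixtures (S1/S2
   transient trains, optional band-limited diastolic "murmur" noise planted
   only in the pre-treatment class, per-channel integer delays, additive
   noise) with full ground truth, so every downstream stage is testable
   without patient data.
2. **preprocess** — delay-and-sum beamforming (cross-correlation delay
   estimation within ±25 ms), 1.5 s / 50 %-overlap windowing, a simplified
   homomorphic-envelope S2 detector (with an annotation-sidecar bypass), and
   128 ms diastolic windows starting 100 ms after each S2 onset.
3. **mp** — Gabor-dictionary matching pursuit with an FFT-accelerated,
   exact all-translation atom search (octaves 2–12, per-octave frequency
   grids capped at 1000 Hz, analytically optimal phase). 100 atoms per
   segment by default; an exhaustive-enumeration path exists as an oracle.
4. **features** — per-atom features: scaled coefficient magnitude,
   sine/cosine phase, min-max scaled frequency and octave, four
   atomic-influence counts (temporal-overlap counts split by extraction
   order and relative octave), and an integer-encoded patient ID.
5. **model** — a permutation-invariant DeepSets classifier (atom encoder →
   shared MLP → sum/mean/max/attention pooling → output head) implemented
   directly on NumPy with hand-written backprop.
6. **train** — 0.70/0.15/0.15 stratified splits with batches of 16, Adam
   with decoupled weight decay, early stopping on validation accuracy,
   seeded random hyperparameter search over the documented space, and a
   Random Forest baseline on set-flattened features.
7. **interpret** — atom-encoder latents → 2-D UMAP → DBSCAN (eps 0.5,
   min 5) → per-cluster selective reconstruction (Gaussian σ=5 smoothing,
   zero-phase 5th-order 65–400 Hz Butterworth), cardiac-cycle power,
   50 Hz-band STFT power deltas 0–400 Hz, and monotonic
   increase/decrease/mixed grouping within a ±1e-6 tolerance.
8. **cli** — reproducible stage orchestration with YAML config, run
   records, and no-op reruns for unchanged stages.

## Running the pipeline

```sh
cardioset --stage all --seed 7 --config my_config.yaml
```

`--config` overlays a YAML file on the defaults (see
`cardioset.config.default_pipeline_config`); defaults reproduce the
reference analysis parameters. Stages can be run individually
(`--stage synth|preprocess|decompose|featurize|train|search|interpret`);
each writes its artifacts plus a JSON run record under the configured
workdir and is skipped when already up to date (override with `--force`).

Outputs include `leaderboard.csv` (ranked trials with code names),
`best_model.npz`, `embeddings.csv` (per-atom UMAP coordinates and DBSCAN
cluster IDs), and `cluster_report.csv` (per-cluster cycle power, band-power
deltas and group labels).

Note on cost: decomposing a full 1.5 s window into 100 atoms with the exact
all-translation search takes minutes of CPU; the bundled test and example
configurations therefore run on diastolic-window segments, where a 100-atom
decomposition takes ~1.5 s.

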