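# diveresp

Behaviour-specific respiration rates and oxygen-consumption estimates for
diving cetaceans, computed from raw time-depth records plus sparse
video-derived behaviour labels.

The pipeline:

1. **Dive segmentation** (`diveresp.segmentation`) — a 0.5 m minimum dive
   threshold splits a 2 Hz depth trace into alternating dives and surface
   intervals; optional zero-offset correction removes surface drift; video
   behaviour labels observed over time intervals are matched to dives by
   overlap.
2. **Track building** (`diveresp.tracks`) — greedy grouping of dive +
   surface-interval cycles into the shortest contiguous tracks of ≥ 10 min
   cumulative duration; short/long dive classification at a 1-minute
   breakpoint.
3. **Rule labels** (`diveresp.rules`) — dive types from depth bands
   (shallow < 7.5 m, medium 10–30 m, deep > 50 m, logging when the surface
   interval exceeds 10 s; in-between depths stay unlabeled) and foraging
   propagation from deep dives to neighbouring dives and whole tracks.
4. **Hierarchical HMM** (`diveresp.hhmm`) — a coarse Markov chain over
   track behaviours (resting / travelling / foraging) selecting a fine
   Markov chain over dive types, with gamma emissions for max depth, dive
   duration and surface interval. Partial labels enter as hard state
   constraints in every forward–backward/Viterbi recursion. Fitting is by
   constrained EM (exact M-steps, optional Dirichlet-pseudocount
   smoothing), decoding by two-level Viterbi.
5. **Validation** (`diveresp.validation`) — leave-one-whale-out
   cross-validation per age class; one-vs-rest confusion matrices and the
   five error metrics (detection, FP/(FP+TP) false-positive rate,
   precision, specificity, accuracy).
6. **Energetics** (`diveresp.energetics`) — one breath per surfacing
   (configurable logging multiplier), Gompertz length-at-age, power-law
   mass, 15 % reference-mass matching, and VO₂ = rate × V_T × E_O₂ with
   activity levels resting→1, travelling/foraging→2.
7. **Synthetic data** (`diveresp.synthetic`) — a generative mirror of the
   model that renders depth traces with exact truth alignment and
   shallow-biased label subsampling, so every stage is testable offline.

## CLI

```sh
diveresp simulate --n-whales 4 --duration 7200 --seed 1 --out depth.csv
diveresp segment depth.csv --out dives.csv
diveresp run-all depth.csv --out-dir out/          # full pipeline
diveresp fit depth.csv --out params.yaml
diveresp decode depth.csv params.yaml --out decoded.csv
diveresp crossval depth.csv --labels labels.csv --out crossval.csv
```

`run-all` writes `dives.csv`, `tracks.csv`, `params.yaml`,
`respiration.csv`, optional `vo2.csv`/`crossval.csv`, and a
`manifest.json` recording the config hash and seed. Exit codes: 0 ok,
2 schema error, 3 numerical failure. Column schemas are documented in
`diveresp/io.py`.

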