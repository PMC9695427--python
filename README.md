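# dissolvekit

Analysis toolkit for powder-reconstitution mixing and dissolution
experiments:

- **colorimetry** — reduces a discoloration video to a per-pixel gray
  threshold (placed at a fraction *X* of each pixel's initial→final gray
  range), a binary mixed/unmixed classification per frame, the
  percent-mixed curve *M(t)*, the discoloration time *t90* (first frame
  with *M* ≥ 90%), and a map of first-mixed times.
- **conductometry** — normalizes raw conductivity traces per run to a
  0–100% scale and extracts the dissolution time as the first sample
  reaching 90% of the range, censored at the experimental window
  (default 60 s). Batch summaries report mean ± SD over complete
  replicates and count incomplete runs separately.
- **doe_stats** — group summaries, one-way ANOVA with Tukey HSD,
  full-factorial effect/interaction F-tests (fixed-effects OLS,
  type-II ANOVA), pooled two-sample t-test, cell-mean matrices, and the
  impeller Reynolds-number scale-up rule (speed factor = diameter
  ratio²).
- **synthetic_data** — generators for discoloration videos (exponential
  per-pixel model with a rotor-centered rate field), first-order
  conductivity traces, and full-factorial design tables — all with
  closed-form ground truth, so every pipeline stage is verifiable
  without lab data.
- **cli** — a `dissolvekit` command-line interface plus config-driven
  pipeline runs with reproducibility manifests.

Both endpoint rules (colorimetric and conductometric) share one
first-crossing implementation (`dissolvekit.crossing`).

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence, closed-form recovery, noise robustness, statistical
calibration, invariances), each checked against independent brute-force
oracles in `tests/_oracles.py`.

## CLI

```bash
# analyze a PNG frame sequence (or video file)
dissolvekit colorimetry run --input frames/ --fps 60 --roi 100,200,400,400 \
    --x 0.5 --level 90 --epsilon 10 --out results/

# dissolution times from a trace CSV (columns: run_id, time_s, conductivity, ...)
dissolvekit conductometry run --input traces.csv --level 90 --window 60 \
    --smooth 11 --out results/

# factorial screening of a design CSV
dissolvekit doe analyze --design design.csv --alpha 0.05 \
    --interactions particle_class:viscosity_mPas,rpm:viscosity_mPas --out results/

# synthetic ground-truth data
dissolvekit synth video --spec video.yaml --seed 1 --out frames/
dissolvekit synth trace --spec trace.yaml --seed 1 --out traces.csv
dissolvekit synth design --spec design.yaml --seed 1 --out design.csv

# config-driven end-to-end run (writes manifest.json)
dissolvekit run --config pipeline.yaml --out results/
```

Example pipeline config:

```yaml
seed: 7
stages:
  - stage: synth_video
    spec: {height: 64, width: 64, duration: 10.0, fps: 60.0, k0: 3.0, decay_length: 100.0}
  - stage: colorimetry
    level: 90
  - stage: synth_trace
    spec: {tau: 0.5, lag: 1.0}
    replicates: 3
  - stage: conductometry
    window: 60
```

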