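# comboscreen

Analysis toolkit for compound screens that enhance T-cell-mediated tumor
killing, with seeded synthetic data and ground truth for every stage:

- **`comboscreen.screen`** — turns well-level percent-cleaved-caspase-3
  readouts into per-compound interaction scores
  `(combo − compound) / til`, ranks, and enhancer calls (score > 1).
- **`comboscreen.synergy`** — median-effect dose-response fitting
  (`fa/fu = (d/Dm)^m`, OLS on the log-log linearization), Chou-Talalay
  combination indexes (`CI = d1/Dx1 + d2/Dx2`, exclusive by default) and
  isobologram point tables.
- **`comboscreen.enrichment`** — cross-cell-line gene ranking (mean
  treated-minus-control log2 difference per line, averaged across lines),
  unweighted KS enrichment scores with a gene-label permutation null, GMT
  parsing, and `2^-ddCT` qPCR quantification.
- **`comboscreen.simulate`** — deterministic simulators for all four data
  types, each emitting a `SimulationTruth` with the planted parameters
  (interaction γ, Dm/m, Loewe α, planted gene set, fold changes).
- **`comboscreen.cli`** — a `comboscreen` command wiring it all together.

## CLI

Each stage reads/writes plain CSV/TSV/JSON:

```bash
# simulate a screen, then score it
comboscreen simulate screen --config sim.yaml --seed 42 --out sim/
comboscreen screen score --wells sim/wells.csv --out results.csv \
    [--threshold 1.0] [--squared] [--background-subtract]

# dose-response fitting and combination indexes
comboscreen synergy fit --dr dr.csv --out models.json
comboscreen synergy ci --models models.json --combos combos.csv \
    --form exclusive --tol 0.05 --out ci.csv
comboscreen synergy isobol --models models.json --combos combos.csv --out iso.csv

# expression rank + enrichment, qPCR
comboscreen rank build --expr expr.tsv --annot annot.csv \
    --treated ganetespib --control DMSO --out rank.tsv
comboscreen rank enrich --rank rank.tsv --gmt sets.gmt --nperm 1000 \
    --seed 7 --out enrich.json
comboscreen qpcr ddct --ct ct.csv --ref GAPDH --calibrator DMSO --out folds.csv
```

A full simulate→analyze pipeline runs from one YAML config and writes a
`manifest.json` (seed, per-stage record counts, outputs); identical config
and seed reproduce every output byte for byte:

```bash
comboscreen run --config run.yaml --out out/ [--seed 42]
```

```yaml
# run.yaml
seed: 42
stages:
  screen:
    simulate: {n_compounds: 850, n_enhancers: 20, gamma_range: [2, 4],
               noise_sd: 1.0, til_pct: 20.0, compound_effect_range: [2, 10]}
    enhancer_threshold: 1.0
  synergy:
    simulate: {alpha: 2.0, y_noise_sd: 0.05}
  expression:
    simulate: {n_probes: 5000, planted_set_size: 50, delta: 1.0, noise_sd: 0.5}
    n_permutations: 1000
  qpcr:
    simulate: {true_folds: {IFIT1: 4.0, IFIT3: 2.0}}
```

Exit codes: 0 success, 2 validation error, 1 stage failure.

## File formats

- wells CSV: `plate_id,well_id,tumor_line_id,compound_id,dose_nM,til_status,replicate,pct_caspase3`
  with `til_status` literals `TIL`/`NOTIL` and `DMSO` reserved for vehicle.
- dose-response CSV: `agent_id,dose,fa` (fa strictly inside (0, 1));
  combination CSV: `d1,d2,fa`.
- expression TSV: first column `probe_id`, one column per sample;
  annotation CSV: `sample_id,cell_line_id,treatment,replicate`.
- gene sets: standard GMT; qPCR CSV: `sample_id,gene,replicate,ct`.

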