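# boutonmap

Quantification pipeline for two-channel fluorescence images of inhibitory
synaptic boutons, plus the linkage of bouton density to evoked-response
probability. The package covers:

- **`boutonmap.synth`** — seeded synthetic scenes with known ground truth:
  region-dependent punctum densities, a region-dependent reporter-positive
  fraction, bimodal per-punctum reporter intensities, smooth illumination,
  dim axon clutter, and Poisson + Gaussian camera noise. Also simulates
  recorded-cell tables via a logistic density link, and noisy landmark pairs.
- **`boutonmap.preprocess`** — wide-Gaussian background estimation and
  subtraction; ROI-based intensity thresholds (pooled median + k·SD).
- **`boutonmap.detect`** — seed maxima with physical non-max suppression and
  marker-based watershed isolation of puncta.
- **`boutonmap.coloc`** — reporter regional-maximum matching (0.7 µm
  center-to-center radius), KDE valley threshold on the bimodal intensity
  histogram, and reporter-positive classification.
- **`boutonmap.atlas`** — landmark similarity/affine registration, a
  350 µm-grid displacement QC metric, and label-map region assignment.
- **`boutonmap.quantify`** — 144×144×4 µm³ voxel-grid density maps,
  cross-section grid averaging, and per-region count/density/fraction
  summaries.
- **`boutonmap.ephys`** — per-region response statistics, local density
  lookup, binned response probability with Wilson 95% intervals, and a
  tie-corrected Mann–Whitney comparison (permutation variant available).
- **`boutonmap.pipeline` / `boutonmap.cli`** — orchestration, provenance
  logging, and TIFF/CSV/JSON file glue.

## CLI

Generate a synthetic scene (stack + region map + ground truth, and
optionally simulated recorded cells):

```sh
boutonmap synth --seed 1 --out-dir scene/ --ephys-cells 300
```

Run the anatomy analysis on a stack (landmarks optional; without them the
section is assumed to be in atlas coordinates):

```sh
boutonmap anatomy --stack scene/scene.tif --region-map scene/region_map.tif \
    --out-dir run/ [--landmarks landmarks.csv] [--config params.yaml]
```

Outputs: `boutons.csv`, `region_summary.csv`, `pc_density_grid.tif` (+ JSON
sidecar), threshold/bimodal/QC reports, and `run_log.json` with parameters,
input hashes, and per-stage counts.

Run the ephys summaries against an averaged density grid:

```sh
boutonmap ephys --cells scene/ephys_cells.csv --grid scene/true_pc_grid.tif \
    --out-dir ephys_run/
```

Config files are flat YAML mirroring `PipelineParams` (or `SceneConfig` for
`synth`); unknown keys are rejected.

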