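# octquant

Volumetric OCT quantification of corneal opacity. The package takes a 3D
anterior-segment scan (multi-page TIFF, one page per B-scan, plus a JSON
geometry sidecar), corrects per-B-scan axial motion, crops a standardized
corneal button, clears the specular artifact, detects the anterior surface,
flattens the volume against it, trims to an anterior fraction of the stroma,
and applies a dual-threshold segmentation — one fixed cutoff isolating the
corneal button from background, a second (calibrated from naive clear
corneas) classifying hyperreflective voxels as opacity. The headline readout
is % opacity: hyperreflective voxels as a percentage of corneal-button
voxels.

Everything is testable offline: a synthetic phantom generator renders
OCT-like corneal volumes (curved stromal shell, speckle, axial signal
falloff, saturated specular stripe, posterior iris/lens clutter, per-B-scan
jitter) with analytic ground-truth masks and known scar burden, and a
rater-table generator draws two-way random-effects tables with known true
reliability.

## Layout

| module                 | contents                                                            |
| ---------------------- | ------------------------------------------------------------------- |
| `octquant.synthetic`   | phantom and rater-table generators with ground truth                |
| `octquant.volio`       | TIFF/CSV/JSON I/O, `OctVolume` and `RatingTable` containers         |
| `octquant.geometry`    | registration, button crop, specular clearing, surface, flatten, trim |
| `octquant.segmentation`| threshold calibration, button/opacity masks, % opacity, CCT, en-face area |
| `octquant.stats`       | ICC (two-way random, absolute agreement), CoV, weekly change, eligibility filter, Kruskal–Wallis + Dunn, Mann–Whitney, sample size |
| `octquant.pipeline`    | end-to-end composition (`preprocess`, `calibrate`, `quantify`)      |
| `octquant.cli`         | `octquant` command-line interface                                   |

## CLI

```bash
# generate a phantom cohort (volumes + truth masks + manifest)
octquant simulate --out-dir scratch/naive --n 12 --seed 1
octquant simulate --out-dir scratch/eyes --n 2 --seed 2 --scar-percent 15

# calibrate the dual thresholds from scar-free cohorts
octquant calibrate --button-dir scratch/naive --naive-dir scratch/naive \
    --out scratch/model.json

# measure % opacity for every volume in a directory
octquant quantify --input-dir scratch/eyes --model scratch/model.json \
    --out scratch/measurements.csv

# reliability report for a subjects x raters CSV
octquant reliability ratings.csv --out icc.json

# group comparison (Mann-Whitney for 2 groups, Kruskal-Wallis + Dunn for >2)
octquant compare measurements.csv --group-column group
```

Pipeline parameters (button radius, anterior fraction, calibration
percentile, jitter search window, ...) can be supplied via `--config
config.yaml`; phantom geometry keys in the same file configure `simulate`.

## Conventions

- Volumes are indexed `(z, x, y)`: axial depth (anterior at low z), A-scan,
  B-scan. On disk: multi-page TIFF, page order = B-scans, each page `(z, x)`.
- All axial shifts (registration, flattening) are integer-only, preserving
  intensity histograms and therefore threshold semantics.
- % opacity is a pure voxel-count ratio; mm³ volumes are derived via the
  sidecar spacings.
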