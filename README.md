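# spatialtme

Spatial tumor-microenvironment analysis of multiplexed-IHC per-cell
segmentation tables. The package re-implements, as a tested and reusable
pipeline, a whole-slide/TMA workflow for head-and-neck squamous cell
carcinoma cohorts:

- **io_tables** — read/write per-cell tables (configurable inForm-like CSV
  dialect) and clinical tables; strict `> 50%` classifier-confidence filter.
- **phenotyping** — per-marker hi/lo thresholds from the intensity
  distribution (two-component Gaussian mixture on log10 intensities with
  equal-posterior crossing, mean + k·SD fallback, or fixed values);
  CD68/CD163 subset labels and PD-L1/PD-1 hi/lo status (strict `>`,
  threshold 0 separates zero from any expression).
- **spatial** — signed Euclidean distance to the epithelium/tumor–stroma
  boundary (negative inside tumor/epithelium), distance-binned density
  profiles in cells/mm² with cross-sample mean ± SE, band areas via exact
  distance transforms (closed-form for disc nests), nearest-distance
  statistics (MND), and centroid+radius cell–cell contact counting.
- **stats** — Wilcoxon rank-sum with Bonferroni correction (exact
  enumeration for small samples), Spearman correlation screens (exact
  permutation p for n ≤ 9), median / fixed-threshold patient splits,
  Kaplan–Meier curves and the two-group log-rank (Mantel–Cox) test, and
  distance-band covariate extraction.
- **synthetic** — fully seeded synthetic cohorts with ground truth: disc
  tumor nests, boundary-accumulating vs. compartment-uniform cell
  patterns (inhomogeneous Poisson by thinning), bimodal log-normal marker
  intensities, distance-dependent checkpoint status, Beta confidences,
  and exponential survival whose hazard depends on the cell density in
  one signed-distance band.
- **pipeline / cli** — configuration-driven orchestration producing CSV
  tables (compartment densities, profiles, MND, checkpoint proportions,
  contacts, correlation screen, KM/log-rank splits), a JSON threshold
  sidecar and a run manifest.

## CLI

```sh
# generate a synthetic cohort (cell tables + GeoJSON geometries + clinical CSV)
spatialtme generate --seed 1 --n-patients 5 --out data/

# run the full analysis from a YAML config (mode: synthetic | tables)
spatialtme analyze --config run.yaml --out results/run1

# re-render summary tables (optionally a density-profile plot)
spatialtme report --run-dir results/run1 --plot
```

A minimal `run.yaml` for re-analyzing generated tables:

```yaml
mode: tables
seed: 1
output_dir: results/run1
bands: [-25, 25, 75]        # signed-distance bin centers used for survival splits
input:
  cell_tables: [data/cells_S000.csv, data/cells_S001.csv]
  geometries: {S000: data/geometry_S000.geojson, S001: data/geometry_S001.geojson}
  clinical: data/clinical.csv
  dialect:
    marker_cols: {CK: CK, CD45: CD45, CD3: CD3, CD68: CD68, CD163: CD163, PD-L1: PD-L1, PD-1: PD-1}
```

Geometries may be GeoJSON polygon sets (frame + epithelium/tumor
features, µm coordinates) or 8/16-bit label-mask images
(0 = outside, 1 = stroma, 2 = epithelium/tumor; `mask_um_per_px` in the
config sets the scale).

## Conventions

- Coordinates are Cartesian micrometres; densities are cells/mm².
- Signed distances: negative inside epithelium/tumor, positive in stroma;
  a cell exactly on the boundary is "inside".
- "hi" always means strictly greater than the threshold; the confidence
  filter keeps cells with confidence strictly greater than 0.5.
- Default profile binning: 25 µm bins over (−512.5, 512.5) µm, so bin
  centers fall on multiples of 25 µm and the default survival bands
  (−25, 25, 75 µm) are exact bin centers.
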