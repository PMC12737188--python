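# holoquant

Label-free quantification of nanoparticle (NP) uptake in cells from 3D
refractive-index (RI) tomograms, with optional co-registered fluorescence
validation.

The pipeline delineates cells by RI thresholding (foreground at RI ≥ 1.34),
detects intracellular NP aggregates as connected high-RI components
(RI > 1.36), computes per-cell uptake metrics (aggregate count, NP volume
fraction, mean RI), quantifies fluorescence/high-RI colocalization
(Manders-style overlap fraction plus voxel Pearson), and assembles a summary
report with Pearson correlations (two-tailed t-transform p-values), group
comparisons, and distribution fits. A fully seeded synthetic-scene generator
produces paired RI/fluorescence volumes with exact ground truth, so every
stage is testable end-to-end without proprietary microscope data. UV-Vis
utilities cover spectrum background subtraction, 518 nm SPR peak calibration,
and direct/indirect gold loading-efficiency computation.

## Data formats

- **Volumes**: multi-page TIFF, one page per z-slice, axis order (z, y, x).
  Voxel spacing (µm) lives in a YAML sidecar `<volume>.tif.yaml` with key
  `spacing_um: [dz, dy, dx]`.
- **Tables**: plain CSV with a header row, floats at 12 significant digits.
- **Spectra**: two-column CSV (`wavelength_nm`, `absorbance`).

## CLI

```bash
# generate a synthetic scene (RI + fluorescence + ground truth)
holoquant simulate --config scene.yaml --out scene/

# individual stages
holoquant segment    --ri scene/ri.tif --out-labels cells.tif --out-table cells.csv
holoquant aggregates --ri scene/ri.tif --cells cells.tif \
                     --out-aggregates aggs.csv --out-cellstats cellstats.csv
holoquant coloc      --ri scene/ri.tif --fluor scene/fluor.tif --cells cells.tif \
                     --out coloc.csv
holoquant report     --cells cellstats.csv --aggregates aggs.csv --coloc coloc.csv \
                     --out report.json

# end-to-end: volumes in, report + all intermediates out
holoquant run --ri scene/ri.tif --fluor scene/fluor.tif --out result/

# simulate scenes, run the pipeline, score recovery against ground truth
holoquant validate --config scene.yaml --seeds 1,2,3 --out recovery.csv

# UV-Vis loading efficiency
holoquant spectro le-indirect --total 100 --free 43.7     # -> 56.3
holoquant spectro le-direct   --encapsulated 47.7 --total 100
holoquant spectro subtract --doped doped.csv --undoped undoped.csv --out diff.csv
```

Exit codes: 0 success, 2 configuration error, 3 data error. Parameter YAML
files are flat mappings of the dataclass fields (e.g.
`background_ri_threshold`, `min_cell_volume_um3`, `high_ri_threshold`,
`min_aggregate_voxels`, `fluor_threshold_method`).

## Package layout

| module | role |
| --- | --- |
| `holoquant.volume_io` | TIFF/CSV/YAML I/O, typed volumes (`RITomogram`, `FluorescenceVolume`, `VoxelSpacing`) |
| `holoquant.synthetic` | seeded scene generator with exact ground truth; uptake-association copula |
| `holoquant.segmentation` | RI foreground mask, cell instances, RI histograms |
| `holoquant.aggregates` | high-RI component detection, per-cell uptake stats, size distribution |
| `holoquant.coloc` | fluorescence binarization, overlap fractions, voxel Pearson |
| `holoquant.stats` | correlation/t-test/ANOVA/Gaussian-fit layer, report assembly |
| `holoquant.spectro` | spectra, SPR peak, calibration, loading efficiencies |
| `holoquant.pipeline` / `holoquant.cli` | orchestration, provenance, CLI |

## Known limitations

- Touching cells are not split (no watershed); the synthetic generator
  guarantees non-overlapping cells.
- High-RI lipid droplets are indistinguishable from NP aggregates by RI
  alone; with fluorescence available they are identifiable as high-RI
  components with zero fluorescence overlap (`holoquant validate` reports
  them).
- Absolute volumes depend entirely on the user-supplied voxel spacing.
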