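# perilymph

Quantification toolkit for dendritic-cell migration into skin lymphatic
vessels and its time-of-day dependence:

* **geometry** — polygon-outline rasterization into binary vessel masks,
  exact anisotropic Euclidean distance transforms in µm, distance-band zone
  maps, and mask volume/area.
* **gradient** — distance-resolved chemokine immunofluorescence profiles
  around vessels (maximum-intensity projection, 1-µm rounded distance bins,
  replicate averaging, isotype subtraction, day-referenced day/night
  normalization).
* **localization** — inside/outside-vessel cell counting normalized to
  vessel volume, per-cell distances to the vessel, zone-wise relative cell
  distributions, and Golgi-high/low intracellular chemokine intensity ratios.
* **rhythm** — 24-h cosinor fitting (mesor, amplitude, acrophase,
  zero-amplitude F-test), immunofluorescence-screen normalization
  (second-highest scaling, 1.5 %-of-max expression flag, fold-change
  matrices), min–max profile integration, 24-h moving-average
  bioluminescence detrending, and one-way ANOVA with Tukey post tests.
* **tracks** — migration-track metrics: velocity, directionality
  (Euclidean/accumulated distance), path distances, frame-window trimming,
  gap filtering and origin normalization.
* **simulate** — seeded generators with ground truth for every input:
  capsule-vessel scenes with a circadian-modulated exponential chemokine
  gradient, distance-weighted cell placements, replicate cosine series,
  persistent biased random-walk tracks, and damped rhythmic bioluminescence.
* **io / cli** — TIFF stacks with µm-spacing sidecars, validated CSV tables,
  YAML run configs, and the `perilymph` command line.

## Command line

```bash
# synthetic inputs (ground truth JSON written alongside)
perilymph simulate scene --seed 1 --time 7 --out scene_dir/
perilymph simulate cells --mask scene_dir/mask.tif --n 50 --seed 1 --out cells.csv
perilymph simulate series --mesor 10 --amplitude 4 --acrophase 7 --out series.csv
perilymph simulate tracks --n 100 --bias 0.6 --seed 1 --out tracks.csv
perilymph simulate lumi --duration-h 96 --out lumi.csv

# analysis stages
perilymph gradient --image scene_dir/intensity.tif --mask scene_dir/mask.tif \
    --max-dist 100 --out profile.csv
perilymph localize --cells cells.csv --mask scene_dir/mask.tif \
    --zones 0,10,20,40,80 --out localization.json
perilymph zones --mask scene_dir/mask.tif --edges 0,10,20,40,80 --out zones.tif
perilymph rhythm --series series.csv --period 24 --out fit.json
perilymph screen --mfi mfi.csv --out screen.csv
perilymph detrend --lumi lumi.csv --window-h 24 --out detrended.csv
perilymph tracks --in tracks.csv --trim 31:300 --out metrics.csv

# end-to-end: simulate -> gradient -> cosinor, with a run record
perilymph run --seed 1 --out run_dir/
```

Exit codes: 0 success, 2 validation error, 1 runtime failure. Spacing is
given in µm either on the command line (`--spacing z,y,x`) or via a sidecar
JSON (`image.tif.json` containing `{"spacing_um": [x, y, z]}`).

## Conventions

* Grids are indexed `(z, y, x)`; `spacing` is per-axis voxel size in µm in
  the same order; voxel centers sit at `index × spacing`.
* Distances are voxel-center to voxel-center; mask foreground is distance 0.
* Zone bins are half-open `[a, b)`; label 0 is on-vessel, the last label is
  a sentinel for "beyond the last edge".
* Clock times live on a 24-h wheel; acrophase is the hour of the fitted
  cosine's maximum.
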