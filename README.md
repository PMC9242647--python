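# pmindex

Quantitative analysis of plasma-membrane (PM) localization of fluorescent
biosensors in time-lapse movies, built around the background-corrected
**PM index**

```
pm_index = (mean PM intensity − background) / (mean cytosol intensity − background)
```

and its baseline-normalized variant, as used to quantify lipid and polarity
sensor translocation during hypoxia/reoxygenation or ATP inhibition/washout.
The package ships a fully ground-truthed synthetic movie generator, so every
stage of the pipeline is testable without any microscopy data.

## What's inside

| module | purpose |
| --- | --- |
| `pmindex.synthetic` | ground-truthed multi-channel movie simulator: Voronoi epithelium or isolated cells, piecewise-exponential PM occupancy kinetics with sensor-specific delays/floors/overshoot, intracellular puncta pools, stage drift, Poisson–Gaussian noise |
| `pmindex.preprocess` | translational stack stabilization (subpixel phase correlation) and variance-stabilized denoising (generalized Anscombe + Gaussian) |
| `pmindex.segmentation` | PM/cytosol masks via ROI-mean thresholding or à trous B3-spline wavelet detail thresholding; puncta/nuclei exclusion; whole-frame background detection |
| `pmindex.quantify` | per-ROI, per-channel PM-index series, normalization conventions, cytosolic-intensity series for intensimetric sensors |
| `pmindex.kymograph` | maximum projection across a wide polyline reslice (time down, position across) |
| `pmindex.kinetics` | piecewise-exponential depletion/recovery fits, t50 summaries, paired bootstrap sensor-ordering comparisons |
| `pmindex.io` | TIFF stack + JSON ROI + CSV table readers/writers, run configuration, provenance records |
| `pmindex.reporting` | deterministic QC figures of the time courses |

## CLI

One umbrella command with subcommands mirroring the pipeline stages:

```sh
# generate a ground-truthed synthetic movie (TIFF + sidecars)
pmindex simulate --out sim/ --seed 1

# stabilize (drift track written beside the output)
pmindex preprocess --in sim/movie.tif --channel dye --upsample 10 --out stabilized.tif

# masks for every frame x ROI
pmindex segment --in sim/movie.tif --rois rois.json --method atrous --out masks.tif

# PM-index table (CSV, one row per frame x ROI x channel)
pmindex quantify --in sim/movie.tif --rois rois.json --baseline 3 --out table.csv

# kymograph: max projection of a 250 px wide line reslice
pmindex kymograph --in sim/movie.tif --line line.json --width 250 --channel PIP2 --out kymo.tif

# kinetics fits and sensor-ordering comparison
pmindex fit --table table.csv --t-hypoxia 600 --t-reoxy 3600 --out fits.csv
pmindex compare --fits fits.csv --pair PIP2,PI4P --phase depletion

# QC figure
pmindex report --table table.csv --out fig.png
```

ROI JSON schema: `[{"label": "...", "kind": "junction"|"cell_region",
"vertices": [[row, col], ...]}]`, 0-based pixel coordinates, row 0 at the top.

## Notes and limitations

- Registration is translation-only; rotation is out of scope.
- The denoiser substitutes an Anscombe + Gaussian scheme for multiscale
  Poisson–Gaussian denoising; masks and intensity measurements therefore
  default to raw frames (`measure_on: raw`), with background detection on
  the denoised working copy. See `RunConfig` for every knob.
- No optics (PSF) simulation, no photobleaching, no 3-D, no proprietary
  microscope formats.
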