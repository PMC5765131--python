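# binoica

Eccentricity- and quadrant-resolved independent component analysis of
binocular image pairs: a reusable pipeline going from verged stereo
luminance rasters to distributions of binocularity, frequency, and
position / phase / orientation disparity of ICA components, with a
synthetic verged-stereo generator standing in for photographic data.

## What it does

1. **`binoica.synthetic_data`** — renders left/right luminance rasters for a
   symmetrically converged viewer (65 mm interocular separation by default):
   a sparse-element texture with a natural 1/f^α-like spectrum, a
   horizontal-disparity field derived from a depth map or parametric ground
   plane (crossed/near below fixation, uncrossed/far above), and a
   quadrant-patterned vertical-disparity field (positive top-left /
   bottom-right). Also provides single-Gabor patches and sparse-source
   matrices as fixtures for the downstream stages.
2. **`binoica.sampling`** — partitions the field into three eccentricity
   bands (centre [0, 150), mid [150, 300), outer [300, 600) arcmin) crossed
   with four quadrants, rescales images to a target sample resolution
   (bicubic), and cuts co-located binocular patches.
3. **`binoica.preprocessing`** — per-eye centring/normalization of patches
   and PCA whitening truncated to K components (default 250).
4. **`binoica.ica`** — fixed-point (log-cosh) ICA in whitened space;
   exposes pixel-space binocular *filters* split into per-eye halves with
   energies and the min/max binocular ratio.
5. **`binoica.gabor`** — deterministic least-squares Gabor fitting
   (Fourier-peak + moment initialization, multi-start phases) with
   canonicalized parameters and accept/reject rules.
6. **`binoica.metrics`** — position/phase/orientation disparity, frequency,
   the mirror-asymmetry statistic, MAD, binocularity classification.
7. **`binoica.stats_report`** — bootstrapped histograms with 95% envelopes,
   Spearman tests, and `run_analysis` orchestrating every
   (region × resolution) cell deterministically from one seed block.

## CLI

```bash
binoica simulate --config config.yaml --seed 1 --out out/sim
binoica sample   --config config.yaml --region centre --resolution 4 --out out/patches
binoica fit      --config config.yaml --region outer --quadrant top_left --resolution 4 --out out/cell
binoica report   --config config.yaml --seed 1 --out out/report --figures
```

The config is a YAML mapping of `binoica.stats_report.AnalysisConfig`
fields (all optional), e.g.:

```yaml
fixation_mm: 10000
field_half_width_arcmin: 640
eye_height_mm: 1600
vertical_gain: 4.0e-5
regions: [[outer, top_left], [outer, bottom_right]]
resolutions: [4.0]
n_patches: 8000
n_components: 96
seed: 1
```

Outputs are 16-bit PNGs (`_L`/`_R`), TSV tables, and JSON reports echoing
the full configuration and seeds; reports are byte-identical across runs
with the same seed block.

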