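# amisquant

Quantification toolkit for **apical-membrane-initiation-site (AMIS)
polarity** in small clusters of cells grown in 3D culture — the stage of
lumenogenesis at which apical determinants such as PAR-3 concentrate at
the centre of a cell–cell interface before any lumen opens.

The package is written for cell biologists quantifying multi-channel
fluorescence z-stacks of doublets and small clusters (e.g. mouse
embryonic stem cells in Matrigel). It implements, as tested and
reusable code, the measurement procedures such studies rely on:

- **Projections** — maximum-value projection of a whole z-stack, and of
  exactly the three central slices (the substrate for all line-scan and
  region measurements).
- **Interface line-scans** — width-averaged (default 0.8 μm) intensity
  profiles along a cell–cell interface; the two F-actin end peaks
  delimit the "1× interface", which is sectioned into 20 bins of 5% arc
  length each; profiles from many cells are averaged bin-wise.
  Perpendicular centre-vs-side scans (3 μm wide) with area-under-curve
  comparison are also provided.
- **Regional enrichment ratios** — mean intensity in a disc (default
  4 μm diameter) over the multi-cellular junction divided by the mean
  over the rest of the cluster; core-vs-whole-cell and
  interface-vs-matrix variants.
- **Per-cell heatmaps** — a square ROI fitted to the cell body reduced
  to a 10×10 matrix of block means, averaged across cells, with the
  central-20% level read from the central 2×2 block.
- **FRAP kinetics** — normalization `FRAP(t) = (F(t) − F(0)) / (F(i) −
  F(0))` with `F(i)` the mean of the pre-bleach frames and `F(0)` the
  first post-bleach frame, followed by a non-linear least-squares fit of
  the exponential one-phase association model `Y(t) = P·(1 − e^(−kt))`
  with `Y(0) = 0`; the plateau `P` is the **mobile fraction**.
- **Morphometrics** — centrosome separation normalised to the doublet
  long axis, Feret-diameter long-axis extraction from masks, kymographs
  (0.2 μm sections) along annotated paths, and a threshold classifier
  for polarized centres (a documented surrogate for by-eye scoring, for
  synthetic benchmarking).
- **Synthetic scenes** — a calibrated scene generator (spherical cells
  with membrane shells, a tunable interface-midpoint PAR-3 focus with
  enrichment factor `E`, peripheral puncta, Poisson–Gaussian camera
  noise) plus FRAP-trace and moving-focus time-lapse simulators, all
  with machine-readable ground truth so every statistic can be verified.

## Worked example

```python
import numpy as np
from amisquant import (
    SceneParams, generate_doublet_scene, sample_path_intensity,
    detect_interface_ends, bin_profile, central_section_project,
    central_vs_surround_ratio, FRAPSimParams, simulate_frap_trace,
    normalize_frap, fit_one_phase_association,
)

# a polarized doublet: PAR-3 focus at 4x the cell-body baseline
stack, truth = generate_doublet_scene(SceneParams(par3_enrichment=4.0))
profile = sample_path_intensity(stack, truth.interface_path())
detect_interface_ends(profile)                 # F-actin end peaks
binned = bin_profile(profile, "par3")          # 20 bins of 5% arc length
print(np.argmax(binned.bin_means), binned.bin_means.max().round(1))

par3 = central_section_project(stack, "par3")
ratio = central_vs_surround_ratio(
    par3, truth.cluster_mask(par3.pixels.shape), truth.interface_midpoint_xy
)
print(round(ratio.ratio, 3))

# FRAP: 3 pre- + 30 post-bleach frames at 10 s
trace = simulate_frap_trace(FRAPSimParams(mobile_fraction=0.6, rate_k=0.02))
fit = fit_one_phase_association(normalize_frap(trace))
print(round(fit.plateau, 3), round(fit.rate_k, 4))
```

Output:

```
8 387.9
2.523
0.6 0.02
```

The brightest bin (index 8, one of the four central bins) sits at the
interface midpoint and reaches ~3.9× the cell-body baseline of 100 a.u.;
the central 4-μm disc is 2.52-fold enriched over the rest of the
doublet; and the noiseless FRAP fit recovers the simulated mobile
fraction (0.6) and rate (0.02 s⁻¹) exactly.

A command-line interface mirrors the library
(`amisquant simulate|linescan|ratio|heatmap|frap|kymo|centrosome|classify|run`);
`amisquant run --config cfg.yaml --out outdir` executes configured
stages end to end and writes a result table plus a reproducibility
manifest.

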