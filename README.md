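# tomopipe

A desk-scale, fully synthetic re-creation of the computational workflow
used to determine membrane-bound macromolecular structures — such as the
ribosome–translocon complex — directly inside cells' membranes by
cryo-electron tomography (CET) and subtomogram averaging.

Structural biologists who want to understand, teach, or prototype this
workflow face a practical problem: the real thing needs hundreds of
tomograms, GPU clusters and weeks of curation. `tomopipe` implements every
computational stage as readable, tested NumPy/SciPy code and pairs it with
a ground-truth simulator, so each stage's recovery performance can be
measured exactly, in minutes, on one CPU.

## What it implements

* **Simulation** — membrane vesicles decorated with two-part particles
  (cytosolic "ribosome" body + membrane-embedded "translocon" foot),
  compositional heterogeneity (an OST-like sub-density in ~55% of
  particles, a tRNA-like one in 29%), 10-nm gold fiducials, and single-axis
  tilt series (−60°…+60°, 2° steps, ~95 e/Å² cumulative dose) with CTF,
  dose-dependent noise and stage jitter.
* **Reconstruction** — movie-frame drift correction, strip-periodogram
  defocus estimation, CTF phase flipping, gold-marker tilt alignment, and
  weighted backprojection with a selectable tilt range (full ±60°
  tomograms; ±20° per-particle subtomograms carrying their wedge spec).
* **Detection** — six-dimensional template matching: a 12.85°
  quasi-uniform SO(3) grid, wedge-filtered templates, FFT-based locally
  normalized correlation, peak extraction and local refinement.
* **Averaging** — missing-wedge constrained cross-correlation, exhaustive
  local pose search with subpixel translation, wedge-compensated averaging,
  and iterative refinement in conventional (FSC = 0.5) and gold-standard
  (independent halves, FSC = 0.143) modes with resolution-adaptive angular
  sampling and band limits.
* **Classification** — constrained PCA: wedge-compensated, mask-focused
  principal components with k-means, for membrane-bound/junk separation,
  OST occupancy, and tRNA-site (translational-state) classes.
* **Validation** — FSC curves and threshold read-out (0.5 / 0.143 / 0.33),
  windowed local resolution (20³ boxes), B-factor sharpening (−500 Å²).
* **Model fitting** — rigid and domain-wise fitting of coordinate models
  into maps, single-helix axial scans, elastic-restrained flexible
  refinement, and screw decomposition (Chasles' theorem) of domain
  motions: the lateral-gate opening of the translocon channel is the
  benchmark scenario, with its published geometry (22° rotation, 13.8 Å
  translation along the screw axis, 13 Å shift of the last transmembrane
  helix, < 3 Å Cα RMSD under flexible refinement) used as ground truth for
  a synthetic two-conformer analog.

The core statistic throughout is the **constrained cross-correlation**:
for two wedge-limited volumes with Fourier supports `W_a`, `W_b` and an
alignment band `B`,

```
CCC(a, b) = Re Σ_{k∈W_a∩W_b∩B} F_a(k) F_b*(k)
            / sqrt( Σ|F_a|² · Σ|F_b|² )        (sums over the same region)
```

which removes the bias the missing wedge would otherwise impose on
alignment and classification. Resolutions are FSC threshold crossings;
domain motions are summarized as `(angle θ about axis û, translation d
along û)` of the fitted rigid transform.

## Worked example

```python
from tomopipe.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(angular_increment_deg=25.0, noise_sigma=0.5, seed=1)
report = run_pipeline(cfg, "run1")
print(report["dose"])
print(report["detection"])
print(report["fit_demo"])
```

prints (numbers from this exact run):

```
{'cumulative_e_A2': 95.0, 'per_image_e_A2': 1.557..., 'reduced_range_e_A2': 32.70...}
{'n_candidates': 119, 'n_true_particles': 10, 'recall_top_n': 0.6, 'recall_all': 1.0}
{'screw_angle_deg': 22.048..., 'screw_translation_A': 13.798...,
 'n_half_fit_score': 0.879..., 'tmh10_shift_A': 13.5,
 'flexible_rmsd_to_start_A': 0.101...}
```

Reading it: the 61-image tilt series accumulates 95 e/Å² and the ±20°
subset used for per-particle reconstruction carries ~31 e/Å²; all 10
planted particles appear among the extracted peaks (the coarse 25° demo
grid costs some top-rank recall — the production 12.85° grid ranks all of
them on top, see the benchmarks); and domain-wise fitting of the
two-conformer channel analog recovers the planted lateral-gate motion: a
22.0° rotation with 13.8 Å axial translation, the 13 Å helix shift (0.5 Å
scan grid), and flexible-refinement motions of 0.1 Å RMSD on converged
data. The same run writes `tomogram.mrc`, class averages, FSC tables and
`report.json` into the run directory.

The same machinery is scriptable from the shell:

```bash
tomopipe run-all --seed 1 --out run1
tomopipe report --out run1
```

## Layout

```
src/tomopipe/
  core.py         volumes, rigid transforms, wedge masks, MRC I/O
  simulate.py     phantoms, scenes, CTF, tilt-series projection
  reconstruct.py  frames, defocus, phase flip, marker alignment, WBP
  detect.py       SO(3) grid, template matching, peaks, refinement
  average.py      constrained CC, alignment, averaging, refinement
  classify.py     constrained PCA + k-means, class averages
  validate.py     FSC, resolution, local resolution, sharpening
  fitmodel.py     atomic models, fitting, flexible refine, screw math
  experiments.py  end-to-end recovery benchmarks
  pipeline.py     orchestration, config, report
  cli.py          command-line interface
docs/methods.md   models, parameters, design decisions, limitations
```
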