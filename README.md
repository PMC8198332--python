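# follimetry

Automated morphometry of thyroid follicles in multi-channel fluorescence
micrographs, for labs quantifying thyroid gland architecture and
protease trafficking in mouse models (TH-transporter and cathepsin
knockouts, goitre models, TSH-signaling studies).

A thyroid mid-section shows discrete round follicles: a colloid-filled
**lumen** enclosed by a one-cell **epithelium** of thyrocytes, sheathed
by a thin **basal lamina**. Given a registered three-channel image —
marker (green role: cathepsin immunostain or basal-lamina stain),
cytoplasm (red role: CellMask-type stain), nuclei (blue role:
Draq5-type stain) — the package measures, per follicle and per section:

* lumen, follicle and epithelium areas (µm²);
* the **epithelial extension** `EExt = sqrt(A_fol/π) − sqrt(A_lum/π)`,
  an area-based proxy for epithelial height (exact for concentric
  circular follicles);
* thyrocyte counts, thyrocyte area `A_epi / n_cells`, cell density per
  1000 µm² follicle area, and intraluminal dead-cell remnants;
* intracellular vs. extracellular marker signal (the extracellular pool
  sums luminal and pericellular signal), normalized per cell;
* standardized lumen-area heat maps.

## How segmentation works

1. Channels are binarized with manual batch thresholds (pixel ≥ t).
2. The basal-lamina channel is morphologically closed and skeletonized
   into 1-px boundary curves.
3. Lumina are identified as connected components of the inverted tissue
   mask with equivalent diameter in 25–800 px, then filtered by
   roundness: **form factor** `FF = 4π·A/P²` ≥ 0.3 (1.0 = perfect
   circle).
4. Follicles grow outward from each lumen by seeded geodesic
   propagation through tissue pixels, stopped by lamina-skeleton
   barriers or a 30-px expansion cap; epithelium = follicle − lumen.
5. Nuclei (watershed-declumped) are assigned to follicles by centroid;
   nuclei whose centroid falls inside a lumen are counted as dead-cell
   remnants.

Because no imaging study ships with per-pixel ground truth, the package
includes a **phantom generator**: synthetic follicular sections with
exact per-follicle truth tables (areas, nucleus counts, marker
compartment sums), used throughout the test suite to score recovery.

## Worked example

```python
from follimetry import (PhantomSpec, PipelineConfig, generate_phantom,
                        run_intensity, run_morphometry)

spec = PhantomSpec(noise_sd=0.0, seed=42)        # 2048x2048, 30 follicles
stack, truth = generate_phantom(spec)
res = run_morphometry(stack, PipelineConfig())
s = res.summary
print(f"{s.n_follicles} follicles, mean EExt {s.mean_eext_um:.2f} um")
print(f"{s.cells_per_1000um2:.2f} cells/1000 um2, dead {s.dead_cell_pct:.2f}%")
p1 = run_intensity(stack, PipelineConfig())
print(f"intracellular marker {p1.intra_pct:.1f}%")
```

prints

```
30 follicles, mean EExt 8.71 um
4.57 cells/1000 um2, dead 3.97%
intracellular marker 69.0%
```

— the pipeline recovers all 30 phantom follicles; the intracellular
share is exactly `100·(1 − luminal_marker_fraction)` because the
phantom placed 31% of the marker signal in the lumina.

## Analysis scripts

The `analysis/` drivers run a complete phantom study:

```sh
python analysis/01_generate_phantoms.py   # 3 genotype groups x 4 animals
python analysis/02_measure_sections.py    # P1/P2/P3 over every section
python analysis/03_compare_genotypes.py   # fold changes over WT + Dunnett
```

Tables land in `results/` (large rasters in `scratch/`). In the
shipped run the degenerative double-knockout group shows a 3.0-fold
dead-cell fraction, 0.41-fold cell density and 1.32-fold EExt over WT
(all Dunnett-significant), mirroring the directions expected for that
phenotype.

There is also a CLI: `follimetry phantom|segment|intensity|summarize|compare --help`.

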