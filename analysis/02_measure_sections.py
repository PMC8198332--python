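"""Run the image-analysis pipelines over every phantom section.

For each section of the manifest written by 01_generate_phantoms.py:
the morphometry pipeline (lumen/follicle/epithelium segmentation,
per-follicle areas, epithelial extension, cell and dead-cell counts),
the intensity pipeline (intracellular vs. extracellular marker share),
and a standardized lumen-area heat map for the first animal of each
genotype.  Section-level summaries land in
results/section_measurements.csv; heat maps in scratch/heatmaps/.
"""

from pathlib import Path

import imageio.v3 as iio
import pandas as pd

from follimetry import PipelineConfig, run_heatmap, run_intensity, run_morphometry
from follimetry.io import read_stack

MANIFEST = Path("scratch/phantoms/manifest.csv")
RESULTS = Path("results")
HEATMAPS = Path("scratch/heatmaps")


def main() -> None:
    manifest = pd.read_csv(MANIFEST)
    cfg = PipelineConfig()
    RESULTS.mkdir(exist_ok=True)
    HEATMAPS.mkdir(parents=True, exist_ok=True)

    rows = []
    seen_genotypes = set()
    for _, entry in manifest.iterrows():
        stack = read_stack(entry["image"], cfg.pixel_size_um)
        seg = run_morphometry(stack, cfg)
        p1 = run_intensity(stack, cfg)
        s = seg.summary
        rows.append(dict(
            animal_id=entry["animal_id"], genotype=entry["genotype"],
            cohort=entry["cohort"], n_follicles=s.n_follicles,
            mean_lumen_area_um2=s.mean_lumen_area_um2,
            mean_follicle_area_um2=s.mean_follicle_area_um2,
            mean_thyrocyte_area_um2=s.mean_thyrocyte_area_um2,
            mean_eext_um=s.mean_eext_um,
            cells_per_1000um2=s.cells_per_1000um2,
            dead_cell_pct=s.dead_cell_pct,
            intra_pct=p1.intra_pct, extra_pct=p1.extra_pct,
            per_cell_total=p1.per_cell_total,
        ))
        print(f"{entry['animal_id']:>18}: {s.n_follicles:2d} follicles, "
              f"EExt {s.mean_eext_um:5.2f} um, "
              f"{s.cells_per_1000um2:5.2f} cells/1000um2, "
              f"dead {s.dead_cell_pct:5.2f}%, intra {p1.intra_pct:5.1f}%")
        if entry["genotype"] not in seen_genotypes:
            seen_genotypes.add(entry["genotype"])
            iio.imwrite(HEATMAPS / f"{entry['animal_id']}_lumen_heatmap.png",
                        run_heatmap(seg, cfg))

    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "section_measurements.csv", index=False)
    print(f"\nwrote {len(df)} section summaries to "
          f"{RESULTS / 'section_measurements.csv'} and "
          f"{len(seen_genotypes)} heat maps to {HEATMAPS}/")


if __name__ == "__main__":
    main()
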