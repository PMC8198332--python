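"""Synthesize phantom thyroid mid-sections for three genotype groups.

Builds the study material for the downstream analyses: per animal, one
three-channel phantom section with exact ground truth.  Genotype effects
are emulated through the generator parameters:

* WT            — baseline geometry (the generator defaults, scaled to a
                  1024x1024 field);
* Mct10-KO-like — hyperplastic epithelium: ~50% more nuclei per follicle
                  and a halved dead-cell fraction;
* Mct8/Mct10-KO-like — degenerative/activated phenotype: larger lumina,
                  taller epithelium, fewer cells and a three-fold
                  dead-cell fraction.

Images (multi-channel TIFF) go to scratch/phantoms/; the manifest and
truth tables are CSV.  Every seed derives from one base seed, so the
whole cohort is reproducible.
"""

from pathlib import Path

import pandas as pd

from follimetry import PhantomSpec, generate_phantom, write_truth
from follimetry.io import write_stack

BASE_SEED = 20210531
N_ANIMALS = 4
OUT = Path("scratch/phantoms")

BASE = dict(
    image_size=(1024, 1024),
    n_follicles=12,
    lumen_radius_range=(18.0, 45.0),
    epithelium_thickness_range=(12.0, 18.0),
    nuclei_per_follicle_range=(8, 20),
    dead_cell_fraction=0.04,
    luminal_marker_fraction=0.31,
    noise_sd=0.01,
)

GENOTYPES = {
    "WT": {},
    "Mct10-KO": {
        "nuclei_per_follicle_range": (12, 30),
        "dead_cell_fraction": 0.02,
    },
    "Mct8-Mct10-KO": {
        "lumen_radius_range": (25.0, 55.0),
        "epithelium_thickness_range": (16.0, 24.0),
        "nuclei_per_follicle_range": (6, 14),
        "dead_cell_fraction": 0.12,
        "luminal_marker_fraction": 0.40,
    },
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = []
    for g_idx, (genotype, overrides) in enumerate(GENOTYPES.items()):
        for a in range(N_ANIMALS):
            seed = (BASE_SEED + 1000 * g_idx + a) % 2**31
            spec = PhantomSpec(**{**BASE, **overrides}, seed=seed)
            stack, truth = generate_phantom(spec)
            animal = f"{genotype}_{a}"
            img = OUT / f"{animal}.tif"
            tru = OUT / f"{animal}_truth.csv"
            write_stack(img, stack)
            write_truth(truth, tru)
            manifest.append(dict(animal_id=animal, genotype=genotype,
                                 cohort="c1", seed=seed, image=str(img),
                                 truth=str(tru)))
            print(f"{animal}: {spec.n_follicles} follicles, "
                  f"{truth.follicles['n_epithelial_nuclei'].sum()} epithelial + "
                  f"{truth.follicles['n_intraluminal_nuclei'].sum()} intraluminal nuclei")
    pd.DataFrame(manifest).to_csv(OUT / "manifest.csv", index=False)
    print(f"\nwrote {len(manifest)} sections and manifest to {OUT}/")


if __name__ == "__main__":
    main()
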