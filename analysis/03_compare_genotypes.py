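"""Genotype comparison: fold changes over WT and Dunnett many-to-one tests.

Reshapes the per-animal section measurements into a cohort table, then
for each morphometric readout reports each knockout genotype's mean fold
change over the wild-type controls of its cohort with Dunnett-adjusted
p-values.  Output: results/genotype_comparisons.csv.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from follimetry import many_to_one_compare

MEASUREMENTS = Path("results/section_measurements.csv")
OUT = Path("results/genotype_comparisons.csv")

METRICS = ["mean_lumen_area_um2", "mean_follicle_area_um2",
           "mean_thyrocyte_area_um2", "mean_eext_um", "cells_per_1000um2",
           "dead_cell_pct", "per_cell_total"]


def main() -> None:
    wide = pd.read_csv(MEASUREMENTS)
    table = wide.melt(id_vars=["animal_id", "genotype", "cohort"],
                      value_vars=METRICS, var_name="metric_name",
                      value_name="value")
    results = many_to_one_compare(table, control="WT", unit="animal")
    df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    df.to_csv(OUT, index=False)

    print(f"{'metric':>24} {'genotype':>16} {'FC':>6} {'SD':>5} {'p_adj':>8}")
    for r in results:
        star = " *" if r.significant else ""
        print(f"{r.metric_name:>24} {r.genotype:>16} "
              f"{r.fold_change_mean:6.2f} {r.fold_change_sd:5.2f} "
              f"{r.adjusted_p:8.4f}{star}")
    print(f"\nwrote {len(df)} comparisons to {OUT}")


if __name__ == "__main__":
    main()
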