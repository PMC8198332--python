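"""Genotype-level statistics: fold changes over wild type and many-to-one tests.

Measurements from different animal cohorts are only comparable after
normalizing each value to the mean of the wild-type controls of its own
cohort; all genotype effects are therefore expressed as fold changes
over WT.  Significance of each genotype against the shared WT control is
assessed with Dunnett's many-to-one procedure (the post-hoc of a one-way
ANOVA design), with family-wise error controlled at alpha = 0.05.  A
generic band/lane ratio is included for densitometry-style
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import dunnett

__all__ = [
    "ComparisonResult",
    "validate_cohort_table",
    "fold_change_over_wt",
    "many_to_one_compare",
    "normalize_band_density",
]

REQUIRED_COLUMNS = ("animal_id", "genotype", "cohort", "metric_name", "value")
ALPHA = 0.05


@dataclass
class ComparisonResult:
    genotype: str
    metric_name: str
    fold_change_mean: float
    fold_change_sd: float
    adjusted_p: float
    significant: bool


def validate_cohort_table(table: pd.DataFrame, control: str = "WT") -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    if not np.all(np.isfinite(table["value"])):
        raise ValueError("cohort table contains non-finite values")
    for (cohort, metric), grp in table.groupby(["cohort", "metric_name"]):
        if not (grp["genotype"] == control).any():
            raise ValueError(
                f"cohort {cohort!r} has no {control} rows for metric {metric!r}"
            )


def fold_change_over_wt(table: pd.DataFrame, control: str = "WT") -> pd.DataFrame:
    """Divide each value by the mean of its cohort-and-metric WT values.

    Returns a table of identical shape with ``value`` on the fold-change
    scale; the mean of each cohort's WT rows maps to exactly 1.0.
    """
    validate_cohort_table(table, control)
    wt_means = (
        table[table["genotype"] == control]
        .groupby(["cohort", "metric_name"])["value"]
        .mean()
        .rename("wt_mean")
    )
    if (wt_means == 0).any():
        bad = wt_means[wt_means == 0].index.tolist()
        raise ValueError(f"WT mean is zero for cohort/metric {bad}")
    out = table.merge(wt_means, left_on=["cohort", "metric_name"], right_index=True,
                      how="left")
    out["value"] = out["value"] / out["wt_mean"]
    return out.drop(columns="wt_mean")


def many_to_one_compare(
    table: pd.DataFrame, control: str = "WT", unit: str = "animal"
) -> list[ComparisonResult]:
    """Dunnett many-to-one comparison of each genotype against WT.

    Values are first expressed as fold changes over each cohort's WT mean
    (which is what makes cohorts poolable), then aggregated to animal
    means (``unit="animal"``, the default) or left as individual
    observations (``unit="observation"``), and finally tested with
    Dunnett's procedure per metric.  Fold-change means and SDs are
    reported on the normalized scale.
    """
    if unit not in ("animal", "observation"):
        raise ValueError(f"unknown unit {unit!r}")
    folds = fold_change_over_wt(table, control)
    if unit == "animal":
        folds = (
            folds.groupby(["metric_name", "cohort", "genotype", "animal_id"],
                          as_index=False)["value"].mean()
        )
    results: list[ComparisonResult] = []
    for metric, grp in folds.groupby("metric_name"):
        by_geno = {g: sub["value"].to_numpy() for g, sub in grp.groupby("genotype")}
        for g, v in by_geno.items():
            if len(v) < 2:
                raise ValueError(
                    f"group {g!r} has a single observation for metric {metric!r}"
                )
        others = [g for g in by_geno if g != control]
        if not others:
            continue
        # fixed rng: the adjusted p is evaluated by randomized quasi-Monte
        # Carlo integration; pinning it makes results reproducible
        res = dunnett(*(by_geno[g] for g in others), control=by_geno[control],
                      rng=np.random.default_rng(0))
        for g, p in zip(others, np.atleast_1d(res.pvalue)):
            v = by_geno[g]
            results.append(
                ComparisonResult(
                    genotype=str(g),
                    metric_name=str(metric),
                    fold_change_mean=float(np.mean(v)),
                    fold_change_sd=float(np.std(v, ddof=1)),
                    adjusted_p=float(p),
                    significant=bool(p < ALPHA),
                )
            )
    return results


def normalize_band_density(band: float, lane_total: float) -> float:
    """Band densitometry normalized to total protein of its lane."""
    if not lane_total > 0:
        raise ValueError(f"lane_total must be positive, got {lane_total}")
    if band < 0:
        raise ValueError("band density cannot be negative")
    return float(band) / float(lane_total)
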