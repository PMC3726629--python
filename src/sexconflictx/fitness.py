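"""Population-mean ANOVA for competitive fitness and offspring sex ratios.

Competitive male fitness is measured per vial as the proportion of adult
offspring sired by the target males against marked competitors; vials within
a population are pseudoreplicates, so the analysis averages the 20 vials of
each population and runs a one-way ANOVA across treatments on the population
means (df = 2, 6 at the source design's replication: 3 treatments x 3
populations).  Sex ratios are arcsine-square-root transformed first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    group_means: dict[str, float] = field(default_factory=dict)


def vial_proportions(
    assay: pd.DataFrame,
    numerator: str = "n_target_offspring",
    denominator: str = "n_total_offspring",
) -> pd.DataFrame:
    """Per-vial proportion = numerator / denominator; the vial is the sample.

    Vials with a zero denominator are excluded with a warning reporting how
    many were dropped.  Returns the input rows (minus exclusions) with a
    ``proportion`` column added.
    """
    if (assay[numerator] > assay[denominator]).any():
        raise ValueError(f"{numerator} exceeds {denominator} in some vials")
    zero = assay[denominator] == 0
    if zero.any():
        warnings.warn(
            f"excluded {int(zero.sum())} vial(s) with zero total offspring",
            stacklevel=2,
        )
    out = assay.loc[~zero].copy()
    out["proportion"] = out[numerator] / out[denominator]
    return out


def sex_ratio_proportions(table: pd.DataFrame) -> pd.DataFrame:
    """Per-vial proportion male among adult offspring."""
    t = table.copy()
    t["n_total_offspring"] = t["n_male_offspring"] + t["n_female_offspring"]
    return vial_proportions(
        t, numerator="n_male_offspring", denominator="n_total_offspring"
    )


def population_means(
    per_vial: pd.DataFrame, value_col: str = "proportion"
) -> pd.DataFrame:
    """Arithmetic mean of the per-vial values for each (treatment, population).

    Every (treatment, population) cell present in the labels must contain at
    least one vial; an empty cell (possible after exclusions) is an error
    naming the cell.
    """
    g = per_vial.groupby(["treatment", "population"], sort=False)[value_col]
    means = g.mean().reset_index().rename(columns={value_col: "mean_value"})
    counts = g.size()
    if (counts < 1).any():
        bad = counts[counts < 1].index.tolist()
        raise ValueError(f"empty (treatment, population) cells: {bad}")
    return means


def oneway_anova(means: pd.DataFrame, value_col: str = "mean_value") -> AnovaResult:
    """One-way ANOVA across treatments on population means.

    Standard between/within decomposition: df1 = k - 1, df2 = sum(n_i - 1).
    Each treatment needs at least two populations (else no residual df).
    """
    groups = [
        np.asarray(sub[value_col], dtype=float)
        for _, sub in means.groupby("treatment", sort=False)
    ]
    labels = list(pd.unique(means["treatment"]))
    if len(groups) < 2:
        raise ValueError("need at least two treatments")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every treatment needs >= 2 populations (residual df)")
    df1 = len(groups) - 1
    df2 = sum(len(g) - 1 for g in groups)
    F, p = stats.f_oneway(*groups)
    if not np.isfinite(F):  # all values identical -> 0/0
        F, p = 0.0, 1.0
    return AnovaResult(
        F=float(F),
        df1=df1,
        df2=df2,
        p=float(p),
        group_means={lab: float(np.mean(g)) for lab, g in zip(labels, groups)},
    )


def arcsine_sqrt(p):
    """Variance-stabilising transform for proportions: asin(sqrt(p)), radians."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def analyze_fitness(assay: pd.DataFrame) -> AnovaResult:
    """Vial proportions -> population means -> one-way ANOVA."""
    return oneway_anova(population_means(vial_proportions(assay)))


def analyze_sex_ratio(
    table: pd.DataFrame, transform_level: str = "vial"
) -> AnovaResult:
    """Sex-ratio ANOVA on arcsine-square-root transformed proportions male.

    ``transform_level`` chooses where the transform is applied: ``"vial"``
    (default; each vial's proportion is transformed before averaging to
    population means, consistent with the vial being the sample) or
    ``"population"`` (population-mean proportions transformed afterwards).
    """
    props = sex_ratio_proportions(table)
    if transform_level == "vial":
        props = props.assign(value=arcsine_sqrt(props["proportion"].to_numpy()))
        means = population_means(props, value_col="value")
    elif transform_level == "population":
        means = population_means(props)
        means["mean_value"] = arcsine_sqrt(means["mean_value"].to_numpy())
    else:
        raise ValueError("transform_level must be 'vial' or 'population'")
    return oneway_anova(means)
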