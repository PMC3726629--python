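"""Factorial sample design for the three-treatment evolution experiment.

The experiment compares three male groups: Control (C), males carrying a
Control X that passed through one generation of father-son transmission
(CDX), and males from the male-limited-X regime (MLX).  Each treatment is
replicated in independent populations, and each population is assayed with
replicate arrays, giving a treatment x population x replicate factorial.
"""

from __future__ import annotations

import itertools

import pandas as pd

#: Canonical treatment labels, in fixed (treatment-major) order.
TREATMENTS = ("C", "CDX", "MLX")

DESIGN_COLUMNS = ("sample_id", "treatment", "population", "replicate")


def treatment_names(n_treatments: int) -> list[str]:
    """First ``n_treatments`` labels; beyond the canonical three, T4, T5, ..."""
    if n_treatments <= len(TREATMENTS):
        return list(TREATMENTS[:n_treatments])
    return list(TREATMENTS) + [f"T{i}" for i in range(4, n_treatments + 1)]


def generate_design(
    n_treatments: int = 3, n_populations: int = 3, n_replicates: int = 2
) -> pd.DataFrame:
    """Full-factorial sample design.

    Parameters
    ----------
    n_treatments, n_populations, n_replicates
        Number of treatments, of replicate populations per treatment, and of
        replicate samples (arrays) per population.  The defaults reproduce
        the 3 x 3 x 2 layout (18 samples) of the source experiment.

    Returns
    -------
    pandas.DataFrame
        Columns ``sample_id, treatment, population, replicate``, ordered
        treatment-major, then population, then replicate.
    """
    for name, v in (
        ("n_treatments", n_treatments),
        ("n_populations", n_populations),
        ("n_replicates", n_replicates),
    ):
        if int(v) != v or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    rows = [
        {
            "sample_id": f"{trt}_p{pop}_r{rep}",
            "treatment": trt,
            "population": pop,
            "replicate": rep,
        }
        for trt, pop, rep in itertools.product(
            treatment_names(n_treatments),
            range(1, n_populations + 1),
            range(1, n_replicates + 1),
        )
    ]
    return pd.DataFrame(rows, columns=list(DESIGN_COLUMNS))


def validate_design(design: pd.DataFrame) -> tuple[list[str], int, int]:
    """Check a design table is balanced; return (treatments, b, r).

    ``b`` is the number of populations per treatment and ``r`` the number of
    replicates per population.  Raises ``ValueError`` for missing columns,
    duplicated (treatment, population, replicate) triples, or imbalance.
    """
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design table lacks columns: {sorted(missing)}")
    triples = design[["treatment", "population", "replicate"]]
    if triples.duplicated().any():
        raise ValueError("duplicated (treatment, population, replicate) triples")
    trts = list(pd.unique(design["treatment"]))
    pops_per_trt = design.groupby("treatment", sort=False)["population"].nunique()
    reps_per_cell = design.groupby(["treatment", "population"], sort=False).size()
    if pops_per_trt.nunique() != 1 or reps_per_cell.nunique() != 1:
        raise ValueError(
            "unbalanced design: equal populations per treatment and equal "
            "replicates per population are required"
        )
    b = int(pops_per_trt.iloc[0])
    r = int(reps_per_cell.iloc[0])
    return trts, b, r
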