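"""Direction-of-change test for feminized expression of paternal X chromosomes.

If the paternal X is imprinted toward daughters, males that received their X
from their father (CDX males) should shift expression of X-linked transcripts
toward the female pattern.  The test cross-classifies every informative
transcript on the selected chromosome(s) by two signs:

  axis 1 - extant sexual dimorphism: sign of (female - male) expression,
           supplied as an external annotation (the assay itself contains
           males only);
  axis 2 - sign of (mean CDX - mean Control) in the experiment.

All transcripts are included regardless of individual significance, to
detect an overall pattern; transcripts with a zero on either axis are
excluded and counted.  The chi-square compares the four cells against a
uniform null (total / 4 expected in each cell, df = 3) - note this is the
equal-cells null, not an independence (margin-product) null.  Feminization
itself shows up as an excess of the two concordant cells, which is reported
alongside the omnibus chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import validate_design


@dataclass
class DirectionCounts:
    """Cross-classification counts, cells ordered as in the source table:
    (female-up, CDX-up), (female-up, CDX-down), (female-down, CDX-up),
    (female-down, CDX-down)."""

    female_up_cdx_up: int
    female_up_cdx_down: int
    female_down_cdx_up: int
    female_down_cdx_down: int
    n_excluded_zero: int = 0

    def cells(self) -> tuple[int, int, int, int]:
        return (
            self.female_up_cdx_up,
            self.female_up_cdx_down,
            self.female_down_cdx_up,
            self.female_down_cdx_down,
        )

    @property
    def total(self) -> int:
        return sum(self.cells())

    @property
    def concordant(self) -> int:
        """Same-direction cells: the feminization signal."""
        return self.female_up_cdx_up + self.female_down_cdx_down

    @property
    def discordant(self) -> int:
        return self.female_up_cdx_down + self.female_down_cdx_up


@dataclass
class FeminizationResult:
    chi2: float
    df: int
    p: float
    expected_per_cell: float
    observed: tuple[int, int, int, int]
    concordant: int
    discordant: int
    concordance_p: float  # two-sided binomial test of concordant vs 1/2


def classify_directions(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    sex_bias_sign: pd.Series,
    chromosome: pd.Series | None = None,
    chromosomes: str | set | None = None,
) -> DirectionCounts:
    """Cross-classify transcripts by sex-bias sign vs CDX-Control direction.

    Parameters
    ----------
    expr, design
        Expression matrix (transcripts x samples) and its design table.
    sex_bias_sign
        Per-transcript sign of (female - male) expression, indexed by
        transcript id, values in {-1, 0, +1}; zeros are excluded and counted.
    chromosome
        Per-transcript chromosome labels (required when ``chromosomes`` is
        given).
    chromosomes
        ``"X"``, ``"autosomes"`` (everything but X), an explicit set of
        labels, or None for all transcripts.
    """
    validate_design(design)
    ids = expr.index
    if chromosomes is not None:
        if chromosome is None:
            raise ValueError("chromosome labels required for a chromosome filter")
        chrom = chromosome.reindex(ids).astype(str)
        if chromosomes == "X":
            keep = chrom == "X"
        elif chromosomes == "autosomes":
            keep = chrom != "X"
        else:
            keep = chrom.isin({str(c) for c in chromosomes})
        ids = ids[keep.to_numpy()]
    if len(ids) == 0:
        raise ValueError("no transcripts selected")

    missing = set(ids) - set(sex_bias_sign.index)
    if missing:
        raise ValueError(f"sex-bias sign missing for: {sorted(missing)[:10]}")

    cols_c = design.loc[design["treatment"] == "C", "sample_id"]
    cols_cdx = design.loc[design["treatment"] == "CDX", "sample_id"]
    if cols_c.empty or cols_cdx.empty:
        raise ValueError("design must contain C and CDX samples")
    sub = expr.loc[ids]
    cdx_sign = np.sign(
        sub[list(cols_cdx)].mean(axis=1) - sub[list(cols_c)].mean(axis=1)
    ).astype(int)
    fem_sign = sex_bias_sign.loc[ids].astype(int)

    informative = (cdx_sign != 0) & (fem_sign != 0)
    n_excluded = int((~informative).sum())
    f, c = fem_sign[informative], cdx_sign[informative]
    return DirectionCounts(
        female_up_cdx_up=int(((f > 0) & (c > 0)).sum()),
        female_up_cdx_down=int(((f > 0) & (c < 0)).sum()),
        female_down_cdx_up=int(((f < 0) & (c > 0)).sum()),
        female_down_cdx_down=int(((f < 0) & (c < 0)).sum()),
        n_excluded_zero=n_excluded,
    )


def feminization_chisq(counts) -> FeminizationResult:
    """Chi-square of the four direction cells against the uniform null.

    ``counts`` is a :class:`DirectionCounts` or a 4-tuple in its cell order.
    Expected value is total/4 in every cell; df = 3.  Also reports the
    concordant (feminization-consistent) vs discordant split with a
    two-sided binomial test.
    """
    if not isinstance(counts, DirectionCounts):
        counts = DirectionCounts(*counts)
    total = counts.total
    if total <= 0:
        raise ValueError("no informative transcripts (total count is zero)")
    observed = np.asarray(counts.cells(), dtype=float)
    expected = total / 4.0
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = 3
    p = float(stats.chi2.sf(chi2, df))
    conc_p = float(
        stats.binomtest(counts.concordant, total, 0.5, alternative="two-sided").pvalue
    )
    return FeminizationResult(
        chi2=chi2,
        df=df,
        p=p,
        expected_per_cell=expected,
        observed=counts.cells(),
        concordant=counts.concordant,
        discordant=counts.discordant,
        concordance_p=conc_p,
    )
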