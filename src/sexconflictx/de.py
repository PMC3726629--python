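"""Per-transcript nested ANOVA and the six-way treatment-pattern classifier.

The model is a balanced two-stage nested design: Treatment is a fixed factor
and Population is a random factor nested within Treatment.  With t
treatments, b populations per treatment and r replicates per population, the
treatment effect is tested against the population-within-treatment mean
square:

    F = MS(Treatment) / MS(Population within Treatment),
    df1 = t - 1,   df2 = t (b - 1)

(df = 2, 6 at the source design, 3 x 3 x 2).  Pairwise treatment contrasts
use the same error term.  Transcripts passing a Benjamini-Hochberg FDR gate
on the overall test are classified into six treatment-pattern categories by
which pairwise contrasts are significant and the ordering of the treatment
means:

    1  CDX and MLX both shifted from C, same direction (maternal effect)
    2  only CDX shifted (candidate imprinting pattern)
    3  only MLX shifted (response to male-limited X evolution)
    4  strictly ordered CDX-C-MLX (fitness-related)
    5  strictly ordered CDX-MLX-C (deleterious maternal effect, adapted)
    6  strictly ordered C-CDX-MLX (beneficial maternal effect, enhanced)

Ambiguous patterns (one significant pair; opposite-direction shifts) stay
unclassified (category 0) with a recorded reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import TREATMENTS, validate_design

PAIRS = (("C", "CDX"), ("C", "MLX"), ("CDX", "MLX"))


def _design_codes(design: pd.DataFrame):
    """Balanced-design bookkeeping: treatment/cell index per sample column."""
    trts, b, r = validate_design(design)
    trt_index = {t: i for i, t in enumerate(trts)}
    sample_trt = np.array([trt_index[t] for t in design["treatment"]])
    cell_codes = pd.factorize(
        design["treatment"].astype(str) + "/" + design["population"].astype(str)
    )[0]
    cell_trt = np.empty(cell_codes.max() + 1, dtype=int)
    cell_trt[cell_codes] = sample_trt
    return trts, b, r, sample_trt, cell_codes, cell_trt


def nested_anova_matrix(values: np.ndarray, design: pd.DataFrame):
    """Vectorised nested ANOVA over a (transcripts x samples) matrix.

    Returns ``(F, df1, df2, p, treatment_means, ms_error)`` where F, p are
    length-m arrays, ``treatment_means`` is (m x t) ordered as the treatments
    appear in the design, and ``ms_error`` is MS(Population within Treatment)
    (the error term reused by the pairwise contrasts).
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    trts, b, r, sample_trt, cell_codes, cell_trt = _design_codes(design)
    if X.shape[1] != len(design):
        raise ValueError("value columns must match design rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("expression values must be finite")
    t = len(trts)
    if t < 2 or b < 2:
        raise ValueError("need >= 2 treatments and >= 2 populations each")

    n_cells = t * b
    cell_sums = np.zeros((X.shape[0], n_cells))
    np.add.at(cell_sums.T, cell_codes, X.T)
    cell_means = cell_sums / r
    trt_means = np.zeros((X.shape[0], t))
    np.add.at(trt_means.T, cell_trt, cell_means.T)
    trt_means /= b
    grand = trt_means.mean(axis=1, keepdims=True)

    ss_trt = b * r * ((trt_means - grand) ** 2).sum(axis=1)
    ss_pop = r * ((cell_means - trt_means[:, cell_trt]) ** 2).sum(axis=1)
    df1, df2 = t - 1, t * (b - 1)
    ms_trt = ss_trt / df1
    ms_pop = ss_pop / df2

    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms_trt / ms_pop
    # Degenerate error term: constant data -> F = 0; perfect separation with
    # zero within-treatment variance -> F = inf (p = 0).
    F = np.where(ms_pop == 0, np.where(ms_trt == 0, 0.0, np.inf), F)
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 1.0, F), df1, df2))
    p = np.where(F == 0, 1.0, p)
    return F, df1, df2, p, trt_means, ms_pop


def nested_anova(values, design: pd.DataFrame):
    """Nested ANOVA for a single transcript.

    Returns ``(F, df1, df2, p, treatment_means)`` with the means keyed by
    treatment label.
    """
    F, df1, df2, p, tm, _ = nested_anova_matrix(np.asarray(values)[None, :], design)
    trts = list(pd.unique(design["treatment"]))
    return (
        float(F[0]),
        df1,
        df2,
        float(p[0]),
        {t: float(m) for t, m in zip(trts, tm[0])},
    )


def _design_pairs(trts) -> list[tuple[str, str]]:
    present = [p for p in PAIRS if p[0] in trts and p[1] in trts]
    if present:
        return present
    import itertools

    return list(itertools.combinations(trts, 2))


def pairwise_contrasts_matrix(values: np.ndarray, design: pd.DataFrame):
    """Pairwise treatment contrasts with the nested error term.

    For each treatment pair (a, b) the difference is mean(b) - mean(a) (log2
    scale) and the t statistic uses MS(Population within Treatment) with its
    df (6 at the source design).  Returns ``(diffs, pvals, pairs)`` with
    diffs/pvals of shape (m x n_pairs), columns in ``pairs`` order
    (:data:`PAIRS` for the canonical three treatments).
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    trts, b, r, *_ = _design_codes(design)
    _, df1, df2, _, tm, ms_pop = nested_anova_matrix(X, design)
    idx = {t: i for i, t in enumerate(trts)}
    pairs = _design_pairs(trts)
    se = np.sqrt(ms_pop * 2.0 / (b * r))
    diffs = np.empty((X.shape[0], len(pairs)))
    pvals = np.empty_like(diffs)
    for k, (a, c) in enumerate(pairs):
        d = tm[:, idx[c]] - tm[:, idx[a]]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = d / se
        pk = 2.0 * stats.t.sf(np.abs(np.where(se == 0, 0.0, tstat)), df2)
        pk = np.where(se == 0, np.where(d == 0, 1.0, 0.0), pk)
        diffs[:, k] = d
        pvals[:, k] = pk
    return diffs, pvals, pairs


def pairwise_contrasts(values, design: pd.DataFrame):
    """Single-transcript contrasts: {(a, b): (difference, p)}."""
    diffs, pvals, pairs = pairwise_contrasts_matrix(
        np.asarray(values)[None, :], design
    )
    return {
        pair: (float(diffs[0, k]), float(pvals[0, k]))
        for k, pair in enumerate(pairs)
    }


def bh_fdr(pvals, q_star: float = 0.05):
    """Benjamini-Hochberg step-up: returns (q-values, reject flags).

    Rejects all p <= p_(k) where k = max{i : p_(i) <= i q*/m}; q-values are
    the monotone-adjusted p m/i, never below the raw p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=q_star, method="fdr_bh")
    return q, reject


@dataclass
class CategoryAssignment:
    category: int
    direction: str  # "up", "down" or "" for unclassified
    reason: str = ""


def classify_category(
    sig: dict[tuple[str, str], bool],
    treatment_means: dict[str, float],
    strict: bool = True,
) -> CategoryAssignment:
    """Map pairwise significance flags + mean ordering to a category.

    ``sig`` keys are the pairs in :data:`PAIRS`; flags are assumed already
    gated on the overall FDR test.  In strict mode (default) categories 4-6
    require all three contrasts significant; lenient mode also maps two-pair
    patterns that include the CDX-MLX contrast onto 4-6 via the strict
    ordering of the three means.
    """
    s12 = bool(sig[("C", "CDX")])
    s13 = bool(sig[("C", "MLX")])
    s23 = bool(sig[("CDX", "MLX")])
    mC, mCDX, mMLX = (treatment_means[t] for t in TREATMENTS)
    nsig = s12 + s13 + s23

    def ordered_category():
        vals = {"C": mC, "CDX": mCDX, "MLX": mMLX}
        ranked = sorted(vals, key=vals.get)
        if len({mC, mCDX, mMLX}) < 3:
            return None
        middle = ranked[1]
        if middle == "C":  # order CDX-C-MLX
            return CategoryAssignment(4, "up" if mMLX > mCDX else "down")
        if middle == "MLX":  # order CDX-MLX-C
            return CategoryAssignment(5, "up" if mC > mCDX else "down")
        return CategoryAssignment(6, "up" if mMLX > mC else "down")  # C-CDX-MLX

    if nsig == 0:
        return CategoryAssignment(0, "", "no significant pairwise differences")
    if nsig == 1:
        return CategoryAssignment(0, "", "only one significant pairwise difference")
    if nsig == 3:
        cat = ordered_category()
        if cat is None:
            return CategoryAssignment(0, "", "treatment means not strictly ordered")
        return cat
    # exactly two significant pairs
    if not strict and s23:
        cat = ordered_category()
        if cat is not None:
            return cat
    if s12 and s13:  # CDX and MLX both differ from C
        d1, d2 = np.sign(mCDX - mC), np.sign(mMLX - mC)
        if d1 == d2 and d1 != 0:
            return CategoryAssignment(1, "up" if d1 > 0 else "down")
        return CategoryAssignment(
            0, "", "CDX and MLX deviate from C in opposite directions"
        )
    if s12 and s23:  # only CDX differs
        return CategoryAssignment(2, "up" if mCDX > mC else "down")
    # s13 and s23: only MLX differs
    return CategoryAssignment(3, "up" if mMLX > mC else "down")


def run_de(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    q_star: float = 0.05,
    pairwise_alpha: float = 0.05,
    pairwise_fdr: bool = False,
    strict_categories: bool = True,
) -> pd.DataFrame:
    """Full differential-expression analysis of an expression matrix.

    Per transcript: nested ANOVA (overall F, p), BH q-value across all
    transcripts, pairwise contrasts, and a category assignment for
    transcripts passing the overall FDR gate.  Pairwise significance is the
    unadjusted ``pairwise_alpha`` by default; ``pairwise_fdr=True`` instead
    applies BH at ``pairwise_alpha`` across all pairwise p-values of
    FDR-passing transcripts.

    Returns one row per transcript with columns ``F, p, q, rejected,
    mean_C, mean_CDX, mean_MLX, diff/p per pair, category, direction,
    reason``.
    """
    design = design.set_index("sample_id").loc[list(expr.columns)].reset_index()
    X = expr.to_numpy(dtype=float)
    F, df1, df2, p, tm, _ = nested_anova_matrix(X, design)
    diffs, pp, pairs = pairwise_contrasts_matrix(X, design)
    if tuple(pairs) != PAIRS:
        raise ValueError("run_de requires the three canonical treatments")
    q, rejected = bh_fdr(p, q_star)

    sig = np.zeros_like(pp, dtype=bool)
    if rejected.any():
        if pairwise_fdr:
            flat = pp[rejected].ravel()
            _, rej_flat = bh_fdr(flat, pairwise_alpha)
            sig[rejected] = rej_flat.reshape(-1, pp.shape[1])
        else:
            sig[rejected] = pp[rejected] < pairwise_alpha

    trts = list(pd.unique(design["treatment"]))
    t_idx = {t: i for i, t in enumerate(trts)}
    cats = np.zeros(len(expr), dtype=int)
    dirs = np.full(len(expr), "", dtype=object)
    reasons = np.full(len(expr), "", dtype=object)
    for i in np.flatnonzero(rejected):
        assign = classify_category(
            {pair: sig[i, k] for k, pair in enumerate(PAIRS)},
            {t: tm[i, t_idx[t]] for t in TREATMENTS},
            strict=strict_categories,
        )
        cats[i], dirs[i], reasons[i] = assign.category, assign.direction, assign.reason

    out = pd.DataFrame(
        {
            "transcript_id": expr.index,
            "F": F,
            "df1": df1,
            "df2": df2,
            "p": p,
            "q": q,
            "rejected": rejected,
            "mean_C": tm[:, t_idx["C"]],
            "mean_CDX": tm[:, t_idx["CDX"]],
            "mean_MLX": tm[:, t_idx["MLX"]],
        }
    )
    for k, (a, c) in enumerate(PAIRS):
        out[f"diff_{a}_{c}"] = diffs[:, k]
        out[f"p_{a}_{c}"] = pp[:, k]
        out[f"sig_{a}_{c}"] = sig[:, k]
    out["category"] = cats
    out["direction"] = dirs
    out["reason"] = reasons
    return out


def category_counts(de_table: pd.DataFrame) -> dict[str, int]:
    """Category membership summary (the six-category count layout)."""
    counts = de_table["category"].value_counts()
    summary = {f"category_{k}": int(counts.get(k, 0)) for k in range(7)}
    summary["n_significant"] = int(de_table["rejected"].sum())
    summary["n_transcripts"] = int(len(de_table))
    return summary
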