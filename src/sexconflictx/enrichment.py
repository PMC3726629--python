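"""Enrichment batteries for a transcript set against the array universe.

Four tests, each usable on any transcript category from the differential-
expression step: GO-term overrepresentation (upper-tail hypergeometric),
chromosomal distribution (chi-square goodness of fit against universe
proportions, with optional chromosome exclusion), tissue-specific expression
(one-tailed Fisher exact per tissue, Bonferroni-corrected across the 17
tissues), and two-tailed mean-rank gene-set enrichment (MR-GSE) against a
genome-wide association ranking (male fitness, female fitness or sexual
antagonism).

The universe is the set of informative transcripts on the array (transcripts
without annotation or with flat expression are assumed filtered upstream).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def _as_set(x) -> set:
    return x if isinstance(x, set) else set(x)


def hypergeom_go(
    gene_set,
    universe,
    go_map: pd.DataFrame,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-GO-term overrepresentation by upper-tail hypergeometric test.

    For each term: population = universe size M, successes = term members in
    the universe K, draws = gene-set size n, p = P(X >= observed).  Raw
    p-values are reported by default; ``adjust="bh"`` adds a BH column.

    ``go_map`` is long-format with columns ``transcript_id, term_id``.
    """
    gene_set, universe = _as_set(gene_set), _as_set(universe)
    stray = gene_set - universe
    if stray:
        raise ValueError(f"gene set members outside universe: {sorted(stray)[:10]}")
    gm = go_map[go_map["transcript_id"].isin(universe)]
    M, n = len(universe), len(gene_set)
    rows = []
    for term, sub in gm.groupby("term_id", sort=True):
        members = set(sub["transcript_id"])
        K = len(members)
        x = len(members & gene_set)
        p = float(stats.hypergeom.sf(x - 1, M, K, n))
        rows.append(
            {
                "term_id": term,
                "observed": x,
                "expected": n * K / M,
                "term_size": K,
                "p_raw": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "observed", "expected", "term_size", "p_raw"]
    )
    if adjust == "bh" and len(out):
        from .de import bh_fdr

        out["p_bh"], _ = bh_fdr(out["p_raw"].to_numpy(), 0.05)
    return out.sort_values("p_raw", kind="stable").reset_index(drop=True)


@dataclass
class ChromChisqResult:
    chi2: float
    df: int
    p: float
    table: pd.DataFrame = field(repr=False, default=None)


def chrom_chisq(
    gene_set,
    annotation: pd.DataFrame,
    universe=None,
    exclude_chromosomes=(),
) -> ChromChisqResult:
    """Chi-square test of the set's chromosomal distribution vs the universe.

    Expected counts are the set size times the universe's chromosome
    proportions; df = #chromosomes - 1.  Excluding chromosomes (e.g. the
    gene-poor fourth) drops their transcripts from both set and universe and
    recomputes proportions over the remainder.  Zero-expected cells are
    dropped with a warning (df reduced).
    """
    ann = annotation.set_index("transcript_id")["chromosome"].astype(str)
    universe = _as_set(universe) if universe is not None else set(ann.index)
    gene_set = _as_set(gene_set)
    missing = gene_set - set(ann.index)
    if missing:
        raise ValueError(f"unannotated set members: {sorted(missing)[:10]}")
    exclude = {str(c) for c in exclude_chromosomes}
    uni_chrom = ann.loc[ann.index.isin(universe) & ~ann.isin(exclude)]
    set_chrom = ann.loc[list(gene_set)]
    set_chrom = set_chrom[~set_chrom.isin(exclude)]
    chroms = sorted(uni_chrom.unique())
    observed = np.array([(set_chrom == c).sum() for c in chroms], dtype=float)
    props = np.array([(uni_chrom == c).mean() for c in chroms])
    expected = observed.sum() * props
    keep = expected > 0
    if not keep.all():
        warnings.warn(
            f"dropped zero-expected chromosome cells: "
            f"{[c for c, k in zip(chroms, keep) if not k]}",
            stacklevel=2,
        )
    observed, expected = observed[keep], expected[keep]
    chroms = [c for c, k in zip(chroms, keep) if k]
    if len(chroms) < 2:
        raise ValueError("need >= 2 chromosome classes with positive expectation")
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = len(chroms) - 1
    table = pd.DataFrame(
        {"chromosome": chroms, "observed": observed.astype(int), "expected": expected}
    )
    return ChromChisqResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)), table=table)


def tissue_fisher(
    gene_set,
    tissue_sets: dict[str, set],
    universe,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """One-tailed Fisher exact test of tissue-specific overabundance per tissue.

    For each tissue the 2x2 table crosses (in gene set vs not) with (tissue-
    specific vs not) over the universe; the one-tailed p tests enrichment.
    ``p_bonferroni = min(1, n_tests * p_raw)`` with ``n_tests`` defaulting to
    the number of tissues (17 in the source panel).
    """
    gene_set, universe = _as_set(gene_set), _as_set(universe)
    if not gene_set <= universe:
        raise ValueError("gene set must be contained in the universe")
    n_tests = n_tests if n_tests is not None else len(tissue_sets)
    M, n = len(universe), len(gene_set)
    rows = []
    for tissue, members in tissue_sets.items():
        members = _as_set(members)
        if not members <= universe:
            raise ValueError(f"tissue set '{tissue}' not contained in universe")
        K = len(members)
        a = len(members & gene_set)
        table = [[a, n - a], [K - a, M - n - K + a]]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "tissue": tissue,
                "observed": a,
                "expected": n * K / M,
                "tissue_set_size": K,
                "p_raw": float(p),
                "p_bonferroni": min(1.0, n_tests * float(p)),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("p_raw", kind="stable")
        .reset_index(drop=True)
    )


@dataclass
class MrGseResult:
    mean_rank: float
    z: float
    p: float
    n: int
    N: int
    method: str  # "normal" or "exact"


def association_ranking(scores: pd.Series) -> pd.Series:
    """Rank transcripts by association score; rank 1 = strongest, ties mid-ranked."""
    return scores.rank(ascending=False, method="average")


def _rank_sum_exact_p(N: int, n: int, observed_sum: float) -> float:
    """Exact two-tailed p for the sum of n ranks drawn from 1..N without
    replacement (full permutation null), via the subset-sum count DP."""
    max_s = n * N - n * (n - 1) // 2
    dp = np.zeros((n + 1, max_s + 1))
    dp[0, 0] = 1.0
    for i in range(1, N + 1):
        for k in range(min(n, i), 0, -1):
            dp[k, i:] += dp[k - 1, :-i]
    counts = dp[n]
    mu = n * (N + 1) / 2.0
    dev = abs(observed_sum - mu)
    s = np.arange(max_s + 1)
    return float(counts[np.abs(s - mu) >= dev - 1e-9].sum() / counts.sum())


def mr_gse(
    gene_set,
    ranking: pd.Series,
    exact: bool | None = None,
    exact_limit: int = 100_000,
    auto_exact_limit: int = 10_000,
) -> MrGseResult:
    """Two-tailed mean-rank gene-set enrichment test.

    The statistic is the mean rank of the set members in a genome-wide
    ranking (1 = strongest association).  Under the null of a random size-n
    subset drawn without replacement from N ranks, the mean rank has mean
    (N + 1)/2 and variance (N - n)(N + 1)/(12 n); the two-tailed p comes from
    the normal approximation, or from the exact permutation distribution when
    ``exact`` is requested (supported for n*N <= ``exact_limit``; chosen
    automatically below ``auto_exact_limit`` when the ranking is untied).
    A low mean rank signals positive association.
    """
    gene_set = _as_set(gene_set)
    stray = gene_set - set(ranking.index)
    if stray:
        raise ValueError(f"set members missing from ranking: {sorted(stray)[:10]}")
    N, n = len(ranking), len(gene_set)
    if not 1 <= n < N:
        raise ValueError("need 1 <= set size < ranking size (degenerate variance)")
    ranks = ranking.loc[list(gene_set)].to_numpy(dtype=float)
    mean_rank = float(ranks.mean())
    mu = (N + 1) / 2.0
    var = (N - n) * (N + 1) / (12.0 * n)
    z = (mean_rank - mu) / math.sqrt(var)
    untied = ranking.round().nunique() == N and np.allclose(
        np.sort(ranking), np.arange(1, N + 1)
    )
    use_exact = (
        exact if exact is not None else (n * N <= auto_exact_limit and untied)
    )
    if use_exact:
        if not untied:
            raise ValueError("exact mode requires an untied integer ranking")
        if n * N > exact_limit:
            raise ValueError(f"exact mode limited to n*N <= {exact_limit}")
        p = _rank_sum_exact_p(N, n, mean_rank * n)
        method = "exact"
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
        method = "normal"
    return MrGseResult(mean_rank=mean_rank, z=float(z), p=min(p, 1.0), n=n, N=N, method=method)
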