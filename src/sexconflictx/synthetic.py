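"""Synthetic data generator emulating the MLX expression experiment.

Everything the analysis pipeline consumes can be generated here with known
ground truth: an 18-sample expression matrix with planted treatment-pattern
categories, transcript annotations (chromosome arm, GO terms, tissue-specific
sets, sex-bias direction, fitness-association scores), and per-vial fitness
and sex-ratio count tables.

The expression model is exactly the structure the downstream nested ANOVA
assumes: for transcript *i* in sample *j* (treatment *t*, population *p*),

    y_ij = baseline_i + delta_i(t) + u_i(t, p) + e_ij

with ``u ~ N(0, population_sd^2)`` drawn once per (transcript, population)
and shared by that population's replicates, and ``e ~ N(0, residual_sd^2)``.
Planted treatment offsets ``delta`` follow the six treatment-pattern
categories (see :data:`CATEGORY_OFFSETS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TREATMENTS, validate_design

# Per-category treatment offsets in units of effect_size, "up" variant,
# order (C, CDX, MLX).  Down variants are the negation.
#   1: shared shift of both DX-mothered groups (maternal effect)
#   2: CDX-only shift (candidate imprinting signal)
#   3: MLX-only shift (response to male-limited evolution)
#   4: monotone CDX < C < MLX (fitness-related)
#   5: monotone CDX < MLX < C (deleterious maternal effect, partly adapted)
#   6: monotone C < CDX < MLX (beneficial maternal effect, enhanced)
CATEGORY_OFFSETS: dict[int, tuple[float, float, float]] = {
    0: (0.0, 0.0, 0.0),
    1: (0.0, 1.0, 1.0),
    2: (0.0, 1.0, 0.0),
    3: (0.0, 0.0, 1.0),
    4: (0.0, -1.0, 1.0),
    5: (0.0, -2.0, -1.0),
    6: (0.0, 1.0, 2.0),
}

#: Default fly-like chromosome weights (two major autosomes split into one
#: label each, the dot fourth chromosome gene-poor).
DEFAULT_CHROMOSOME_WEIGHTS = {"X": 0.16, "2": 0.40, "3": 0.42, "4": 0.02}

#: 17 adult tissues, mirroring the tissue panel used for tissue-specificity
#: calls (two-fold enrichment over whole fly) in the fly expression atlas.
DEFAULT_TISSUES = (
    "brain",
    "head",
    "eye",
    "thoracic_ganglion",
    "salivary_gland",
    "crop",
    "midgut",
    "hindgut",
    "malpighian_tubule",
    "fat_body",
    "testis",
    "accessory_gland",
    "ejaculatory_duct",
    "ovary",
    "spermatheca",
    "carcass",
    "heart",
)


@dataclass
class TranscriptAnnotation:
    """Annotation bundle: per-transcript table, GO map and tissue sets.

    ``table`` has one row per transcript with columns ``transcript_id,
    chromosome, sex_bias_sign, male_fitness_score, female_fitness_score,
    antagonism_score``; ``go_map`` is long-format (transcript_id, term_id);
    ``tissue_sets`` maps tissue name -> set of transcript ids specific to it
    (sets are mutually disjoint).
    """

    table: pd.DataFrame
    go_map: pd.DataFrame
    tissue_sets: dict[str, set] = field(default_factory=dict)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.table["transcript_id"])


def _transcript_ids(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"tr{i:0{width}d}" for i in range(n)]


def category_offsets(category: int, effect_size: float, direction: int = 1):
    """Planted (delta_C, delta_CDX, delta_MLX) for a category, log2 units."""
    base = CATEGORY_OFFSETS[category]
    return tuple(direction * effect_size * v for v in base)


def generate_expression(
    design: pd.DataFrame,
    n_transcripts: int,
    category_fractions: dict[int, float] | None = None,
    effect_size: float = 1.0,
    population_sd: float = 0.1,
    residual_sd: float = 0.3,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
    extra_cdx_offset: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix with planted treatment-pattern categories.

    Parameters
    ----------
    design
        Balanced sample design (see :func:`generate_design`).
    n_transcripts
        Number of transcripts (rows).
    category_fractions
        Map category (1-6) -> fraction of transcripts planted with that
        pattern.  Fractions must sum to <= 1; the remainder is category 0
        (no treatment effect).
    effect_size
        Offset magnitude in log2 units (see :data:`CATEGORY_OFFSETS`).
    population_sd, residual_sd
        Random population effect and residual standard deviations.
    extra_cdx_offset
        Optional per-transcript additive shift applied to the CDX treatment
        only (length ``n_transcripts``).  Used by the "feminized" coupling
        mode, see :func:`feminized_cdx_offsets`.
    seed
        Seed; identical arguments + seed give bit-identical output.

    Returns
    -------
    (expression, truth)
        ``expression``: DataFrame, rows = transcript ids, columns = sample
        ids, log2-scale values.  ``truth``: one row per transcript with the
        planted category, direction and the three treatment offsets.
    """
    trts, b, r = validate_design(design)
    category_fractions = dict(category_fractions or {})
    bad = set(category_fractions) - set(range(1, 7))
    if bad:
        raise ValueError(f"unknown categories in fractions: {sorted(bad)}")
    total = sum(category_fractions.values())
    if total > 1 + 1e-12:
        raise ValueError(f"category fractions sum to {total} > 1")
    if population_sd < 0 or residual_sd < 0:
        raise ValueError("standard deviations must be >= 0")

    rng = np.random.default_rng(seed)
    ids = _transcript_ids(n_transcripts)

    # Assign planted categories to a random subset of transcripts.
    categories = np.zeros(n_transcripts, dtype=int)
    perm = rng.permutation(n_transcripts)
    pos = 0
    for cat in sorted(category_fractions):
        k = int(round(category_fractions[cat] * n_transcripts))
        categories[perm[pos : pos + k]] = cat
        pos += k
    directions = rng.choice([-1, 1], size=n_transcripts)
    directions[categories == 0] = 0

    offsets = np.zeros((n_transcripts, 3))  # columns follow TREATMENTS order
    for cat, base in CATEGORY_OFFSETS.items():
        mask = categories == cat
        if mask.any():
            offsets[mask] = (
                directions[mask, None] * effect_size * np.asarray(base)[None, :]
            )
    if extra_cdx_offset is not None:
        extra = np.asarray(extra_cdx_offset, dtype=float)
        if extra.shape != (n_transcripts,):
            raise ValueError("extra_cdx_offset must have length n_transcripts")
        offsets[:, 1] += extra

    trt_col = {t: k for k, t in enumerate(TREATMENTS)}
    sample_trt = np.array([trt_col.get(t, -1) for t in design["treatment"]])
    if (sample_trt < 0).any():
        raise ValueError("design contains treatments outside {C, CDX, MLX}")
    cell_codes = pd.factorize(
        design["treatment"].astype(str) + "/" + design["population"].astype(str)
    )[0]
    n_cells = cell_codes.max() + 1

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_transcripts)
    pop_eff = rng.normal(0.0, population_sd, size=(n_transcripts, n_cells))
    resid = rng.normal(0.0, residual_sd, size=(n_transcripts, len(design)))

    values = (
        baseline[:, None]
        + offsets[:, sample_trt]
        + pop_eff[:, cell_codes]
        + resid
    )
    expr = pd.DataFrame(values, index=ids, columns=list(design["sample_id"]))
    expr.index.name = "transcript_id"
    truth = pd.DataFrame(
        {
            "transcript_id": ids,
            "category": categories,
            "direction": directions,
            "delta_C": offsets[:, 0],
            "delta_CDX": offsets[:, 1],
            "delta_MLX": offsets[:, 2],
        }
    )
    return expr, truth


def generate_annotations(
    n_transcripts: int,
    chromosome_weights: dict[str, float] | None = None,
    n_go_terms: int = 50,
    go_term_size_range: tuple[int, int] = (5, 100),
    tissues: tuple[str, ...] | None = None,
    tissue_set_fraction: float = 0.2,
    sex_bias_prob: float = 0.5,
    sex_bias_zero_fraction: float = 0.0,
    fitness_truth: pd.DataFrame | None = None,
    fitness_coupling: float = 0.0,
    strict_tissues: bool = True,
    transcript_ids: list[str] | None = None,
    seed: int = 0,
) -> TranscriptAnnotation:
    """Synthetic transcript annotation (chromosome, GO, tissues, sex bias).

    Stands in for the real annotation resources: a GO term map, a 17-tissue
    atlas of tissue-specific transcript sets (defined in the real resource by
    two-fold enrichment over whole fly), a sex-bias direction per transcript
    (sign of female minus male expression measured in an external contrast),
    and fitness-association scores used only through their ranks.

    ``fitness_coupling`` > 0 (requires ``fitness_truth``) shifts the male
    fitness and antagonism scores of transcripts planted in categories 3 and
    4 upward by that amount, so rank-based enrichment recovery can be tested;
    by default scores are independent of the planted structure.
    """
    if chromosome_weights is None:
        chromosome_weights = dict(DEFAULT_CHROMOSOME_WEIGHTS)
    tissues = tuple(tissues if tissues is not None else DEFAULT_TISSUES)
    if strict_tissues and len(tissues) != 17:
        raise ValueError(
            f"strict mode requires exactly 17 tissues, got {len(tissues)}"
        )
    w = np.array(list(chromosome_weights.values()), dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("chromosome weights must be non-negative, sum > 0")
    if not 0 <= tissue_set_fraction <= 1:
        raise ValueError("tissue_set_fraction must be in [0, 1]")
    if not 0 <= sex_bias_prob <= 1 or not 0 <= sex_bias_zero_fraction <= 1:
        raise ValueError("sex-bias probabilities must be in [0, 1]")

    rng = np.random.default_rng(seed)
    ids = list(transcript_ids) if transcript_ids is not None else _transcript_ids(
        n_transcripts
    )
    if len(ids) != n_transcripts:
        raise ValueError("transcript_ids length must equal n_transcripts")
    id_arr = np.asarray(ids)

    chroms = rng.choice(list(chromosome_weights), size=n_transcripts, p=w / w.sum())

    signs = np.where(rng.random(n_transcripts) < sex_bias_prob, 1, -1)
    if sex_bias_zero_fraction > 0:
        signs[rng.random(n_transcripts) < sex_bias_zero_fraction] = 0

    scores = {
        name: rng.standard_normal(n_transcripts)
        for name in ("male_fitness_score", "female_fitness_score", "antagonism_score")
    }
    if fitness_coupling and fitness_truth is not None:
        coupled = fitness_truth["category"].isin([3, 4]).to_numpy()
        scores["male_fitness_score"] = scores["male_fitness_score"] + np.where(
            coupled, fitness_coupling, 0.0
        )
        scores["antagonism_score"] = scores["antagonism_score"] + np.where(
            coupled, fitness_coupling, 0.0
        )

    lo, hi = go_term_size_range
    if not 1 <= lo <= hi:
        raise ValueError("go_term_size_range must satisfy 1 <= lo <= hi")
    lo, hi = min(lo, n_transcripts), min(hi, n_transcripts)  # clamp to universe
    go_rows = []
    for t in range(n_go_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_transcripts, size=size, replace=False)
        term = f"GO:{t:07d}"
        go_rows.extend((id_arr[m], term) for m in members)
    go_map = pd.DataFrame(go_rows, columns=["transcript_id", "term_id"])

    # Tissue-specific sets: a random tissue_set_fraction of transcripts is
    # tissue-specific, partitioned among tissues (disjoint by construction).
    n_specific = int(round(tissue_set_fraction * n_transcripts))
    specific = rng.choice(n_transcripts, size=n_specific, replace=False)
    assignment = rng.integers(0, len(tissues), size=n_specific)
    tissue_sets: dict[str, set] = {t: set() for t in tissues}
    for idx, t_idx in zip(specific, assignment):
        tissue_sets[tissues[t_idx]].add(id_arr[idx])

    table = pd.DataFrame(
        {
            "transcript_id": ids,
            "chromosome": chroms,
            "sex_bias_sign": signs,
            **scores,
        }
    )
    return TranscriptAnnotation(table=table, go_map=go_map, tissue_sets=tissue_sets)


def feminized_cdx_offsets(
    annotation: TranscriptAnnotation, shift: float
) -> np.ndarray:
    """CDX-only offsets aligned with each transcript's sex-bias direction.

    Feeding the result to ``generate_expression(extra_cdx_offset=...)``
    couples the CDX-vs-Control expression change to extant sexual dimorphism
    — the signal a feminized paternal X would produce — for power tests of
    the feminization test.  With the default generators (no coupling) that
    test is null-calibrated.
    """
    return shift * annotation.table["sex_bias_sign"].to_numpy(dtype=float)


def _beta_binomial(
    rng: np.random.Generator, n: int, p: np.ndarray, overdispersion: float
) -> np.ndarray:
    """Beta-binomial draws with mean n*p and intra-class correlation rho."""
    p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    if overdispersion <= 0:
        return rng.binomial(n, p)
    rho = min(overdispersion, 1 - 1e-9)
    c = (1 - rho) / rho  # concentration: alpha + beta
    out = np.empty(p.shape, dtype=int)
    edge = (p <= 0) | (p >= 1)
    out[edge] = (p[edge] >= 1) * n
    if (~edge).any():
        a = p[~edge] * c
        bpar = (1 - p[~edge]) * c
        out[~edge] = rng.binomial(n, rng.beta(a, bpar))
    return out


def _vial_counts(
    props: dict[str, float],
    n_populations: int,
    n_vials: int,
    offspring_per_vial: int,
    overdispersion: float,
    population_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    for t, p in props.items():
        if not 0 <= p <= 1:
            raise ValueError(f"proportion for {t} outside [0, 1]: {p}")
    if n_populations < 1 or n_vials < 1 or offspring_per_vial < 1:
        raise ValueError("counts must be >= 1")
    rows = []
    for trt, base in props.items():
        for pop in range(1, n_populations + 1):
            mu = base + (rng.normal(0, population_sd) if population_sd > 0 else 0.0)
            mu = float(np.clip(mu, 0.0, 1.0))
            counts = _beta_binomial(
                rng, offspring_per_vial, np.full(n_vials, mu), overdispersion
            )
            rows.extend(
                {
                    "treatment": trt,
                    "population": pop,
                    "vial_id": f"{trt}_p{pop}_v{v + 1}",
                    "count": int(c),
                    "total": offspring_per_vial,
                }
                for v, c in enumerate(counts)
            )
    return pd.DataFrame(rows)


def generate_fitness_assay(
    treatment_props: dict[str, float],
    n_populations: int = 3,
    n_vials: int = 20,
    offspring_per_vial: int = 100,
    overdispersion: float = 0.0,
    population_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-vial competitive-fitness counts (target-sired vs total offspring).

    Each vial's target-sired count is beta-binomial with mean given by the
    treatment proportion plus a population-level normal deviation, which lets
    the generator create the vial-level overdispersion that motivates
    analysing population means.  Defaults give the source design's 20 vials x
    3 populations x 3 treatments = 180 vials.
    """
    rng = np.random.default_rng(seed)
    df = _vial_counts(
        treatment_props,
        n_populations,
        n_vials,
        offspring_per_vial,
        overdispersion,
        population_sd,
        rng,
    )
    return df.rename(
        columns={"count": "n_target_offspring", "total": "n_total_offspring"}
    )


def generate_sex_ratio(
    treatment_male_props: dict[str, float],
    n_populations: int = 3,
    n_vials: int = 20,
    offspring_per_vial: int = 100,
    overdispersion: float = 0.0,
    population_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-vial adult offspring sex counts (males vs females)."""
    rng = np.random.default_rng(seed)
    df = _vial_counts(
        treatment_male_props,
        n_populations,
        n_vials,
        offspring_per_vial,
        overdispersion,
        population_sd,
        rng,
    )
    df["n_female_offspring"] = df["total"] - df["count"]
    return df.rename(columns={"count": "n_male_offspring"}).drop(columns="total")
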