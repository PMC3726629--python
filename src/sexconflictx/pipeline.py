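"""End-to-end pipeline: simulate -> DE -> categorise -> enrich -> feminization.

Driven by a :class:`PipelineConfig` (YAML-loadable).  By default all inputs
are generated by the synthetic module with the configured seed; setting
``input_dir`` instead reads previously written inputs (design.csv,
expression.tsv, annotation.csv, go_map.tsv, tissue_sets.yaml, fitness.csv,
sex_ratio.csv) so real or doctored data can be analysed with the same code
path.  Identical config + seed give identical outputs; every output file
carries the config hash and seed in its comment header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io
from .de import category_counts, run_de
from .design import generate_design
from .enrichment import association_ranking, chrom_chisq, hypergeom_go, mr_gse, tissue_fisher
from .feminization import classify_directions, feminization_chisq
from .fitness import analyze_fitness, analyze_sex_ratio
from .synthetic import (
    generate_annotations,
    generate_expression,
    generate_fitness_assay,
    generate_sex_ratio,
)

log = logging.getLogger("sexconflictx")

RANKING_SCORES = ("male_fitness_score", "female_fitness_score", "antagonism_score")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (defaults emulate the source design)."""

    seed: int = 0
    # design
    n_treatments: int = 3
    n_populations: int = 3
    n_replicates: int = 2
    # expression generator
    n_transcripts: int = 5000
    category_fractions: dict = field(
        default_factory=lambda: {1: 0.002, 3: 0.01, 4: 0.01, 5: 0.002, 6: 0.002}
    )
    effect_size: float = 1.0
    population_sd: float = 0.1
    residual_sd: float = 0.3
    # annotations
    n_go_terms: int = 50
    go_term_size_range: tuple = (5, 100)
    tissue_set_fraction: float = 0.2
    fitness_coupling: float = 0.0
    # fitness / sex-ratio assays
    fitness_props: dict = field(
        default_factory=lambda: {"C": 0.30, "CDX": 0.24, "MLX": 0.36}
    )
    sex_ratio_props: dict = field(
        default_factory=lambda: {"C": 0.50, "CDX": 0.47, "MLX": 0.53}
    )
    n_vials: int = 20
    offspring_per_vial: int = 100
    assay_overdispersion: float = 0.05
    assay_population_sd: float = 0.02
    # analysis
    q_star: float = 0.05
    pairwise_alpha: float = 0.05
    pairwise_fdr: bool = False
    strict_categories: bool = True
    min_category_size: int = 10
    sex_ratio_transform_level: str = "vial"
    # I/O
    input_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        if isinstance(cfg.category_fractions, dict):
            cfg.category_fractions = {int(k): v for k, v in cfg.category_fractions.items()}
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_inputs(cfg: PipelineConfig):
    d = Path(cfg.input_dir)
    design = io.read_table(d / "design.csv", sep=",")
    expr = io.read_expression(d / "expression.tsv")
    annot_table = io.read_table(d / "annotation.csv", sep=",")
    go_map = io.read_table(d / "go_map.tsv")
    tissue_sets = io.read_tissue_sets(d / "tissue_sets.yaml")
    fitness = io.read_table(d / "fitness.csv", sep=",")
    sex_ratio = io.read_table(d / "sex_ratio.csv", sep=",")
    truth_path = d / "truth.csv"
    truth = io.read_table(truth_path, sep=",") if truth_path.exists() else None
    return design, expr, truth, annot_table, go_map, tissue_sets, fitness, sex_ratio


def _generate_inputs(cfg: PipelineConfig):
    design = generate_design(cfg.n_treatments, cfg.n_populations, cfg.n_replicates)
    expr, truth = generate_expression(
        design,
        cfg.n_transcripts,
        cfg.category_fractions,
        effect_size=cfg.effect_size,
        population_sd=cfg.population_sd,
        residual_sd=cfg.residual_sd,
        seed=cfg.seed,
    )
    annot = generate_annotations(
        cfg.n_transcripts,
        n_go_terms=cfg.n_go_terms,
        go_term_size_range=tuple(cfg.go_term_size_range),
        tissue_set_fraction=cfg.tissue_set_fraction,
        fitness_truth=truth,
        fitness_coupling=cfg.fitness_coupling,
        transcript_ids=list(expr.index),
        seed=cfg.seed + 1,
    )
    fitness = generate_fitness_assay(
        cfg.fitness_props,
        n_populations=cfg.n_populations,
        n_vials=cfg.n_vials,
        offspring_per_vial=cfg.offspring_per_vial,
        overdispersion=cfg.assay_overdispersion,
        population_sd=cfg.assay_population_sd,
        seed=cfg.seed + 2,
    )
    sex_ratio = generate_sex_ratio(
        cfg.sex_ratio_props,
        n_populations=cfg.n_populations,
        n_vials=cfg.n_vials,
        offspring_per_vial=cfg.offspring_per_vial,
        overdispersion=cfg.assay_overdispersion,
        population_sd=cfg.assay_population_sd,
        seed=cfg.seed + 3,
    )
    return design, expr, truth, annot.table, annot.go_map, annot.tissue_sets, fitness, sex_ratio


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Run all stages; write per-stage outputs under ``out_dir``; return report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": cfg.seed, "config_sha256": cfg.digest()}
    report: dict = {"seed": cfg.seed, "config_sha256": cfg.digest()}

    stage = "inputs"
    try:
        if cfg.input_dir:
            inputs = _load_inputs(cfg)
        else:
            inputs = _generate_inputs(cfg)
        design, expr, truth, annot_table, go_map, tissue_sets, fitness, sex_ratio = inputs
        io.write_table(design, out / "design.csv", sep=",", meta=meta)
        io.write_expression(expr, out / "expression.tsv", meta=meta)
        if truth is not None:
            io.write_table(truth, out / "truth.csv", sep=",", meta=meta)
        io.write_table(annot_table, out / "annotation.csv", sep=",", meta=meta)
        io.write_table(go_map, out / "go_map.tsv", meta=meta)
        io.write_tissue_sets(tissue_sets, out / "tissue_sets.yaml", meta=meta)
        io.write_table(fitness, out / "fitness.csv", sep=",", meta=meta)
        io.write_table(sex_ratio, out / "sex_ratio.csv", sep=",", meta=meta)

        stage = "fitness_anova"
        log.info("stage %s", stage)
        fit_res = analyze_fitness(fitness)
        sr_res = analyze_sex_ratio(sex_ratio, transform_level=cfg.sex_ratio_transform_level)
        report["fitness_anova"] = dataclasses.asdict(fit_res)
        report["sex_ratio_anova"] = dataclasses.asdict(sr_res)
        io.write_json(report["fitness_anova"], out / "fitness_anova.json", meta=meta)
        io.write_json(report["sex_ratio_anova"], out / "sex_ratio_anova.json", meta=meta)

        stage = "differential_expression"
        log.info("stage %s", stage)
        de = run_de(
            expr,
            design,
            q_star=cfg.q_star,
            pairwise_alpha=cfg.pairwise_alpha,
            pairwise_fdr=cfg.pairwise_fdr,
            strict_categories=cfg.strict_categories,
        )
        io.write_table(de, out / "de_results.tsv", meta=meta)
        summary = category_counts(de)
        report["categories"] = summary
        io.write_json(summary, out / "category_summary.json", meta=meta)

        stage = "enrichment"
        log.info("stage %s", stage)
        universe = set(expr.index)
        rankings = {
            name: association_ranking(
                annot_table.set_index("transcript_id")[name]
            )
            for name in RANKING_SCORES
        }
        enrich_report: dict = {}
        for cat in range(1, 7):
            members = set(de.loc[de["category"] == cat, "transcript_id"])
            if len(members) < cfg.min_category_size:
                continue
            go = hypergeom_go(members, universe, go_map)
            io.write_table(go, out / f"enrichment_cat{cat}_go.tsv", meta=meta)
            chrom = chrom_chisq(members, annot_table, universe)
            tis = tissue_fisher(members, tissue_sets, universe)
            io.write_table(tis, out / f"enrichment_cat{cat}_tissue.tsv", meta=meta)
            gse = {
                name: dataclasses.asdict(mr_gse(members, rank))
                for name, rank in rankings.items()
            }
            enrich_report[f"category_{cat}"] = {
                "n_members": len(members),
                "top_go_terms": go.head(5).to_dict(orient="records"),
                "chromosome_chisq": {
                    "chi2": chrom.chi2,
                    "df": chrom.df,
                    "p": chrom.p,
                },
                "top_tissues": tis.head(5).to_dict(orient="records"),
                "mr_gse": gse,
            }
        report["enrichment"] = enrich_report
        io.write_json(enrich_report, out / "enrichment_summary.json", meta=meta)

        stage = "feminization"
        log.info("stage %s", stage)
        ann = annot_table.set_index("transcript_id")
        fem_report = {}
        for label, which in (("X", "X"), ("autosomes", "autosomes")):
            counts = classify_directions(
                expr,
                design,
                sex_bias_sign=ann["sex_bias_sign"],
                chromosome=ann["chromosome"],
                chromosomes=which,
            )
            res = feminization_chisq(counts)
            fem_report[label] = {
                "observed": list(res.observed),
                "expected_per_cell": res.expected_per_cell,
                "chi2": res.chi2,
                "df": res.df,
                "p": res.p,
                "concordant": res.concordant,
                "discordant": res.discordant,
                "concordance_p": res.concordance_p,
                "n_excluded_zero": counts.n_excluded_zero,
            }
        report["feminization"] = fem_report
        io.write_json(fem_report, out / "feminization.json", meta=meta)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    io.write_json(report, out / "report.json", meta=meta)
    return report
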