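"""Enrichment batteries on a transcript category.

GO hypergeometric, chromosome chi-square, tissue Fisher (Bonferroni over the
17-tissue panel) and mean-rank gene-set enrichment against a male-fitness
association ranking.
"""

from sexconflictx import (
    association_ranking,
    chrom_chisq,
    generate_annotations,
    generate_design,
    generate_expression,
    hypergeom_go,
    mr_gse,
    run_de,
    tissue_fisher,
)

design = generate_design(3, 3, 2)
expr, truth = generate_expression(
    design, 3000, {3: 0.01, 4: 0.01}, effect_size=1.5, seed=11
)
ann = generate_annotations(
    3000,
    fitness_truth=truth,
    fitness_coupling=1.0,  # planted categories rank high for male fitness
    transcript_ids=list(expr.index),
    seed=12,
)
de = run_de(expr, design)
cat4 = set(de.loc[de["category"] == 4, "transcript_id"])
universe = set(expr.index)
print(f"category-4 ('fitness') transcripts: {len(cat4)}")

go = hypergeom_go(cat4, universe, ann.go_map)
print("top GO term:", go.iloc[0][["term_id", "observed", "p_raw"]].to_dict())

chrom = chrom_chisq(cat4, ann.table, universe)
print(f"chromosome distribution: chi2 = {chrom.chi2:.3f}, df = {chrom.df}, "
      f"P = {chrom.p:.4f}")

tis = tissue_fisher(cat4, ann.tissue_sets, universe)
print("top tissue:", tis.iloc[0][["tissue", "observed", "p_bonferroni"]].to_dict())

ranking = association_ranking(
    ann.table.set_index("transcript_id")["male_fitness_score"]
)
gse = mr_gse(cat4, ranking)
print(f"MR-GSE vs male fitness: mean rank = {gse.mean_rank:.1f} "
      f"(null {(gse.N + 1) / 2:.1f}), z = {gse.z:.2f}, P = {gse.p:.2g}")
# A mean rank far below (N+1)/2 means the category is enriched for
# transcripts strongly associated with male fitness.
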