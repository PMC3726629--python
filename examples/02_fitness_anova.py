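"""Competitive-fitness and sex-ratio ANOVAs on population means.

The vial is the sample; vial proportions are averaged per population and a
one-way ANOVA compares treatments across population means (df = 2, 6 at the
source replication).  Sex ratios are arcsine-square-root transformed first.
"""

from sexconflictx import (
    analyze_fitness,
    analyze_sex_ratio,
    generate_fitness_assay,
    generate_sex_ratio,
)

assay = generate_fitness_assay(
    {"C": 0.30, "CDX": 0.24, "MLX": 0.36},
    overdispersion=0.05,
    population_sd=0.02,
    seed=1,
)
fit = analyze_fitness(assay)
print(f"fitness: F_{fit.df1},{fit.df2} = {fit.F:.3f}, P = {fit.p:.4f}")
print("treatment means:", {k: round(v, 3) for k, v in fit.group_means.items()})

ratios = generate_sex_ratio(
    {"C": 0.50, "CDX": 0.47, "MLX": 0.53},
    overdispersion=0.05,
    population_sd=0.02,
    seed=2,
)
sr = analyze_sex_ratio(ratios)
print(f"sex ratio (arcsine-sqrt): F_{sr.df1},{sr.df2} = {sr.F:.3f}, P = {sr.p:.4f}")
# A small P says the treatments differ in proportion sired (or in proportion
# of male offspring); the group means show the direction (MLX > C > CDX).
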