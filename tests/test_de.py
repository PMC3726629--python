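"""Nested ANOVA, pairwise contrasts, BH-FDR and the category classifier."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sexconflictx import (
    bh_fdr,
    classify_category,
    generate_design,
    generate_expression,
    nested_anova,
    nested_anova_matrix,
    pairwise_contrasts,
    run_de,
)
from sexconflictx.de import PAIRS


def brute_force_nested_anova(values, design):
    """Independent sums-of-squares oracle: explicit loops over cells."""
    df = design.copy()
    df["y"] = np.asarray(values, dtype=float)
    trts = list(pd.unique(df["treatment"]))
    b = df.groupby("treatment")["population"].nunique().iloc[0]
    r = df.groupby(["treatment", "population"]).size().iloc[0]
    trt_means = {t: df.loc[df.treatment == t, "y"].mean() for t in trts}
    grand = np.mean(list(trt_means.values()))
    ss_trt = b * r * sum((m - grand) ** 2 for m in trt_means.values())
    ss_pop = 0.0
    for (t, p), cell in df.groupby(["treatment", "population"]):
        ss_pop += r * (cell["y"].mean() - trt_means[t]) ** 2
    df1, df2 = len(trts) - 1, len(trts) * (b - 1)
    ms_t, ms_p = ss_trt / df1, ss_pop / df2
    F = 0.0 if ms_t == 0 else (np.inf if ms_p == 0 else ms_t / ms_p)
    return F, df1, df2


class TestNestedAnova:
    def test_paper_design_degrees_of_freedom(self, paper_design, rng):
        y = rng.normal(size=18)
        _, df1, df2, p, means = nested_anova(y, paper_design)
        assert (df1, df2) == (2, 6)
        assert set(means) == {"C", "CDX", "MLX"}

    def test_constant_data_guarded_to_zero_f(self, paper_design):
        F, _, _, p, _ = nested_anova(np.full(18, 7.0), paper_design)
        assert F == 0.0 and p == 1.0

    def test_zero_residual_hand_construction(self, paper_design):
        # population means (0,0,0)/(1,1,1)/(2,2,2), zero residual:
        # SS_trt = 6*((−1)²+0+1²) = 12, SS_pop = 0 -> F = inf, p = 0
        offsets = {"C": 0.0, "CDX": 1.0, "MLX": 2.0}
        y = paper_design["treatment"].map(offsets).to_numpy()
        F, _, _, p, _ = nested_anova(y, paper_design)
        assert np.isinf(F) and p == 0.0

    def test_matches_brute_force_oracle(self, paper_design, rng):
        for _ in range(100):
            y = rng.normal(size=18)
            F, df1, df2, _, _ = nested_anova(y, paper_design)
            Fo, df1o, df2o = brute_force_nested_anova(y, paper_design)
            assert (df1, df2) == (df1o, df2o)
            assert F == pytest.approx(Fo, rel=1e-10)

    def test_oracle_on_other_balanced_shapes(self, rng):
        for t, b, r in [(2, 2, 2), (3, 2, 3), (4, 3, 2)]:
            d = generate_design(t, b, r)
            y = rng.normal(size=len(d))
            F = nested_anova_matrix(y[None, :], d)[0]
            Fo, _, _ = brute_force_nested_anova(y, d)
            assert F[0] == pytest.approx(Fo, rel=1e-10)

    def test_unbalanced_design_rejected(self, paper_design, rng):
        with pytest.raises(ValueError, match="unbalanced"):
            nested_anova(rng.normal(size=17), paper_design.iloc[:-1])

    def test_f_invariant_to_affine_transform(self, paper_design, rng):
        y = rng.normal(size=18)
        F1, *_ = nested_anova(y, paper_design)
        F2, *_ = nested_anova(3.0 * y + 11.0, paper_design)
        assert F2 == pytest.approx(F1, rel=1e-10)


class TestPairwiseContrasts:
    def test_symmetric_data_gives_zero_contrast(self, paper_design, rng):
        pop_eff = {(t, p): rng.normal(scale=0.2) for t in ("C", "CDX", "MLX") for p in (1, 2, 3)}
        # make C and MLX population means exactly equal
        for p in (1, 2, 3):
            pop_eff[("MLX", p)] = pop_eff[("C", p)]
        y = np.array(
            [pop_eff[(row.treatment, row.population)] for row in paper_design.itertuples()]
        )
        contrasts = pairwise_contrasts(y, paper_design)
        diff, p = contrasts[("C", "MLX")]
        assert diff == pytest.approx(0.0)
        assert p > 0.9

    def test_recovers_planted_category2_pattern(self, paper_design):
        # CDX shifted by 10x residual sd; C = MLX
        expr, truth = generate_expression(
            paper_design, 200, {2: 0.1}, effect_size=3.0,
            population_sd=0.1, residual_sd=0.3, seed=3,
        )
        planted = truth.loc[truth["category"] == 2, "transcript_id"]
        assert len(planted) == 20
        ok = 0
        for tid in planted:
            c = pairwise_contrasts(expr.loc[tid].to_numpy(), paper_design)
            sig = {pair: p < 0.05 for pair, (_, p) in c.items()}
            ok += sig[("C", "CDX")] and sig[("CDX", "MLX")] and not sig[("C", "MLX")]
        assert ok >= 18

    def test_t_squared_equals_two_group_nested_f(self, rng):
        # on a two-treatment design the contrast is the nested ANOVA:
        # t^2 = F and the p-values agree
        d = generate_design(2, 3, 2)
        y = rng.normal(size=len(d)) + (d["treatment"] == "CDX") * 0.8
        F, df1, df2, p_f, _ = nested_anova(y, d)
        contrasts = pairwise_contrasts(y, d)
        (diff, p_t) = contrasts[("C", "CDX")]
        _, _, _, _, _, ms_pop = nested_anova_matrix(np.asarray(y)[None, :], d)
        t_stat = diff / np.sqrt(ms_pop[0] * 2 / 6)
        assert t_stat**2 == pytest.approx(F, rel=1e-10)
        assert p_t == pytest.approx(p_f, rel=1e-10)


class TestBhFdr:
    def test_all_ones_no_rejections(self):
        q, rej = bh_fdr([1.0, 1.0, 1.0], 0.05)
        assert not rej.any()

    def test_step_up_accepts_all_when_largest_passes(self):
        # p_(4) = 0.04 <= 4*0.05/4 -> all four rejected
        _, rej = bh_fdr([0.01, 0.02, 0.03, 0.04], 0.05)
        assert rej.all()

    def test_step_up_partial(self):
        # only 0.001 <= 1*0.05/3
        _, rej = bh_fdr([0.001, 0.3, 0.9], 0.05)
        assert rej.tolist() == [True, False, False]

    def test_empty_input(self):
        q, rej = bh_fdr([], 0.05)
        assert q.size == 0 and rej.size == 0

    def test_qvalues_bound_pvalues(self, rng):
        p = rng.uniform(size=500)
        q, _ = bh_fdr(p, 0.05)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0).all()

    def test_matches_hand_step_up(self, rng):
        p = rng.uniform(size=50)
        q_star = 0.05
        _, rej = bh_fdr(p, q_star)
        order = np.argsort(p)
        sorted_p = p[order]
        ks = np.flatnonzero(sorted_p <= (np.arange(1, 51) * q_star / 50))
        expected = np.zeros(50, dtype=bool)
        if ks.size:
            expected[order[: ks.max() + 1]] = True
        assert (rej == expected).all()


class TestClassifier:
    def sig(self, s12, s13, s23):
        return {("C", "CDX"): s12, ("C", "MLX"): s13, ("CDX", "MLX"): s23}

    def test_no_significant_pairs_unclassified(self):
        a = classify_category(self.sig(False, False, False), {"C": 0, "CDX": 1, "MLX": 2})
        assert a.category == 0

    def test_single_pair_unclassified_with_reason(self):
        a = classify_category(self.sig(True, False, False), {"C": 0, "CDX": 1, "MLX": 0})
        assert a.category == 0 and "one significant" in a.reason

    def test_category1_same_direction(self):
        a = classify_category(self.sig(True, True, False), {"C": 0, "CDX": 1, "MLX": 1.1})
        assert (a.category, a.direction) == (1, "up")

    def test_category1_pattern_opposite_directions_rejected(self):
        a = classify_category(self.sig(True, True, False), {"C": 0, "CDX": 1, "MLX": -1})
        assert a.category == 0 and "opposite" in a.reason

    def test_category2_cdx_only(self):
        a = classify_category(self.sig(True, False, True), {"C": 0, "CDX": -1, "MLX": 0.1})
        assert (a.category, a.direction) == (2, "down")

    def test_category3_mlx_only(self):
        a = classify_category(self.sig(False, True, True), {"C": 0, "CDX": 0.1, "MLX": 1})
        assert (a.category, a.direction) == (3, "up")

    @pytest.mark.parametrize(
        "means,expected_cat,expected_dir",
        [
            ({"C": 0.0, "CDX": -1.0, "MLX": 1.0}, 4, "up"),   # CDX-C-MLX
            ({"C": 0.0, "CDX": 1.0, "MLX": -1.0}, 4, "down"),
            ({"C": 0.0, "CDX": -2.0, "MLX": -1.0}, 5, "up"),  # CDX-MLX-C
            ({"C": 0.0, "CDX": 1.0, "MLX": 2.0}, 6, "up"),    # C-CDX-MLX
            ({"C": 0.0, "CDX": -1.0, "MLX": -2.0}, 6, "down"),
        ],
    )
    def test_all_significant_ordered_categories(self, means, expected_cat, expected_dir):
        a = classify_category(self.sig(True, True, True), means)
        assert (a.category, a.direction) == (expected_cat, expected_dir)

    def test_lenient_mode_upgrades_two_pair_patterns(self):
        # sig(C,CDX) + sig(CDX,MLX), strictly ordered CDX < C < MLX
        flags = self.sig(True, False, True)
        means = {"C": 0.0, "CDX": -1.0, "MLX": 0.4}
        assert classify_category(flags, means, strict=True).category == 2
        assert classify_category(flags, means, strict=False).category == 4


class TestRunDe:
    def test_null_matrix_rejects_few(self, paper_design):
        expr, _ = generate_expression(paper_design, 2000, {}, seed=9)
        de = run_de(expr, paper_design)
        assert de["rejected"].sum() <= 5
        assert (de.loc[~de["rejected"], "category"] == 0).all()

    def test_planted_categories_recovered(self, planted_experiment, paper_design):
        expr, truth = planted_experiment
        de = run_de(expr, paper_design).merge(truth, on="transcript_id")
        for cat in (1, 2, 3, 4):
            sub = de[de["category_y"] == cat]
            assert (sub["category_x"] == cat).mean() >= 0.9

    def test_q_never_below_p(self, planted_experiment, paper_design):
        expr, _ = planted_experiment
        de = run_de(expr, paper_design)
        assert (de["q"] >= de["p"] - 1e-12).all()
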