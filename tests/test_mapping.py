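"""Single-marker model fits against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from agemap import ArchitectureSpec, StudyDesign, fit_model1, fit_model2, map_genome
from agemap.mapping import SCORE_CAP, scan_model1, scan_model2
from agemap.simulate import category_architectures, simulate_expression, simulate_genotypes


def _ttest_score(y, g):
    """Independent oracle: equal-variance two-sample t test."""
    res = stats.ttest_ind(y[g == 1], y[g == -1], equal_var=True)
    return -np.log10(res.pvalue)


class TestModel1:
    def test_matches_t_test_oracle_on_worked_example(self):
        y = np.array([1.0, 2, 1, 2, 5, 6, 5, 6])
        g = np.array([-1, -1, -1, -1, 1, 1, 1, 1])
        fit = fit_model1(y, g)
        assert fit.score == pytest.approx(_ttest_score(y, g), abs=1e-8)
        assert fit.effect == pytest.approx((y[4:].mean() - y[:4].mean()) / 2)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_t_test_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(8, 37)
        g = rng.choice([-1, 1], n)
        while len(np.unique(g)) < 2:
            g = rng.choice([-1, 1], n)
        y = rng.normal(0, 1, n) + 0.3 * g
        fit = fit_model1(y, g)
        assert fit.score == pytest.approx(_ttest_score(y, g), abs=1e-8)

    def test_constant_expression_scores_zero(self):
        g = np.array([-1, -1, 1, 1, -1, 1])
        fit = fit_model1(np.full(6, 2.5), g)
        assert fit.score == 0.0 and fit.effect == 0.0

    def test_perfect_separation_hits_score_cap(self):
        g = np.array([-1, -1, -1, 1, 1, 1])
        fit = fit_model1(np.where(g == 1, 2.0, 1.0), g)
        assert fit.score == SCORE_CAP

    def test_monomorphic_marker_untestable(self):
        fit = fit_model1(np.array([1.0, 2, 3, 4]), np.ones(4))
        assert not fit.testable and fit.score == 0.0

    def test_affine_invariance_and_allele_swap(self):
        rng = np.random.default_rng(5)
        g = rng.choice([-1, 1], 20)
        y = rng.normal(0, 1, 20) + 0.5 * g
        base = fit_model1(y, g)
        scaled = fit_model1(3.0 * y - 7.0, g)
        assert scaled.score == pytest.approx(base.score, abs=1e-8)
        assert scaled.effect == pytest.approx(3.0 * base.effect)
        swapped = fit_model1(y, -g)
        assert swapped.score == pytest.approx(base.score, abs=1e-8)
        assert swapped.effect == pytest.approx(-base.effect)

    def test_missing_values_dropped_pairwise(self):
        g = np.array([-1, -1, -1, 1, 1, 1, 1])
        y = np.array([1.0, 1.1, np.nan, 2.0, 2.1, 1.9, 2.0])
        fit = fit_model1(y, g)
        assert fit.n_used == 6
        ok = np.isfinite(y)
        assert fit.score == pytest.approx(_ttest_score(y[ok], g[ok]), abs=1e-8)


class TestModel2:
    def _design(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.choice([-1, 1], n)
        pa = np.concatenate([rng.uniform(0.08, 0.15, n // 2), rng.uniform(0.2, 0.35, n - n // 2)])
        return g, pa

    def test_pure_age_signal_caps_age_term_only(self):
        g, pa = self._design()
        res = fit_model2(3.0 * pa, g, pa)
        assert res["age"].score == SCORE_CAP
        assert res["marker"].effect == pytest.approx(0.0, abs=1e-8)
        assert res["marker_by_age"].effect == pytest.approx(0.0, abs=1e-8)

    def test_pure_interaction_signal_caps_interaction_term(self):
        g, pa = self._design(seed=1)
        res = fit_model2(g * pa, g, pa)
        assert res["marker_by_age"].score == SCORE_CAP

    def test_term_pvalues_match_statsmodels_oracle(self):
        import statsmodels.api as sm

        g, pa = self._design(seed=2)
        rng = np.random.default_rng(3)
        y = 0.2 * g + 1.5 * pa + rng.normal(0, 0.3, len(g))
        res = fit_model2(y, g, pa)
        X = sm.add_constant(np.column_stack([g, pa, g * pa]))
        fit = sm.OLS(y, X).fit()
        for k, term in ((1, "marker"), (2, "age"), (3, "marker_by_age")):
            assert res[term].score == pytest.approx(-np.log10(fit.pvalues[k]), abs=1e-8)
            assert res[term].effect == pytest.approx(fit.params[k], abs=1e-10)

    def test_constant_phys_age_degrades_to_model1(self):
        rng = np.random.default_rng(4)
        g = rng.choice([-1, 1], 24)
        y = rng.normal(0, 1, 24) + 0.4 * g
        res = fit_model2(y, g, np.full(24, 0.2))
        m1 = fit_model1(y, g)
        assert not res["age"].testable
        assert res["marker"].score == pytest.approx(m1.score, abs=1e-8)


class TestScans:
    def test_scan_model1_agrees_with_per_fit_loop(self):
        rng = np.random.default_rng(6)
        Y = rng.normal(0, 1, (5, 20))
        X = rng.choice([-1, 1], (20, 7))
        eff, sco = scan_model1(Y, X)
        for gi in range(5):
            for mi in range(7):
                fit = fit_model1(Y[gi], X[:, mi])
                assert sco[gi, mi] == pytest.approx(fit.score, abs=1e-8)
                assert eff[gi, mi] == pytest.approx(fit.effect, abs=1e-10)

    def test_scan_model1_nan_path_agrees(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(0, 1, (3, 15))
        Y[0, 3] = np.nan
        X = rng.choice([-1, 1], (15, 4))
        eff, sco = scan_model1(Y, X)
        fit = fit_model1(Y[0], X[:, 2])
        assert sco[0, 2] == pytest.approx(fit.score, abs=1e-8)

    def test_scan_model2_agrees_with_per_fit_loop(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(0, 1, (4, 30))
        X = rng.choice([-1, 1], (30, 5))
        pa = rng.uniform(0.1, 0.4, 30)
        eff, sco = scan_model2(Y, X, pa)
        from agemap.mapping import MODEL2_TERMS

        for gi in range(4):
            for mi in range(5):
                res = fit_model2(Y[gi], X[:, mi], pa)
                for k, term in enumerate(MODEL2_TERMS):
                    assert sco[gi, mi, k] == pytest.approx(res[term].score, abs=1e-8)


class TestMapGenome:
    def test_strong_locus_peaks_at_causal_or_neighbour(self, default_map):
        hits = 0
        for seed in range(10):
            design = StudyDesign(seed=100 + seed)
            panel = simulate_genotypes(design, default_map)
            rng = np.random.default_rng(seed)
            arch = category_architectures("A")(default_map, rng, name="a")
            study = simulate_expression(panel, design, [arch])
            tab = map_genome(study, panel, model=1, window="t1")
            causal = list(arch.additive)[0]
            ok = [causal] + default_map.adjacent(causal)
            if len(tab.calls) and tab.calls.iloc[0]["peak_marker"] in ok:
                hits += 1
        assert hits >= 9

    def test_parental_contrast_detects_category_a_gap(self, default_map):
        design = StudyDesign(seed=11)
        panel = simulate_genotypes(design, default_map)
        rng = np.random.default_rng(1)
        arch = category_architectures("A")(default_map, rng, name="a")
        study = simulate_expression(panel, design, [arch])
        tab = map_genome(study, panel, model=1, window="t1", population="parents")
        assert len(tab.calls) == 1
        assert tab.calls.iloc[0]["peak_marker"] == "parental_genotype"
        assert tab.calls.iloc[0]["score"] >= 2.0

    def test_window_model_compatibility_enforced(self, panel36, design36, default_map):
        study = simulate_expression(panel36, design36, [ArchitectureSpec(noise_sd=0.1)])
        with pytest.raises(ValueError, match="model 1"):
            map_genome(study, panel36, model=1, window="developing")
        with pytest.raises(ValueError, match="model 2"):
            map_genome(study, panel36, model=2, window="t1")

    def test_too_few_shared_strains_rejected(self, panel36, design36):
        study = simulate_expression(panel36, design36, [ArchitectureSpec(noise_sd=0.1)])
        tiny = study.subset(strains=["RIL001", "RIL002"])
        with pytest.raises(ValueError, match="RIL strains"):
            map_genome(tiny, panel36, model=1, window="t1")
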