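"""Candidate marker spacing and the stepwise BIC search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from agemap import (
    ArchitectureSpec,
    GeneticMap,
    select_candidate_markers,
    simulate_expression,
    stepwise_bic,
)
from agemap.multilocus import multilocus_table, polygenic_summary


def _one_chrom_map(positions, chrom="c1"):
    rows = [(f"{chrom}m{i:02d}", chrom, float(p)) for i, p in enumerate(positions, 1)]
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"]))


class TestCandidateSelection:
    def test_chromosome_with_exactly_four_markers_forced(self, small_map):
        cand = select_candidate_markers(small_map, per_chrom=4)
        assert len(cand.markers) == 8
        assert set(cand.markers) == set(small_map.markers)

    def test_default_map_yields_24_markers_and_all_pairs(self, default_map):
        cand = select_candidate_markers(default_map, per_chrom=4)
        assert len(cand.markers) == 24
        assert len(cand.pairs) == 24 * 23 // 2

    def test_max_min_spacing_matches_exhaustive_oracle(self):
        pos = np.linspace(0, 100, 21)
        gmap = _one_chrom_map(pos)
        cand = select_candidate_markers(gmap, per_chrom=4)
        markers = gmap.markers
        # oracle: brute-force max-min spacing over C(21, 4)
        def min_gap(comb):
            p = pos[list(comb)]
            return np.min(np.diff(p))
        best = max(min_gap(c) for c in itertools.combinations(range(21), 4))
        chosen_idx = [markers.index(m) for m in cand.markers]
        assert min_gap(sorted(chosen_idx)) == pytest.approx(best)
        # ties broken toward lower positions: the first marker is always in
        assert markers[0] in cand.markers

    def test_too_few_markers_per_chromosome_rejected(self):
        gmap = _one_chrom_map([0.0, 10.0])
        with pytest.raises(ValueError, match="per_chrom"):
            select_candidate_markers(gmap, per_chrom=4)


def _columns_from_panel(panel, candidates, strains, pa):
    from agemap.multilocus import _candidate_matrix

    return _candidate_matrix(panel, candidates, strains, pa)


@pytest.fixture(scope="module")
def stepwise_setup(panel36, design36):
    from agemap.multilocus import _candidate_matrix, select_candidate_markers

    cand = select_candidate_markers(panel36.gmap)
    rils = panel36.rils
    strains = rils * 2
    rng = np.random.default_rng(0)
    pa = np.concatenate([rng.uniform(0.08, 0.14, 36), rng.uniform(0.2, 0.35, 36)])
    cols = _candidate_matrix(panel36, cand, strains, pa)
    return cand, cols, pa


class TestStepwiseBic:
    def test_bic_formula_matches_hand_computation(self, stepwise_setup):
        cand, cols, pa = stepwise_setup
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 72)
        model = stepwise_bic(y, {"A": cols["A"]}, max_terms=1)
        X = np.column_stack([np.ones(72), cols["A"]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss_age = float(np.sum((y - X @ beta) ** 2))
        rss_null = float(np.sum((y - y.mean()) ** 2))
        expected = min(
            72 * np.log(rss_age / 72) + 3 * np.log(72),
            72 * np.log(rss_null / 72) + 1 * np.log(72),
        )
        assert model.bic == pytest.approx(expected, abs=1e-9)

    def test_single_strong_locus_recovered(self, stepwise_setup, panel36):
        cand, cols, pa = stepwise_setup
        rng = np.random.default_rng(2)
        target = f"M:{cand.markers[5]}"
        y = 1.0 * cols[target] + rng.normal(0, 0.2, 72)
        model = stepwise_bic(y, cols)
        assert target in model.selected_terms
        assert model.bic <= 72 * np.log(np.var(y)) + np.log(72)  # beats the null fit

    def test_pure_epistatic_pair_enters_interaction_first(self, stepwise_setup):
        cand, cols, pa = stepwise_setup
        rng = np.random.default_rng(3)
        a, b = cand.markers[0], cand.markers[12]  # different chromosomes
        pair = f"I:{a}*{b}"
        y = 1.0 * cols[pair] + rng.normal(0, 0.2, 72)
        model = stepwise_bic(y, cols)
        assert model.has_epistasis
        assert pair in model.selected_terms

    def test_limits_and_determinism(self, stepwise_setup):
        cand, cols, pa = stepwise_setup
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, 72)
        m1 = stepwise_bic(y, cols, max_terms=6, max_steps=2000)
        m2 = stepwise_bic(y, cols, max_terms=6, max_steps=2000)
        assert m1.selected_terms == m2.selected_terms
        assert len(m1.selected_terms) <= 6
        assert m1.n_steps_used <= 2000
        start_bic = 72 * np.log(np.sum((y - y.mean()) ** 2) / 72) + np.log(72)
        assert m1.bic <= start_bic + 1e-9

    def test_constant_expression_returns_null_model(self, stepwise_setup):
        cand, cols, pa = stepwise_setup
        model = stepwise_bic(np.full(72, 3.0), cols)
        assert model.selected_terms == []
        assert np.isfinite(model.bic)

    def test_max_steps_respected(self, stepwise_setup):
        cand, cols, pa = stepwise_setup
        rng = np.random.default_rng(5)
        y = rng.normal(0, 1, 72)
        model = stepwise_bic(y, cols, max_steps=1)
        assert model.n_steps_used <= 1
        assert len(model.selected_terms) <= 2  # start (age) plus at most one move


class TestStudyLevel:
    def test_multilocus_table_runs_and_reports_epistasis(self, panel36, design36):
        rng = np.random.default_rng(6)
        from agemap.simulate import category_architectures

        archs = [category_architectures("C")(panel36.gmap, rng, name=f"c{i}") for i in range(5)]
        study = simulate_expression(panel36, design36, archs)
        tab = multilocus_table(study, panel36, "developing")
        assert len(tab) == 5
        assert (tab["n_steps_used"] <= 2000).all()
        assert tab["bic"].notna().all()

    def test_polygenic_summary_bins(self):
        models = pd.DataFrame(
            {
                "gene": ["g1", "g2", "g3"],
                "window": "developing",
                "selected_terms": ["A;M:x", "A", "I:x*y"],
                "bic": [0.0, 0.0, 0.0],
                "n_markers": [1, 0, 2],
                "has_epistasis": [False, False, True],
                "n_steps_used": [2, 1, 3],
            }
        )
        h2 = pd.DataFrame({"gene": ["g1", "g2", "g3"], "h2": [0.95, 0.1, 0.92]})
        summary = polygenic_summary(models, h2, bin_edges=(0.0, 0.5, 1.0))
        top = summary[summary["h2_bin"].str.startswith("(0.5")].iloc[0]
        assert top["n_genes"] == 2
        assert top["pct_epistasis"] == pytest.approx(50.0)
        assert top["pct_exactly_one_marker"] == pytest.approx(50.0)
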