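"""Generator properties: segregation, map consistency, effect arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from agemap import (
    ArchitectureSpec,
    GeneticMap,
    StudyDesign,
    category_architectures,
    simulate_expression,
    simulate_genotypes,
)
from agemap.data import PARENTS
from agemap.simulate import haldane_recombination_fraction, ril_switch_probability


def _one_chrom_map(positions, chrom="c1"):
    rows = [(f"{chrom}m{i}", chrom, float(p)) for i, p in enumerate(positions, 1)]
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"]))


def test_zero_distance_chromosomes_have_no_recombinants():
    gmap = _one_chrom_map([5.0] * 8)
    panel = simulate_genotypes(StudyDesign(n_rils=200, seed=1), gmap)
    rils = panel.ril_alleles().to_numpy()
    assert (np.ptp(rils, axis=1) == 0).all()  # each RIL uniformly -1 or +1


def test_allele_frequency_converges_to_half():
    gmap = _one_chrom_map([0.0])
    panel = simulate_genotypes(StudyDesign(n_rils=2000, seed=2), gmap)
    n_plus = int((panel.ril_alleles().to_numpy() == 1).sum())
    lo, hi = stats.binom.ppf([0.005, 0.995], 2000, 0.5)
    assert lo <= n_plus <= hi


def test_switch_fraction_matches_selfed_ril_expansion():
    d = 10.0
    gmap = _one_chrom_map([0.0, d])
    panel = simulate_genotypes(StudyDesign(n_rils=2000, seed=3), gmap)
    rils = panel.ril_alleles().to_numpy()
    observed = float((rils[:, 0] != rils[:, 1]).mean())
    r = (1.0 - np.exp(-2 * d / 100)) / 2.0
    expected = 2 * r / (1 + 2 * r)
    se = np.sqrt(expected * (1 - expected) / 2000)
    assert abs(observed - expected) < 3 * se
    assert ril_switch_probability(d) == pytest.approx(expected)
    assert haldane_recombination_fraction(d) == pytest.approx(r)


@given(st.floats(min_value=0.0, max_value=1e4, allow_nan=False))
@settings(max_examples=50, deadline=None)
def test_switch_probability_is_a_probability_below_half(d):
    p = float(ril_switch_probability(d))
    assert 0.0 <= p < 0.5 or np.isclose(p, 0.5)


def test_seed_determinism(default_map):
    design = StudyDesign(seed=42)
    p1 = simulate_genotypes(design, default_map)
    p2 = simulate_genotypes(design, default_map)
    pd.testing.assert_frame_equal(p1.alleles, p2.alleles)
    arch = [ArchitectureSpec(additive={"Im01": 0.5}, noise_sd=0.1)]
    s1 = simulate_expression(p1, design, arch)
    s2 = simulate_expression(p2, design, arch)
    pd.testing.assert_frame_equal(s1.expr, s2.expr)


def test_parents_are_constant_rows_and_rils_inbred(panel36):
    assert (panel36.alleles.loc["N2"] == 1).all()
    assert (panel36.alleles.loc["CB4856"] == -1).all()
    assert np.isin(panel36.ril_alleles().to_numpy(), (-1, 1)).all()


def test_nonmonotone_map_positions_rejected():
    with pytest.raises(ValueError, match="nondecreasing"):
        _one_chrom_map([0.0, 10.0, 5.0])


def test_null_architecture_reproduces_noise_variance(panel36, design36):
    noise_sd = 0.3
    arch = [ArchitectureSpec(noise_sd=noise_sd, name=f"g{i}") for i in range(200)]
    study = simulate_expression(panel36, design36, arch)
    n = study.expr.shape[1]
    var = study.expr.var(axis=1, ddof=1).to_numpy()
    lo = noise_sd**2 * stats.chi2.ppf(0.0005, n - 1) / (n - 1)
    hi = noise_sd**2 * stats.chi2.ppf(0.9995, n - 1) / (n - 1)
    assert ((var > lo) & (var < hi)).mean() > 0.98
    assert study.expr.sub(6.0).abs().mean().mean() < 1.0  # centred at baseline


def test_additive_effect_gives_group_mean_gap_of_twice_effect(panel36, design36):
    a = 0.7
    arch = [ArchitectureSpec(additive={"IIm05": a}, noise_sd=1e-6)]
    study = simulate_expression(panel36, design36, arch)
    t1 = study.window("t1", strains=panel36.rils)
    y = t1.expr.to_numpy()[0]
    g = panel36.alleles.loc[t1.samples["strain"], "IIm05"].to_numpy()
    gap = y[g == 1].mean() - y[g == -1].mean()
    assert gap == pytest.approx(2 * a, abs=1e-4)


def test_pure_epistasis_has_null_marginal_effects(default_map):
    design = StudyDesign(n_rils=500, seed=9)
    panel = simulate_genotypes(design, default_map)
    arch = [ArchitectureSpec(epistatic={("Im01", "Xm01"): 1.0}, noise_sd=1e-6)]
    study = simulate_expression(panel, design, arch)
    t1 = study.window("t1", strains=panel.rils)
    y = t1.expr.to_numpy()[0]
    for marker in ("Im01", "Xm01"):
        g = panel.alleles.loc[t1.samples["strain"], marker].to_numpy()
        gap = y[g == 1].mean() - y[g == -1].mean()
        # marginal of g1*g2 given g1 is 0; Monte-Carlo error ~ 2/sqrt(n)
        assert abs(gap) < 6 / np.sqrt(500)


class TestCategoryFactories:
    def test_category_a_parent_gap_is_twice_total_effect(self, default_map):
        rng = np.random.default_rng(0)
        arch = category_architectures("A")(default_map, rng, effect=1.0)
        assert sum(arch.additive.values()) == 1.0
        assert arch.category == "A"

    def test_category_b_sums_to_one_log2_unit_parent_gap(self, default_map):
        rng = np.random.default_rng(0)
        arch = category_architectures("B")(default_map, rng)
        assert len(arch.additive) == 10
        assert sum(arch.additive.values()) == pytest.approx(0.5)  # parent gap 2*0.5 = 1.0
        assert max(arch.additive.values()) == pytest.approx(0.05)  # per-marker gap 0.1

    def test_category_c_parents_have_equal_expectations(self, default_map, design36):
        rng = np.random.default_rng(1)
        arch = category_architectures("C")(default_map, rng)
        panel = simulate_genotypes(design36, default_map)
        arch = ArchitectureSpec(
            epistatic=arch.epistatic, noise_sd=1e-7, baseline=arch.baseline
        )
        study = simulate_expression(panel, design36, [arch])
        t1 = study.window("t1")
        y = t1.expr.to_numpy()[0]
        strains = t1.samples["strain"].to_numpy()
        m_n2 = y[strains == "N2"].mean()
        m_cb = y[strains == "CB4856"].mean()
        assert m_n2 == pytest.approx(m_cb, abs=1e-5)

    def test_category_c_opposite_additive_parents_equal(self, default_map):
        rng = np.random.default_rng(2)
        arch = category_architectures("C")(default_map, rng, mode="additive_opposite")
        assert sum(arch.additive.values()) == pytest.approx(0.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="category"):
            category_architectures("D")


def test_physiological_age_in_study_uses_strain_lifespan(panel36, design36):
    arch = [ArchitectureSpec(noise_sd=0.1)]
    study = simulate_expression(panel36, design36, arch)
    n2_t1 = study.samples.loc["N2_t1_r1"]
    assert n2_t1["phys_age"] == pytest.approx(40 / (16 * 24))
    cb_t3 = study.samples.loc["CB4856_t3_r1"]
    assert cb_t3["phys_age"] == pytest.approx(214 / (13 * 24))
    for parent in PARENTS:
        cols = study.samples["strain"] == parent
        assert cols.sum() == 3 * design36.parent_replicates_per_age


def test_architecture_referencing_unknown_marker_rejected(panel36, design36):
    with pytest.raises(ValueError, match="unknown markers"):
        simulate_expression(
            panel36, design36, [ArchitectureSpec(additive={"nope": 1.0})]
        )
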