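"""Physiological age and the two outlier screens."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from agemap import (
    ArchitectureSpec,
    StudyDesign,
    compute_physiological_age,
    mask_sd_outliers,
    recursive_regression_outliers,
    simulate_expression,
)
from agemap.preprocess import apply_parent_outlier_masks


class TestPhysiologicalAge:
    @pytest.mark.parametrize(
        "age,lifespan,expected",
        [
            (384.0, 384.0, 1.0),
            (40.0, 16 * 24.0, 0.10417),  # young sample of the longer-lived parent
            (214.0, 13 * 24.0, 0.68590),  # old sample of the shorter-lived parent
        ],
    )
    def test_ratio(self, age, lifespan, expected):
        assert compute_physiological_age(age, lifespan) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("age,lifespan", [(40.0, 0.0), (40.0, -1.0), (0.0, 100.0)])
    def test_nonpositive_inputs_rejected(self, age, lifespan):
        with pytest.raises(ValueError):
            compute_physiological_age(age, lifespan)

    @given(
        age=st.floats(1.0, 500.0),
        lifespan=st.floats(300.0, 800.0),
        d_age=st.floats(1.0, 100.0),
        d_life=st.floats(1.0, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_age_antitone_in_lifespan(self, age, lifespan, d_age, d_life):
        base = compute_physiological_age(age, lifespan)
        assert compute_physiological_age(age + d_age, lifespan) > base
        assert compute_physiological_age(age, lifespan + d_life) < base


class TestSdOutlierScreen:
    def test_constant_values_never_masked(self):
        assert mask_sd_outliers(np.ones(6)).all()

    def test_gross_value_masked_by_direct_arithmetic(self):
        # mean = 1.667, SD ~ 4.08, |10 - 1.667| ~ 8.33 > 2*SD ~ 8.16
        values = np.array([0.0, 0, 0, 0, 0, 10.0])
        keep = mask_sd_outliers(values, k=2.0)
        assert list(keep) == [True] * 5 + [False]

    def test_two_values_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 3"):
            keep = mask_sd_outliers(np.array([-5.0, 5.0]))
        assert keep.all()


def _two_age_data(n_per=6, sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    groups = np.array(["t1"] * n_per + ["t2"] * n_per)
    values = np.where(groups == "t1", 1.0, 3.0) + rng.normal(0, sd, 2 * n_per)
    return values, groups


class TestRecursiveRegressionScreen:
    def test_perfect_fit_removes_nothing(self):
        values = np.array([1.0, 1, 1, 3, 3, 3])
        groups = np.array(["t1"] * 3 + ["t2"] * 3)
        keep, removed = recursive_regression_outliers(values, groups)
        assert keep.all() and removed == []

    def test_single_gross_outlier_removed_first(self):
        values, groups = _two_age_data(seed=1)
        values[2] += 20 * 0.1  # +20 SD
        keep, removed = recursive_regression_outliers(values, groups)
        assert removed[0] == 2
        # oracle: its externally studentized residual exceeds the 0.995 cutoff
        idx = np.arange(len(values))
        X = np.column_stack([np.ones(len(values)), (groups == "t2").astype(float)])
        mask = idx != 2
        beta, *_ = np.linalg.lstsq(X[mask], values[mask], rcond=None)
        resid = values[2] - X[2] @ beta
        s2 = np.sum((values[mask] - X[mask] @ beta) ** 2) / (mask.sum() - 2)
        h = X[2] @ np.linalg.inv(X[mask].T @ X[mask]) @ X[2]
        t_ext = resid / np.sqrt(s2 * (1 + h))
        cutoff = stats.t.ppf(1 - 0.0025, len(values) - 2 - 1)
        assert abs(t_ext) > cutoff

    def test_removal_capped_at_six(self):
        # ten graded gross outliers (graded so the extremes are never masked
        # by each other): the recursion must stop at the cap of six
        values, groups = _two_age_data(n_per=12, seed=2)
        mags = np.array([400, 300, 220, 160, 120, 90, 65, 50, 38, 28], float)
        idx = np.array([0, 2, 4, 6, 8, 12, 14, 16, 18, 20])
        values[idx] += mags * np.where(np.arange(10) % 2 == 0, 1, -1)
        keep, removed = recursive_regression_outliers(values, groups, max_removed=6)
        assert len(removed) == 6
        assert (~keep).sum() == 6
        assert set(removed) <= set(idx)

    def test_idempotent_on_cleaned_data(self):
        values, groups = _two_age_data(seed=3)
        values[0] += 5.0
        keep, _ = recursive_regression_outliers(values, groups)
        cleaned = np.where(keep, values, np.nan)
        keep2, removed2 = recursive_regression_outliers(cleaned, groups)
        assert removed2 == []

    def test_too_few_values_warns_and_keeps(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            keep, removed = recursive_regression_outliers(
                np.array([1.0, 2.0, 3.0]), np.array(["t1", "t1", "t2"])
            )
        assert keep.all() and removed == []

    def test_null_removal_rate_stays_near_nominal(self):
        # on Gaussian data at conf 0.995 about 1% of values go on average
        rng = np.random.default_rng(4)
        removed_frac = []
        for _ in range(300):
            values = rng.normal(0, 1, 12)
            groups = np.array(["t1"] * 6 + ["t2"] * 6)
            _, removed = recursive_regression_outliers(values, groups)
            removed_frac.append(len(removed) / 12)
        assert np.mean(removed_frac) <= 0.01


def test_parent_mask_pipeline_only_touches_parents(panel36, design36):
    study = simulate_expression(
        panel36, design36, [ArchitectureSpec(noise_sd=0.1, name=f"g{i}") for i in range(5)]
    )
    # inject one gross parental outlier and one gross RIL value
    study.expr.loc["g0", "N2_t2_r3"] += 50.0
    study.expr.loc["g0", "RIL001_t1_r1"] += 50.0
    masked = apply_parent_outlier_masks(study)
    assert not masked.mask.loc["g0", "N2_t2_r3"]
    assert masked.mask.loc["g0", "RIL001_t1_r1"]  # RILs untouched
    ril_cols = masked.samples.index[~masked.samples["strain"].isin(["N2", "CB4856"])]
    assert masked.mask[ril_cols].all().all()
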