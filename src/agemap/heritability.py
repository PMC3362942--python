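"""Broad-sense heritability of transcript abundance.

For one age group, H² = (V_RIL − V_P) / V_RIL, where V_RIL is the sample
variance of expression across the RILs (one value per line, so it mixes
genetic and environmental variance) and V_P is the pooled within-line
variance of the two parents' replicates (environmental variance only, the
parents being isogenic). H² ≤ 1 by construction and may be negative by
sampling noise; negative values are kept in the tables and only excluded
from threshold-crossing counts.

For a two-age window the quantity of interest is the genotype effect on the
expression *pattern* over time, with the genotype × age interaction
excluded: V_RIL is the variance across RILs of each line's two-age mean
(the age main effect drops out of a between-line variance, and a crossing
interaction cancels within the mean), and V_P is the parental environmental
variance on the same scale — the pooled age-centered replicate variance
divided by two, i.e. the within-line variance of a mean of two ages. With
genetic variance σg² and environmental variance σe² per sample, the
estimator's expectation is approximately σg² / (σg² + σe²/2).

High-heritability cutoffs come from permutations: expression values are
reassigned to strains at random within each age group, the full H² vector is
recomputed per permutation, and the cutoff is the smallest observed H² at
which (mean permuted count ≥ t) / (observed count ≥ t) ≤ the target FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    ExpressionStudy,
    PARENTS,
    SINGLE_AGE_WINDOWS,
    TWO_AGE_WINDOWS,
    parent_replicate_matrix,
    ril_value_matrix,
    window_age_groups,
)

__all__ = [
    "H2Row",
    "heritability_single_age",
    "heritability_over_time",
    "heritability_table",
    "high_h2_cutoff",
]


@dataclass(frozen=True)
class H2Row:
    v_ril: float
    v_p: float
    h2: float  # NaN when V_RIL = 0 (undefined)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.h2)


def _pooled_within_variance(groups: Sequence[np.ndarray]) -> float:
    """Degrees-of-freedom-weighted pool of within-group variances."""
    num = 0.0
    den = 0
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[np.isfinite(g)]
        if len(g) >= 2:
            num += (len(g) - 1) * g.var(ddof=1)
            den += len(g) - 1
    if den == 0:
        raise ValueError("pooled variance needs >=2 replicates in some group")
    return num / den


def _h2_from_variances(v_ril: float, v_p: float) -> H2Row:
    if v_ril <= 0:
        return H2Row(v_ril=float(v_ril), v_p=float(v_p), h2=np.nan)
    return H2Row(v_ril=float(v_ril), v_p=float(v_p), h2=float((v_ril - v_p) / v_ril))


def heritability_single_age(
    ril_values: np.ndarray, parent_values: Mapping[str, np.ndarray]
) -> H2Row:
    """H² at one age: one expression value per RIL, replicates per parent."""
    rv = np.asarray(ril_values, dtype=float)
    rv = rv[np.isfinite(rv)]
    if len(rv) < 3:
        raise ValueError("need >=3 RIL values")
    for p, vals in parent_values.items():
        if np.sum(np.isfinite(np.asarray(vals, dtype=float))) < 2:
            raise ValueError(f"parent {p} needs >=2 replicates")
    v_ril = rv.var(ddof=1)
    v_p = _pooled_within_variance(list(parent_values.values()))
    return _h2_from_variances(v_ril, v_p)


def heritability_over_time(
    ril_values: np.ndarray, parent_values: Mapping[str, np.ndarray]
) -> H2Row:
    """H² of the expression pattern over a two-age window.

    ``ril_values``: RILs × 2 ages; ``parent_values``: per parent a
    replicates × 2 ages array. V_RIL is the variance of per-RIL two-age
    means; V_P is the parents' age-centered pooled replicate variance / 2
    (the environmental variance of a two-age mean).
    """
    rv = np.asarray(ril_values, dtype=float)
    if rv.ndim != 2 or rv.shape[1] != 2:
        raise ValueError("ril_values must be RILs x 2 ages")
    means = rv.mean(axis=1)
    means = means[np.isfinite(means)]
    if len(means) < 3:
        raise ValueError("need >=3 RILs with both ages observed")
    v_ril = means.var(ddof=1)
    # age-centered residuals have within-age df; pooling uses df = n-1 per age
    num = 0.0
    den = 0
    for p, vals in parent_values.items():
        v = np.asarray(vals, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError(f"parent {p} values must be replicates x 2 ages")
        for a in range(2):
            col = v[:, a]
            col = col[np.isfinite(col)]
            if len(col) >= 2:
                num += (len(col) - 1) * col.var(ddof=1)
                den += len(col) - 1
    if den == 0:
        raise ValueError("parents need >=2 replicates at both ages")
    v_p = (num / den) / 2.0
    return _h2_from_variances(v_ril, v_p)


# ----------------------------------------------------------------------
# vectorized study-level table
# ----------------------------------------------------------------------

def _single_age_vectors(
    study: ExpressionStudy, age_group: str
) -> tuple[np.ndarray, np.ndarray]:
    """(v_ril, v_p) per gene at one age, vectorized."""
    rils = [s for s in study.samples["strain"].unique() if s not in PARENTS]
    R = ril_value_matrix(study, rils, age_group)  # genes × rils
    v_ril = np.nanvar(R, axis=1, ddof=1)
    num = np.zeros(R.shape[0])
    den = np.zeros(R.shape[0])
    for parent in PARENTS:
        P = parent_replicate_matrix(study, parent, age_group)
        n = np.isfinite(P).sum(axis=1)
        with np.errstate(invalid="ignore"):
            var = np.nanvar(P, axis=1, ddof=1)
        good = n >= 2
        num[good] += (n[good] - 1) * var[good]
        den[good] += n[good] - 1
    v_p = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return v_ril, v_p


def _over_time_vectors(
    study: ExpressionStudy, window: str
) -> tuple[np.ndarray, np.ndarray]:
    a1, a2 = window_age_groups(window)
    rils = [s for s in study.samples["strain"].unique() if s not in PARENTS]
    R1 = ril_value_matrix(study, rils, a1)
    R2 = ril_value_matrix(study, rils, a2)
    means = (R1 + R2) / 2.0
    v_ril = np.nanvar(means, axis=1, ddof=1)
    num = np.zeros(R1.shape[0])
    den = np.zeros(R1.shape[0])
    for parent in PARENTS:
        for a in (a1, a2):
            P = parent_replicate_matrix(study, parent, a)
            n = np.isfinite(P).sum(axis=1)
            with np.errstate(invalid="ignore"):
                var = np.nanvar(P, axis=1, ddof=1)
            good = n >= 2
            num[good] += (n[good] - 1) * var[good]
            den[good] += n[good] - 1
    v_p = np.where(den > 0, num / np.maximum(den, 1), np.nan) / 2.0
    return v_ril, v_p


def _h2_vector(study: ExpressionStudy, window: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if window in SINGLE_AGE_WINDOWS:
        v_ril, v_p = _single_age_vectors(study, window)
    elif window in TWO_AGE_WINDOWS:
        v_ril, v_p = _over_time_vectors(study, window)
    else:
        raise ValueError(f"unknown window {window!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        h2 = np.where(v_ril > 0, (v_ril - v_p) / np.where(v_ril > 0, v_ril, 1.0), np.nan)
    return v_ril, v_p, h2


def heritability_table(
    study: ExpressionStudy, window: str, cutoff: float | None = None
) -> pd.DataFrame:
    """Per-gene H² table for a window; ``high_h2`` flags h2 > cutoff (if any)."""
    v_ril, v_p, h2 = _h2_vector(study, window)
    tab = pd.DataFrame(
        {
            "gene": study.genes,
            "window": window,
            "v_ril": v_ril,
            "v_p": v_p,
            "h2": h2,
        }
    )
    tab["high_h2"] = (h2 > cutoff) if cutoff is not None else False
    return tab


def high_h2_cutoff(
    study: ExpressionStudy,
    window: str,
    fdr: float = 0.01,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Permutation cutoff: smallest observed H² held at ≤ ``fdr`` false calls.

    Per permutation the sample → strain assignment is shuffled within each
    age group (so age structure survives, genotype association does not) and
    the H² vector is recomputed; counts are averaged over permutations.
    Returns (cutoff, diagnostics table); the cutoff is NaN when no observed
    H² attains the FDR. Negative H² never enters the candidate set.
    """
    _, _, obs = _h2_vector(study, window)
    obs_finite = obs[np.isfinite(obs)]
    candidates = np.unique(obs_finite[obs_finite > 0])
    if len(candidates) == 0:
        return np.nan, pd.DataFrame()
    rng = np.random.default_rng(seed)
    meta = study.samples
    perm_sorted = []
    for _ in range(n_perm):
        shuffled = study.copy()
        strain_col = shuffled.samples["strain"].to_numpy().copy()
        for grp in meta["age_group"].unique():
            idx = np.flatnonzero((meta["age_group"] == grp).to_numpy())
            strain_col[idx] = strain_col[idx[rng.permutation(len(idx))]]
        shuffled.samples["strain"] = strain_col
        _, _, h2p = _h2_vector(shuffled, window)
        perm_sorted.append(np.sort(h2p[np.isfinite(h2p)]))
    obs_sorted = np.sort(obs_finite)
    n_obs_ge = len(obs_sorted) - np.searchsorted(obs_sorted, candidates, side="left")
    perm_ge = np.zeros(len(candidates))
    for ps in perm_sorted:
        perm_ge += len(ps) - np.searchsorted(ps, candidates, side="left")
    perm_ge /= n_perm
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_obs_ge > 0, perm_ge / np.maximum(n_obs_ge, 1), np.inf)
    ratio = np.minimum(ratio, np.where(n_obs_ge > 0, 1.0, np.inf))  # FDR clipped to 1
    diag = pd.DataFrame(
        {
            "candidate": candidates,
            "n_observed": n_obs_ge,
            "mean_false": perm_ge,
            "fdr": ratio,
        }
    )
    ok = np.flatnonzero(ratio <= fdr)
    cutoff = float(candidates[ok[0]]) if len(ok) else np.nan
    return cutoff, diag
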