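"""Transgressive segregation of expression.

A transcript segregates transgressively when RILs express it outside the
range spanned by both parents — the signature of multiple loci with
opposing or interacting effects recombined into new combinations.

Per gene and age, the upper bound is mean + 2·SD of the *higher-mean*
parent's replicates and the lower bound is mean − 2·SD of the *lower-mean*
parent's (each parent contributes its own replicate SD; parents may swap
rank between ages). RILs strictly outside a bound are counted; a gene is
called transgressive when at least ``k_min`` (default 6) RILs fall beyond
one bound. For a two-age window a RIL counts only if it is beyond the
age-specific bound, in the same direction, at *both* ages.

The count threshold is calibrated by permutation: RIL/parent strain labels
are shuffled across samples within each age group and the significant-gene
count recomputed; the FDR is the mean permuted count over the observed one
(100 permutations by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

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
from .thresholds import FdrEstimate

__all__ = [
    "TransgressionResult",
    "transgression_single_age",
    "transgression_over_time",
    "transgression_table",
    "transgression_fdr",
]

DEFAULT_K_MIN = 6
DEFAULT_SD_MULT = 2.0


@dataclass(frozen=True)
class TransgressionResult:
    n_high: int
    n_low: int
    direction: str  # high / low / both / none
    significant: bool


def _direction(n_high: int, n_low: int, k_min: int) -> tuple[str, bool]:
    hi, lo = n_high >= k_min, n_low >= k_min
    if hi and lo:
        return "both", True
    if hi:
        return "high", True
    if lo:
        return "low", True
    return "none", False


def _bounds(parent_values: Mapping[str, np.ndarray], sd_mult: float) -> tuple[float, float]:
    """(upper, lower) transgression bounds from the two parents' replicates."""
    stats = {}
    for p, vals in parent_values.items():
        v = np.asarray(vals, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise ValueError(f"parent {p} needs >=2 replicates for an SD")
        stats[p] = (v.mean(), v.std(ddof=1))
    means = {p: m for p, (m, _) in stats.items()}
    hi_p = max(means, key=means.get)
    lo_p = min(means, key=means.get)
    upper = stats[hi_p][0] + sd_mult * stats[hi_p][1]
    lower = stats[lo_p][0] - sd_mult * stats[lo_p][1]
    return upper, lower


def transgression_single_age(
    ril_values: np.ndarray,
    parent_values: Mapping[str, np.ndarray],
    k_min: int = DEFAULT_K_MIN,
    sd_mult: float = DEFAULT_SD_MULT,
) -> TransgressionResult:
    """Count RILs strictly beyond the parental 2·SD bounds at one age."""
    upper, lower = _bounds(parent_values, sd_mult)
    rv = np.asarray(ril_values, dtype=float)
    n_high = int(np.sum(rv > upper))
    n_low = int(np.sum(rv < lower))
    direction, significant = _direction(n_high, n_low, k_min)
    return TransgressionResult(n_high, n_low, direction, significant)


def transgression_over_time(
    ril_values: np.ndarray,
    parent_values: Mapping[str, np.ndarray],
    k_min: int = DEFAULT_K_MIN,
    sd_mult: float = DEFAULT_SD_MULT,
) -> TransgressionResult:
    """Two-age transgression: beyond the bound in the same direction at both ages.

    ``ril_values``: RILs × 2; ``parent_values``: per parent replicates × 2.
    """
    rv = np.asarray(ril_values, dtype=float)
    if rv.ndim != 2 or rv.shape[1] != 2:
        raise ValueError("ril_values must be RILs x 2 ages")
    hi = np.ones(rv.shape[0], dtype=bool)
    lo = np.ones(rv.shape[0], dtype=bool)
    for a in range(2):
        pv = {p: np.asarray(v, dtype=float)[:, a] for p, v in parent_values.items()}
        upper, lower = _bounds(pv, sd_mult)
        hi &= rv[:, a] > upper
        lo &= rv[:, a] < lower
    n_high, n_low = int(hi.sum()), int(lo.sum())
    direction, significant = _direction(n_high, n_low, k_min)
    return TransgressionResult(n_high, n_low, direction, significant)


# ----------------------------------------------------------------------
# study-level (vectorized) interface
# ----------------------------------------------------------------------

def _study_counts(
    study: ExpressionStudy, window: str, sd_mult: float
) -> tuple[np.ndarray, np.ndarray]:
    """(n_high, n_low) per gene for a window, vectorized over genes."""
    rils = [s for s in study.samples["strain"].unique() if s not in PARENTS]
    ages = window_age_groups(window)
    hi = None
    lo = None
    for a in ages:
        R = ril_value_matrix(study, rils, a)  # genes × rils
        uppers = np.full(R.shape[0], np.nan)
        lowers = np.full(R.shape[0], np.nan)
        pstats = {}
        for p in PARENTS:
            P = parent_replicate_matrix(study, p, a)
            if (np.isfinite(P).sum(axis=1) < 2).any():
                bad = int((np.isfinite(P).sum(axis=1) < 2).sum())
                if bad == P.shape[0]:
                    raise ValueError(f"parent {p} lacks replicates at {a}")
            pstats[p] = (np.nanmean(P, axis=1), np.nanstd(P, axis=1, ddof=1))
        mean_a = np.vstack([pstats[p][0] for p in PARENTS])
        sd_a = np.vstack([pstats[p][1] for p in PARENTS])
        hi_idx = np.argmax(mean_a, axis=0)
        lo_idx = np.argmin(mean_a, axis=0)
        cols = np.arange(mean_a.shape[1])
        uppers = mean_a[hi_idx, cols] + sd_mult * sd_a[hi_idx, cols]
        lowers = mean_a[lo_idx, cols] - sd_mult * sd_a[lo_idx, cols]
        hi_a = R > uppers[:, None]
        lo_a = R < lowers[:, None]
        hi = hi_a if hi is None else (hi & hi_a)
        lo = lo_a if lo is None else (lo & lo_a)
    return hi.sum(axis=1), lo.sum(axis=1)


def transgression_table(
    study: ExpressionStudy,
    window: str,
    k_min: int = DEFAULT_K_MIN,
    sd_mult: float = DEFAULT_SD_MULT,
) -> pd.DataFrame:
    """Per-gene transgression counts/calls for a window."""
    n_high, n_low = _study_counts(study, window, sd_mult)
    rows = []
    for gene, nh, nl in zip(study.genes, n_high, n_low):
        direction, significant = _direction(int(nh), int(nl), k_min)
        rows.append((gene, window, int(nh), int(nl), direction, significant))
    return pd.DataFrame(
        rows, columns=["gene", "window", "n_high", "n_low", "direction", "significant"]
    )


def transgression_fdr(
    study: ExpressionStudy,
    window: str,
    k_min: int = DEFAULT_K_MIN,
    sd_mult: float = DEFAULT_SD_MULT,
    n_perm: int = 100,
    seed: int = 0,
) -> FdrEstimate:
    """Permutation FDR of the k_min-RIL transgression call for a window.

    Strain labels are shuffled within each age group per permutation. The
    FDR is NaN when no gene is called on the observed data.
    """
    n_high, n_low = _study_counts(study, window, sd_mult)
    obs = int(np.sum((n_high >= k_min) | (n_low >= k_min)))
    rng = np.random.default_rng(seed)
    meta = study.samples
    counts = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = study.copy()
        strain_col = shuffled.samples["strain"].to_numpy().copy()
        for grp in meta["age_group"].unique():
            idx = np.flatnonzero((meta["age_group"] == grp).to_numpy())
            strain_col[idx] = strain_col[idx[rng.permutation(len(idx))]]
        shuffled.samples["strain"] = strain_col
        nh, nl = _study_counts(shuffled, window, sd_mult)
        counts[i] = np.sum((nh >= k_min) | (nl >= k_min))
    mean_false = float(counts.mean())
    if obs == 0:
        fdr = np.nan if mean_false == 0 else 1.0
    else:
        fdr = min(mean_false / obs, 1.0)
    return FdrEstimate(
        threshold=float(k_min),
        n_observed=obs,
        mean_false=mean_false,
        fdr=fdr,
        n_perm=n_perm,
        perm_counts=counts,
        term="transgression",
        window=window,
    )
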