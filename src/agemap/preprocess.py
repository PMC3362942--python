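"""Physiological age and outlier removal.

Strains age at different absolute rates (the parental mean lifespans differ
by ~3 days), so samples taken at a fixed chronological age are at different
points of their lifespan. All two-age models therefore use *physiological
age*: chronological age at mRNA extraction divided by the strain's mean
lifespan.

Two outlier screens are provided, mirroring common practice for replicated
expression arrays:

* a single-pass per-gene, per-age-group screen that masks values further
  than ``k`` standard deviations from the group mean (default k = 2);
* a recursive regression screen for one genotype over a two-age window:
  expression is regressed on the age-group factor, the single most extreme
  externally studentized residual outside the two-sided 0.995 interval is
  removed, and the fit is repeated — at most six removals.

For the middle age group, which belongs to both two-age windows, a value is
treated as an outlier if either window's recursive screen removed it (union
of masks). Masked values are missing downstream; they are never imputed.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import ExpressionStudy, PARENTS, window_age_groups

__all__ = [
    "compute_physiological_age",
    "assign_physiological_age",
    "mask_sd_outliers",
    "recursive_regression_outliers",
    "apply_parent_outlier_masks",
]


def compute_physiological_age(age_hours: float, lifespan_hours: float) -> float:
    """Dimensionless age: chronological age / mean lifespan of the strain."""
    if lifespan_hours <= 0:
        raise ValueError("lifespan must be positive")
    if age_hours <= 0:
        raise ValueError("age must be positive")
    return age_hours / lifespan_hours


def assign_physiological_age(
    study: ExpressionStudy, lifespans: Mapping[str, float]
) -> ExpressionStudy:
    """Return a copy of ``study`` with the ``phys_age`` column filled in."""
    missing = set(study.samples["strain"]) - set(lifespans)
    if missing:
        raise ValueError(f"no lifespan for strains {sorted(missing)}")
    bad = [s for s, v in lifespans.items() if v <= 0]
    if bad:
        raise ValueError(f"nonpositive lifespan for {sorted(bad)}")
    out = study.copy()
    out.samples["phys_age"] = out.samples["age_hours"] / out.samples["strain"].map(
        dict(lifespans)
    )
    out.lifespans = dict(lifespans)
    return out


def mask_sd_outliers(values: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Boolean keep-mask over a replicate vector: False outside mean ± k·SD.

    Single pass: the mean and (n−1)-denominator SD come from all non-missing
    values. Needs at least 3 values; with fewer the vector is returned
    unmasked with a warning.
    """
    values = np.asarray(values, dtype=float)
    keep = np.ones(values.shape, dtype=bool)
    finite = np.isfinite(values)
    if finite.sum() < 3:
        warnings.warn("fewer than 3 values; SD outlier screen skipped", stacklevel=2)
        return keep
    v = values[finite]
    mean, sd = v.mean(), v.std(ddof=1)
    keep[finite] = np.abs(v - mean) <= k * sd
    return keep


def _studentized_threshold(conf: float, n: int, n_params: int) -> float:
    """Two-sided cutoff for an externally studentized residual."""
    df = n - n_params - 1
    if df < 1:
        return np.inf
    return stats.t.ppf(1.0 - (1.0 - conf) / 2.0, df)


def recursive_regression_outliers(
    values: np.ndarray,
    age_groups: Sequence[str],
    conf: float = 0.995,
    max_removed: int = 6,
) -> tuple[np.ndarray, list[int]]:
    """Recursive outlier deletion for one gene of one genotype, two ages.

    Fits expression on the age-group factor (two-level regression), removes
    the single most extreme value whose externally studentized residual falls
    outside the two-sided ``conf`` interval, refits, and repeats; at most
    ``max_removed`` values go. Returns (keep mask, removal order as indices
    into ``values``).
    """
    values = np.asarray(values, dtype=float)
    age_groups = np.asarray(age_groups)
    if values.shape != age_groups.shape:
        raise ValueError("values and age_groups must align")
    keep = np.isfinite(values)
    removed: list[int] = []
    if keep.sum() < 4:
        warnings.warn("fewer than 4 values; recursive outlier screen skipped", stacklevel=2)
        return keep, removed

    levels = np.unique(age_groups[keep])
    while len(removed) < max_removed:
        idx = np.flatnonzero(keep)
        y = values[idx]
        if len(idx) < 4 or len(np.unique(age_groups[idx])) < 2:
            break
        X = sm.add_constant((age_groups[idx] == levels[-1]).astype(float))
        fit = sm.OLS(y, X).fit()
        if fit.df_resid <= 1 or fit.ssr <= 0:
            break  # perfect fit: nothing to studentize
        resid = fit.get_influence().resid_studentized_external
        resid = np.nan_to_num(resid, nan=0.0, posinf=np.inf, neginf=-np.inf)
        cutoff = _studentized_threshold(conf, len(idx), X.shape[1])
        worst = int(np.argmax(np.abs(resid)))
        if np.abs(resid[worst]) <= cutoff:
            break
        keep[idx[worst]] = False
        removed.append(int(idx[worst]))
    return keep, removed


def apply_parent_outlier_masks(
    study: ExpressionStudy,
    conf: float = 0.995,
    max_removed: int = 6,
    sd_mult: float | None = 2.0,
    strains: Sequence[str] | None = None,
) -> ExpressionStudy:
    """Apply both outlier screens to the replicated (parental) samples.

    Per gene and per parent: first the per-age-group ``sd_mult``·SD screen
    (skipped when ``sd_mult`` is None), then the recursive regression screen
    on each two-age window. The middle age group is masked when either
    window's recursive screen removed it. Other strains are untouched.
    """
    strains = list(strains) if strains is not None else list(PARENTS)
    out = study.copy()
    vals = out.values()
    meta = out.samples
    windows = [("developing",), ("aging",)] if "t3" in set(meta["age_group"]) else [("developing",)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for strain in strains:
            scols = meta.index[meta["strain"] == strain]
            if len(scols) == 0:
                continue
            groups = meta.loc[scols, "age_group"]
            if sd_mult is not None:
                for grp in groups.unique():
                    cols = scols[(groups == grp).to_numpy()]
                    block = vals[cols].to_numpy(dtype=float)
                    for gi in range(block.shape[0]):
                        keep = mask_sd_outliers(block[gi], k=sd_mult)
                        out.mask.loc[out.mask.index[gi], cols[~keep]] = False
            vals2 = out.values()
            for (window,) in windows:
                wanted = window_age_groups(window)
                cols = scols[groups.isin(wanted).to_numpy()]
                if len(cols) == 0:
                    continue
                grp_vec = meta.loc[cols, "age_group"].to_numpy()
                block = vals2[cols].to_numpy(dtype=float)
                for gi in range(block.shape[0]):
                    keep, _ = recursive_regression_outliers(
                        block[gi], grp_vec, conf=conf, max_removed=max_removed
                    )
                    out.mask.loc[out.mask.index[gi], cols[~keep]] = False
    return out
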