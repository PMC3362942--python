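"""Single-marker eQTL models.

Two linear models are fitted per gene and marker on log2 expression:

* model 1 (one age group):   ``expression = marker + error``
* model 2 (two age groups):  ``expression = marker + physiological age +
  marker × physiological age + error``

Markers are the ±1-coded RIL genotypes; for the parental strains the same
code path runs with a single pseudo-marker equal to strain identity (+1 N2,
−1 CB4856), which turns model 1 into a differential-expression test and
model 2 into an age-resolved one. Scores are −log10 two-sided p-values of
the relevant t statistic, capped at :data:`SCORE_CAP` so tables stay finite
when p underflows. Genes with no variance score 0 by convention, and a
monomorphic marker yields an untestable record instead of NaN propagation.

Peak calling follows the "genes with an eQTL" convention: per gene × term ×
window, one call at the maximum-score marker when that score reaches the
threshold (default −log10 p = 3 for RIL eQTL, 2 for parental contrasts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    ExpressionStudy,
    GenotypePanel,
    PARENTS,
    SINGLE_AGE_WINDOWS,
    TWO_AGE_WINDOWS,
    window_age_groups,
)

__all__ = [
    "SCORE_CAP",
    "MODEL2_TERMS",
    "fit_model1",
    "fit_model2",
    "scan_model1",
    "scan_model2",
    "map_genome",
    "MappingTables",
]

SCORE_CAP = 300.0
MODEL2_TERMS = ("marker", "age", "marker_by_age")
PARENT_PSEUDOMARKER = "parental_genotype"

_P_FLOOR = 10.0 ** (-SCORE_CAP)


def _score(p: np.ndarray | float) -> np.ndarray | float:
    """−log10 p, floored/capped to [0, SCORE_CAP]."""
    return np.minimum(-np.log10(np.maximum(p, _P_FLOOR)), SCORE_CAP)


@dataclass(frozen=True)
class FitResult:
    """One gene × marker × term fit."""

    effect: float
    score: float
    n_used: int
    testable: bool = True


def fit_model1(y: np.ndarray, genotype: np.ndarray) -> FitResult:
    """OLS of one gene's expression on a single ±1 marker (one age group).

    Equivalent to the equal-variance two-group t test; the effect is the
    slope on the ±1 coding (half the group-mean difference). Missing values
    are dropped pairwise. A monomorphic marker or <3 usable strains gives an
    untestable record (score 0, effect NaN); constant expression scores 0
    with effect 0 by convention.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(genotype, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g)
    y, g = y[ok], g[ok]
    n = len(y)
    if n < 3 or len(np.unique(g)) < 2:
        return FitResult(np.nan, 0.0, n, testable=False)
    if np.ptp(y) == 0.0:
        return FitResult(0.0, 0.0, n)
    gc = g - g.mean()
    yc = y - y.mean()
    sxx = gc @ gc
    slope = (gc @ yc) / sxx
    rss = yc @ yc - slope**2 * sxx
    df = n - 2
    if rss <= max(1e-12 * (yc @ yc), 0.0):
        return FitResult(float(slope), SCORE_CAP, n)
    se = np.sqrt(rss / df / sxx)
    t = slope / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return FitResult(float(slope), float(_score(p)), n)


def fit_model2(
    y: np.ndarray, genotype: np.ndarray, phys_age: np.ndarray
) -> dict[str, FitResult]:
    """OLS of one gene on marker, physiological age and their product.

    Returns one :class:`FitResult` per term. A rank-deficient design (e.g.
    constant physiological age, monomorphic marker) leaves the affected
    terms untestable; with constant ``phys_age`` the marker term equals the
    model-1 fit on the pooled samples.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(genotype, dtype=float)
    pa = np.asarray(phys_age, dtype=float)
    ok = np.isfinite(y) & np.isfinite(g) & np.isfinite(pa)
    y, g, pa = y[ok], g[ok], pa[ok]
    n = len(y)
    out = {t: FitResult(np.nan, 0.0, n, testable=False) for t in MODEL2_TERMS}
    if n < 5 or len(np.unique(g)) < 2:
        return out
    X = np.column_stack([np.ones(n), g, pa, g * pa])
    # drop collinear columns (keep intercept + marker at minimum)
    rank = np.linalg.matrix_rank(X)
    if rank < 4:
        if len(np.unique(pa)) < 2:
            m1 = fit_model1(y, g)
            out["marker"] = m1
        return out
    if np.ptp(y) == 0.0:
        zero = FitResult(0.0, 0.0, n)
        return {t: zero for t in MODEL2_TERMS}
    beta, rss_arr, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - 4
    xtx_inv = np.linalg.inv(X.T @ X)
    tss = float(np.sum((y - y.mean()) ** 2))
    for k, term in ((1, "marker"), (2, "age"), (3, "marker_by_age")):
        if rss <= 1e-12 * max(tss, 1.0):
            score = SCORE_CAP if abs(beta[k]) > 1e-8 * max(1.0, abs(y).max()) else 0.0
            out[term] = FitResult(float(beta[k]), float(score), n)
            continue
        se = np.sqrt(rss / df * xtx_inv[k, k])
        p = 2.0 * stats.t.sf(abs(beta[k] / se), df)
        out[term] = FitResult(float(beta[k]), float(_score(p)), n)
    return out


# ----------------------------------------------------------------------
# vectorized genome scans
# ----------------------------------------------------------------------

def scan_model1(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Model-1 scan: all genes × all markers at once.

    Y: genes × strains expression (may contain NaN → per-gene fallback);
    X: strains × markers ±1. Returns (effects, scores), each genes × markers.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    G, S = Y.shape
    M = X.shape[1]
    if np.isnan(Y).any():
        eff = np.empty((G, M))
        sco = np.empty((G, M))
        for gi in range(G):
            for mi in range(M):
                r = fit_model1(Y[gi], X[:, mi])
                eff[gi, mi], sco[gi, mi] = r.effect, r.score
        return eff, sco

    Xc = X - X.mean(axis=0, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = np.einsum("sm,sm->m", Xc, Xc)
    syy = np.einsum("gs,gs->g", Yc, Yc)
    num = Yc @ Xc  # G × M
    mono = sxx <= 0
    sxx_safe = np.where(mono, 1.0, sxx)
    effects = num / sxx_safe
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = num**2 / (sxx_safe * np.where(syy <= 0, 1.0, syy)[:, None])
        r2 = np.clip(r2, 0.0, 1.0)
        df = S - 2
        t2 = r2 * df / np.maximum(1.0 - r2, 1e-300)
        p = 2.0 * stats.t.sf(np.sqrt(t2), df)
    scores = np.asarray(_score(p))
    scores[r2 >= 1.0 - 1e-12] = SCORE_CAP
    scores[syy <= 0, :] = 0.0
    effects[syy <= 0, :] = 0.0
    scores[:, mono] = 0.0
    effects[:, mono] = np.nan
    return effects, scores


def scan_model2(
    Y: np.ndarray, X: np.ndarray, phys_age: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Model-2 scan over all genes × markers.

    Y: genes × samples; X: samples × markers; phys_age: per sample.
    Returns (effects, scores) with shape genes × markers × 3, term order
    :data:`MODEL2_TERMS`.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    pa = np.asarray(phys_age, dtype=float)
    G, S = Y.shape
    M = X.shape[1]
    effects = np.full((G, M, 3), np.nan)
    scores = np.zeros((G, M, 3))
    has_nan = np.isnan(Y).any()
    df = S - 4
    syy = np.einsum("gs,gs->g", Y - Y.mean(axis=1, keepdims=True), Y - Y.mean(axis=1, keepdims=True))
    for mi in range(M):
        g = X[:, mi]
        if has_nan:
            for gi in range(G):
                res = fit_model2(Y[gi], g, pa)
                for k, term in enumerate(MODEL2_TERMS):
                    effects[gi, mi, k] = res[term].effect
                    scores[gi, mi, k] = res[term].score
            continue
        D = np.column_stack([np.ones(S), g, pa, g * pa])
        if np.linalg.matrix_rank(D) < 4 or df < 1:
            for gi in range(G):
                res = fit_model2(Y[gi], g, pa)
                for k, term in enumerate(MODEL2_TERMS):
                    effects[gi, mi, k] = res[term].effect
                    scores[gi, mi, k] = res[term].score
            continue
        dtd_inv = np.linalg.inv(D.T @ D)
        B = dtd_inv @ D.T @ Y.T  # 4 × G
        resid = Y.T - D @ B
        rss = np.einsum("sg,sg->g", resid, resid)
        zero_rss = rss <= 1e-12 * np.maximum(syy, 1.0)
        sigma2 = np.where(zero_rss, 1.0, rss) / df
        for k, term_k in ((1, 0), (2, 1), (3, 2)):
            se = np.sqrt(sigma2 * dtd_inv[k, k])
            with np.errstate(invalid="ignore", divide="ignore"):
                t = B[k] / se
                p = 2.0 * stats.t.sf(np.abs(t), df)
            sc = np.asarray(_score(p))
            sc[zero_rss] = np.where(np.abs(B[k][zero_rss]) > 1e-8, SCORE_CAP, 0.0)
            const = syy <= 0
            sc[const] = 0.0
            effects[:, mi, term_k] = np.where(const, 0.0, B[k])
            scores[:, mi, term_k] = sc
    return effects, scores


# ----------------------------------------------------------------------
# genome-wide mapping
# ----------------------------------------------------------------------

@dataclass
class MappingTables:
    """Scan output: per-gene peak table, thresholded calls, raw score arrays."""

    peaks: pd.DataFrame  # gene, term, peak_marker, effect, score, n_used, window
    calls: pd.DataFrame  # peaks passing the threshold (+ threshold_used, age_window)
    scores: np.ndarray  # genes × markers (model 1) or genes × markers × 3 (model 2)
    effects: np.ndarray
    genes: list[str]
    markers: list[str]
    model: int
    window: str

    def peak_scores(self, term: str = "marker") -> pd.Series:
        sub = self.peaks[self.peaks["term"] == term]
        return sub.set_index("gene")["score"]


def _design_arrays(
    study: ExpressionStudy, panel: GenotypePanel, window: str, population: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, list[str], list[str]]:
    if population == "rils":
        strains = [s for s in panel.rils if s in set(study.samples["strain"])]
        if not strains:
            raise ValueError("study and panel share no RIL strains")
        if len(strains) < 3:
            raise ValueError(
                f"only {len(strains)} RIL strains shared; single-marker models "
                "need at least 3 with both alleles represented"
            )
        sub = study.window(window, strains=strains)
        X = panel.alleles.loc[sub.samples["strain"]].to_numpy(dtype=float)
        markers = panel.gmap.markers
    elif population == "parents":
        sub = study.window(window, strains=list(PARENTS))
        if len(sub.samples) == 0:
            raise ValueError("no parental samples in study")
        X = np.where(sub.samples["strain"].to_numpy() == PARENTS[0], 1.0, -1.0)[:, None]
        markers = [PARENT_PSEUDOMARKER]
    else:
        raise ValueError(f"unknown population {population!r}")
    Y = sub.values().to_numpy(dtype=float)
    pa = None
    if window in TWO_AGE_WINDOWS:
        if not sub.has_phys_age():
            raise ValueError("two-age window mapping needs physiological age")
        pa = sub.samples["phys_age"].to_numpy(dtype=float)
    return Y, X, pa, list(sub.expr.index), markers


def map_genome(
    study: ExpressionStudy,
    panel: GenotypePanel,
    model: int,
    window: str,
    population: str = "rils",
    threshold: float | None = None,
) -> MappingTables:
    """Fit model 1 or 2 at every marker for every gene and call peaks.

    ``window`` must be a single age group for model 1 and ``developing`` /
    ``aging`` for model 2. ``population`` selects the RIL scan (markers =
    genotypes) or the parental contrast (single strain-identity
    pseudo-marker). Default thresholds: −log10 p = 3 for RILs, 2 for parents.
    """
    if model == 1 and window not in SINGLE_AGE_WINDOWS:
        raise ValueError("model 1 maps one age group at a time")
    if model == 2 and window not in TWO_AGE_WINDOWS:
        raise ValueError("model 2 needs a two-age window (developing/aging)")
    if threshold is None:
        threshold = 2.0 if population == "parents" else 3.0

    Y, X, pa, genes, markers = _design_arrays(study, panel, window, population)
    n_used = np.isfinite(Y).sum(axis=1)

    rows = []
    if model == 1:
        effects, scores = scan_model1(Y, X)
        peak_idx = np.argmax(scores, axis=1)
        for gi, gene in enumerate(genes):
            mi = peak_idx[gi]
            rows.append(
                (gene, "marker", markers[mi], effects[gi, mi], scores[gi, mi], int(n_used[gi]))
            )
    else:
        effects, scores = scan_model2(Y, X, pa)
        for k, term in enumerate(MODEL2_TERMS):
            peak_idx = np.argmax(scores[:, :, k], axis=1)
            for gi, gene in enumerate(genes):
                mi = peak_idx[gi]
                rows.append(
                    (gene, term, markers[mi], effects[gi, mi, k], scores[gi, mi, k], int(n_used[gi]))
                )
    peaks = pd.DataFrame(
        rows, columns=["gene", "term", "peak_marker", "effect", "score", "n_used"]
    )
    peaks["window"] = window
    calls = peaks[peaks["score"] >= threshold].copy()
    calls["threshold_used"] = threshold
    calls["age_window"] = window
    return MappingTables(
        peaks=peaks,
        calls=calls.reset_index(drop=True),
        scores=scores,
        effects=effects,
        genes=genes,
        markers=markers,
        model=model,
        window=window,
    )
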