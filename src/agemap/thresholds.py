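"""Permutation nulls, genome-wide FDR and the joint-FDR.

The FDR at a score threshold is the permutation plug-in estimator

    FDR(t) = E_perm[ #genes with permuted peak ≥ t ] / #genes with observed peak ≥ t.

Permutations relabel whole sample columns (the sample → strain assignment,
and for model 2 additionally the sample → age assignment, drawn
independently), so every gene's value multiset and the gene × gene
covariance structure are untouched — only the genotype/age labelling is
broken.

The joint-FDR asks how many genes pass *both* the parental
differential-expression threshold and the RIL eQTL threshold by chance:
parental and RIL permutations are drawn independently (30 pairs by default)
and the plug-in ratio is formed from genes passing both permuted thresholds.
A product-rule approximation (product of marginal permuted pass rates ×
universe size) is reported alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionStudy, GenotypePanel
from .mapping import MODEL2_TERMS, map_genome

__all__ = [
    "PermutationNull",
    "FdrEstimate",
    "permute_labels",
    "permutation_null",
    "estimate_fdr",
    "joint_fdr",
    "JointFdrEstimate",
]

#: paper-matched default permutation counts
DEFAULT_N_PERM_MODEL2 = 100
DEFAULT_N_PERM_JOINT = 30


@dataclass
class PermutationNull:
    """Per-permutation, per-gene peak scores for one model term."""

    term: str
    window: str
    n_perm: int
    peak_scores: np.ndarray  # n_perm × genes
    genes: list[str]
    seed: int | None = None
    scheme: str = "model1"

    def counts_at(self, threshold: float) -> np.ndarray:
        return (self.peak_scores >= threshold).sum(axis=1)


@dataclass
class FdrEstimate:
    """Plug-in FDR at a threshold: mean permuted calls / observed calls."""

    threshold: float
    n_observed: int
    mean_false: float
    fdr: float  # NaN when both counts are zero; clipped to [0, 1]
    n_perm: int
    perm_counts: np.ndarray = field(default_factory=lambda: np.array([]))
    term: str = ""
    window: str = ""

    def monte_carlo_se(self) -> float:
        """SE of the estimate, counting both permutation and observed-draw noise.

        Under the null the observed count is one more draw from the permuted
        count distribution, so its variance is estimated from the permuted
        spread as well.
        """
        if self.n_observed == 0 or len(self.perm_counts) < 2:
            return np.nan
        var_perm_mean = self.perm_counts.var(ddof=1) / self.n_perm
        var_obs = self.perm_counts.var(ddof=1)
        return float(np.sqrt(var_perm_mean + var_obs * self.fdr**2) / self.n_observed)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def permute_labels(
    study: ExpressionStudy,
    scheme: str = "model1",
    seed: int | np.random.Generator | None = None,
    permutation: np.ndarray | None = None,
) -> ExpressionStudy:
    """Randomly reassign sample → strain labels (and ages for model 2).

    Whole sample columns are relabelled, never values within a gene, so the
    among-gene structure is intact. Relabelling is design-preserving: strain
    labels are shuffled among the samples of each age group (every labelled
    strain keeps its per-age sample count), and for model 2 the age labels
    are additionally shuffled among each relabelled strain's samples, drawn
    independently. ``permutation`` injects an explicit global strain
    permutation (e.g. the identity) for testing.
    """
    if scheme not in {"model1", "model2"}:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    rng = _rng(seed)
    out = study.copy()
    n = len(out.samples)
    strain = out.samples["strain"].to_numpy().copy()
    if permutation is not None:
        strain = strain[np.asarray(permutation)]
    else:
        age_grp = out.samples["age_group"].to_numpy()
        for grp in pd.unique(age_grp):
            idx = np.flatnonzero(age_grp == grp)
            strain[idx] = strain[idx[rng.permutation(len(idx))]]
    out.samples["strain"] = strain
    if scheme == "model2":
        ages = out.samples["age_hours"].to_numpy().copy()
        groups = out.samples["age_group"].to_numpy().copy()
        for s in pd.unique(strain):
            idx = np.flatnonzero(strain == s)
            p = rng.permutation(len(idx))
            ages[idx] = ages[idx[p]]
            groups[idx] = groups[idx[p]]
        out.samples["age_hours"] = ages
        out.samples["age_group"] = groups
    if out.lifespans is not None:
        out.samples["phys_age"] = out.samples["age_hours"] / out.samples["strain"].map(
            out.lifespans
        )
    return out


def permutation_null(
    study: ExpressionStudy,
    panel: GenotypePanel,
    model: int,
    window: str,
    term: str = "marker",
    population: str = "rils",
    n_perm: int = DEFAULT_N_PERM_MODEL2,
    seed: int = 0,
) -> PermutationNull:
    """Build a :class:`PermutationNull` of per-gene peak scores."""
    if model == 2 and term not in MODEL2_TERMS:
        raise ValueError(f"model 2 term must be one of {MODEL2_TERMS}")
    scheme = "model1" if model == 1 else "model2"
    rng = np.random.default_rng(seed)
    peaks = []
    genes: list[str] | None = None
    for _ in range(n_perm):
        perm_study = permute_labels(study, scheme=scheme, seed=rng)
        tab = map_genome(perm_study, panel, model=model, window=window, population=population)
        ps = tab.peak_scores("marker" if model == 1 else term)
        genes = genes or list(ps.index)
        peaks.append(ps.to_numpy())
    return PermutationNull(
        term=term if model == 2 else "marker",
        window=window,
        n_perm=n_perm,
        peak_scores=np.vstack(peaks),
        genes=genes or [],
        seed=seed,
        scheme=scheme,
    )


def estimate_fdr(
    observed_peaks: pd.Series | np.ndarray,
    null: PermutationNull,
    threshold: float,
    term: str | None = None,
    window: str | None = None,
) -> FdrEstimate:
    """Plug-in FDR at ``threshold`` from observed peaks and a permutation null.

    Conventions: FDR = 1 when nothing is observed but permutations call
    genes; NaN when both sides are empty; values above 1 are clipped.
    """
    if term is not None and term != null.term:
        raise ValueError(f"null built for term {null.term!r}, not {term!r}")
    if window is not None and window != null.window:
        raise ValueError(f"null built for window {null.window!r}, not {window!r}")
    obs = np.asarray(observed_peaks, dtype=float)
    n_obs = int((obs >= threshold).sum())
    perm_counts = null.counts_at(threshold)
    mean_false = float(perm_counts.mean())
    if n_obs == 0:
        fdr = np.nan if mean_false == 0 else 1.0
    else:
        fdr = min(mean_false / n_obs, 1.0)
    return FdrEstimate(
        threshold=threshold,
        n_observed=n_obs,
        mean_false=mean_false,
        fdr=fdr,
        n_perm=null.n_perm,
        perm_counts=perm_counts,
        term=null.term,
        window=null.window,
    )


@dataclass
class JointFdrEstimate:
    """Joint-FDR for genes passing both the parental and the eQTL threshold."""

    thresholds: tuple[float, float]
    n_observed: int
    mean_false: float
    fdr: float
    product_rule: float  # G · q_parent · q_ril under independence
    n_perm: int
    perm_counts: np.ndarray


def joint_fdr(
    parent_peaks: pd.Series,
    ril_peaks: pd.Series,
    parent_null: PermutationNull,
    ril_null: PermutationNull,
    thresholds: tuple[float, float] = (2.0, 3.0),
    n_perm: int | None = None,
) -> JointFdrEstimate:
    """Permutation joint-FDR for the parental × eQTL overlap.

    ``thresholds`` is (parent threshold, RIL threshold). The two nulls must
    cover the same gene universe; permutation pairs are matched by index
    (they were drawn independently).
    """
    genes = list(parent_peaks.index)
    if set(genes) != set(ril_peaks.index):
        raise ValueError("parent and RIL peaks cover different gene universes")
    if set(parent_null.genes) != set(genes) or set(ril_null.genes) != set(genes):
        raise ValueError("permutation nulls cover a different gene universe")
    thr_p, thr_r = thresholds
    obs_both = int(
        ((parent_peaks >= thr_p) & (ril_peaks.reindex(genes) >= thr_r)).sum()
    )
    avail = min(parent_null.n_perm, ril_null.n_perm)
    n_perm = avail if n_perm is None else min(n_perm, avail)
    p_order = [parent_null.genes.index(g) for g in genes]
    r_order = [ril_null.genes.index(g) for g in genes]
    p_pass = parent_null.peak_scores[:n_perm][:, p_order] >= thr_p
    r_pass = ril_null.peak_scores[:n_perm][:, r_order] >= thr_r
    perm_counts = (p_pass & r_pass).sum(axis=1)
    mean_false = float(perm_counts.mean())
    if obs_both == 0:
        fdr = np.nan if mean_false == 0 else 1.0
    else:
        fdr = min(mean_false / obs_both, 1.0)
    G = len(genes)
    q_p = p_pass.mean()
    q_r = r_pass.mean()
    product = float(G * q_p * q_r)
    return JointFdrEstimate(
        thresholds=(thr_p, thr_r),
        n_observed=obs_both,
        mean_false=mean_false,
        fdr=fdr,
        product_rule=product,
        n_perm=n_perm,
        perm_counts=perm_counts,
    )
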