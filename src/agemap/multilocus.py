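"""Multi-marker modelling: stepwise BIC with epistasis.

Single-marker scans miss genes regulated by several loci or by loci that
only act jointly. This module searches, per gene and two-age window, over a
reduced candidate set: 24 markers (4 per chromosome, chosen to maximize the
minimum pairwise genetic distance), all unordered marker-pair products
(epistasis), physiological age, and marker × age products. Pair and
marker × age terms are admissible without their main effects — a pure
epistatic architecture must be able to enter interaction-first.

Search: start from the age-only model; each step takes the single move —
adding the candidate with the largest BIC decrease, or removing the
selected term whose removal most decreases BIC — that lowers BIC the most,
stopping when no move lowers it, when 2000 steps are spent, or when the
model would exceed six explanatory variables and no removal helps. BIC is
the Gaussian form n·ln(RSS/n) + k·ln(n) with k counting all coefficients
including the intercept. Ties prefer removal over addition, then the
earlier candidate in the fixed ordering (age, markers in map order, pairs,
marker × age), so selection is fully deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ExpressionStudy, GeneticMap, GenotypePanel, PARENTS, TWO_AGE_WINDOWS

__all__ = [
    "CandidateTermSet",
    "MultiLocusModel",
    "select_candidate_markers",
    "stepwise_bic",
    "multilocus_table",
    "polygenic_summary",
]

AGE_TERM = "A"


@dataclass(frozen=True)
class CandidateTermSet:
    """Reduced term universe for the stepwise search."""

    markers: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]

    @property
    def term_codes(self) -> list[str]:
        """Fixed candidate ordering: age, marker mains, pairs, marker × age."""
        out = [AGE_TERM]
        out += [f"M:{m}" for m in self.markers]
        out += [f"I:{a}*{b}" for a, b in self.pairs]
        out += [f"AxM:{m}" for m in self.markers]
        return out


def select_candidate_markers(gmap: GeneticMap, per_chrom: int = 4) -> CandidateTermSet:
    """Pick ``per_chrom`` markers per chromosome by maximal min-distance spacing.

    Exhaustive over combinations per chromosome (deterministic; ties broken
    toward lower positions, then lexical marker id, by scanning combinations
    in lexicographic order and keeping the first optimum).
    """
    chosen: list[str] = []
    for chrom in gmap.chromosomes:
        tab = gmap.chromosome_table(chrom).sort_values(
            ["position_cm", "marker"], kind="stable"
        )
        markers = tab["marker"].tolist()
        pos = tab["position_cm"].to_numpy()
        if len(markers) < per_chrom:
            raise ValueError(
                f"chromosome {chrom} has {len(markers)} markers < per_chrom={per_chrom}"
            )
        if len(markers) == per_chrom:
            chosen += markers
            continue
        best = None
        best_idx = None
        for comb in itertools.combinations(range(len(markers)), per_chrom):
            p = pos[list(comb)]
            score = np.min(np.diff(p)) if per_chrom > 1 else np.inf
            if best is None or score > best:
                best, best_idx = score, comb
        chosen += [markers[i] for i in best_idx]
    pairs = tuple(itertools.combinations(chosen, 2))
    return CandidateTermSet(markers=tuple(chosen), pairs=pairs)


@dataclass
class MultiLocusModel:
    """BIC-selected model for one gene in one window."""

    gene: str
    window: str
    selected_terms: list[str]
    bic: float
    n_markers: int
    has_epistasis: bool
    n_steps_used: int

    @staticmethod
    def term_markers(term: str) -> set[str]:
        if term == AGE_TERM:
            return set()
        kind, rest = term.split(":", 1)
        if kind == "I":
            return set(rest.split("*"))
        return {rest}

    @classmethod
    def summarize(cls, gene, window, terms, bic, steps) -> "MultiLocusModel":
        markers: set[str] = set()
        for t in terms:
            markers |= cls.term_markers(t)
        return cls(
            gene=gene,
            window=window,
            selected_terms=list(terms),
            bic=float(bic),
            n_markers=len(markers),
            has_epistasis=any(t.startswith("I:") for t in terms),
            n_steps_used=steps,
        )


_RSS_FLOOR = 1e-10  # keeps BIC finite on exact fits


def _bic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, _RSS_FLOOR) / n) + k * np.log(n)


def _fit_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def stepwise_bic(
    y: np.ndarray,
    candidate_columns: dict[str, np.ndarray],
    max_terms: int = 6,
    max_steps: int = 2000,
    gene: str = "",
    window: str = "",
    start_terms: Sequence[str] = (AGE_TERM,),
) -> MultiLocusModel:
    """Forward/backward BIC selection over the candidate columns.

    ``candidate_columns`` maps term code → regressor column (ordered dict,
    order = tie-break priority). Starts from ``start_terms`` (age-only by
    default; terms absent from the candidates are ignored). Deterministic:
    no randomness is used anywhere in the search.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    order = list(candidate_columns)
    cols = {t: np.asarray(c, dtype=float) for t, c in candidate_columns.items()}
    if n < max_terms + 2:
        raise ValueError("too few samples for the requested model size")
    if np.ptp(y) == 0.0:
        return MultiLocusModel.summarize(gene, window, [], _bic(0.0, n, 1), 0)

    terms = [t for t in start_terms if t in cols]

    def design(tlist: list[str]) -> np.ndarray:
        return np.column_stack([np.ones(n)] + [cols[t] for t in tlist])

    cur_bic = _bic(_fit_rss(design(terms), y), n, len(terms) + 1)
    steps = 0
    while steps < max_steps:
        steps += 1
        X = design(terms)
        # forward: residualize all absent candidates against the current design
        best_add: tuple[float, str] | None = None
        if len(terms) < max_terms:
            absent = [t for t in order if t not in terms]
            if absent:
                C = np.column_stack([cols[t] for t in absent])
                beta_y, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
                ry = y - X @ beta_y
                beta_c, _, _, _ = np.linalg.lstsq(X, C, rcond=None)
                rc = C - X @ beta_c
                rss_cur = float(ry @ ry)
                cc = np.einsum("ij,ij->j", rc, rc)
                proj = ry @ rc
                with np.errstate(divide="ignore", invalid="ignore"):
                    drop = np.where(cc > 1e-12, proj**2 / np.maximum(cc, 1e-300), 0.0)
                rss_new = np.maximum(rss_cur - drop, 0.0)
                bics = np.array(
                    [_bic(r, n, len(terms) + 2) for r in rss_new]
                )
                j = int(np.argmin(bics))
                best_add = (float(bics[j]), absent[j])
        # backward: refit without each selected term
        best_rm: tuple[float, str] | None = None
        for t in terms:
            rest = [u for u in terms if u != t]
            b = _bic(_fit_rss(design(rest), y), n, len(rest) + 1)
            if best_rm is None or b < best_rm[0] or (
                b == best_rm[0] and order.index(t) < order.index(best_rm[1])
            ):
                best_rm = (b, t)
        # pick the better move; removal wins ties
        move = None
        if best_rm is not None and best_rm[0] < cur_bic:
            move = ("rm", best_rm)
        if best_add is not None and best_add[0] < cur_bic:
            if move is None or best_add[0] < move[1][0]:
                move = ("add", best_add)
        if move is None:
            break
        kind, (b, t) = move
        if kind == "add":
            terms.append(t)
            # exact refit (the projected RSS is a fast screen, not the record)
            cur_bic = _bic(_fit_rss(design(terms), y), n, len(terms) + 1)
        else:
            terms.remove(t)
            cur_bic = b
    terms_sorted = sorted(terms, key=order.index)
    return MultiLocusModel.summarize(gene, window, terms_sorted, cur_bic, steps)


def _candidate_matrix(
    panel: GenotypePanel,
    candidates: CandidateTermSet,
    strain_per_sample: Sequence[str],
    phys_age: np.ndarray,
) -> dict[str, np.ndarray]:
    G = panel.alleles.loc[list(strain_per_sample), list(candidates.markers)].to_numpy(
        dtype=float
    )
    pos = {m: i for i, m in enumerate(candidates.markers)}
    out: dict[str, np.ndarray] = {AGE_TERM: np.asarray(phys_age, dtype=float)}
    for m in candidates.markers:
        out[f"M:{m}"] = G[:, pos[m]]
    for a, b in candidates.pairs:
        out[f"I:{a}*{b}"] = G[:, pos[a]] * G[:, pos[b]]
    for m in candidates.markers:
        out[f"AxM:{m}"] = G[:, pos[m]] * out[AGE_TERM]
    return out


def multilocus_table(
    study: ExpressionStudy,
    panel: GenotypePanel,
    window: str,
    per_chrom: int = 4,
    max_terms: int = 6,
    max_steps: int = 2000,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Stepwise models for every gene of a two-age window (RIL samples only)."""
    if window not in TWO_AGE_WINDOWS:
        raise ValueError("multilocus modelling runs on developing/aging windows")
    candidates = select_candidate_markers(panel.gmap, per_chrom=per_chrom)
    rils = [s for s in panel.rils if s in set(study.samples["strain"])]
    sub = study.window(window, strains=rils)
    if genes is not None:
        sub = sub.subset(genes=genes)
    if not sub.has_phys_age():
        raise ValueError("multilocus modelling needs physiological age")
    strain_per_sample = sub.samples["strain"].tolist()
    pa = sub.samples["phys_age"].to_numpy(dtype=float)
    cols = _candidate_matrix(panel, candidates, strain_per_sample, pa)
    Y = sub.values().to_numpy(dtype=float)
    rows = []
    for gi, gene in enumerate(sub.expr.index):
        y = Y[gi]
        ok = np.isfinite(y)
        if ok.all():
            model = stepwise_bic(
                y, cols, max_terms=max_terms, max_steps=max_steps, gene=gene, window=window
            )
        else:
            sub_cols = {t: c[ok] for t, c in cols.items()}
            model = stepwise_bic(
                y[ok], sub_cols, max_terms=max_terms, max_steps=max_steps,
                gene=gene, window=window,
            )
        rows.append(
            (
                gene,
                window,
                ";".join(model.selected_terms),
                model.bic,
                model.n_markers,
                model.has_epistasis,
                model.n_steps_used,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "window", "selected_terms", "bic", "n_markers",
            "has_epistasis", "n_steps_used",
        ],
    )


def polygenic_summary(
    models: pd.DataFrame,
    h2: pd.DataFrame,
    bin_edges: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0),
) -> pd.DataFrame:
    """Per-heritability-bin percentages of single/multi-marker/epistatic models.

    The machine-readable analogue of the "% of eQTL by heritability class"
    figure: per h2 bin and window, % of genes with ≥1 selected marker term,
    with exactly one distinct marker, with ≥2, and with an epistatic term.
    Empty bins are reported with NaN percentages, not dropped.
    """
    merged = models.merge(h2[["gene", "h2"]], on="gene", how="inner")
    merged["bin"] = pd.cut(merged["h2"], bins=list(bin_edges), include_lowest=True)
    rows = []
    for (window, h2_bin), grp in merged.groupby(
        ["window", "bin"], observed=False, dropna=False
    ):
        n = len(grp)
        if n == 0:
            rows.append((window, str(h2_bin), 0, np.nan, np.nan, np.nan, np.nan))
            continue
        any_marker = (grp["n_markers"] >= 1).mean() * 100
        exactly_one = (grp["n_markers"] == 1).mean() * 100
        two_plus = (grp["n_markers"] >= 2).mean() * 100
        epi = grp["has_epistasis"].mean() * 100
        rows.append((window, str(h2_bin), n, any_marker, exactly_one, two_plus, epi))
    return pd.DataFrame(
        rows,
        columns=[
            "window", "h2_bin", "n_genes", "pct_any_marker",
            "pct_exactly_one_marker", "pct_two_plus_markers", "pct_epistasis",
        ],
    )
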