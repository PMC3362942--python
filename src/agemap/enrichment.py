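"""Hypergeometric over-representation test for gene sets.

Generic GO-style enrichment: given an annotation table (term → gene set), a
gene universe and a query set, each term is scored by the upper-tail
hypergeometric probability of observing at least the actual overlap when
drawing |query| genes from the universe. Terms with fewer than two genes
(after intersecting with the universe) are discarded up front. No
multiple-testing correction is applied by default (flag at α = 0.01), with
an optional Bonferroni switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

__all__ = ["AnnotationTable", "hypergeom_enrich"]

MIN_TERM_SIZE = 2


@dataclass
class AnnotationTable:
    """term_id → set of annotated genes (+ optional term names)."""

    terms: dict[str, set[str]]
    names: dict[str, str]

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        names: Mapping[str, str] | None = None,
        min_size: int = MIN_TERM_SIZE,
    ) -> "AnnotationTable":
        """Build from (gene, term_id) pairs, dropping terms below ``min_size``."""
        terms: dict[str, set[str]] = {}
        for gene, term in pairs:
            terms.setdefault(str(term), set()).add(str(gene))
        terms = {t: g for t, g in terms.items() if len(g) >= min_size}
        return cls(terms=terms, names=dict(names or {}))

    @classmethod
    def from_table(cls, df: pd.DataFrame, gene_col: str = "gene", term_col: str = "term_id",
                   name_col: str | None = None) -> "AnnotationTable":
        names = None
        if name_col is not None and name_col in df.columns:
            names = dict(zip(df[term_col], df[name_col]))
        return cls.from_pairs(zip(df[gene_col], df[term_col]), names=names)


def hypergeom_enrich(
    gene_set: Iterable[str],
    annotation: AnnotationTable,
    universe: Iterable[str],
    alpha: float = 0.01,
    correct: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per term.

    For a universe of N genes, a term with K genes in the universe and a
    query of n genes overlapping k of them, p = P(X ≥ k), X ~
    Hypergeom(N, K, n). ``correct=True`` applies Bonferroni over the tested
    terms before flagging. Raises on an empty universe or query; query genes
    must lie inside the universe.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not universe:
        raise ValueError("empty gene universe")
    if not gene_set:
        raise ValueError("empty query gene set")
    stray = gene_set - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}...")
    rows = []
    N, n = len(universe), len(gene_set)
    for term_id, genes in sorted(annotation.terms.items()):
        in_universe = genes & universe
        K = len(in_universe)
        if K < MIN_TERM_SIZE:
            continue
        k = len(in_universe & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, annotation.names.get(term_id, ""), n, K, k, p))
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "set_count", "term_count", "overlap", "p"]
    )
    thr = alpha / max(len(out), 1) if correct else alpha
    out["enriched"] = out["p"] < thr
    return out.sort_values("p", kind="stable").reset_index(drop=True)
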