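"""Shared data containers for the aging eQTL pipeline.

The pipeline works on three in-memory objects:

* :class:`GeneticMap` — ordered SNP markers with chromosome and genetic
  position (cM).
* :class:`GenotypePanel` — strains × markers allele matrix for a two-parent
  recombinant inbred line (RIL) panel, coded −1 (CB4856 allele) / +1
  (N2 allele), plus the map.
* :class:`ExpressionStudy` — genes × samples log2 expression matrix with
  per-sample metadata (strain, chronological age, age group, replicate,
  physiological age) and a boolean mask of retained values.

Age groups are labelled ``t1`` (young, 40 h), ``t2`` (reproductive, 96 h)
and ``t3`` (old, 214 h); the two-age analysis windows are ``developing``
(t1 + t2) and ``aging`` (t2 + t3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PARENT_N2 = "N2"
PARENT_CB = "CB4856"
PARENTS: tuple[str, str] = (PARENT_N2, PARENT_CB)

#: allele codes: +1 = N2, −1 = CB4856
N2_ALLELE = 1
CB_ALLELE = -1

AGE_GROUPS = ("t1", "t2", "t3")

#: analysis windows → age groups they pool
WINDOWS: dict[str, tuple[str, ...]] = {
    "t1": ("t1",),
    "t2": ("t2",),
    "t3": ("t3",),
    "developing": ("t1", "t2"),
    "aging": ("t2", "t3"),
}
SINGLE_AGE_WINDOWS = ("t1", "t2", "t3")
TWO_AGE_WINDOWS = ("developing", "aging")


def window_age_groups(window: str) -> tuple[str, ...]:
    """Age groups pooled by a named analysis window."""
    try:
        return WINDOWS[window]
    except KeyError:
        raise ValueError(f"unknown window {window!r}; expected one of {sorted(WINDOWS)}") from None


@dataclass(frozen=True)
class GeneticMap:
    """Genetic map: one row per marker with chromosome and position in cM.

    ``table`` columns: ``marker``, ``chromosome``, ``position_cm``. Markers are
    kept in map order (chromosome blocks, nondecreasing position within each).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chromosome", "position_cm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"genetic map missing columns {sorted(missing)}")
        if self.table["marker"].duplicated().any():
            raise ValueError("duplicate marker ids in genetic map")
        if (self.table["position_cm"] < 0).any():
            raise ValueError("negative genetic positions")
        for chrom, grp in self.table.groupby("chromosome", sort=False):
            pos = grp["position_cm"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not nondecreasing on chromosome {chrom}")

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def chromosomes(self) -> list[str]:
        seen: list[str] = []
        for c in self.table["chromosome"]:
            if c not in seen:
                seen.append(c)
        return seen

    def chromosome_table(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chrom]

    def adjacent(self, marker: str) -> list[str]:
        """Immediate map neighbours of ``marker`` on its chromosome."""
        row = self.table.index[self.table["marker"] == marker]
        if len(row) == 0:
            raise KeyError(marker)
        i = self.table.index.get_loc(row[0])
        chrom = self.table.iloc[i]["chromosome"]
        out = []
        for j in (i - 1, i + 1):
            if 0 <= j < len(self.table) and self.table.iloc[j]["chromosome"] == chrom:
                out.append(self.table.iloc[j]["marker"])
        return out

    @classmethod
    def evenly_spaced(
        cls,
        n_markers: int = 121,
        chromosomes: Sequence[str] = ("I", "II", "III", "IV", "V", "X"),
        length_cm: float = 50.0,
    ) -> "GeneticMap":
        """Evenly spaced default map: 121 markers over six ~50 cM chromosomes.

        Markers are distributed as evenly as possible (extras go to the first
        chromosomes), named ``<chrom>m<index>``.
        """
        n_chrom = len(chromosomes)
        base, extra = divmod(n_markers, n_chrom)
        rows = []
        for ci, chrom in enumerate(chromosomes):
            k = base + (1 if ci < extra else 0)
            if k < 1:
                raise ValueError("need at least one marker per chromosome")
            pos = np.linspace(0.0, length_cm, k) if k > 1 else np.array([0.0])
            for mi, p in enumerate(pos, start=1):
                rows.append((f"{chrom}m{mi:02d}", chrom, float(p)))
        return cls(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"]))


@dataclass
class GenotypePanel:
    """Strains × markers allele matrix (±1) for a RIL panel plus its parents.

    Parents are the constant rows: +1 everywhere for N2, −1 everywhere for
    CB4856. RIL rows contain only ±1 (fully inbred, no heterozygotes).
    """

    alleles: pd.DataFrame  # strains × markers, values in {−1, +1}
    gmap: GeneticMap
    parents: tuple[str, str] = PARENTS

    def __post_init__(self) -> None:
        if list(self.alleles.columns) != self.gmap.markers:
            raise ValueError("allele matrix columns do not match the genetic map")
        vals = self.alleles.to_numpy()
        if not np.isin(vals, (-1, 1)).all():
            raise ValueError("alleles must be coded -1/+1 (no heterozygotes)")
        for parent, allele in zip(self.parents, (N2_ALLELE, CB_ALLELE)):
            if parent in self.alleles.index:
                if not (self.alleles.loc[parent] == allele).all():
                    raise ValueError(f"parent {parent} must be the constant {allele:+d} row")

    @property
    def strains(self) -> list[str]:
        return self.alleles.index.tolist()

    @property
    def rils(self) -> list[str]:
        return [s for s in self.alleles.index if s not in self.parents]

    def ril_alleles(self) -> pd.DataFrame:
        return self.alleles.loc[self.rils]


@dataclass
class ExpressionStudy:
    """Genes × samples log2 expression with sample metadata and value mask.

    ``samples`` is indexed by sample id and carries ``strain``, ``age_hours``,
    ``age_group``, ``replicate`` and (once assigned) ``phys_age`` =
    age_hours / mean lifespan of the strain. ``mask`` marks retained values;
    masked entries are treated as missing downstream, never imputed.
    """

    expr: pd.DataFrame
    samples: pd.DataFrame
    mask: pd.DataFrame | None = None
    lifespans: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if list(self.expr.columns) != list(self.samples.index):
            raise ValueError("expression columns and sample metadata index differ")
        required = {"strain", "age_hours", "age_group", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata missing columns {sorted(missing)}")
        if self.mask is None:
            self.mask = pd.DataFrame(
                True, index=self.expr.index, columns=self.expr.columns
            )
        else:
            if self.mask.shape != self.expr.shape:
                raise ValueError("mask shape differs from expression matrix")
            self.mask = self.mask.astype(bool)

    # -- basic views ------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return self.expr.index.tolist()

    @property
    def strains(self) -> list[str]:
        return sorted(self.samples["strain"].unique().tolist())

    def values(self) -> pd.DataFrame:
        """Expression with masked entries as NaN."""
        return self.expr.where(self.mask)

    def has_phys_age(self) -> bool:
        return "phys_age" in self.samples.columns

    # -- subsetting -------------------------------------------------------

    def subset(
        self,
        age_groups: Iterable[str] | None = None,
        strains: Iterable[str] | None = None,
        genes: Iterable[str] | None = None,
    ) -> "ExpressionStudy":
        keep = pd.Series(True, index=self.samples.index)
        if age_groups is not None:
            keep &= self.samples["age_group"].isin(list(age_groups))
        if strains is not None:
            keep &= self.samples["strain"].isin(list(strains))
        cols = self.samples.index[keep]
        gene_idx = self.expr.index if genes is None else pd.Index(genes)
        return ExpressionStudy(
            expr=self.expr.loc[gene_idx, cols],
            samples=self.samples.loc[cols].copy(),
            mask=self.mask.loc[gene_idx, cols],
            lifespans=self.lifespans,
        )

    def window(self, window: str, strains: Iterable[str] | None = None) -> "ExpressionStudy":
        return self.subset(age_groups=window_age_groups(window), strains=strains)

    def copy(self) -> "ExpressionStudy":
        return ExpressionStudy(
            expr=self.expr.copy(),
            samples=self.samples.copy(),
            mask=self.mask.copy(),
            lifespans=None if self.lifespans is None else dict(self.lifespans),
        )


def parent_replicate_matrix(
    study: ExpressionStudy, parent: str, age_group: str
) -> np.ndarray:
    """Genes × replicates matrix (NaN-masked) for one parent at one age."""
    cols = study.samples.index[
        (study.samples["strain"] == parent) & (study.samples["age_group"] == age_group)
    ]
    return study.values()[cols].to_numpy(dtype=float)


def ril_value_matrix(
    study: ExpressionStudy, rils: Sequence[str], age_group: str
) -> np.ndarray:
    """Genes × RILs matrix at one age (one sample per RIL per age expected).

    When a RIL has several samples at the age their mean is used; a missing
    RIL yields a NaN column.
    """
    vals = study.values()
    meta = study.samples
    out = np.full((len(study.genes), len(rils)), np.nan)
    for j, ril in enumerate(rils):
        cols = meta.index[(meta["strain"] == ril) & (meta["age_group"] == age_group)]
        if len(cols):
            block = vals[cols].to_numpy(dtype=float)
            cnt = np.isfinite(block).sum(axis=1)
            tot = np.nansum(block, axis=1)
            out[:, j] = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return out
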