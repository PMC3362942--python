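"""TSV reading/writing for panels, studies and lifespan tables."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .data import ExpressionStudy, GeneticMap, GenotypePanel

__all__ = [
    "write_genotype_panel",
    "read_genotype_panel",
    "write_expression_study",
    "read_expression_study",
    "write_lifespans",
    "read_lifespans",
]


def write_genotype_panel(panel: GenotypePanel, alleles_path, map_path) -> None:
    panel.alleles.to_csv(alleles_path, sep="\t", index_label="strain")
    panel.gmap.table.to_csv(map_path, sep="\t", index=False)


def read_genotype_panel(alleles_path, map_path) -> GenotypePanel:
    alleles = pd.read_csv(alleles_path, sep="\t", index_col="strain")
    alleles.index.name = None
    gmap = GeneticMap(pd.read_csv(map_path, sep="\t"))
    return GenotypePanel(alleles=alleles.astype(int), gmap=gmap)


def write_expression_study(study: ExpressionStudy, expr_path, samples_path, mask_path=None) -> None:
    study.expr.to_csv(expr_path, sep="\t", index_label="gene")
    study.samples.to_csv(samples_path, sep="\t", index_label="sample_id")
    if mask_path is not None:
        study.mask.astype(int).to_csv(mask_path, sep="\t", index_label="gene")


def read_expression_study(expr_path, samples_path, mask_path=None,
                          lifespans: Mapping[str, float] | None = None) -> ExpressionStudy:
    expr = pd.read_csv(expr_path, sep="\t", index_col="gene")
    expr.index.name = None
    expr.columns.name = "sample_id"
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    mask = None
    if mask_path is not None and Path(mask_path).exists():
        mask = pd.read_csv(mask_path, sep="\t", index_col="gene").astype(bool)
        mask.index.name = None
        mask.columns.name = "sample_id"
    return ExpressionStudy(
        expr=expr, samples=samples, mask=mask,
        lifespans=dict(lifespans) if lifespans else None,
    )


def write_lifespans(lifespans: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"strain": list(lifespans), "mean_lifespan_hours": list(lifespans.values())}
    ).to_csv(path, sep="\t", index=False)


def read_lifespans(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["strain"], df["mean_lifespan_hours"].astype(float)))
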