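"""Pipeline orchestration and summary tables.

Ties the stages together — simulate → preprocess → single- and two-age
mapping (RILs and parents) → permutation thresholds → heritability →
transgression → multilocus models — and computes the overlap categories
that interpret a segregating population against its parents:

* **A** — parent-differential genes with an eQTL (simple, strong locus);
* **B** — parent-differential genes without an eQTL (dispersed small
  effects);
* **C** — genes with an eQTL but no parental difference (opposing or
  epistatic effects; transgression-prone).

By construction A + B = parent-differential count and A + C = eQTL count.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import ExpressionStudy, GenotypePanel, TWO_AGE_WINDOWS
from .heritability import heritability_table, high_h2_cutoff
from .mapping import map_genome
from .multilocus import multilocus_table, polygenic_summary
from .preprocess import apply_parent_outlier_masks
from .simulate import (
    ArchitectureSpec,
    GeneticMap,
    StudyDesign,
    category_architectures,
    simulate_study,
)
from .thresholds import estimate_fdr, joint_fdr, permutation_null
from .transgression import transgression_fdr, transgression_table

__all__ = ["categorize_genes", "h2_eqtl_profile", "PipelineConfig", "run_pipeline"]


def categorize_genes(
    parent_calls: Iterable[str],
    ril_calls: Iterable[str],
    universe: Sequence[str],
) -> dict[str, object]:
    """Exact set arithmetic for the A/B/C overlap categories."""
    universe_list = list(universe)
    if len(set(universe_list)) != len(universe_list):
        raise ValueError("duplicate gene entries in universe")
    uni = set(universe_list)
    parents = set(parent_calls) & uni
    eqtl = set(ril_calls) & uni
    a = parents & eqtl
    b = parents - eqtl
    c = eqtl - parents
    out = {
        "n_universe": len(uni),
        "n_eqtl": len(eqtl),
        "n_parent_differential": len(parents),
        "A": len(a),
        "B": len(b),
        "C": len(c),
        "genes_A": sorted(a),
        "genes_B": sorted(b),
        "genes_C": sorted(c),
    }
    assert out["A"] + out["B"] == out["n_parent_differential"]
    assert out["A"] + out["C"] == out["n_eqtl"]
    return out


def h2_eqtl_profile(
    h2: pd.DataFrame,
    calls: Iterable[str],
    bin_edges: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0),
) -> pd.DataFrame:
    """Percentage of genes with a call per heritability bin (with denominators)."""
    call_set = set(calls)
    tab = h2.copy()
    tab["bin"] = pd.cut(tab["h2"], bins=list(bin_edges), include_lowest=True)
    rows = []
    for h2_bin, grp in tab.groupby("bin", observed=False, dropna=False):
        n = len(grp)
        pct = 100.0 * grp["gene"].isin(call_set).mean() if n else np.nan
        rows.append((str(h2_bin), n, pct))
    return pd.DataFrame(rows, columns=["h2_bin", "n_genes", "pct_with_call"])


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All knobs of the pipeline with their study defaults."""

    # simulation
    n_rils: int = 36
    n_genes_a: int = 20
    n_genes_b: int = 20
    n_genes_c: int = 20
    n_null_genes: int = 40
    ages_hours: tuple[float, ...] = (40.0, 96.0, 214.0)
    parent_replicates_per_age: int = 6
    seed: int = 0
    # preprocessing
    outlier_conf: float = 0.995
    outlier_max_removed: int = 6
    outlier_sd_mult: float = 2.0
    # mapping thresholds (−log10 p)
    eqtl_threshold: float = 3.0
    parent_threshold: float = 2.0
    age_threshold_developing: float = 8.0
    age_threshold_aging: float = 6.0
    # permutations
    n_perm_fdr: int = 100
    n_perm_joint: int = 30
    # transgression
    k_min: int = 6
    sd_mult: float = 2.0
    n_perm_transgression: int = 100
    # heritability
    h2_fdr: float = 0.01
    n_perm_h2: int = 100
    # multilocus
    per_chrom: int = 4
    max_terms: int = 6
    max_steps: int = 2000
    h2_bin_edges: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 0.9, 1.0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        for key in ("ages_hours", "h2_bin_edges"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _mixture_architectures(config: PipelineConfig, gmap: GeneticMap) -> list[ArchitectureSpec]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10]))
    archs: list[ArchitectureSpec] = []
    for kind, count in (("A", config.n_genes_a), ("B", config.n_genes_b), ("C", config.n_genes_c)):
        factory = category_architectures(kind)
        for i in range(count):
            archs.append(factory(gmap, rng, name=f"cat{kind}_{i + 1:04d}"))
    return archs


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    study: ExpressionStudy | None = None,
    panel: GenotypePanel | None = None,
) -> dict[str, object]:
    """Run the full analysis and write TSV outputs plus a run manifest.

    Without a supplied study/panel, a labelled synthetic mixture (category
    A/B/C + null genes) is simulated first. Outputs are deterministic for a
    fixed config (the manifest echoes it).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if study is None or panel is None:
            design = StudyDesign(
                n_rils=config.n_rils,
                ages_hours=config.ages_hours,
                parent_replicates_per_age=config.parent_replicates_per_age,
                seed=config.seed,
            )
            gmap = GeneticMap.evenly_spaced()
            panel, study = simulate_study(
                design, gmap, _mixture_architectures(config, gmap),
                n_null_genes=config.n_null_genes,
            )

        stage = "preprocess"
        study = apply_parent_outlier_masks(
            study,
            conf=config.outlier_conf,
            max_removed=config.outlier_max_removed,
            sd_mult=config.outlier_sd_mult,
        )

        stage = "mapping"
        results: dict[str, object] = {}
        peak_frames = []
        call_frames = []
        for window in ("t1", "t2", "t3"):
            for pop in ("rils", "parents"):
                thr = config.eqtl_threshold if pop == "rils" else config.parent_threshold
                tab = map_genome(study, panel, model=1, window=window, population=pop,
                                 threshold=thr)
                peak_frames.append(tab.peaks.assign(population=pop, model=1))
                call_frames.append(tab.calls.assign(population=pop, model=1))
        model2_tabs: dict[tuple[str, str], object] = {}
        for window in TWO_AGE_WINDOWS:
            for pop in ("rils", "parents"):
                thr = config.eqtl_threshold if pop == "rils" else config.parent_threshold
                tab = map_genome(study, panel, model=2, window=window, population=pop,
                                 threshold=thr)
                model2_tabs[(window, pop)] = tab
                peak_frames.append(tab.peaks.assign(population=pop, model=2))
                call_frames.append(tab.calls.assign(population=pop, model=2))
        peaks = pd.concat(peak_frames, ignore_index=True)
        calls = pd.concat(call_frames, ignore_index=True)
        peaks.to_csv(out / "mapping_peaks.tsv", sep="\t", index=False)
        calls.to_csv(out / "mapping_calls.tsv", sep="\t", index=False)
        results["peaks"] = peaks
        results["calls"] = calls

        stage = "categories"
        universe = study.genes
        cat_rows = []
        for window in TWO_AGE_WINDOWS:
            for term, label in (("marker", "genotype"), ("marker_by_age", "age_by_genotype")):
                ril_tab = model2_tabs[(window, "rils")]
                par_tab = model2_tabs[(window, "parents")]
                ril_genes = ril_tab.calls.loc[ril_tab.calls["term"] == term, "gene"]
                par_genes = par_tab.calls.loc[par_tab.calls["term"] == term, "gene"]
                cat = categorize_genes(par_genes, ril_genes, universe)
                cat_rows.append(
                    (window, label, cat["n_eqtl"], cat["n_parent_differential"],
                     cat["A"], cat["B"], cat["C"])
                )
        categories = pd.DataFrame(
            cat_rows,
            columns=["window", "effect_term", "n_eqtl", "n_parent_differential",
                     "A", "B", "C"],
        )
        categories.to_csv(out / "categories.tsv", sep="\t", index=False)
        results["categories"] = categories

        stage = "thresholds"
        fdr_rows = []
        joint_rows = []
        for window in TWO_AGE_WINDOWS:
            age_thr = (
                config.age_threshold_developing
                if window == "developing"
                else config.age_threshold_aging
            )
            ril_null = {}
            par_null = {}
            for pop, store, pseed in (
                ("rils", ril_null, config.seed + 3),
                ("parents", par_null, config.seed + 4),  # independent draws for the joint-FDR
            ):
                for term in ("marker", "age", "marker_by_age"):
                    store[term] = permutation_null(
                        study, panel, model=2, window=window, term=term,
                        population=pop, n_perm=config.n_perm_fdr, seed=pseed,
                    )
            for term, thr in (
                ("marker", config.eqtl_threshold),
                ("age", age_thr),
                ("marker_by_age", config.eqtl_threshold),
            ):
                est = estimate_fdr(
                    model2_tabs[(window, "rils")].peak_scores(term), ril_null[term], thr
                )
                fdr_rows.append(
                    (term, window, "rils", thr, est.n_observed, est.mean_false,
                     est.fdr, est.n_perm)
                )
            for term in ("marker", "marker_by_age"):
                jest = joint_fdr(
                    model2_tabs[(window, "parents")].peak_scores(term),
                    model2_tabs[(window, "rils")].peak_scores(term),
                    par_null[term],
                    ril_null[term],
                    thresholds=(config.parent_threshold, config.eqtl_threshold),
                    n_perm=config.n_perm_joint,
                )
                joint_rows.append(
                    (term, window, config.parent_threshold, config.eqtl_threshold,
                     jest.n_observed, jest.mean_false, jest.fdr, jest.product_rule,
                     jest.n_perm)
                )
        fdr_tab = pd.DataFrame(
            fdr_rows,
            columns=["term", "window", "population", "threshold", "n_observed",
                     "mean_false", "fdr", "n_perm"],
        )
        fdr_tab.to_csv(out / "fdr.tsv", sep="\t", index=False)
        joint_tab = pd.DataFrame(
            joint_rows,
            columns=["term", "window", "parent_threshold", "eqtl_threshold",
                     "n_observed", "mean_false", "fdr", "product_rule", "n_perm"],
        )
        joint_tab.to_csv(out / "joint_fdr.tsv", sep="\t", index=False)
        results["fdr"] = fdr_tab
        results["joint_fdr"] = joint_tab

        stage = "heritability"
        h2_frames = []
        profiles = []
        for window in TWO_AGE_WINDOWS:
            cutoff, _ = high_h2_cutoff(
                study, window, fdr=config.h2_fdr, n_perm=config.n_perm_h2,
                seed=config.seed + 1,
            )
            tab = heritability_table(study, window, cutoff=cutoff if np.isfinite(cutoff) else None)
            tab["cutoff"] = cutoff
            h2_frames.append(tab)
            ril_tab = model2_tabs[(window, "rils")]
            eqtl_genes = ril_tab.calls.loc[ril_tab.calls["term"] == "marker", "gene"]
            prof = h2_eqtl_profile(tab, eqtl_genes, bin_edges=config.h2_bin_edges)
            prof["window"] = window
            profiles.append(prof)
        h2_all = pd.concat(h2_frames, ignore_index=True)
        h2_all.to_csv(out / "heritability.tsv", sep="\t", index=False)
        profile = pd.concat(profiles, ignore_index=True)
        profile.to_csv(out / "h2_eqtl_profile.tsv", sep="\t", index=False)
        results["heritability"] = h2_all
        results["h2_eqtl_profile"] = profile

        stage = "transgression"
        tg_frames = []
        tg_fdr_rows = []
        for window in ("t1", "t2", "t3") + TWO_AGE_WINDOWS:
            tab = transgression_table(study, window, k_min=config.k_min, sd_mult=config.sd_mult)
            tg_frames.append(tab)
            est = transgression_fdr(
                study, window, k_min=config.k_min, sd_mult=config.sd_mult,
                n_perm=config.n_perm_transgression, seed=config.seed + 2,
            )
            tg_fdr_rows.append((window, est.n_observed, est.mean_false, est.fdr, est.n_perm))
        tg_all = pd.concat(tg_frames, ignore_index=True)
        tg_all.to_csv(out / "transgression.tsv", sep="\t", index=False)
        tg_fdr = pd.DataFrame(
            tg_fdr_rows, columns=["window", "n_observed", "mean_false", "fdr", "n_perm"]
        )
        tg_fdr.to_csv(out / "transgression_fdr.tsv", sep="\t", index=False)
        results["transgression"] = tg_all
        results["transgression_fdr"] = tg_fdr

        stage = "multilocus"
        ml_frames = []
        summaries = []
        for window in TWO_AGE_WINDOWS:
            ml = multilocus_table(
                study, panel, window,
                per_chrom=config.per_chrom, max_terms=config.max_terms,
                max_steps=config.max_steps,
            )
            ml_frames.append(ml)
            h2_win = h2_all[h2_all["window"] == window]
            summaries.append(polygenic_summary(ml, h2_win, bin_edges=config.h2_bin_edges))
        ml_all = pd.concat(ml_frames, ignore_index=True)
        ml_all.to_csv(out / "multilocus.tsv", sep="\t", index=False)
        summary = pd.concat(summaries, ignore_index=True)
        summary.to_csv(out / "polygenic_summary.tsv", sep="\t", index=False)
        results["multilocus"] = ml_all
        results["polygenic_summary"] = summary

        stage = "manifest"
        manifest = {
            "agemap_version": __version__,
            "config": asdict(config),
            "n_genes": len(universe),
            "n_samples": len(study.samples),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
        results["manifest"] = manifest
        return results
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
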