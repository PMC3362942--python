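"""Calibration experiments for the pipeline's statistical machinery.

Each function runs a self-contained simulation experiment under the default
study conditions (36 RILs, two parents with six replicates per age, three
sampling ages, 121 markers on six chromosomes) and returns the measured
quantities: oracle agreement of the model-1 fit, null calibration of
p-values and permutation FDR, heritability recovery against its analytic
expectation, transgression calibration, recovery of the three architecture
categories, stepwise-search sanity and hypergeometric exactness. The test
suite asserts on these numbers; ``scripts/acceptance.py`` reports them.

All experiments are deterministic given their seed.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats

from .data import GeneticMap
from .heritability import heritability_table
from .mapping import fit_model1, map_genome, scan_model1, scan_model2
from .multilocus import MultiLocusModel, _candidate_matrix, select_candidate_markers, stepwise_bic
from .simulate import (
    ArchitectureSpec,
    StudyDesign,
    category_architectures,
    simulate_expression,
    simulate_genotypes,
    simulate_heritability_study,
)
from .thresholds import estimate_fdr, permutation_null
from .transgression import transgression_fdr

__all__ = [
    "model1_oracle_agreement",
    "null_calibration",
    "heritability_recovery",
    "transgression_calibration",
    "architecture_recovery",
    "stepwise_sanity",
    "hypergeom_exactness",
]


def model1_oracle_agreement(seed: int = 0, n_instances: int = 100) -> dict[str, float]:
    """Max |score difference| between the model-1 fit and a t-test oracle.

    Random instances of 8–36 strains with a two-level marker; the oracle is
    the equal-variance two-sample t test (scipy), an independent route to
    the same p-value.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(8, 37))
        g = rng.choice([-1.0, 1.0], n)
        while len(np.unique(g)) < 2 or min((g == 1).sum(), (g == -1).sum()) < 2:
            g = rng.choice([-1.0, 1.0], n)
        y = rng.normal(0, 1, n) + rng.uniform(-1, 1) * g
        fit = fit_model1(y, g)
        oracle = -np.log10(stats.ttest_ind(y[g == 1], y[g == -1], equal_var=True).pvalue)
        worst = max(worst, abs(fit.score - oracle))
    return {"max_abs_score_deviation": float(worst), "n_instances": n_instances}


def null_calibration(
    seed: int = 0, n_genes: int = 1000, n_perm: int = 100
) -> dict[str, float]:
    """Uniformity of null p-values and permutation FDR ≈ 1 on null data."""
    design = StudyDesign(seed=seed)
    gmap = GeneticMap.evenly_spaced()
    panel = simulate_genotypes(design, gmap)
    archs = [ArchitectureSpec(noise_sd=0.2, name=f"null{i:05d}") for i in range(n_genes)]
    study = simulate_expression(panel, design, archs)

    probe = gmap.n_markers // 2  # independent genes at one fixed marker
    t1 = study.window("t1", strains=panel.rils)
    Y = t1.values().to_numpy()
    X = panel.alleles.loc[t1.samples["strain"]].to_numpy(float)
    _, sco1 = scan_model1(Y, X[:, [probe]])
    out = {"ks_p_model1_marker": float(stats.kstest(10.0 ** (-sco1[:, 0]), "uniform").pvalue)}

    dev = study.window("developing", strains=panel.rils)
    Y2 = dev.values().to_numpy()
    X2 = panel.alleles.loc[dev.samples["strain"]].to_numpy(float)
    pa = dev.samples["phys_age"].to_numpy()
    _, sco2 = scan_model2(Y2, X2[:, [probe]], pa)
    for k, term in enumerate(("marker", "age", "marker_by_age")):
        p = 10.0 ** (-sco2[:, 0, k])
        out[f"ks_p_model2_{term}"] = float(stats.kstest(p, "uniform").pvalue)

    null = permutation_null(
        study, panel, model=1, window="t1", n_perm=n_perm, seed=seed + 1
    )
    obs = map_genome(study, panel, model=1, window="t1").peak_scores("marker")
    est = estimate_fdr(obs, null, threshold=2.0)
    out["null_fdr_at_2"] = float(est.fdr)
    out["null_fdr_se"] = float(est.monte_carlo_se())
    out["n_genes"] = n_genes
    return out


def heritability_recovery(
    seed: int = 0, n_genes: int = 5000, truths: tuple[float, ...] = (0.0, 0.3, 0.6, 0.9)
) -> dict[str, float]:
    """Mean estimated H² per truth vs the estimator's analytic expectation.

    With R RILs, V_RIL ~ (σg²+σe²)·χ²/(R−1), so E[ĥ²] = 1 − (1−H²)(R−1)/(R−3).
    Also reports the fraction of negative estimates at truth 0, whose
    analytic value is P(F(R−1, 10) < 1) for six replicates per parent.
    """
    design = StudyDesign(seed=seed)
    per = n_genes // len(truths)
    study, truth = simulate_heritability_study(design, truths, n_genes_per=per, seed=seed + 1)
    tab = heritability_table(study, "t1")
    est = tab["h2"].to_numpy()
    R = design.n_rils
    out: dict[str, float] = {"n_genes": per * len(truths)}
    for h2 in truths:
        sel = truth == h2
        out[f"mean_h2_at_{h2:g}"] = float(np.nanmean(est[sel]))
        out[f"expected_h2_at_{h2:g}"] = float(1 - (1 - h2) * (R - 1) / (R - 3))
    zero = truth == 0.0
    out["neg_fraction_at_0"] = float(np.mean(est[zero] < 0))
    df_p = 2 * (design.parent_replicates_per_age - 1)
    out["neg_fraction_analytic"] = float(stats.f.cdf(1.0, R - 1, df_p))
    return out


def transgression_calibration(
    seed: int = 0, n_genes: int = 500, n_perm: int = 100
) -> dict[str, float]:
    """Null transgression FDR ≈ 1, and signal dominance with epistatic genes.

    Null clause: RILs and parents drawn from one distribution (single-age
    window, where the baseline call rate is non-trivial). Signal clause:
    10% pure-epistasis genes injected; counted on the over-time window,
    where a null RIL must clear the bound at both ages to count.
    """
    design = StudyDesign(seed=seed)
    gmap = GeneticMap.evenly_spaced()
    panel = simulate_genotypes(design, gmap)
    rng = np.random.default_rng(seed + 2)
    n_sig = n_genes // 10
    archs = [ArchitectureSpec(noise_sd=0.2, name=f"null{i:05d}") for i in range(n_genes - n_sig)]
    archs += [
        category_architectures("C")(gmap, rng, name=f"epi{i:04d}") for i in range(n_sig)
    ]
    study = simulate_expression(panel, design, archs)
    null_only = study.subset(genes=[a.name for a in archs[: n_genes - n_sig]])

    null_est = transgression_fdr(null_only, "t1", n_perm=n_perm, seed=seed + 3)
    sig_est = transgression_fdr(study, "developing", n_perm=n_perm, seed=seed + 3)
    return {
        "null_fdr": float(null_est.fdr),
        "null_fdr_se": float(null_est.monte_carlo_se()),
        "null_observed": float(null_est.n_observed),
        "signal_observed": float(sig_est.n_observed),
        "signal_mean_false": float(sig_est.mean_false),
        "signal_ratio": float(sig_est.n_observed / max(sig_est.mean_false, 1e-9)),
        "n_genes": n_genes,
    }


def _marker_terms(model: MultiLocusModel) -> list[str]:
    return [t for t in model.selected_terms if t != "A"]


def architecture_recovery(seed: int = 0, n_each: int = 100) -> dict[str, float]:
    """Recovery of the A/B/C architecture mixture (the central mechanism).

    * A: % with a model-1 eQTL peaking at the causal marker or an immediate
      map neighbour.
    * B: % parent-differential at −log10 p ≥ 2; % with a model-1 eQTL at 3.
    * B/C: stepwise-BIC behaviour at 72 samples (two-age window): % of B
      genes with ≥ 2 marker-involving terms and % of C genes flagged
      epistatic.
    """
    design = StudyDesign(seed=seed)
    gmap = GeneticMap.evenly_spaced()
    panel = simulate_genotypes(design, gmap)
    rng = np.random.default_rng(seed + 4)
    archs: list[ArchitectureSpec] = []
    for kind in ("A", "B", "C"):
        factory = category_architectures(kind)
        archs += [factory(gmap, rng, name=f"cat{kind}_{i:04d}") for i in range(n_each)]
    study = simulate_expression(panel, design, archs)

    ril = map_genome(study, panel, model=1, window="t1")
    par = map_genome(study, panel, model=1, window="t1", population="parents")
    calls = ril.calls.set_index("gene")
    a_hits = 0
    for arch in archs[:n_each]:
        causal = next(iter(arch.additive))
        if arch.name in calls.index:
            peak = calls.loc[arch.name, "peak_marker"]
            if peak == causal or peak in gmap.adjacent(causal):
                a_hits += 1
    b_names = [a.name for a in archs[n_each : 2 * n_each]]
    c_names = [a.name for a in archs[2 * n_each :]]
    b_parent = par.calls["gene"].isin(b_names).sum()
    b_eqtl = ril.calls["gene"].isin(b_names).sum()

    cand = select_candidate_markers(gmap)
    dev = study.window("developing", strains=panel.rils)
    cols = _candidate_matrix(
        panel, cand, dev.samples["strain"].tolist(), dev.samples["phys_age"].to_numpy()
    )
    Y = dev.values().to_numpy()
    gene_index = {g: i for i, g in enumerate(dev.expr.index)}
    b_multi = 0
    for name in b_names:
        model = stepwise_bic(Y[gene_index[name]], cols, gene=name)
        if len(_marker_terms(model)) >= 2:
            b_multi += 1
    c_epi = 0
    for name in c_names:
        model = stepwise_bic(Y[gene_index[name]], cols, gene=name)
        if model.has_epistasis:
            c_epi += 1
    return {
        "pct_A_recovered": 100.0 * a_hits / n_each,
        "pct_B_parent_differential": 100.0 * b_parent / n_each,
        "pct_B_with_eqtl": 100.0 * b_eqtl / n_each,
        "pct_B_multi_term": 100.0 * b_multi / n_each,
        "pct_C_epistasis_flagged": 100.0 * c_epi / n_each,
        "n_each": n_each,
    }


def stepwise_sanity(seed: int = 0, n_noise: int = 100) -> dict[str, float]:
    """Search invariants on pure-noise genes at 72 samples.

    Reports whether every returned model improved on the start BIC within
    the step and term budgets, and the fraction of noise genes for which no
    marker term was selected.
    """
    design = StudyDesign(seed=seed)
    gmap = GeneticMap.evenly_spaced()
    panel = simulate_genotypes(design, gmap)
    archs = [ArchitectureSpec(noise_sd=0.2, name=f"noise{i:04d}") for i in range(n_noise)]
    study = simulate_expression(panel, design, archs)
    cand = select_candidate_markers(gmap)
    dev = study.window("developing", strains=panel.rils)
    cols = _candidate_matrix(
        panel, cand, dev.samples["strain"].tolist(), dev.samples["phys_age"].to_numpy()
    )
    Y = dev.values().to_numpy()
    n = Y.shape[1]
    bic_ok = terms_ok = steps_ok = no_marker = 0
    for gi in range(n_noise):
        y = Y[gi]
        start_bic = n * np.log(np.sum((y - y.mean()) ** 2) / n) + np.log(n)
        model = stepwise_bic(y, cols)
        bic_ok += model.bic <= start_bic + 1e-9
        terms_ok += len(model.selected_terms) <= 6
        steps_ok += model.n_steps_used <= 2000
        no_marker += len(_marker_terms(model)) == 0
    return {
        "pct_bic_not_worse_than_start": 100.0 * bic_ok / n_noise,
        "pct_within_term_budget": 100.0 * terms_ok / n_noise,
        "pct_within_step_budget": 100.0 * steps_ok / n_noise,
        "pct_noise_without_marker_term": 100.0 * no_marker / n_noise,
        "n_noise": n_noise,
    }


def hypergeom_exactness(max_universe: int = 12) -> dict[str, float]:
    """Max |p − exact tail| over every configuration with universe ≤ 12.

    The oracle is exact rational arithmetic over the enumeration identity
    P(X ≥ k) = Σ_{j≥k} C(K,j)·C(N−K,n−j)/C(N,n).
    """
    worst = 0.0
    n_checked = 0
    for N in range(2, max_universe + 1):
        for K in range(2, N + 1):
            for n in range(1, N + 1):
                for k in range(0, min(K, n) + 1):
                    exact = Fraction(0)
                    for j in range(k, min(K, n) + 1):
                        exact += Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
                    p = float(stats.hypergeom.sf(k - 1, N, K, n))
                    worst = max(worst, abs(p - float(exact)))
                    n_checked += 1
    return {"max_abs_error": worst, "n_configurations": float(n_checked)}
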