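"""Synthetic RIL panels and expression phenotypes.

This module generates data with the statistical structure the downstream
analyses assume: a two-parent (N2 × CB4856) selfed recombinant inbred line
panel genotyped at mapped SNP markers, and log2 expression values built from
additive, epistatic, age and age-by-marker genetic effects plus Gaussian
noise, sampled at three ages with parental replication.

Genotypes
---------
Each RIL chromosome is simulated as a Markov chain over {−1, +1}. The first
marker's allele is equiprobable; between adjacent markers ``d`` cM apart the
chain switches parent-of-origin with probability

    R = 2r / (1 + 2r),    r = (1 − exp(−2 d / 100)) / 2,

i.e. the Haldane map function followed by the map expansion of a selfed RIL
(recombination accumulates over the selfing generations). Chromosomes are
independent, RILs are fully homozygous, and the two parents are appended as
the constant +1 (N2) and −1 (CB4856) rows.

Expression
----------
For gene *g*, strain *s*, age *t* (physiological age ``pa = t / lifespan_s``):

    y = baseline + Σ a_m·x_sm + Σ e_ij·x_si·x_sj + b·pa + Σ c_m·x_sm·pa + ε,

with ε ~ N(0, noise_sd²). Parents get independent replicates per age, RILs
one sample per age, matching the replication asymmetry of a typical RIL
microarray study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import (
    CB_ALLELE,
    N2_ALLELE,
    PARENT_CB,
    PARENT_N2,
    PARENTS,
    ExpressionStudy,
    GeneticMap,
    GenotypePanel,
)

__all__ = [
    "StudyDesign",
    "ArchitectureSpec",
    "haldane_recombination_fraction",
    "ril_switch_probability",
    "simulate_genotypes",
    "simulate_expression",
    "category_architectures",
    "simulate_study",
]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of the study the simulator emulates.

    Defaults follow the reference design: 36 RILs and the two parents,
    sampled at 40, 96 and 214 hours, six parental replicates per age,
    mean lifespans ≈16 d (N2) and ≈13 d (CB4856); RIL lifespans are drawn
    uniformly between the parental means unless given explicitly.
    """

    n_rils: int = 36
    ages_hours: tuple[float, ...] = (40.0, 96.0, 214.0)
    parent_replicates_per_age: int = 6
    lifespans_hours: Mapping[str, float] = field(
        default_factory=lambda: {PARENT_N2: 16 * HOURS_PER_DAY, PARENT_CB: 13 * HOURS_PER_DAY}
    )
    ril_lifespan_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rils < 2:
            raise ValueError("need at least 2 RILs")
        ages = np.asarray(self.ages_hours, dtype=float)
        if len(ages) < 1 or np.any(np.diff(ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        lo, hi = self.lifespan_bounds()
        if lo <= max(ages):
            raise ValueError("lifespans must exceed the oldest sampling age")

    def lifespan_bounds(self) -> tuple[float, float]:
        if self.ril_lifespan_range is not None:
            return tuple(sorted(self.ril_lifespan_range))  # type: ignore[return-value]
        vals = [self.lifespans_hours[p] for p in PARENTS]
        return (min(vals), max(vals))

    @property
    def age_groups(self) -> tuple[str, ...]:
        return tuple(f"t{i + 1}" for i in range(len(self.ages_hours)))

    def ril_names(self) -> list[str]:
        return [f"RIL{i + 1:03d}" for i in range(self.n_rils)]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Genetic architecture of one simulated transcript (log2 scale)."""

    baseline: float = 6.0
    additive: Mapping[str, float] = field(default_factory=dict)
    epistatic: Mapping[tuple[str, str], float] = field(default_factory=dict)
    age_slope: float = 0.0
    age_by_marker: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.2
    name: str | None = None
    category: str | None = None  # optional ground-truth label (A/B/C/null)

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def referenced_markers(self) -> set[str]:
        out = set(self.additive) | set(self.age_by_marker)
        for i, j in self.epistatic:
            out.update((i, j))
        return out

    def validate_against(self, gmap: GeneticMap) -> None:
        unknown = self.referenced_markers() - set(gmap.markers)
        if unknown:
            raise ValueError(f"architecture references unknown markers {sorted(unknown)}")


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------

def haldane_recombination_fraction(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Meiotic recombination fraction r for a Haldane distance of ``d_cm``."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_switch_probability(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Probability that adjacent markers differ in a selfed RIL: R = 2r/(1+2r)."""
    r = haldane_recombination_fraction(d_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


def simulate_genotypes(design: StudyDesign, gmap: GeneticMap) -> GenotypePanel:
    """Simulate a fully inbred RIL panel on ``gmap`` and append the parents."""
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0]))
    n = design.n_rils
    blocks: list[np.ndarray] = []
    for chrom in gmap.chromosomes:
        pos = gmap.chromosome_table(chrom)["position_cm"].to_numpy()
        m = len(pos)
        chrom_geno = np.empty((n, m), dtype=np.int8)
        chrom_geno[:, 0] = rng.choice(np.array([-1, 1], dtype=np.int8), size=n)
        if m > 1:
            switch_p = ril_switch_probability(np.diff(pos))
            switches = rng.random((n, m - 1)) < switch_p  # broadcast over intervals
            signs = np.where(switches, -1, 1).astype(np.int8)
            chrom_geno[:, 1:] = chrom_geno[:, [0]] * np.cumprod(signs, axis=1)
        blocks.append(chrom_geno)
    ril_rows = np.concatenate(blocks, axis=1)
    strains = design.ril_names() + list(PARENTS)
    alleles = np.vstack(
        [
            ril_rows,
            np.full((1, gmap.n_markers), N2_ALLELE, dtype=np.int8),
            np.full((1, gmap.n_markers), CB_ALLELE, dtype=np.int8),
        ]
    )
    df = pd.DataFrame(alleles, index=strains, columns=gmap.markers)
    return GenotypePanel(alleles=df, gmap=gmap)


def draw_ril_lifespans(design: StudyDesign) -> dict[str, float]:
    """Strain → mean lifespan (h); RILs uniform in the configured range."""
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 1]))
    lo, hi = design.lifespan_bounds()
    out = dict(design.lifespans_hours)
    for name, u in zip(design.ril_names(), rng.uniform(lo, hi, design.n_rils)):
        out[name] = float(u)
    return out


# ----------------------------------------------------------------------
# expression
# ----------------------------------------------------------------------

def _sample_frame(design: StudyDesign, panel: GenotypePanel) -> pd.DataFrame:
    rows = []
    for strain in panel.rils:
        for age, group in zip(design.ages_hours, design.age_groups):
            rows.append((f"{strain}_{group}_r1", strain, age, group, 1))
    for parent in PARENTS:
        for age, group in zip(design.ages_hours, design.age_groups):
            for rep in range(1, design.parent_replicates_per_age + 1):
                rows.append((f"{parent}_{group}_r{rep}", parent, age, group, rep))
    df = pd.DataFrame(rows, columns=["sample_id", "strain", "age_hours", "age_group", "replicate"])
    return df.set_index("sample_id")


def simulate_expression(
    panel: GenotypePanel,
    design: StudyDesign,
    architectures: Sequence[ArchitectureSpec],
    lifespans: Mapping[str, float] | None = None,
) -> ExpressionStudy:
    """Generate an :class:`ExpressionStudy` from per-gene architectures.

    Deterministic under the design seed. ``lifespans`` overrides the drawn
    RIL lifespans (parents always come from the design).
    """
    for arch in architectures:
        arch.validate_against(panel.gmap)
    life = dict(lifespans) if lifespans is not None else draw_ril_lifespans(design)
    samples = _sample_frame(design, panel)
    missing = set(samples["strain"]) - set(life)
    if missing:
        raise ValueError(f"no lifespan for strains {sorted(missing)}")
    samples["phys_age"] = samples["age_hours"] / samples["strain"].map(life)

    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 2]))
    marker_pos = {m: k for k, m in enumerate(panel.gmap.markers)}
    G = panel.alleles.to_numpy(dtype=float)  # strains × markers
    strain_row = {s: i for i, s in enumerate(panel.strains)}
    srow = samples["strain"].map(strain_row).to_numpy()
    pa = samples["phys_age"].to_numpy()

    n_samples = len(samples)
    names = []
    mat = np.empty((len(architectures), n_samples))
    for gi, arch in enumerate(architectures):
        genetic = np.zeros(len(panel.strains))
        for m, a in arch.additive.items():
            genetic += a * G[:, marker_pos[m]]
        for (mi, mj), e in arch.epistatic.items():
            genetic += e * G[:, marker_pos[mi]] * G[:, marker_pos[mj]]
        age_gain = np.zeros(len(panel.strains))
        for m, c in arch.age_by_marker.items():
            age_gain += c * G[:, marker_pos[m]]
        mu = arch.baseline + genetic[srow] + (arch.age_slope + age_gain[srow]) * pa
        mat[gi] = mu + rng.normal(0.0, arch.noise_sd, n_samples)
        names.append(arch.name or f"g{gi + 1:05d}")
    expr = pd.DataFrame(mat, index=names, columns=samples.index)
    return ExpressionStudy(expr=expr, samples=samples, lifespans=life)


# ----------------------------------------------------------------------
# the three architecture categories
# ----------------------------------------------------------------------

def category_architectures(kind: str) -> Callable[..., ArchitectureSpec]:
    """Factory for the three architecture scenarios seen when comparing RIL
    linkage with parental differential expression.

    * ``A`` — one strong-effect locus: parent-differential and mappable.
    * ``B`` — many small same-direction loci: parent-differential, but no
      single locus is detectable.
    * ``C`` — loci with equal parental expectations (a pure epistatic pair
      by default, or two opposite additive effects): mappable and/or
      transgressive, parents equal.

    The returned factory takes ``(gmap, rng, **overrides)`` and draws the
    marker positions; effect sizes default to effect 1.0 / noise 0.2 for the
    single-locus categories and ten +0.05 effects for category B.
    """
    kind = kind.upper()
    if kind not in {"A", "B", "C"}:
        raise ValueError(f"unknown architecture category {kind!r}")

    def make_a(
        gmap: GeneticMap,
        rng: np.random.Generator,
        effect: float = 1.0,
        noise_sd: float = 0.2,
        baseline: float = 6.0,
        name: str | None = None,
    ) -> ArchitectureSpec:
        m = gmap.markers[rng.integers(gmap.n_markers)]
        return ArchitectureSpec(
            baseline=baseline, additive={m: effect}, noise_sd=noise_sd, name=name, category="A"
        )

    def make_b(
        gmap: GeneticMap,
        rng: np.random.Generator,
        n_loci: int = 10,
        effect_each: float = 0.05,
        noise_sd: float = 0.2,
        baseline: float = 6.0,
        min_sep_cm: float = 20.0,
        name: str | None = None,
    ) -> ArchitectureSpec:
        # loci are dispersed: round-robin over chromosomes, and within a
        # chromosome at least min_sep_cm apart — colocalized small effects
        # would merge into one mappable aggregate, which is category A, not B
        chrom_order = rng.permutation(len(gmap.chromosomes))
        picked: list[str] = []
        by_chrom: dict[str, list[float]] = {}
        ci = 0
        attempts = 0
        while len(picked) < n_loci:
            chrom = gmap.chromosomes[chrom_order[ci % len(chrom_order)]]
            tab = gmap.chromosome_table(chrom)
            j = rng.integers(len(tab))
            pos = float(tab["position_cm"].iloc[j])
            marker = tab["marker"].iloc[j]
            taken = by_chrom.setdefault(chrom, [])
            attempts += 1
            if marker not in picked and all(abs(pos - q) >= min_sep_cm for q in taken):
                picked.append(marker)
                taken.append(pos)
                ci += 1
            elif attempts > 100 * n_loci:
                raise ValueError("cannot place dispersed loci; relax min_sep_cm")
        return ArchitectureSpec(
            baseline=baseline,
            additive={m: effect_each for m in picked},
            noise_sd=noise_sd,
            name=name,
            category="B",
        )

    def make_c(
        gmap: GeneticMap,
        rng: np.random.Generator,
        effect: float = 1.0,
        noise_sd: float = 0.2,
        baseline: float = 6.0,
        mode: str = "epistatic",
        name: str | None = None,
    ) -> ArchitectureSpec:
        # two loci on different chromosomes so the pair segregates freely
        chroms = rng.choice(len(gmap.chromosomes), size=2, replace=False)
        picks = []
        for c in chroms:
            tab = gmap.chromosome_table(gmap.chromosomes[c])
            picks.append(tab["marker"].iloc[rng.integers(len(tab))])
        if mode == "epistatic":
            # parents: x_i·x_j = +1 for both, so parental expectations are equal
            return ArchitectureSpec(
                baseline=baseline,
                epistatic={(picks[0], picks[1]): effect},
                noise_sd=noise_sd,
                name=name,
                category="C",
            )
        if mode == "additive_opposite":
            return ArchitectureSpec(
                baseline=baseline,
                additive={picks[0]: effect / 2, picks[1]: -effect / 2},
                noise_sd=noise_sd,
                name=name,
                category="C",
            )
        raise ValueError(f"unknown category-C mode {mode!r}")

    return {"A": make_a, "B": make_b, "C": make_c}[kind]


def simulate_heritability_study(
    design: StudyDesign,
    h2_values: Sequence[float],
    n_genes_per: int = 1,
    total_sd: float = 1.0,
    baseline: float = 6.0,
    seed: int | None = None,
) -> tuple[ExpressionStudy, np.ndarray]:
    """Expression study with known broad-sense heritability per gene.

    For each target H² (repeated ``n_genes_per`` times), every strain gets a
    genotypic value ~ N(0, H²·total_sd²) shared by all its samples, and every
    sample adds environmental noise ~ N(0, (1−H²)·total_sd²). Ages carry no
    effect, so each single-age slice realizes the target exactly. Returns the
    study and the per-gene true H² vector.
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    life = draw_ril_lifespans(design)
    strains = design.ril_names() + list(PARENTS)
    rows = []
    for strain in design.ril_names():
        for age, group in zip(design.ages_hours, design.age_groups):
            rows.append((f"{strain}_{group}_r1", strain, age, group, 1))
    for parent in PARENTS:
        for age, group in zip(design.ages_hours, design.age_groups):
            for rep in range(1, design.parent_replicates_per_age + 1):
                rows.append((f"{parent}_{group}_r{rep}", parent, age, group, rep))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "strain", "age_hours", "age_group", "replicate"]
    ).set_index("sample_id")
    samples["phys_age"] = samples["age_hours"] / samples["strain"].map(life)
    srow = samples["strain"].map({s: i for i, s in enumerate(strains)}).to_numpy()
    truth = np.repeat(np.asarray(h2_values, dtype=float), n_genes_per)
    mat = np.empty((len(truth), len(samples)))
    for gi, h2 in enumerate(truth):
        sg = np.sqrt(h2) * total_sd
        se = np.sqrt(1.0 - h2) * total_sd
        gvals = rng.normal(0.0, sg, len(strains)) if sg > 0 else np.zeros(len(strains))
        mat[gi] = baseline + gvals[srow] + rng.normal(0.0, se, len(samples))
    expr = pd.DataFrame(
        mat, index=[f"h2gene{i + 1:05d}" for i in range(len(truth))], columns=samples.index
    )
    return ExpressionStudy(expr=expr, samples=samples, lifespans=life), truth


def simulate_study(
    design: StudyDesign,
    gmap: GeneticMap | None = None,
    architectures: Sequence[ArchitectureSpec] | None = None,
    n_null_genes: int = 0,
    noise_sd: float = 0.2,
) -> tuple[GenotypePanel, ExpressionStudy]:
    """Convenience wrapper: map → genotypes → expression in one call.

    ``n_null_genes`` appends pure-noise transcripts (no genetic or age
    effects) after the supplied architectures.
    """
    gmap = gmap or GeneticMap.evenly_spaced()
    panel = simulate_genotypes(design, gmap)
    archs = list(architectures or [])
    archs += [
        ArchitectureSpec(noise_sd=noise_sd, name=f"null{i + 1:05d}", category="null")
        for i in range(n_null_genes)
    ]
    if not archs:
        raise ValueError("no architectures to simulate")
    return panel, simulate_expression(panel, design, archs)
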