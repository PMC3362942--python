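# Methods

This note records the statistical models the package implements, the
estimator and design choices that were genuinely open, and what the
synthetic data does and does not emulate.

## Study design and physiological age

The default design mirrors a two-parent *C. elegans* RIL transcriptome
study: 36 fully inbred lines derived from N2 × CB4856, genotyped at 121
evenly spaced SNP markers on six chromosomes, with expression sampled at
40 h (t1, late L4), 96 h (t2, reproductive) and 214 h (t3, old). Parents
contribute six replicates per age; RILs one sample per age. Two-age
analysis windows are fixed: *developing* = {t1, t2}, *aging* = {t2, t3}.

Because mean lifespan differs between lines (defaults 384 h for N2, 312 h
for CB4856; RIL lifespans drawn uniformly between the parental means unless
supplied), a fixed chronological age corresponds to different physiological
stages. All two-age models therefore use physiological age
`pa = age_hours / mean_lifespan_hours`, a dimensionless quantity in (0, 1)
for the ages above (0.104 for N2 at t1 up to 0.686 for CB4856 at t3).

## Genotype simulation

Each RIL chromosome is a two-state Markov chain over {−1 (CB4856), +1
(N2)}: the first allele is equiprobable, and between adjacent markers d cM
apart the parent-of-origin switches with probability R = 2r/(1+2r), where
r = (1 − e^(−2d/100))/2 is the Haldane recombination fraction. The 2r/(1+2r)
map expansion is the standard closed form for a selfed RIL, where
recombination accumulates over the inbreeding generations. Chromosomes are
independent; residual heterozygosity is zero. The map function is a
modelling choice (the marker spacing in cM of the real panel is not part of
the default configuration; 50 cM chromosomes with even spacing are used).

## Expression simulation

For gene g, strain s, age t:

    y = baseline + Σ a_m x_sm + Σ e_ij x_si x_sj + b·pa + Σ c_m x_sm·pa + ε,
    ε ~ N(0, noise_sd²)

on the log2 scale (the analyses operate on log2 normalized intensities, so
Gaussian noise on that scale is the natural choice). Three architecture
factories generate the canonical scenarios seen when RIL linkage is
compared with parental differential expression:

* **A** — one strong locus (default effect 1.0, noise 0.2): the parents
  differ by 2×effect and the locus is mappable.
* **B** — ten same-direction effects of +0.05 (parent gap 1.0 log2 units,
  per-locus gap 0.1): parent-differential but no locus is individually
  detectable. The loci are deliberately *dispersed* — round-robin over
  chromosomes, ≥ 20 cM apart within one — because colocalized small effects
  merge into a single mappable aggregate, which is scenario A, not B.
* **C** — equal parental expectations: by default a pure epistatic pair
  (effect 1.0) on two chromosomes — both parents carry x_i x_j = +1, so only
  recombinant genotypes reveal the effect — or optionally two opposite
  additive effects. These genes are mappable and/or transgressive with
  identical parents.

Noise is a per-gene constant (default SD 0.2 log2 units) independent of the
architecture category: residual noise in real data has no reason to depend
on a gene's regulatory architecture.

What the generator does **not** emulate: probe-level microarray artifacts,
dye effects, array normalization residue, correlated noise across genes
(each gene's noise is independent), gene–gene regulatory correlation, and
lifespan measurement error. Passing calibration on this generator shows the
estimators are correct under their assumptions, not that real microarray
noise is benign.

## Outlier handling

Two screens, applied by default to the replicated parental samples only
(the context where replicate-based screening is well defined):

1. per gene × age group, values outside mean ± 2 SD are masked (single
   pass; needs ≥ 3 values);
2. per gene × genotype × two-age window, expression is regressed on the
   age-group factor and the single most extreme *externally studentized*
   residual outside the two-sided 0.995 interval is removed, recursively,
   at most six removals. The residual type is a choice; externally
   studentized residuals are the standard deletion diagnostic for exactly
   this procedure. The middle age group belongs to both windows and is
   masked if either window's screen removed it (union rule).

Masked values become missing and are dropped per fit (pairwise-complete),
never imputed. On Gaussian null data the recursive screen removes well
under 1% of values on average at conf = 0.995.

## Single-marker models and scores

Model 1 regresses one gene's expression on one ±1 marker within one age
group — algebraically the equal-variance two-group t test; the reported
effect is the slope on the ±1 coding (half the group-mean difference).
Model 2 adds physiological age and the marker × age product over a two-age
window; each term is scored by its coefficient's two-sided t p-value.
Scores are −log10 p capped at 300 (double-precision p-values underflow
around 10⁻³⁰⁸); degenerate fits follow fixed conventions instead of NaN:
constant expression → score 0 and effect 0; zero residual variance with a
non-zero coefficient → the cap; a monomorphic marker or rank-deficient
design → an untestable record with score 0. With constant physiological age
model 2 collapses to model 1 on the pooled samples.

Peak calling is per gene × term × window at the maximum-score marker
("genes with an eQTL", not per-marker calls), at thresholds −log10 p = 3
for RIL eQTL and 2 for parental contrasts; the physiological-age term uses
8 (developing) / 6 (aging) in the pipeline defaults.

## Permutation FDR

FDR(t) = mean permuted count of genes with peak ≥ t / observed count,
clipped to [0, 1]; 1 when nothing is observed but permutations call genes;
undefined when both sides are empty. Permutations relabel whole sample
columns, never values within a gene, so the gene × gene covariance is
untouched. Relabelling is **design-preserving**: strain labels are shuffled
among the samples of each age group (every labelled strain keeps exactly
its per-age sample count), and for model 2 the age labels are additionally
shuffled within each relabelled strain, independently. The stratification
matters: an unstratified global shuffle changes the realized design
(duplicate/missing genotypes per age), which measurably deflates permuted
peak scores and biases the null FDR below 1.

The joint-FDR pairs independent parental and RIL permutations (30 by
default) and counts genes passing both thresholds; a product-rule
approximation (universe × marginal pass rates) is reported alongside.

## Heritability

Single age: H² = (V_RIL − V_P)/V_RIL with V_RIL the (n−1)-denominator
variance of one value per RIL and V_P the replicate-df-weighted pool of the
two parents' within-line variances. H² ≤ 1 by construction; negative values
(sampling noise) are retained in tables and excluded only from
threshold-crossing counts. With R RILs the estimator's expectation is
1 − (1−H²)(R−1)/(R−3), the basis of the recovery calibration.

Over time, the target is the genotype effect on the expression *pattern*
with the genotype × age interaction excluded. V_RIL is the variance across
RILs of each line's two-age mean: the age main effect cancels in a
between-line variance, and a crossing interaction cancels inside the mean.
V_P must then be the parental environmental variance *on the same scale* —
the within-line variance of a mean of two ages — so the pooled age-centered
replicate variance is divided by two. (Leaving it undivided compares a
two-age-mean variance against a single-sample variance and biases H²
downward; with genetic variance σg² and per-sample environmental variance
σe², the implemented estimator centres on σg²/(σg² + σe²/2).) The
alternative operationalization — an ANOVA genotype mean square — was
considered and not mixed in; the variance-of-means estimator is the
simplest one satisfying the stated exclusion.

High-H² cutoffs: per permutation, strain labels are shuffled within each
age group and the full H² vector recomputed; the cutoff is the smallest
observed (positive) H² at which mean-permuted/observed counts ≤ the target
FDR (0.01, 100 permutations). At FDR = 1 this degenerates to the smallest
positive observed value.

## Transgression

Per gene and age the upper bound is mean + 2 SD of the higher-mean parent's
replicates, the lower bound mean − 2 SD of the lower-mean parent's; parents
are ranked per gene per age and may swap. RILs strictly beyond a bound
count (ties do not); a gene is transgressive when ≥ 6 RILs clear one bound.
Over a two-age window a RIL counts only if it clears the age-specific bound
in the same direction at both ages — the sharp version of the statistic:
independent noise must clear both bounds, so the single-age base rate
(tens of percent) collapses to near zero under the null while true
epistatic/opposing-effect genes persist. The permutation FDR shuffles
RIL/parent strain labels within each age group.

## Multi-marker models

Candidates: 4 markers per chromosome (24 total) maximizing the minimum
pairwise genetic distance (exhaustive per chromosome; ties broken toward
lower positions, then lexical ids — on an equally spaced chromosome this
keeps the first endpoint but not necessarily the last), all 276 unordered
pair products, physiological age, and all 24 marker × age products. No
heredity constraint: a pure epistatic pair must be able to enter
interaction-first.

Search: start from the age-only model; per step take the single best move —
add the candidate with the largest BIC decrease (computed exactly via
residualization of all absent candidates against the current design) or
remove the selected term whose removal most decreases BIC — stopping when
no move decreases BIC, at 2000 steps, or at 6 explanatory variables.
BIC = n·ln(RSS/n) + k·ln(n), k counting all coefficients including the
intercept; RSS is floored at 1e−10 so exact fits keep BIC finite. Ties
prefer removal, then the earlier candidate in the fixed ordering, making
selection fully deterministic (no RNG anywhere in the search). A full-model
start (325 candidate coefficients against ~72 samples) is rank-deficient
and unfittable, which is why the candidate set is a search space, not a
start model.

**Known limitation.** With ~324 admissible candidates at n = 72, the best
single candidate under a pure-noise gene is the maximum of hundreds of
near-χ²₁ statistics (≈ 10–12), which always exceeds the ln(72) ≈ 4.28
per-coefficient BIC entry penalty. Plain BIC stepwise therefore selects
spurious terms for essentially every noise gene at this sample size; its
model-selection consistency is an asymptotic property that does not hold at
this n-to-candidate ratio. The search is kept as specified (the selection
criterion is part of the method's definition); selected term sets at n = 72
should be read as descriptive best-fit models, not as evidence of distinct
regulators — between-condition *contrasts* of selection rates (e.g.
epistasis terms in aging vs developing windows) remain meaningful because
the spurious-selection floor is common to both. Relatedly, with 36 lines a
genome-wide single-marker peak can capitalize on sample LD between markers
and a gene's aggregate genotypic value, so even architectures whose
individual loci are far below detection (category B) map more often than
orthogonal per-locus arithmetic suggests; the calibration suite measures
this rate rather than assuming it away.

## Enrichment

Upper-tail hypergeometric probability per term (scipy's exact sf), terms
with fewer than two genes in the universe discarded, no multiple-testing
correction by default (α = 0.01; Bonferroni available). The universe
defaults to the genes on the expression matrix, not all annotated genes.

## Calibration experiment sizes

The calibration suite (`agemap.calibration`, also behind
`scripts/acceptance.py`) uses: 100 random instances for the model-1 oracle
check; 1,000 null genes with 100 permutations for null calibration; 5,000
genes for heritability recovery; 500 genes (10% epistatic) with 100
permutations for transgression; 100 genes per architecture category; 100
noise genes for stepwise sanity; and every hypergeometric configuration
with universe ≤ 12. These sizes give Monte-Carlo errors comfortably inside
the asserted tolerances while keeping the whole suite in the tens of
seconds on one CPU.
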