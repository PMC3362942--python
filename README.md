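# agemap

Age-aware expression-QTL analysis for two-parent recombinant inbred line
(RIL) panels, built around the *C. elegans* N2 × CB4856 design: 36 RILs and
the two parental wild types profiled at three ages (40 h, 96 h, 214 h) on
121 SNP markers across six chromosomes.

Strains age at different absolute rates (mean lifespan ≈16 d for N2, ≈13 d
for CB4856), so the package analyses expression against **physiological
age** — chronological age divided by the strain's mean lifespan — and asks
how the genetic architecture of transcript abundance changes as animals
age: do strong single loci keep explaining expression, or does regulation
become polygenic and epistatic?

## What it computes

For each transcript (log2 expression):

* **Single-marker linkage** (model 1, per age group):
  `expression = marker + error`, scored as −log10 p of the marker t
  statistic. The same code path with a strain-identity pseudo-marker gives
  parental differential expression.
* **Age-resolved linkage** (model 2, two age groups):
  `expression = marker + physiological age + marker × physiological age +
  error`, separating genotype, age and genotype-by-age (g×a) effects over
  the *developing* (t1+t2) and *aging* (t2+t3) windows.
* **Permutation thresholds**: genome-wide plug-in FDR at a score cutoff
  (sample labels shuffled design-preservingly; default 100 permutations)
  and the **joint-FDR** for genes passing both the parental (−log10 p ≥ 2)
  and eQTL (−log10 p ≥ 3) thresholds by chance (30 permutation pairs).
* **Broad-sense heritability**: H² = (V_RIL − V_P)/V_RIL with V_RIL the
  among-line RIL variance and V_P the pooled within-line parental variance;
  a two-age variant isolates the genotype effect on expression *patterns*
  (interaction excluded); permutation-derived high-H² cutoffs at FDR 0.01.
* **Transgressive segregation**: genes where ≥ 6 RILs exceed the
  higher/lower parent's mean ± 2 SD (per age, or at both ages of a window),
  with a permutation FDR on the count threshold.
* **Multi-marker models**: forward/backward stepwise BIC over 24 spaced
  markers (4 per chromosome), all marker-pair (epistasis) products,
  physiological age and marker × age terms — at most 6 explanatory
  variables, 2000 steps.
* **Overlap categories** (parents × RILs): **A** parent-differential with
  an eQTL, **B** parent-differential without one (dispersed small effects),
  **C** eQTL without parental difference (opposing/epistatic effects,
  transgression-prone); plus % -of-genes-with-eQTL profiles by H² bin.
* **Enrichment**: hypergeometric over-representation of gene sets against
  any annotation table (terms with < 2 genes discarded, α = 0.01).

A synthetic-study generator (`agemap.simulate`) produces RIL panels via a
Haldane map function with the selfed-RIL expansion R = 2r/(1+2r), and
expression from configurable additive/epistatic/age-interacting
architectures — including factories for the A/B/C categories — so the whole
pipeline is testable without any microarray download.

## Worked example

```python
import numpy as np
from agemap import (GeneticMap, StudyDesign, simulate_genotypes,
                    simulate_expression, category_architectures, map_genome)

gmap = GeneticMap.evenly_spaced()            # 121 markers, 6 chromosomes
design = StudyDesign(seed=1)                 # 36 RILs, ages 40/96/214 h
panel = simulate_genotypes(design, gmap)

rng = np.random.default_rng(0)
archs = [category_architectures("A")(gmap, rng, name=f"a{i}") for i in range(5)]
study = simulate_expression(panel, design, archs)

tab = map_genome(study, panel, model=1, window="t1")   # RIL eQTL scan at t1
print(tab.calls[["gene", "peak_marker", "score"]])
```

prints (strong single-locus genes map at or next to their causal marker;
scores are −log10 p, called at the genome-wide threshold of 3):

```
  gene peak_marker      score
0   a0        Xm01  22.467958
1   a1       IVm17  23.436010
2   a2       IVm01  23.733206
3   a3       IIm12  25.807068
4   a4       IIm17  24.185904
```

The full pipeline — simulation, outlier masking, both models for RILs and
parents, FDR/joint-FDR, heritability, transgression, multi-marker models
and the category tables — runs from one command:

```bash
agemap run --out-dir out/           # or: agemap run --config config.yaml
agemap simulate --n-rils 36 --n-genes 100 --seed 1 --out-dir sim/
agemap map --model 2 --window developing --expr ... --genotypes ...
```

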