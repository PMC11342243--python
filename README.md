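# braintx

Imaging–transcriptomics association analysis for major depressive disorder
(MDD): identify genes whose spatial expression tracks case–control brain
imaging differences, classify them by directional effect, and characterize
the resulting gene classes by protein-interaction network topology,
temporal–spatial expression specificity, gene-set enrichment and sex
differences. Every pipeline input can be generated synthetically with known
ground truth, so the whole analysis is testable end to end without any
external data download.

## Who this is for

Researchers linking brain-wide transcriptomic atlases (genes × tissue-sample
sites) to macroscopic neuroimaging phenotypes — resting-state functional
indices (ALFF, fALFF, ReHo) and grey matter density (GMD) — and anyone who
wants a reproducible, seeded reference implementation of the
permutation-null Spearman selection rule and the SPI/DPI specificity
measures on developmental expression data.

## The method

**Contrast maps.** For each imaging index, a per-site two-sided two-sample
*t* statistic contrasts cases with controls (positive *t* = higher in
cases), with Benjamini–Hochberg control across sites.

**Gene selection.** For gene *g* with spatial expression profile
*x<sub>g</sub>* and contrast map *t*, compute Spearman's ρ(*x<sub>g</sub>*, *t*)
and a two-sided permutation p-value by shuffling the map across sites:

    p = (1 + #{ |ρ_perm| ≥ |ρ_obs| }) / (n_perm + 1)

A gene is *depression-related* when p < α for GMD **and** for at least one
of ALFF/fALFF/ReHo (defaults α = 0.001, n_perm = 10,000). Selected genes
split by directional effect: **Class 1** (ρ<sub>GMD</sub> < 0, significant
functional ρ > 0), **Class 2** (the mirror image); mixed-sign genes stay
unclassified, non-selected genes are controls.

**Specificity.** For a nonnegative expression profile
X = (x₁, …, x<sub>n</sub>), the specificity index of sample *i* is
SPI<sub>i</sub> = x<sub>i</sub>/‖X‖₂ (a cosine, so Σ SPI<sub>i</sub>² = 1),
and the dispersion index

    DPI = sqrt( n · Σᵢ (SPIᵢ − mean(SPI))² / (n − 1) )

lies in [0, 1]: 0 for uniform expression, 1 for single-sample
concentration, invariant to expression level and sample count. Temporal
DPI uses per-period mean profiles (8 developmental periods), spatial DPI
per-region means (16 brain regions).

**Characterization.** Class overlaps with reference lists (post-mortem
downregulated genes, GWAS risk genes) as percentages with raw counts;
accumulative hypergeometric term enrichment filtered at adjusted p < 0.01,
count ≥ 3, enrichment factor > 1.5; degree / unnormalized betweenness /
clustering coefficient on the combined_score > 900 interaction graph; and
female-vs-male differential expression across shared developmental periods.

## Worked example

```python
from braintx.simulate import (make_ground_truth, default_effect_maps,
                              gen_imaging_cohort, gen_expression_matrix)
from braintx.imaging import group_difference_map
from braintx.association import (identify_depression_genes,
                                 classify_directional, class_counts)
from braintx.types import INDICES

truth = make_ground_truth(seed=1)                      # 150 / 200 planted genes
effects = default_effect_maps(n_sites=200, seed=1)
cohort = gen_imaging_cohort(200, n_per_group=100, effect_maps=effects, seed=1)
maps = {name: group_difference_map(cohort[name]) for name in INDICES}
expr = gen_expression_matrix(2000, list(cohort["ALFF"].values.columns),
                             truth, corr_strength=0.8, seed=1)
records, selected = identify_depression_genes(expr, maps, alpha=0.001,
                                              n_perm=1000, seed=1)
cls = classify_directional(records, selected, alpha=0.001)
counts = class_counts(cls)
print(f"selected: {len(selected)} depression-related genes")
print(f"Class 1: {counts['Class1']}  Class 2: {counts['Class2']}  "
      f"total: {counts['depression_related']}")
c1 = set(cls.index[cls["class"] == "Class1"])
print(f"Class-1 sensitivity: {len(c1 & truth.class1_genes) / 150:.3f}")
```

prints

```
selected: 351 depression-related genes
Class 1: 151  Class 2: 200  total: 351
Class-1 sensitivity: 1.000
```

i.e. all 150 planted Class-1 and 200 planted Class-2 genes are recovered
(one null gene slips in, a false-discovery rate under 1%), and every
recovered gene carries the planted sign pattern.

The same analysis runs from the shell, stage by stage or end to end:

```sh
braintx full-run --workdir run/ --seed 1 --simulate
```

which writes the contrast maps, classification, overlap, enrichment,
topology, DPI and sex-difference tables plus a manifest into `run/`.

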