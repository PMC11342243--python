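# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Imaging contrasts

Each imaging index (ALFF, fALFF, ReHo, GMD) arrives as a subject × site
table with case/control labels. The contrast is a per-site two-sided
two-sample *t* (positive = higher in cases). Pooled-variance Student's *t*
is the default because it is the conventional neuroimaging group statistic;
Welch's *t* is available via `variant="welch"` since nothing in the problem
forces equal variances. Benjamini–Hochberg adjustment runs across sites
with significance declared strictly below the threshold (default
q = 0.001). Sites where both groups have zero variance are resolved by the
mean difference (p = 0 if the means differ, 1 otherwise) and logged —
silent NaNs would otherwise propagate into the association stage.

No subject-level covariate regression (age, sex, scanning site) is
performed: the pipeline operates on per-site scalars that are assumed
already harmonized upstream.

## Gene selection by permutation-null Spearman correlation

Spearman's ρ (average ranks for ties) links each gene's spatial expression
profile to each contrast map. The permutation null shuffles the map across
sites; the two-sided p-value carries an add-one correction,
p = (1 + #{|ρ_perm| ≥ |ρ_obs|})/(n_perm + 1), so p is never zero and the
α = 0.001 threshold is exactly attainable at 10,000 permutations
(min p = 1/10,001). A gene is selected when p < α for GMD **and** for at
least one functional index.

Numerical implementation: ρ is the Pearson correlation of rank vectors, so
the full null ensemble for all genes against one map is a single matrix
product of standardized rank matrices — 2,000 genes × 1,000 permutations ×
200 sites runs in well under a second. By default one seeded permutation
set is shared by all genes within an index (bit-reproducible and fast);
per-gene independent permutation sets are available with
`shared_permutations=False`. The two modes have identical marginal
p-values; they differ in the *joint* distribution across genes — with a
shared set, false positives cluster, so calibration experiments that lean
on independence across genes (e.g. binomial error bars on a selection
rate) must use the independent mode.

Two properties of this null are deliberate: it does **not** preserve
spatial autocorrelation (no spin-test surrogate — site labels are treated
as exchangeable), and constant expression rows yield a flagged missing ρ
rather than an arbitrary value.

Classification uses only *significant* functional correlations: Class 1
requires ρ_GMD < 0 and every significant functional ρ > 0, Class 2 the
mirror image. A selected gene whose significant functional signs disagree
is reported as `unclassified` rather than forced into a class; the class
tables therefore always partition selected genes into
Class1/Class2/unclassified.

## Gene-set characterization

Differential expression on case/control sample matrices is a per-gene
two-sided *t*-test filtered at p < 0.01; "down" means case mean below
control mean. Overlap of a gene class with a reference list is reported as
100·|class ∩ reference|/|class| to two decimals, always accompanied by the
raw counts so the arithmetic is auditable. Term enrichment is the
accumulative (upper-tail) hypergeometric p with BH adjustment across terms
(a method flag exposes the other `statsmodels` adjustments), and a term
"passes" only with adjusted p < 0.01, overlap count ≥ 3 and enrichment
factor (count/set_size)/(bg_count/bg_size) > 1.5.

## Network topology

The interaction graph keeps edges with combined_score strictly greater
than 900 (STRING's 0–1000 confidence scale), collapses duplicate
orientations to the maximum score and drops self-loops. Per node:
degree; betweenness centrality unnormalized over unordered pairs
(Σ σ_st(v)/σ_st — raw shortest-path counts, since only group comparisons
are of interest a normalization flag exists); clustering coefficient
2·triangles/(k(k−1)). Class comparisons are two-sided t-tests per metric.
Genes absent from the thresholded graph are excluded from comparisons by
default — interaction databases have partial coverage and zero-filling
would manufacture a degree difference — but `include_missing_as_zero=True`
provides the other convention.

## SPI and DPI

SPI embeds a nonnegative profile X on the unit sphere
(SPI_i = x_i/‖X‖₂, the cosine between X and its single-sample axis
embedding); DPI = sqrt(n·Σ(SPI_i − mean SPI)²/(n−1)) condenses the profile
into a 0–1 dispersion score. DPI is invariant to positive scaling and
coordinate permutation, equals 0 exactly for uniform profiles and 1
exactly for delta profiles, and transferring mass toward the peak never
decreases it (verified numerically). Inputs must be nonnegative and not
all zero — a cosine specificity on signed (z-scored) data would be
meaningless, so SPI/DPI always runs on raw developmental expression, never
on the normalized imaging-association matrix.

Temporal and spatial profiles are per-level **means over samples** (8
periods, 16 regions) before DPI. The alternative — one coordinate per
sample — would make DPI depend on how many samples each period/region
happens to have; per-level means are the only reading under which the
index is genuinely independent of sampling depth. Genes silent everywhere
yield NaN DPI and are dropped from group comparisons.

Overexpression grids compute, per (period, region) cell, each gene's mean
expression over the cell's samples, then a two-sided t-test of class genes
vs control genes (positive t = class higher). Cells without samples are
flagged missing, not errors. The significance threshold for grids defaults
to 0.01, with the stricter 0.001 available — both appear in practice and
neither is privileged by the implementation.

## Sex differences

Per gene, expression is pooled over the periods sampled in **both** sexes
and compared female vs male with one two-sided t-test (p < 0.01 default).
Restricting to shared periods prevents period composition from
masquerading as a sex effect; pooling matches the single p-value per gene
that the downstream percentage summaries need. Per-class percentages of
female-high vs male-high genes sum to 100 within each class; classes with
no sex-different genes are reported as missing. The sex overexpression
grid contrasts per-gene female-minus-male differences between the
sex-different genes and control genes within each cell — differencing
removes regional baselines shared by the sexes.

## Synthetic data: what it emulates and what it does not

The generators plant known structure at desk scale (defaults: 200 sites,
2,000 genes, 150 Class-1 / 200 Class-2, 100 subjects per imaging group,
8 × 16 × 4 developmental samples, 2,000-node network) so that every
downstream stage can be scored against ground truth in minutes.

* **Imaging/expression coupling.** All four effect maps share one latent
  per-site pattern b: functional maps are positive multiples of b (plus a
  small independent component), the GMD map a negative multiple — function
  up where grey-matter density is down. A Class-1 gene's profile is
  corr_strength·z(b) + sqrt(1−corr_strength²)·noise (Class-2 negated), so
  one profile carries all four sign constraints with Spearman magnitude
  controlled by corr_strength (default 0.8); non-planted genes are pure
  noise. Because the maps share b, a null gene lucky against b correlates
  with *all* indices at once — the GMD-AND-functional rule protects
  against independent noise, not against this shared-pattern null; the
  calibration experiments therefore use zero-effect cohorts whose four
  t-maps are mutually independent.
* **Developmental expression.** Nonnegative (Gaussian noise on a baseline
  of 5, clamped at 0, noise SD 1). Non-planted genes carry random
  period-to-period modulation (SD 0.75 on the baseline) — real genes are
  not flat in time — while region-specific planted genes are temporally
  flat with a +4 boost in their target region across all periods, giving
  them the high-spatial/low-temporal DPI signature; period-specific genes
  mirror this. Sex-biased genes get a +1 (1 noise SD) shift in the labeled
  sex. Sexes alternate within and across cells so both are present in
  every (period, region) cell when n_per_cell ≥ 2.
* **Interaction network.** Edge endpoints drawn proportionally to
  attachment weights (hubs 20, Class-1 genes 0.3, others 1; mean degree
  12 before thresholding), scores uniform on [700, 1000] so roughly a
  third of edges survive the >900 filter with the periphery structure
  intact.
* **Reference lists.** Each class gene enters a list independently with
  its configured rate (defaults 0.2 / 0.1 / 0.05 for Class 1 / Class 2 /
  control), padded with out-of-universe ids to a fixed size.

Not emulated: MRI geometry and preprocessing, donor/batch structure of
microarray data, spatial autocorrelation of brain maps, linkage structure
of GWAS hits, and realistic scale (the real analyses run on ~15,000 genes,
~1,300 sites and ~10,000 permutations; the generator's defaults keep the
full test suite and recovery experiments within minutes while preserving
the proportions between planted classes and the control pool). Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the stated generative model, not robustness to the
autocorrelated, batch-confounded structure of real atlas data — in
particular, the naive permutation null is anticonservative on spatially
smooth maps, which is a property of the method itself.

## Numerical choices and degenerate inputs

* Probe filtering retains probes above background in exactly half the
  sites (the elimination rule targets strictly-more-than-half failures);
  representative-probe ties break to the lexicographically smallest probe
  id for determinism.
* Scaled robust sigmoid: sigmoid((x − median)/(IQR/1.35)) then min–max to
  [0, 1]; zero-IQR rows return all 0.5 with a warning. The normalization
  chain (donor centering → SRS → z-score) is order-preserving per row but
  not exactly idempotent (the sigmoid is nonlinear); re-normalizing a
  normalized matrix reproduces the rank order and the mean-0/SD-1 row
  invariant, which is what downstream rank statistics consume. Donor
  centering replaces model-based batch removal: the post-condition —
  aggregated sites show no additive inter-donor disparities — is what the
  tests assert. Donors contributing one site are skipped (offset
  unidentifiable) and logged.
* All randomness flows from one root seed through named substreams
  (`_stats.substream`), so stages are independently re-runnable and
  bit-reproducible; re-running a stage never perturbs another stage's
  draws.

## Known limitations

* The permutation null treats sites as exchangeable; no
  autocorrelation-preserving surrogate is provided by design.
* Betweenness for graphs at the scale of full interactomes uses exact
  Brandes computation; no approximation is implemented.
* The enrichment stage takes annotation term sets as input (GMT); there is
  no ontology handling or live database access.
* Mixed-sign selected genes are surfaced as `unclassified`; analyses that
  assume the two classes exhaust the selection should check that count.
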