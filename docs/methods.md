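# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the synthetic-data model, and the limits of what the test
suite demonstrates.

## Coordinates and conventions

Input files follow their native conventions — methratio tables and GFF3
are 1-based inclusive, BED and collinear-block TSVs 0-based half-open.
Internally every interval is 0-based half-open and every site keeps its
1-based `pos` as read; selection converts at the boundary. All writers
convert back. This single documented convention is the guard against
off-by-one drift between layers.

CG sites are kept per strand throughout (matching per-strand methratio
rows); symmetric-CG merging is deliberately not performed, since every
downstream statistic pools counts anyway and merging would only
redistribute them.

## Weighted methylation and methylcytosine calling

The level of any region is the weighted methylation level
w = (Σ #C)/(Σ #C + #T) over covered cytosines of the requested context.
Pooling weights deep sites more, so no per-site coverage floor is applied
for regional levels; an empty selection is *missing* (NaN), never zero.

Methylcytosine calling tests each site against the null that all its C
reads are bisulfite non-conversion failures: upper-tail
P(X ≥ c | n = coverage, p = 1 − conversion rate), Benjamini–Hochberg
adjusted across all tested sites, called at q ≤ 0.05 by default. Sites
with coverage < 4 are not tested: a binomial test on fewer than 4 reads
has essentially no power and only inflates the multiple-testing burden.
The conversion rate comes from an unmethylated spike-in genome as
(Σ #T)/(Σ #C + #T) and must exceed 0.5 to be meaningful.

Metaprofiles use 20 body bins and 20 bins per 2-kb flank by default
(configurable); bodies are rescaled so a site at body fraction f lands in
bin ⌊f · n_bins⌋, which handles features shorter than the bin count by
fractional overlap. Bin 0 is always the 5′-most upstream bin; minus-strand
features are mirrored before accumulation.

## DMR calling

Analysis is restricted to collinear regions (aligner blocks with score
strictly > 2000, merged per genome side) because cross-genome methylation
differences over non-shared sequence are not interpretable. Merged regions
are tiled into 100-bp windows; a terminal remainder window is kept and
flagged. Windows need ≥ 4 covered cytosines of a context in *every*
replicate to be tested for that context (exclusion is per context).

The test is the classic equal-variance one-way ANOVA on replicate window
levels — for two groups identically t² of the pooled-variance t-test, an
identity the suite verifies on random fixtures. A window is a DMR iff
p ≤ α (default 0.05, raw; BH-adjusted mode by flag) **and** the absolute
group-mean difference strictly exceeds the context threshold (0.4 for
CG/CHG, 0.1 for CHH). The difference thresholds are the primary filter;
α on raw p is secondary, which is why raw α is the default. Windows with
zero within-group variance resolve deterministically (p = 1 if the means
agree, p = 0 otherwise). Each passing window is one DMR; adjacent passing
windows are *not* merged, so DMR counts are window-granular.

Cross-genome comparison maps tetraploid calls into diploid (query)
coordinates through the affine offset of the enclosing collinear block;
inverted blocks reverse coordinates and flip strand. Genes whose body
± 2 kb overlaps ≥ 1 DMR (half-open, ≥ 1 bp) are DMGs; DMR genomic
distribution uses the precedence gene body > upstream 2 kb >
downstream 2 kb > TE > intergenic.

## Expression normalization and the DE surrogate

FPKM = counts · 10⁹ / (gene length · library size). TMM factors follow
the published trimmed-mean-of-M-values recipe: per-gene
M = log₂ ratio of library-size-scaled proportions against a reference
column (the one whose 75th count-proportion percentile is closest to the
mean of those percentiles), A = mean log₂ proportion, genes zero in
either column dropped pairwise; trim 30% total on M (15% per tail) and 5%
total on A (2.5% per tail); the factor is 2 to the precision-weighted
mean of surviving M values, and factors are rescaled to geometric mean 1.
Columns where fewer than `min_genes` (default 10) genes survive the trims
fall back to factor 1 with a warning. Factors act on the library size
inside the FPKM denominator, i.e. normalization precedes FPKM on the
count scale.

Differential expression is a deliberate surrogate for a full
negative-binomial GLM: Welch t per gene on log₂(TMM-scaled FPKM + 0.5),
BH adjustment, status gated at |log₂FC| ≥ 1 (inclusive) and adjusted
p < 0.05 (exclusive). The 0.5 pseudocount keeps fold changes finite at
zeros. This model is deterministic, dependency-free and has ample power
at the ≥ 4-fold planted effects the synthetic benchmarks use; it is *not*
a substitute for shrinkage estimators on marginal real-data effects, and
its output metadata labels it accordingly.

Cross-species normalization (needed for parent-vs-polyploid contrasts)
estimates TMM factors on the homoeolog-matched quartet universe only —
diploid entries are the quartet's gene counts, tetraploid entries the
At + Bt sum — because TMM assumes a shared, majority-unchanged gene set,
which holds for matched single-copy quartets but not for whole genomes of
different ploidy.

## Bias and ELD classification

Per expressed quartet (mean FPKM ≥ 1 in ≥ 1 species):

*Bias.* The parental call contrasts the Ad gene in Ad replicates against
the Ai gene in Ai replicates (unpaired Welch t on log₂(x + 0.5)); the
progeny call contrasts At against Bt *within the same tetraploid
libraries*, hence a paired t on the per-replicate log differences —
homoeologs measured in one library share its depth, and pairing removes
it. A side is biased at |log₂FC| ≥ 1 and p < α. Transitions:
same non-none state → Parental Condition; bias lost → No Bias in Progeny;
progeny bias absent from (or opposite to) the parents → Novel Bias in
Progeny; neither biased → Unbiased.

*ELD.* Three relations — t vs a, t vs b, a vs b with t = At + Bt per
tetraploid replicate — each take sign +/0/− where 0 means t-test
non-significance. The sign triple maps onto the 12-subcategory framework
through a module-level table (editable data, so numeral conventions can
be swapped without code change): {I, XII} additivity; {II, XI} ELD-A;
{IV, IX} ELD-B; {V, VI, VIII} transgressive up; {III, VII, X}
transgressive down; all-zero no change. Transitively impossible triples
(e.g. t = a, a = b, t > b) are resolved deterministically in favor of the
a-vs-b relation, then t-vs-a, and flagged `inconsistent` in the output.

Two optional guards tighten "=" beyond raw non-significance, both off by
default: BH adjustment of the relation p-values across quartets, and an
equivalence fold margin (relations below, e.g., 1.5-fold count as "=").
The margin matters because "=" by raw α alone mislabels
1 − (1 − α)³ ≈ 14% of truly unchanged quartets when three tests are made
per quartet; a 1.5-fold margin is a ≈ 3σ event under replicate noise at
realistic depth, so it suppresses those false relations without touching
genuinely separated (here ≥ 4-fold) levels. The recovery benchmarks
engage the margin; note that BH instead *costs* power at n = 3 and is
provided for larger designs.

Direction imbalances (A-bias vs B-bias counts; up- vs down-modification
counts in the ELD cause decomposition) are tested with the exact
two-sided binomial test, p = min(1, 2 · tail beyond and including k) at
p₀ = 0.5.

## Methylation–expression integration

Homoeolog methylation differences are computed per region (gene body,
upstream 2 kb, downstream 2 kb, strand-aware) and context, replicates
pooled, as A-side minus B-side weighted level; either side uncovered
makes the record missing. A record is *classified* when |Δm| strictly
exceeds the DMR context cutoff and the matching expression contrast is
≥ 2-fold; its direction is negative when the signs oppose. Per (region,
context) the negative/positive split is tested with the exact binomial
test. DEG-in-DMG enrichment is a Pearson χ² without continuity correction
on the 2 × 2 DMG × DEG table over an explicitly supplied gene universe
(the right universe is analysis-dependent and is never assumed), with a
Fisher-exact fallback when an expected cell drops below 1. Correlation
between Δm and expression contrasts is Spearman by default (Pearson by
flag), requiring ≥ 5 complete pairs; ties get average ranks.

Stage comparisons reuse the same DMR/DEG/DMG machinery between
developmental stages against a named baseline and report per-(context,
direction) DMR counts, associated-DEG counts and the enrichment test per
comparison.

## The synthetic-data model

The generator emulates the study design — two diploids plus one
tetraploid, 2 WGBS replicates and 3 RNA-seq replicates per condition,
three contexts, planted DMRs and bias/ELD categories — at desk scale
(defaults: 40 quartets on 200-kb single-chromosome genomes; benchmarks in
this repository use 2 quartets × 110 kb for methylation recovery over
≥ 1,000 windows per lineage and 120 quartets × 360 kb for classifier
recovery; these sizes were chosen so each benchmark has the sample size
its statistic needs while a full run stays interactive).

*Genomes.* The A-lineage chromosome is shared verbatim between Ad and At
(likewise Ai/Bt), so collinear blocks are exact whole-chromosome interval
pairs and every methylation difference between a diploid and its
descendant subgenome is attributable to the planted effects — which is
the point of the benchmark. The affine/inverted liftover path is
exercised separately on constructed fixtures. Genes (one per quartet per
genome) sit in equal slots with ≥ 2-kb margins; one TE per slot occupies
the inter-gene margin. Pericentromeric methylation gradients are *not*
modeled: every downstream operation is position-agnostic, so flat
per-context baselines (defaults CG 0.70, CHG 0.45, CHH 0.08, the typical
ordering of plant leaf methylomes) exercise everything.

*Methylomes.* Per site, the true level is the context baseline, shifted
by the planted effect (CG/CHG 0.55, CHH 0.25 — comfortably above the
0.4/0.1 call thresholds) in planted windows of the tetraploid subgenome;
the shift direction is chosen to keep the level in [0, 1] and recorded
signed. Coverage is Poisson (mean 20); observed methylated counts are
Binomial(coverage, ℓ(1 − e) + (1 − ℓ)e) with e the non-conversion error
(0.007, matching a ~99.3% conversion rate), i.e. non-conversion acts as a
symmetric false-positive error. Replicate variation beyond binomial
sampling is off by default (`meth_replicate_sd`), since tissue-level
between-replicate variance is not identified by the study design; it is
configurable. Each sample also carries an unmethylated spike-in table for
the conversion-rate estimate.

*Expression.* Each quartet first draws an ELD subcategory from the
configured class fractions (defaults shaped like a leaf-tissue
allopolyploid comparison: ~74% no change, ~14% ELD, transgressive-down
above transgressive-up, additivity rare), which fixes the (a, b, t)
geometry in multiples of a base level with every unequal pair ≥ the
planted fold (default 6; additivity uses parents fold² apart so the
intermediate t still clears the fold against both). The parental bias
state is whatever that geometry implies, and a transition label
compatible with it is drawn from the renormalized bias fractions — so
the realized transition marginals deviate from the configured fractions
exactly where ELD geometry forces the parental state; planting is
contradiction-free by construction. The tetraploid total then splits
At/Bt evenly (unbiased) or at the fold ratio (biased). Counts are
negative-binomial (dispersion 0.05; Poisson in the dispersion → 0 limit)
with mean = planted level × gene length (kb) × replicate depth factor ×
`depth_scale`. Depth factors cycle 0.6/1.0/1.35 with ±5% jitter, making
library sizes span > 2-fold to exercise normalization; `depth_scale`
(default 50) puts the least-expressed planted class at tens of reads, the
realistic regime for genes passing an FPKM ≥ 1 filter.

*What passing tests do and do not show.* The benchmarks demonstrate that
every estimator recovers what was planted under its own model assumptions
(binomial bisulfite noise, NB counts, large well-separated effects, flat
baselines, exact collinearity). They do not demonstrate performance under
mapping bias, context misassignment, overdispersed replicate effects,
marginal effect sizes, pericentromeric composition gradients, or
imperfect homoeolog assignment — all properties of real data this
generator intentionally does not model.

## Numerical choices and degenerate inputs

- Zero-variance t-tests resolve to p = 1 (equal means) or p = 0 (unequal),
  making noise-free truth-recovery exact and deterministic.
- Fold-change gates use a 10⁻⁹ tolerance on the log₂ scale so an exactly
  2-fold change is reliably inclusive under floating-point rounding.
- Threshold semantics: DMR level differences and association |Δm| are
  strict (>); fold gates and the FPKM ≥ 1 filter are inclusive (≥);
  FDR/α gates on adjusted p are exclusive (<) for DE status, inclusive
  (≤) for mC calls and DMR α — each matching its documented contract.
- Empty selections are missing (NaN), never zero; missing records are
  excluded from tests rather than imputed.
- RNG: a single integer seed drives every simulation through
  `numpy.random.default_rng`; identical configuration gives byte-identical
  emitted files.

## Known limitations

- The DE surrogate underpowers marginal effects relative to NB shrinkage
  models; conclusions from it should be restricted to large effects.
- DMR units are windows; biological "regions" spanning several windows
  are counted multiply.
- TMM on the quartet-matched universe assumes most quartets unchanged —
  true here by construction, checkable (not guaranteed) on real data.
- The ELD "=" relation at n = 3 with raw α mislabels ~14% of unchanged
  quartets; use the equivalence margin (or more replicates) when the
  no-change class dominates.
- `correlate_meth_expr` and the enrichment test treat quartets/genes as
  independent; linked genes violate this mildly in real genomes.
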