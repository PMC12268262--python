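# allometh

Comparative DNA-methylome and transcriptome analysis for an allotetraploid
and its two diploid progenitors — the analysis design used to study how
DNA methylation shapes homoeolog expression in allotetraploid peanut
(*Arachis hypogaea*, subgenomes At/Bt) relative to *A. duranensis* (Ad) and
*A. ipaensis* (Ai).

It is written for researchers who have per-cytosine bisulfite call tables
(BSMAP `methratio`-style TSV), gene-level RNA-seq count matrices, a
homoeolog quartet table (Ad/Ai/At/Bt gene ids), and collinear-block
intervals from a whole-genome aligner, and who want the downstream
statistics reproducibly and testably — plus a synthetic-data generator
that plants known truth through every layer so each statistic can be
benchmarked end to end without any sequencing data.

## What it computes

**Methylome layer** (`allometh.methylome`)
- Weighted methylation level of a region: w = (Σ #C) / (Σ #C + #T) over
  covered cytosines of a context (CG, CHG, CHH; H ∈ {A,T,C}) — pooled
  counts, never a mean of per-site ratios.
- Bisulfite conversion rate from an unmethylated spike-in, and binomial
  methylcytosine calls: a site with coverage n and c methylated reads is
  methylated when the BH-adjusted upper tail P(X ≥ c | n, p = 1 − rate)
  falls below q.
- Genome tracks and strand-oriented gene/TE metaprofiles
  (flank | body | flank bins).

**DMR layer** (`allometh.dmr`) — restricted to collinear blocks with
alignment score > 2000, tiled into 100-bp windows. A window is a DMR when
a one-way two-group ANOVA on replicate window levels gives p ≤ α *and*
the group-mean difference exceeds 0.4 (CG, CHG) or 0.1 (CHH), strictly.
Genes whose body ± 2 kb overlaps a DMR are differentially methylated
genes (DMGs).

**Expression layer** (`allometh.expression`) — FPKM
(counts · 10⁹ / (length · library size)), TMM scaling factors
(doubly-trimmed, precision-weighted mean of M-values; geometric mean 1),
an FPKM ≥ 1 expressed-gene filter, and a documented differential-
expression surrogate: Welch t on log₂(TMM-scaled FPKM + 0.5), BH-adjusted,
called at |log₂FC| ≥ 1 and FDR < 0.05.

**Homoeolog layer** (`allometh.homoeolog`) — per quartet:
- expression **bias** (A vs B side > 2-fold with t-test support) in the
  parental and tetraploid generations, and its transition category
  (Parental Condition / No Bias in Progeny / Novel Bias in Progeny /
  Unbiased);
- **expression-level dominance** from the sign pattern of three t-tested
  relations — t vs a, t vs b, a vs b with t = At + Bt — mapped onto the
  classic 12-subcategory framework (I–XII; additivity, ELD-A, ELD-B,
  transgressive up/down, no change);
- the cause decomposition of ELD into homoeolog up/down-modification
  patterns, and exact two-sided binomial direction tests.

**Integration layer** (`allometh.integration`) — homoeolog methylation
differences per region (body / upstream 2 kb / downstream 2 kb), their
association with expression differences (|Δm| above the DMR cutoffs and
≥ 2-fold expression change; direction negative when signs oppose),
binomial sign tests, DEG-in-DMG χ² enrichment, Spearman correlation,
developmental-stage comparisons, and the end-to-end pipeline driver.

**Synthetic data** (`allometh.synthetic_data`) — four toy genomes with
genes, TEs, collinear blocks and quartets; per-replicate binomial
bisulfite counts with planted DMR windows; negative-binomial counts whose
means realize planted bias/ELD labels. All planted truth is emitted for
recovery testing.

## Worked example

Run the whole analysis on a freshly simulated study:

```sh
allometh run --out demo --seed 42
```

or equivalently, with explicit conditions:

```python
from allometh.integration import run_pipeline
summary = run_pipeline({"sim": {"n_quartets": 24, "chrom_length_bp": 120_000,
                                "seed": 42}}, "demo")
```

With those settings the summary (also written to `demo/summary.json`)
contains:

```
"dmr_counts":  {"Ad_vs_At": {"CG": 60, "CHG": 59, "CHH": 60},
                "Ai_vs_Bt": {"CG": 59, "CHG": 58, "CHH": 60}}
"bias_counts": {"Unbiased": 12, "NovelBiasInProgeny": 7,
                "ParentalCondition": 3, "NoBiasInProgeny": 2}
"eld_counts":  {"no_change": 17, "transgressive_up": 3,
                "ELD-B": 2, "transgressive_down": 2}
"bias_direction_test": {"A": 3, "B": 7, "p": 0.34375}
"conversion_rate": {"Ad_rep1": 0.9929, ...}
```

Reading: the simulator planted differential methylation in 5% of the
1,200 collinear 100-bp windows per lineage (60 per context); the DMR
caller recovers essentially all of them. Of 24 quartets, 12 are unbiased
in both generations, 7 gained a novel bias in the tetraploid; 3 of the
biased tetraploid pairs favor the A side and 7 the B side, a split the
exact binomial test does not call directionally significant (p = 0.34).
The spike-in conversion rate (~99.3%) sets the error rate of the
methylcytosine binomial test.

Individual steps are available as subcommands (`allometh simulate`,
`wml`, `mcall`, `track`, `metaprofile`, `dmr`, `normalize`, `degs`,
`bias`, `eld`, `eld-decompose`, `assoc`, `enrich`); see `allometh --help`.

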