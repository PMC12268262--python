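"""Windowed DMR calling restricted to collinear (alignable) regions.

Cross-species methylation comparison is only meaningful on sequence both
genomes actually share, so analysis is confined to collinear blocks from a
whole-genome aligner (score > 2000), tiled into 100-bp windows.  A window
is a DMR between two replicate groups when a one-way ANOVA on the
replicate-level weighted methylation is significant *and* the group-mean
difference exceeds a context-specific threshold: 0.4 for CG and CHG, 0.1
for CHH (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import ParameterError, RowError
from .methylome import CONTEXTS, MethylomeSample

#: context -> minimum |group-mean difference| for a DMR (strict >)
DEFAULT_THRESHOLDS: Mapping[str, float] = {"CG": 0.4, "CHG": 0.4, "CHH": 0.1}


@dataclass(frozen=True)
class CollinearBlock:
    """One aligned interval pair between a query and a target genome."""

    q_chrom: str
    q_start: int
    q_end: int
    t_chrom: str
    t_start: int
    t_end: int
    score: float
    orientation: str = "same"  # or "inverted"

    def map_to_target(self, start: int, end: int) -> tuple[str, int, int]:
        """Affine within-block liftover of a query sub-interval.

        Inverted blocks map with orientation reversal, so the image of
        [start, end) keeps half-open semantics on the target side.
        """
        if start < self.q_start or end > self.q_end:
            raise ParameterError(
                f"interval [{start}, {end}) outside block query range "
                f"[{self.q_start}, {self.q_end})"
            )
        if self.orientation == "same":
            off = self.t_start - self.q_start
            return (self.t_chrom, start + off, end + off)
        return (
            self.t_chrom,
            self.t_end - (end - self.q_start),
            self.t_end - (start - self.q_start),
        )


def read_collinear_blocks(path: str | Path, min_score: float = 2000) -> list[CollinearBlock]:
    """Load aligner interval pairs, keeping blocks with score strictly > ``min_score``.

    Expects a TSV with header columns q_chrom, q_start, q_end, t_chrom,
    t_start, t_end, score, strand (strand "+" = same orientation, "-" =
    inverted).  Coordinates are 0-based half-open.  Rows with inverted
    (start >= end) intervals raise :class:`RowError`.
    """
    table = pd.read_csv(path, sep="\t", dtype={"q_chrom": str, "t_chrom": str, "strand": str})
    blocks = []
    for i, row in enumerate(table.itertuples(index=False)):
        if row.q_start >= row.q_end or row.t_start >= row.t_end:
            raise RowError(f"{path}: inverted interval at data line {i + 2}")
        if row.score > min_score:
            blocks.append(
                CollinearBlock(
                    q_chrom=row.q_chrom,
                    q_start=int(row.q_start),
                    q_end=int(row.q_end),
                    t_chrom=row.t_chrom,
                    t_start=int(row.t_start),
                    t_end=int(row.t_end),
                    score=float(row.score),
                    orientation="same" if getattr(row, "strand", "+") == "+" else "inverted",
                )
            )
    return blocks


def merge_block_regions(
    blocks: Iterable[CollinearBlock], side: str = "query"
) -> list[tuple[str, int, int]]:
    """Merge overlapping or abutting block intervals on one genome side."""
    if side == "query":
        ivs = [(b.q_chrom, b.q_start, b.q_end) for b in blocks]
    elif side == "target":
        ivs = [(b.t_chrom, b.t_start, b.t_end) for b in blocks]
    else:
        raise ParameterError(f"side must be 'query' or 'target', got {side!r}")
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in sorted(ivs):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged.pop()
            merged.append((chrom, prev[1], max(prev[2], end)))
        else:
            merged.append((chrom, start, end))
    return merged


def tile_windows(
    regions: Sequence[tuple[str, int, int]] | Sequence[CollinearBlock],
    size: int = 100,
) -> pd.DataFrame:
    """Tile merged collinear regions into non-overlapping ``size``-bp windows.

    A terminal remainder shorter than ``size`` is kept and flagged
    (``is_remainder``).  Accepts either merged (chrom, start, end) triples
    or raw blocks, which are then merged on the query side first.
    """
    regs = list(regions)
    if regs and isinstance(regs[0], CollinearBlock):
        regs = merge_block_regions(regs, "query")
    rows = []
    for chrom, start, end in regs:
        edges = np.arange(start, end, size)
        for s in edges:
            e = min(s + size, end)
            rows.append((chrom, int(s), int(e), e - s < size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "is_remainder"])


def window_levels(
    windows: pd.DataFrame,
    samples: Mapping[str, pd.DataFrame | MethylomeSample],
    min_sites: int = 4,
    contexts: Sequence[str] = CONTEXTS,
) -> pd.DataFrame:
    """Per-replicate pooled weighted level per window per context.

    Returns a long table (chrom, start, end, context, sample_id, level,
    n_sites).  A (window, context) combination is excluded outright when
    any sample covers fewer than ``min_sites`` cytosines of that context in
    it — exclusion is per context, so CG may pass where CHH fails.
    """
    frames = []
    win_by_chrom = {c: g.sort_values("start") for c, g in windows.groupby("chrom")}
    for sample_id, sample in samples.items():
        calls = sample.calls if isinstance(sample, MethylomeSample) else sample
        for chrom, grp in calls.groupby("chrom"):
            if chrom not in win_by_chrom:
                continue
            win = win_by_chrom[chrom]
            starts = win["start"].to_numpy()
            ends = win["end"].to_numpy()
            site0 = grp["pos"].to_numpy() - 1
            idx = np.searchsorted(starts, site0, side="right") - 1
            ok = (idx >= 0) & (site0 < ends[np.clip(idx, 0, len(ends) - 1)])
            sub = grp.loc[ok].copy()
            sub["wstart"] = starts[idx[ok]]
            agg = (
                sub.groupby(["wstart", "context"])
                .agg(c=("c_count", "sum"), ct=("ct_count", "sum"), n_sites=("pos", "size"))
                .reset_index()
            )
            agg = agg[agg["context"].isin(contexts)]
            agg["chrom"] = chrom
            agg["sample_id"] = sample_id
            frames.append(agg)
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "context", "sample_id", "level", "n_sites"]
        )
    long = pd.concat(frames, ignore_index=True).rename(columns={"wstart": "start"})
    ends = windows.set_index(["chrom", "start"])["end"]
    long["end"] = ends.loc[list(zip(long["chrom"], long["start"]))].to_numpy()
    long["level"] = long["c"] / long["ct"]
    # drop (window, context) combos where any sample is under-covered or absent
    n_samples = len(samples)
    key = ["chrom", "start", "end", "context"]
    grp = long.groupby(key)["n_sites"]
    good = (grp.transform("min") >= min_sites) & (grp.transform("size") == n_samples)
    return long.loc[good, key + ["sample_id", "level", "n_sites"]].reset_index(drop=True)


def _anova_two_group(g1: np.ndarray, g2: np.ndarray) -> float:
    """Classic equal-variance one-way ANOVA p for two groups.

    Degenerate zero-within-variance windows resolve to p = 1 when the group
    means coincide and p = 0 when they differ.
    """
    m1, m2 = g1.mean(), g2.mean()
    ssw = ((g1 - m1) ** 2).sum() + ((g2 - m2) ** 2).sum()
    if ssw == 0:
        return 1.0 if m1 == m2 else 0.0
    return float(stats.f_oneway(g1, g2).pvalue)


def call_dmrs(
    meth_windows: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Call DMRs between two replicate groups on window-level tables.

    A window is a DMR in a context iff the one-way ANOVA p (group1
    replicate levels vs group2) satisfies p <= alpha and the absolute
    group-mean difference strictly exceeds ``thresholds[context]``.
    Direction is "hyper" when group1's mean is higher.  ``adjust=True``
    applies Benjamini-Hochberg across all tested windows before the alpha
    gate.  Windows with fewer than two replicates in either group are
    skipped (counted in ``call_dmrs.last_skipped``).
    """
    group1, group2 = list(group1), list(group2)
    key = ["chrom", "start", "end", "context"]
    piv = meth_windows.pivot_table(index=key, columns="sample_id", values="level")
    have1 = piv[ [c for c in group1 if c in piv.columns] ]
    have2 = piv[ [c for c in group2 if c in piv.columns] ]
    ok = have1.notna().sum(axis=1).ge(2) & have2.notna().sum(axis=1).ge(2)
    call_dmrs.last_skipped = int((~ok).sum())
    piv = piv.loc[ok]
    if piv.empty:
        return pd.DataFrame(columns=key + ["direction", "mean_diff", "p_value", "n1", "n2"])

    records = []
    a1 = piv[[c for c in group1 if c in piv.columns]].to_numpy()
    a2 = piv[[c for c in group2 if c in piv.columns]].to_numpy()
    for i, idx in enumerate(piv.index):
        g1 = a1[i][~np.isnan(a1[i])]
        g2 = a2[i][~np.isnan(a2[i])]
        p = _anova_two_group(g1, g2)
        records.append(idx + (float(g1.mean() - g2.mean()), p, len(g1), len(g2)))
    res = pd.DataFrame(records, columns=key + ["mean_diff", "p_value", "n1", "n2"])
    pcol = res["p_value"].to_numpy()
    if adjust and len(pcol):
        pcol = multipletests(pcol, method="fdr_bh")[1]
        res["p_adj"] = pcol
    thr = res["context"].map(thresholds).to_numpy(dtype=float)
    is_dmr = (pcol <= alpha) & (np.abs(res["mean_diff"].to_numpy()) > thr)
    out = res.loc[is_dmr].copy()
    out["direction"] = np.where(out["mean_diff"] > 0, "hyper", "hypo")
    cols = key + ["direction", "mean_diff", "p_value", "n1", "n2"]
    if "p_adj" in out.columns:
        cols.append("p_adj")
    return out[cols].reset_index(drop=True)


call_dmrs.last_skipped = 0

#: annotation precedence for DMR genomic distribution
DISTRIBUTION_CATEGORIES = ("gene_body", "upstream2k", "downstream2k", "TE", "intergenic")


def _build_trees(features: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for feat in features.itertuples(index=False):
        if feat.end > feat.start:
            trees.setdefault(feat.chrom, IntervalTree()).addi(feat.start, feat.end)
    return trees


def _flank_frames(genes: pd.DataFrame, flank_bp: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    plus = genes["strand"] != "-"
    up = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.where(plus, genes["start"] - flank_bp, genes["end"]),
            "end": np.where(plus, genes["start"], genes["end"] + flank_bp),
        }
    )
    down = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.where(plus, genes["end"], genes["start"] - flank_bp),
            "end": np.where(plus, genes["end"] + flank_bp, genes["start"]),
        }
    )
    for f in (up, down):
        f["start"] = f["start"].clip(lower=0)
    return up, down


def annotate_dmrs(
    dmrs: pd.DataFrame,
    genes: pd.DataFrame,
    tes: pd.DataFrame,
    flank_bp: int = 2000,
) -> pd.DataFrame:
    """Genomic distribution of DMRs with precedence gene body > upstream2k > downstream2k > TE > intergenic."""
    up, down = _flank_frames(genes, flank_bp)
    trees = {
        "gene_body": _build_trees(genes),
        "upstream2k": _build_trees(up),
        "downstream2k": _build_trees(down),
        "TE": _build_trees(tes),
    }
    counts = dict.fromkeys(DISTRIBUTION_CATEGORIES, 0)
    for d in dmrs.itertuples(index=False):
        for cat in DISTRIBUTION_CATEGORIES[:-1]:
            tree = trees[cat].get(d.chrom)
            if tree is not None and tree.overlap(d.start, d.end):
                counts[cat] += 1
                break
        else:
            counts["intergenic"] += 1
    total = max(sum(counts.values()), 1)
    return pd.DataFrame(
        {
            "category": list(counts),
            "count": list(counts.values()),
            "fraction": [v / total for v in counts.values()],
        }
    )


def assign_dmgs(dmrs: pd.DataFrame, genes: pd.DataFrame, flank_bp: int = 2000) -> pd.DataFrame:
    """Differentially methylated genes: gene body ± ``flank_bp`` overlapping >= 1 DMR.

    Overlap is half-open and requires at least 1 bp.  Returns one row per
    (gene, DMR) pair with the overlap zone (body / upstream2k /
    downstream2k, body taking precedence); a gene with several DMRs yields
    several rows sharing the gene_id.
    """
    rows = []
    dmr_by_chrom = {c: g.reset_index() for c, g in dmrs.groupby("chrom")}
    for gene in genes.itertuples(index=False):
        sub = dmr_by_chrom.get(gene.chrom)
        if sub is None:
            continue
        lo, hi = max(0, gene.start - flank_bp), gene.end + flank_bp
        hit = sub[(sub["start"] < hi) & (sub["end"] > lo)]
        plus = getattr(gene, "strand", "+") != "-"
        for d in hit.itertuples(index=False):
            if d.start < gene.end and d.end > gene.start:
                zone = "body"
            elif (d.end <= gene.start) == plus:
                zone = "upstream2k"
            else:
                zone = "downstream2k"
            rows.append(
                {
                    "gene_id": gene.gene_id,
                    "dmr_chrom": d.chrom,
                    "dmr_start": d.start,
                    "dmr_end": d.end,
                    "context": d.context,
                    "direction": getattr(d, "direction", ""),
                    "zone": zone,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "dmr_chrom", "dmr_start", "dmr_end", "context", "direction", "zone"],
    )
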