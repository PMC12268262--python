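"""Joining the methylation and expression layers, and the pipeline driver.

The central questions this module answers: do homoeolog methylation
differences line up (negatively) with homoeolog expression differences,
and are differentially expressed genes enriched among differentially
methylated genes?  Classification cutoffs mirror the DMR thresholds —
|delta m| > 0.4 for CG/CHG, > 0.1 for CHH — combined with a >= 2-fold
expression change; direction is "negative" when the methylation and
expression differences have opposite signs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigError, ParameterError
from . import __version__
from .dmr import (
    DEFAULT_THRESHOLDS,
    CollinearBlock,
    assign_dmgs,
    call_dmrs,
    tile_windows,
    window_levels,
)
from .expression import call_degs
from .homoeolog import (
    binomial_direction_test,
    classify_bias,
    classify_eld,
    eld_cause_decomposition,
    normalize_quartet_expression,
)
from .methylome import CONTEXTS, conversion_rate, global_level, pool_replicates

REGIONS = ("body", "upstream2k", "downstream2k")


@dataclass
class EnrichmentResult:
    """2x2 DEG x DMG association: counts, chi-square, and the two proportions."""

    table: np.ndarray  # rows: DMG / non-DMG; cols: DEG / non-DEG
    chi2: float
    p: float
    prop_deg_in_dmg: float
    prop_deg_universe: float
    method: str = "chi2"


def _gene_regions(genes: pd.DataFrame, flank_bp: int) -> dict[str, pd.DataFrame]:
    plus = genes["strand"] != "-"
    body = genes[["gene_id", "chrom", "start", "end"]].copy()
    up = body.copy()
    up["start"] = np.where(plus, genes["start"] - flank_bp, genes["end"])
    up["end"] = np.where(plus, genes["start"], genes["end"] + flank_bp)
    down = body.copy()
    down["start"] = np.where(plus, genes["end"], genes["start"] - flank_bp)
    down["end"] = np.where(plus, genes["end"] + flank_bp, genes["start"])
    for f in (up, down):
        f["start"] = f["start"].clip(lower=0)
    return {"body": body, "upstream2k": up, "downstream2k": down}


def _region_levels(calls: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Pooled c/ct per (gene region, context); regions must not overlap."""
    out = []
    for chrom, grp in calls.groupby("chrom"):
        reg = regions[regions["chrom"] == chrom].sort_values("start")
        if reg.empty:
            continue
        starts, ends = reg["start"].to_numpy(), reg["end"].to_numpy()
        site0 = grp["pos"].to_numpy() - 1
        idx = np.searchsorted(starts, site0, side="right") - 1
        ok = (idx >= 0) & (site0 < ends[np.clip(idx, 0, len(ends) - 1)])
        sub = grp.loc[ok].copy()
        sub["gene_id"] = reg["gene_id"].to_numpy()[idx[ok]]
        out.append(
            sub.groupby(["gene_id", "context"], as_index=False)[["c_count", "ct_count"]].sum()
        )
    if not out:
        return pd.DataFrame(columns=["gene_id", "context", "c_count", "ct_count"])
    return pd.concat(out, ignore_index=True)


def homoeolog_meth_diff(
    calls_by_genome: Mapping[str, pd.DataFrame],
    genes: pd.DataFrame,
    quartets: pd.DataFrame,
    a_col: str = "at_gene",
    b_col: str = "bt_gene",
    regions: Sequence[str] = REGIONS,
    contexts: Sequence[str] = CONTEXTS,
    flank_bp: int = 2000,
) -> pd.DataFrame:
    """Per-quartet A-side minus B-side weighted methylation, per region/context.

    ``calls_by_genome`` holds replicate-pooled call tables keyed by genome
    name matching the ``genome`` column of ``genes``.  A record is missing
    (NaN) when either side has no covered cytosine of the context in the
    region.
    """
    reg_frames = _gene_regions(genes, flank_bp)
    levels: dict[tuple[str, str], pd.DataFrame] = {}
    for side_col in (a_col, b_col):
        side_genomes = genes.set_index("gene_id")["genome"].reindex(quartets[side_col]).unique()
        for g in side_genomes:
            sub_genes = genes[genes["genome"] == g]
            for rname in regions:
                key = (g, rname)
                if key not in levels:
                    levels[key] = _region_levels(
                        calls_by_genome[g], reg_frames[rname][reg_frames[rname]["gene_id"].isin(sub_genes["gene_id"])]
                    ).set_index(["gene_id", "context"])

    gene_genome = genes.set_index("gene_id")["genome"]

    def level_of(gene: str, rname: str, context: str) -> float:
        tab = levels.get((gene_genome.get(gene), rname))
        if tab is None or (gene, context) not in tab.index:
            return np.nan
        row = tab.loc[(gene, context)]
        return float(row["c_count"] / row["ct_count"]) if row["ct_count"] > 0 else np.nan

    rows = []
    for q, qr in quartets.iterrows():
        for rname in regions:
            for context in contexts:
                la = level_of(qr[a_col], rname, context)
                lb = level_of(qr[b_col], rname, context)
                rows.append(
                    {
                        "quartet": q,
                        "region": rname,
                        "context": context,
                        "level_a": la,
                        "level_b": lb,
                        "delta_m": la - lb,
                    }
                )
    return pd.DataFrame(rows)


def classify_associations(
    meth_diff: pd.DataFrame,
    expr_log2fc: pd.Series | Mapping,
    cutoffs: Mapping[str, float] = DEFAULT_THRESHOLDS,
    fc: float = 2.0,
) -> pd.DataFrame:
    """Pair methylation and expression contrasts and apply both cutoffs.

    A record is classified when |delta_m| strictly exceeds the context
    cutoff and |log2FC| >= log2(fc); its direction is "negative" when the
    two differences have opposite signs, "positive" otherwise.
    """
    fcv = pd.Series(expr_log2fc)
    out = meth_diff.copy()
    out["log2FC"] = fcv.reindex(out["quartet"]).to_numpy()
    cut = out["context"].map(cutoffs).to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
        classified = (
            (np.abs(out["delta_m"].to_numpy()) > cut)
            & (np.abs(out["log2FC"].to_numpy()) >= np.log2(fc))
        )
    classified &= out["delta_m"].notna().to_numpy() & out["log2FC"].notna().to_numpy()
    out["classified"] = classified
    sign_opposite = np.sign(out["delta_m"]) != np.sign(out["log2FC"])
    out["direction"] = np.where(
        classified, np.where(sign_opposite, "negative", "positive"), ""
    )
    return out


def association_sign_test(associations: pd.DataFrame) -> pd.DataFrame:
    """Two-sided binomial test of negative vs positive counts per (region, context)."""
    rows = []
    for (region, context), grp in associations.groupby(["region", "context"]):
        cls = grp[grp["classified"]]
        n_neg = int((cls["direction"] == "negative").sum())
        n_pos = int((cls["direction"] == "positive").sum())
        p = (
            binomial_direction_test(n_neg, n_neg + n_pos)
            if n_neg + n_pos >= 1
            else np.nan
        )
        rows.append(
            {
                "region": region,
                "context": context,
                "n_negative": n_neg,
                "n_positive": n_pos,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def deg_dmg_enrichment(
    degs: set[str], dmgs: set[str], universe: set[str]
) -> EnrichmentResult:
    """Pearson chi-square (no continuity correction) on the 2x2 DMG x DEG table.

    Falls back to Fisher's exact test (with a warning) when any expected
    cell is below 1.
    """
    if not degs <= universe or not dmgs <= universe:
        raise ParameterError("deg and dmg sets must be subsets of the universe")
    n = len(universe)
    a = len(degs & dmgs)
    b = len(dmgs) - a
    c = len(degs) - a
    d = n - len(dmgs) - c
    table = np.array([[a, b], [c, d]], dtype=float)
    prop_in_dmg = a / max(len(dmgs), 1)
    prop_universe = len(degs) / max(n, 1)
    expected = np.outer(table.sum(1), table.sum(0)) / max(table.sum(), 1)
    if (expected < 1).any():
        warnings.warn("expected cell < 1; using Fisher's exact test")
        _, p = stats.fisher_exact(table)
        return EnrichmentResult(table, np.nan, float(p), prop_in_dmg, prop_universe, "fisher")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return EnrichmentResult(table, float(chi2), float(p), prop_in_dmg, prop_universe, "chi2")


def correlate_meth_expr(
    delta_m: Sequence[float],
    expr_contrast: Sequence[float],
    method: str = "spearman",
) -> tuple[float, float]:
    """Rank (or Pearson) correlation between paired non-missing contrasts.

    Requires >= 5 complete pairs; a constant vector yields (nan, nan).
    Ties are handled by average ranks (scipy's convention).
    """
    x = np.asarray(delta_m, dtype=float)
    y = np.asarray(expr_contrast, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ParameterError(f"correlate_meth_expr needs >= 5 complete pairs, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), float("nan"))
    if method == "spearman":
        r = stats.spearmanr(x, y)
    elif method == "pearson":
        r = stats.pearsonr(x, y)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    return float(r.statistic), float(r.pvalue)


def stage_comparison(
    windows: pd.DataFrame,
    meth_samples: Mapping[str, object],
    meth_stages: Mapping[str, str],
    counts: pd.DataFrame,
    gene_lengths: pd.Series | Mapping[str, float],
    expr_stages: Mapping[str, str],
    genes: pd.DataFrame,
    baseline: str,
    thresholds: Mapping[str, float] = DEFAULT_THRESHOLDS,
    alpha: float = 0.05,
    fc: float = 2.0,
    fdr: float = 0.05,
    min_sites: int = 4,
    flank_bp: int = 2000,
) -> dict[str, dict]:
    """Per-stage DMR/DEG/DMG report against a baseline stage.

    For every non-baseline stage: DMRs (stage vs baseline) per context and
    direction, DEGs, DMG assignment, the count of DEGs associated with
    each (context, direction) DMR class, and DEG-in-DMG enrichment over
    the gene universe.
    """
    stages = set(meth_stages.values())
    if baseline not in stages:
        raise ConfigError(f"unknown baseline stage {baseline!r}; have {sorted(stages)}")
    if set(expr_stages.values()) != stages:
        raise ConfigError("methylome and expression stage labels disagree")
    universe = set(genes["gene_id"])
    report: dict[str, dict] = {}
    base_meth = [s for s, st in meth_stages.items() if st == baseline]
    base_expr = [s for s, st in expr_stages.items() if st == baseline]
    for stage in sorted(stages - {baseline}):
        grp_meth = [s for s, st in meth_stages.items() if st == stage]
        grp_expr = [s for s, st in expr_stages.items() if st == stage]
        use = {sid: meth_samples[sid] for sid in grp_meth + base_meth}
        levels = window_levels(windows, use, min_sites=min_sites)
        dmrs = call_dmrs(levels, grp_meth, base_meth, thresholds, alpha)
        degs = call_degs(counts, gene_lengths, grp_expr, base_expr, fc=fc, fdr=fdr)
        deg_set = set(degs.index[degs["status"] != "ns"])
        dmgs = assign_dmgs(dmrs, genes, flank_bp)
        dmr_counts = (
            dmrs.groupby(["context", "direction"]).size().rename("count").reset_index()
        )
        assoc_rows = []
        for (context, direction), grp in (
            dmgs.groupby(["context", "direction"]) if not dmgs.empty else ()
        ):
            genes_in_class = set(grp["gene_id"])
            assoc_rows.append(
                {
                    "context": context,
                    "direction": direction,
                    "n_dmg": len(genes_in_class),
                    "n_deg_associated": len(genes_in_class & deg_set),
                }
            )
        dmg_set = set(dmgs["gene_id"]) if not dmgs.empty else set()
        enr = (
            deg_dmg_enrichment(deg_set, dmg_set, universe)
            if dmg_set and universe
            else None
        )
        report[stage] = {
            "dmr_counts": dmr_counts,
            "n_deg": len(deg_set),
            "deg_dmr_association": pd.DataFrame(
                assoc_rows, columns=["context", "direction", "n_dmg", "n_deg_associated"]
            ),
            "enrichment": enr,
        }
    return report


# ---------------------------------------------------------------------------
# pipeline driver


def lift_calls_to_query(calls: pd.DataFrame, blocks: Sequence[CollinearBlock]) -> pd.DataFrame:
    """Map target-genome call coordinates into query coordinates via blocks.

    Sites outside every block are dropped; inverted blocks flip strand.
    """
    out = []
    for b in blocks:
        sub = calls[
            (calls["chrom"] == b.t_chrom)
            & (calls["pos"] > b.t_start)
            & (calls["pos"] <= b.t_end)
        ].copy()
        if sub.empty:
            continue
        if b.orientation == "same":
            sub["pos"] = sub["pos"] + (b.q_start - b.t_start)
        else:
            sub["pos"] = b.q_end - (sub["pos"] - 1 - b.t_start)
            sub["strand"] = np.where(sub["strand"] == "+", "-", "+")
        sub["chrom"] = b.q_chrom
        out.append(sub)
    if not out:
        return calls.iloc[0:0]
    return pd.concat(out, ignore_index=True)


def run_pipeline(config: Mapping, outdir: str | Path | None = None) -> dict:
    """End-to-end run on a simulated study; returns (and writes) the summary.

    ``config`` keys: ``sim`` (SimConfig fields), ``thresholds``, ``alpha``,
    ``fc``, ``fdr``, ``q_threshold``, ``min_sites``, ``flank_bp``.  The
    summary JSON contains every category count, every test p-value and the
    exact thresholds used; identical configs produce identical summaries.
    """
    from .synthetic_data import LINEAGES, SimConfig, simulate_bundle

    sim_cfg = SimConfig(**config.get("sim", {}))
    thresholds = dict(config.get("thresholds", DEFAULT_THRESHOLDS))
    alpha = float(config.get("alpha", 0.05))
    fc = float(config.get("fc", 2.0))
    fdr = float(config.get("fdr", 0.05))
    q_threshold = float(config.get("q_threshold", 0.05))
    min_sites = int(config.get("min_sites", 4))
    flank_bp = int(config.get("flank_bp", 2000))
    eld_adjust = bool(config.get("eld_adjust", False))
    eld_equiv_fold = float(config.get("eld_equiv_fold", 1.0))

    bundle, samples, controls, counts, sheet, truth = simulate_bundle(sim_cfg)
    summary: dict = {
        "version": __version__,
        "parameters": {
            "thresholds": thresholds,
            "alpha": alpha,
            "fc": fc,
            "fdr": fdr,
            "q_threshold": q_threshold,
            "min_sites": min_sites,
            "flank_bp": flank_bp,
            "eld_adjust": eld_adjust,
            "eld_equiv_fold": eld_equiv_fold,
            "sim": {k: (dict(v) if isinstance(v, Mapping) else v)
                    for k, v in vars(sim_cfg).items()},
        },
    }

    # methylome layer: conversion rates and global levels
    summary["conversion_rate"] = {
        sid: conversion_rate(ctl) for sid, ctl in sorted(controls.items())
    }
    summary["global_levels"] = {
        sid: {ctx: global_level(s, ctx) for ctx in CONTEXTS}
        for sid, s in sorted(samples.items())
    }

    # DMRs per lineage pair (diploid = query side)
    windows = tile_windows(bundle.blocks, 100)
    dmr_tables = {}
    for dip, tet in LINEAGES.items():
        use: dict[str, pd.DataFrame] = {}
        g1, g2 = [], []
        for sid, s in samples.items():
            if s.genome == dip:
                use[sid] = s.calls
                g1.append(sid)
            elif s.genome == tet:
                use[sid] = lift_calls_to_query(s.calls, bundle.blocks)
                g2.append(sid)
        win = windows[windows["chrom"] == f"{dip}_chr1"]
        levels = window_levels(win, use, min_sites=min_sites)
        dmrs = call_dmrs(levels, sorted(g2), sorted(g1), thresholds, alpha)
        dmr_tables[f"{dip}_vs_{tet}"] = dmrs
    summary["dmr_counts"] = {
        pair: {
            ctx: int((tab["context"] == ctx).sum()) for ctx in CONTEXTS
        }
        for pair, tab in dmr_tables.items()
    }

    # expression layer: quartet normalization, bias, ELD
    lengths = bundle.genes.set_index("gene_id")["length"]
    qe = normalize_quartet_expression(counts, lengths, bundle.quartets, sheet)
    bias = classify_bias(qe, alpha=alpha, fc=fc)
    eld = classify_eld(qe, alpha=alpha, adjust=eld_adjust, equiv_fold=eld_equiv_fold)
    summary["bias_counts"] = bias["transition"].value_counts().to_dict()
    summary["bias_states_progeny"] = bias["progeny_state"].value_counts().to_dict()
    summary["eld_counts"] = eld["major"].value_counts().to_dict()
    summary["eld_subcategories"] = eld["subcategory"].value_counts().to_dict()
    n_a = int((bias["progeny_state"] == "A-bias").sum())
    n_b = int((bias["progeny_state"] == "B-bias").sum())
    summary["bias_direction_test"] = {
        "A": n_a,
        "B": n_b,
        "p": binomial_direction_test(max(n_a, n_b), n_a + n_b) if n_a + n_b else None,
    }

    # ELD cause decomposition from progeny-vs-parent quartet DEG calls
    ah = list(sheet.loc[sheet["species"] == "Ah", "sample_id"])
    ad = list(sheet.loc[sheet["species"] == "Ad", "sample_id"])
    ai = list(sheet.loc[sheet["species"] == "Ai", "sample_id"])
    deg_a = call_degs(None, None, ah, ad, fc=fc, fdr=fdr,
                      normalized=pd.concat([qe.at, qe.a], axis=1))
    deg_b = call_degs(None, None, ah, ai, fc=fc, fdr=fdr,
                      normalized=pd.concat([qe.bt, qe.b], axis=1))
    decomp = eld_cause_decomposition(eld, deg_a["status"], deg_b["status"])
    summary["eld_decomposition"] = decomp.to_dict(orient="records")

    # methylation vs progeny expression bias associations
    pooled = {
        g: pool_replicates([s for s in samples.values() if s.genome == g])
        for g in ("At", "Bt")
    }
    meth_diff = homoeolog_meth_diff(
        pooled, bundle.genes, bundle.quartets, flank_bp=flank_bp
    )
    assoc = classify_associations(meth_diff, bias["progeny_log2FC"], thresholds, fc)
    sign = association_sign_test(assoc)
    summary["association_sign_tests"] = sign.to_dict(orient="records")

    # DEG-DMG enrichment on the A lineage (diploid coordinates)
    genes_a = bundle.genes[bundle.genes["genome"] == "Ad"]
    dmgs_a = assign_dmgs(dmr_tables["Ad_vs_At"], genes_a, flank_bp)
    deg_set = {
        bundle.quartets.loc[q, "ad_gene"]
        for q in deg_a.index[deg_a["status"] != "ns"]
    }
    dmg_set = set(dmgs_a["gene_id"]) if not dmgs_a.empty else set()
    universe = set(genes_a["gene_id"])
    if dmg_set:
        enr = deg_dmg_enrichment(deg_set, dmg_set, universe)
        summary["deg_dmg_enrichment"] = {
            "table": enr.table.astype(int).tolist(),
            "chi2": enr.chi2,
            "p": enr.p,
            "prop_deg_in_dmg": enr.prop_deg_in_dmg,
            "prop_deg_universe": enr.prop_deg_universe,
            "method": enr.method,
        }
    else:
        summary["deg_dmg_enrichment"] = None

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for pair, tab in dmr_tables.items():
            tab.to_csv(out / f"dmrs_{pair}.tsv", sep="\t", index=False)
        bias.to_csv(out / "bias.tsv", sep="\t")
        eld.to_csv(out / "eld.tsv", sep="\t")
        decomp.to_csv(out / "eld_decomposition.tsv", sep="\t", index=False)
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
        sign.to_csv(out / "association_sign_tests.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True, default=float)
    return summary
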