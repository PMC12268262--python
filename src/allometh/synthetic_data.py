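"""Miniature allotetraploid study generator with planted ground truth.

Emulates the design of a two-diploid + allotetraploid methylome/
transcriptome study: four genomes (diploids Ad and Ai; tetraploid
subgenomes At and Bt, one toy chromosome each), gene and TE annotations,
collinear blocks, per-replicate bisulfite call tables with planted DMR
windows, and negative-binomial expression counts realizing planted
homoeolog-bias and ELD categories.  Every planted quantity is recorded in
:class:`SimTruth` so downstream callers can be scored against it.

The A-lineage chromosome sequence is shared verbatim between Ad and At
(likewise Ai/Bt), so collinear blocks are exact whole-chromosome interval
pairs; methylation differences between a diploid and its descendant
subgenome are then attributable purely to the planted effects, which is
the point of the benchmark.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._errors import ConfigError
from .dmr import CollinearBlock, tile_windows
from .methylome import MethylomeSample, write_methratio

GENOMES = ("Ad", "Ai", "At", "Bt")
SPECIES = ("Ad", "Ai", "Ah")
#: diploid -> descendant tetraploid subgenome
LINEAGES = {"Ad": "At", "Ai": "Bt"}

_DEF_BASELINE = {"CG": 0.70, "CHG": 0.45, "CHH": 0.08}
_DEF_EFFECT = {"CG": 0.55, "CHG": 0.55, "CHH": 0.25}
_DEF_BIAS = {
    "ParentalCondition": 0.15,
    "NoBiasInProgeny": 0.10,
    "NovelBiasInProgeny": 0.10,
    "Unbiased": 0.65,
}
# fractions shaped like the category proportions a leaf-tissue
# allopolyploid comparison typically reports: no-change dominates, ELD and
# transgressive-down outnumber additivity and transgressive-up
_DEF_ELD = {
    "no_change": 0.7413,
    "ELD-A": 0.0670,
    "ELD-B": 0.0690,
    "additivity": 0.0130,
    "transgressive_up": 0.0320,
    "transgressive_down": 0.0777,
}

_SUBCATS = {
    "no_change": ["none"],
    "ELD-A": ["II", "XI"],
    "ELD-B": ["IV", "IX"],
    "additivity": ["I", "XII"],
    "transgressive_up": ["V", "VI", "VIII"],
    "transgressive_down": ["III", "VII", "X"],
}


@dataclass
class SimConfig:
    """All tunable study conditions for the synthetic dataset."""

    n_quartets: int = 40
    chrom_length_bp: int = 200_000
    n_meth_replicates: int = 2
    n_expr_replicates: int = 3
    conversion_error: float = 0.007
    coverage_mean: float = 20.0
    context_baseline: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_BASELINE))
    dmr_fraction: float = 0.05
    dmr_effect: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_EFFECT))
    bias_fractions: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_BIAS))
    eld_fractions: Mapping[str, float] = field(default_factory=lambda: dict(_DEF_ELD))
    nb_dispersion: float = 0.05
    meth_replicate_sd: float = 0.0
    expr_fold: float = 6.0
    base_expression: float = 60.0
    #: expected fragments per (normalized-unit x kb) at unit depth; the
    #: default puts the least-expressed planted class at tens of reads,
    #: the typical regime for genes passing an FPKM >= 1 filter
    depth_scale: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_quartets < 0:
            raise ConfigError("n_quartets must be >= 0")
        if self.n_quartets and self.chrom_length_bp < 100 * self.n_quartets:
            raise ConfigError("chrom_length_bp must be >= 100 * n_quartets")
        if not 0 <= self.conversion_error < 0.5:
            raise ConfigError("conversion_error must lie in [0, 0.5)")
        if self.coverage_mean <= 0:
            raise ConfigError("coverage_mean must be > 0")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.expr_fold < 2:
            raise ConfigError("expr_fold must be >= 2 to make planted bias callable")
        for name in ("bias_fractions", "eld_fractions"):
            fr = getattr(self, name)
            if any(not 0 <= v <= 1 for v in fr.values()):
                raise ConfigError(f"{name}: every fraction must lie in [0, 1]")
            if abs(sum(fr.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name}: fractions must sum to 1")
        for k, v in self.context_baseline.items():
            if not 0 <= v <= 1:
                raise ConfigError(f"context_baseline[{k}]: level outside [0, 1]")
        if not 0 <= self.dmr_fraction <= 1:
            raise ConfigError("dmr_fraction must lie in [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the synthetic data."""

    #: columns: pair (e.g. "Ad_vs_At"), chrom (diploid side), start, end,
    #: context, effect (tetraploid true level minus diploid true level)
    planted_dmrs: pd.DataFrame
    #: per quartet: parental_state, progeny_state, transition
    pair_bias_label: pd.DataFrame
    #: per quartet: major, subcategory
    pair_eld_label: pd.DataFrame
    #: per quartet: a_mean, b_mean, at_mean, bt_mean (normalized units)
    planted_expression_means: pd.DataFrame


@dataclass
class GenomeBundle:
    config: SimConfig
    sequences: dict[str, dict[str, str]]
    genes: pd.DataFrame
    tes: pd.DataFrame
    blocks: list[CollinearBlock]
    quartets: pd.DataFrame


def _empty_genes() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["genome", "gene_id", "chrom", "start", "end", "strand", "length"]
    )


def find_cytosines(sequence: str, chrom: str) -> pd.DataFrame:
    """Vectorized enumeration of all context-classifiable cytosines.

    Returns chrom, pos (1-based), strand, context for both strands;
    cytosines whose 2-base context runs off the sequence end are skipped.
    """
    arr = np.frombuffer(sequence.upper().encode(), dtype="S1")
    n = arr.size
    rows = []
    # plus strand: C at i; CG needs one following base, CHG/CHH need two
    ci = np.flatnonzero(arr == b"C")
    ci = ci[ci < n - 1]
    if ci.size:
        n1 = arr[ci + 1]
        is_cg = n1 == b"G"
        cg = ci[is_cg]
        rest = ci[~is_cg]
        rest = rest[rest < n - 2]
        if cg.size:
            rows.append(pd.DataFrame({"chrom": chrom, "pos": cg + 1, "strand": "+", "context": "CG"}))
        if rest.size:
            ctx = np.where(arr[rest + 2] == b"G", "CHG", "CHH")
            rows.append(pd.DataFrame({"chrom": chrom, "pos": rest + 1, "strand": "+", "context": ctx}))
    # minus strand: G at i; context bases are complements of arr[i-1], arr[i-2]
    gi = np.flatnonzero(arr == b"G")
    gi = gi[gi >= 1]
    if gi.size:
        p1 = arr[gi - 1]
        is_cg = p1 == b"C"
        cg = gi[is_cg]
        rest = gi[~is_cg]
        rest = rest[rest >= 2]
        if cg.size:
            rows.append(pd.DataFrame({"chrom": chrom, "pos": cg + 1, "strand": "-", "context": "CG"}))
        if rest.size:
            ctx = np.where(arr[rest - 2] == b"C", "CHG", "CHH")
            rows.append(pd.DataFrame({"chrom": chrom, "pos": rest + 1, "strand": "-", "context": ctx}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context"])
    out = pd.concat(rows, ignore_index=True).sort_values(["pos", "strand"], ignore_index=True)
    return out


def simulate_genomes(config: SimConfig) -> GenomeBundle:
    """Four toy genomes with non-overlapping genes, TEs, quartets and blocks.

    One chromosome per genome; the A lineage (Ad/At) and B lineage (Ai/Bt)
    each share a sequence, giving exact whole-chromosome collinear blocks.
    Genes sit one per equal slot with >= 2 kb margins so every gene body
    plus 2 kb flank lies inside a collinear block.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_quartets
    sequences: dict[str, dict[str, str]] = {}
    lineage_seq = {}
    for lin in ("A", "B"):
        seq = "".join(rng.choice(list("ACGT"), size=config.chrom_length_bp))
        lineage_seq[lin] = seq
    for g in GENOMES:
        lin = "A" if g in ("Ad", "At") else "B"
        sequences[g] = {f"{g}_chr1": lineage_seq[lin]}

    gene_rows, te_rows, quartet_rows = [], [], []
    if n > 0:
        slot = config.chrom_length_bp // n
        margin = min(2000, max(20, slot // 3))
        for lin, members in (("A", ("Ad", "At")), ("B", ("Ai", "Bt"))):
            lengths = rng.integers(
                max(60, min(400, slot // 4)), max(61, min(1001, slot - 2 * margin)), size=n
            )
            offsets = rng.integers(0, np.maximum(slot - 2 * margin - lengths, 1))
            strands = rng.choice(["+", "-"], size=n)
            for i in range(n):
                start = i * slot + margin + int(offsets[i])
                end = start + int(lengths[i])
                for g in members:
                    gene_rows.append(
                        {
                            "genome": g,
                            "gene_id": f"{g}_g{i:04d}",
                            "chrom": f"{g}_chr1",
                            "start": start,
                            "end": end,
                            "strand": strands[i],
                            "length": end - start,
                        }
                    )
                # one TE per slot in the inter-gene margin, shared per lineage
                te_len = int(rng.integers(80, min(300, max(81, margin))))
                te_start = i * slot + int(rng.integers(0, max(margin - te_len, 1)))
                for g in members:
                    te_rows.append(
                        {
                            "genome": g,
                            "te_id": f"{g}_te{i:04d}",
                            "chrom": f"{g}_chr1",
                            "start": te_start,
                            "end": te_start + te_len,
                            "strand": "+",
                        }
                    )
        for i in range(n):
            quartet_rows.append(
                {
                    "ad_gene": f"Ad_g{i:04d}",
                    "ai_gene": f"Ai_g{i:04d}",
                    "at_gene": f"At_g{i:04d}",
                    "bt_gene": f"Bt_g{i:04d}",
                }
            )

    blocks = [
        CollinearBlock("Ad_chr1", 0, config.chrom_length_bp, "At_chr1", 0,
                       config.chrom_length_bp, 5000.0, "same"),
        CollinearBlock("Ai_chr1", 0, config.chrom_length_bp, "Bt_chr1", 0,
                       config.chrom_length_bp, 5000.0, "same"),
    ]
    genes = pd.DataFrame(gene_rows) if gene_rows else _empty_genes()
    tes = pd.DataFrame(te_rows) if te_rows else pd.DataFrame(
        columns=["genome", "te_id", "chrom", "start", "end", "strand"]
    )
    quartets = pd.DataFrame(quartet_rows, columns=["ad_gene", "ai_gene", "at_gene", "bt_gene"])
    quartets.index = pd.RangeIndex(len(quartets), name="quartet")
    return GenomeBundle(config, sequences, genes, tes, blocks, quartets)


def _feasible_sign(base: float, effect: float, rng: np.random.Generator) -> float:
    """Pick a planted-effect sign keeping the shifted level inside [0, 1]."""
    up_ok = base + effect <= 1.0
    down_ok = base - effect >= 0.0
    if up_ok and down_ok:
        return effect if rng.random() < 0.5 else -effect
    if up_ok:
        return effect
    if down_ok:
        return -effect
    raise ConfigError(
        f"dmr_effect {effect} infeasible for baseline {base}: neither direction stays in [0, 1]"
    )


def simulate_methylomes(
    bundle: GenomeBundle, config: SimConfig | None = None
) -> tuple[dict[str, MethylomeSample], dict[str, pd.DataFrame], SimTruth]:
    """Per-replicate cytosine call tables for all four genomes, plus truth.

    Observed methylated counts follow Binomial(coverage, q) with
    q = level*(1-e) + (1-level)*e where e is the bisulfite non-conversion
    error, mirroring symmetric false-positive conversion noise.  Planted
    DMR windows shift the true level of the tetraploid subgenome by the
    (feasibility-signed) context effect.  Returns (samples keyed by
    sample_id, unmethylated spike-in control tables per sample, truth).
    """
    config = config or bundle.config
    rng = np.random.default_rng(config.seed + 1)
    windows = tile_windows(bundle.blocks, 100)

    planted = []
    level_shift: dict[tuple[str, str], dict[int, float]] = {}
    for dip, tet in LINEAGES.items():
        chrom_d = f"{dip}_chr1"
        win = windows[windows["chrom"] == chrom_d]
        for context, effect in config.dmr_effect.items():
            base = config.context_baseline[context]
            n_pick = int(round(config.dmr_fraction * len(win)))
            if n_pick == 0:
                continue
            picks = rng.choice(win.index.to_numpy(), size=n_pick, replace=False)
            shifts = level_shift.setdefault((tet, context), {})
            for w in picks:
                signed = _feasible_sign(base, effect, rng)
                start = int(win.loc[w, "start"])
                shifts[start // 100] = signed
                planted.append(
                    {
                        "pair": f"{dip}_vs_{tet}",
                        "chrom": chrom_d,
                        "start": start,
                        "end": int(win.loc[w, "end"]),
                        "context": context,
                        "effect": signed,
                    }
                )

    e = config.conversion_error
    samples: dict[str, MethylomeSample] = {}
    controls: dict[str, pd.DataFrame] = {}
    for g in GENOMES:
        chrom = f"{g}_chr1"
        sites = find_cytosines(bundle.sequences[g][chrom], chrom)
        base_level = sites["context"].map(config.context_baseline).to_numpy(dtype=float)
        level = base_level.copy()
        for context in config.dmr_effect:
            shifts = level_shift.get((g, context))
            if not shifts:
                continue
            in_ctx = sites["context"].to_numpy() == context
            widx = (sites["pos"].to_numpy() - 1) // 100
            shift_arr = np.array([shifts.get(int(w), 0.0) for w in widx])
            level = np.clip(level + np.where(in_ctx, shift_arr, 0.0), 0.0, 1.0)
        for rep in range(1, config.n_meth_replicates + 1):
            lvl = level
            if config.meth_replicate_sd > 0:
                lvl = np.clip(
                    level + rng.normal(0, config.meth_replicate_sd, size=level.size), 0, 1
                )
            cov = rng.poisson(config.coverage_mean, size=len(sites))
            keep = cov > 0
            q = lvl * (1 - e) + (1 - lvl) * e
            c = rng.binomial(cov[keep], q[keep])
            calls = sites.loc[keep, ["chrom", "pos", "strand", "context"]].copy()
            calls["c_count"] = c
            calls["ct_count"] = cov[keep]
            sid = f"{g}_rep{rep}"
            samples[sid] = MethylomeSample(
                sample_id=sid,
                species="Ah" if g in ("At", "Bt") else g,
                genome=g,
                replicate=rep,
                calls=calls.reset_index(drop=True),
            )
            # unmethylated spike-in (phage-like) for the conversion-rate estimate
            n_ctl = 2000
            ctl_cov = rng.poisson(config.coverage_mean, size=n_ctl)
            ctl_cov = ctl_cov[ctl_cov > 0]
            controls[sid] = pd.DataFrame(
                {
                    "chrom": "spikein",
                    "pos": np.arange(1, len(ctl_cov) + 1),
                    "strand": "+",
                    "context": "CHH",
                    "c_count": rng.binomial(ctl_cov, e),
                    "ct_count": ctl_cov,
                }
            )

    truth = SimTruth(
        planted_dmrs=pd.DataFrame(
            planted, columns=["pair", "chrom", "start", "end", "context", "effect"]
        ),
        pair_bias_label=pd.DataFrame(columns=["parental_state", "progeny_state", "transition"]),
        pair_eld_label=pd.DataFrame(columns=["major", "subcategory"]),
        planted_expression_means=pd.DataFrame(columns=["a_mean", "b_mean", "at_mean", "bt_mean"]),
    )
    return samples, controls, truth


def _eld_geometry(f: float) -> dict[str, tuple[float, float, float]]:
    """Planted (a, b, t) means per subcategory, in multiples of the base level.

    Every pair of unequal groups differs by at least factor ``f``;
    additivity uses parents f**2 apart so the intermediate total still
    clears f against both.
    """
    return {
        "none": (1, 1, 1),
        "I": (1, f * f, f),
        "XII": (f * f, 1, f),
        "II": (f, 1, f),
        "XI": (1, f, 1),
        "IV": (1, f, f),
        "IX": (f, 1, 1),
        "V": (1, f, f * f),
        "VI": (1, 1, f),
        "VIII": (f, 1, f * f),
        "III": (1, f, 1 / f),
        "VII": (1, 1, 1 / f),
        "X": (f, 1, 1 / f),
    }


def _eld_means(sub: str, base: float, fold: float) -> tuple[float, float, float]:
    a_m, b_m, t_m = _eld_geometry(fold)[sub]
    return base * a_m, base * b_m, base * t_m


def simulate_expression(
    bundle: GenomeBundle, config: SimConfig | None = None, truth: SimTruth | None = None
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, SimTruth]:
    """Negative-binomial count matrices realizing planted bias/ELD labels.

    Per quartet an ELD subcategory is drawn from ``eld_fractions`` (uniform
    within the class); the parental a-vs-b relation is then fixed by that
    geometry, and a bias-transition label compatible with it is drawn from
    the renormalized ``bias_fractions``, which determines the At/Bt split
    of the tetraploid total.  All unequal groups differ by at least
    ``expr_fold`` (>= 4-fold by default); library sizes cycle through a
    >= 2-fold depth range to exercise normalization.  Returns (counts per
    species, sample sheet, truth).
    """
    config = config or bundle.config
    rng = np.random.default_rng(config.seed + 2)
    n = config.n_quartets
    fold = config.expr_fold
    base = config.base_expression

    eld_classes = list(config.eld_fractions)
    eld_p = np.array([config.eld_fractions[k] for k in eld_classes], dtype=float)
    eld_p = eld_p / eld_p.sum()

    labels, means = [], []
    for q in range(n):
        major = rng.choice(eld_classes, p=eld_p)
        sub = rng.choice(_SUBCATS[major])
        a_mean, b_mean, t_mean = _eld_means(sub, base, fold)
        parental = (
            "A-bias" if a_mean > b_mean else "B-bias" if b_mean > a_mean else "none"
        )
        # transitions compatible with the parental state forced by geometry
        if parental == "none":
            compat = ["Unbiased", "NovelBiasInProgeny"]
        else:
            compat = ["ParentalCondition", "NoBiasInProgeny", "NovelBiasInProgeny"]
        w = np.array([config.bias_fractions[c] for c in compat], dtype=float)
        if w.sum() == 0:
            w = np.ones_like(w)
        transition = rng.choice(compat, p=w / w.sum())
        if transition == "ParentalCondition":
            progeny = parental
        elif transition in ("NoBiasInProgeny", "Unbiased"):
            progeny = "none"
        else:  # NovelBiasInProgeny: biased, and different from the parental state
            if parental == "none":
                progeny = rng.choice(["A-bias", "B-bias"])
            else:
                progeny = "B-bias" if parental == "A-bias" else "A-bias"
        if progeny == "none":
            at_mean = bt_mean = t_mean / 2
        elif progeny == "A-bias":
            at_mean, bt_mean = t_mean * fold / (fold + 1), t_mean / (fold + 1)
        else:
            at_mean, bt_mean = t_mean / (fold + 1), t_mean * fold / (fold + 1)
        labels.append(
            {
                "major": major,
                "subcategory": sub,
                "parental_state": parental,
                "progeny_state": progeny,
                "transition": transition,
            }
        )
        means.append({"a_mean": a_mean, "b_mean": b_mean, "at_mean": at_mean, "bt_mean": bt_mean})

    label_df = pd.DataFrame(labels, index=pd.RangeIndex(n, name="quartet"))
    means_df = pd.DataFrame(means, index=pd.RangeIndex(n, name="quartet"))

    lengths = bundle.genes.set_index("gene_id")["length"]
    depth_cycle = (0.6, 1.0, 1.35)

    def draw(mean: np.ndarray) -> np.ndarray:
        mean = np.maximum(mean, 1e-9)
        if config.nb_dispersion < 1e-8:
            return rng.poisson(mean)
        r = 1.0 / config.nb_dispersion
        return rng.negative_binomial(r, r / (r + mean))

    counts: dict[str, pd.DataFrame] = {}
    sheet_rows = []
    role_map = {
        "Ad": [("ad_gene", "a_mean")],
        "Ai": [("ai_gene", "b_mean")],
        "Ah": [("at_gene", "at_mean"), ("bt_gene", "bt_mean")],
    }
    for sp in SPECIES:
        gene_ids = np.concatenate(
            [bundle.quartets[col].to_numpy() for col, _ in role_map[sp]]
        ) if n else np.array([], dtype=str)
        mu_expr = np.concatenate(
            [means_df[mcol].to_numpy() for _, mcol in role_map[sp]]
        ) if n else np.array([])
        glen = lengths.reindex(gene_ids).to_numpy(dtype=float) if n else np.array([])
        mat = {}
        for rep in range(1, config.n_expr_replicates + 1):
            depth = depth_cycle[(rep - 1) % len(depth_cycle)] * rng.uniform(0.95, 1.05)
            sid = f"{sp}_rna{rep}"
            mu = mu_expr * (glen / 1000.0) * depth * config.depth_scale
            mat[sid] = draw(mu) if n else np.array([], dtype=int)
            sheet_rows.append({"sample_id": sid, "species": sp, "replicate": rep})
        counts[sp] = pd.DataFrame(mat, index=pd.Index(gene_ids, name="gene_id"))

    new_truth = SimTruth(
        planted_dmrs=truth.planted_dmrs if truth is not None else pd.DataFrame(
            columns=["pair", "chrom", "start", "end", "context", "effect"]
        ),
        pair_bias_label=label_df[["parental_state", "progeny_state", "transition"]],
        pair_eld_label=label_df[["major", "subcategory"]],
        planted_expression_means=means_df,
    )
    return counts, pd.DataFrame(sheet_rows), new_truth


def simulate_bundle(config: SimConfig):
    """Convenience driver: genomes + methylomes + expression in one call."""
    bundle = simulate_genomes(config)
    samples, controls, truth = simulate_methylomes(bundle, config)
    counts, sheet, truth = simulate_expression(bundle, config, truth)
    return bundle, samples, controls, counts, sheet, truth


# ---------------------------------------------------------------------------
# file emission / ingestion


def write_bundle(outdir: str | Path, bundle: GenomeBundle, samples, controls, counts,
                 sheet: pd.DataFrame, truth: SimTruth) -> None:
    """Emit the whole synthetic study in the package's plain-text dialects."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genomes.fa", "w") as fh:
        for g in GENOMES:
            for chrom, seq in bundle.sequences[g].items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
    with open(out / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g in bundle.genes.itertuples(index=False):
            fh.write(
                f"{g.chrom}\tallometh_sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
    bundle.tes[["chrom", "start", "end", "te_id", "strand"]].assign(score=0)[
        ["chrom", "start", "end", "te_id", "score", "strand"]
    ].to_csv(out / "tes.bed", sep="\t", header=False, index=False)
    pd.DataFrame(
        [
            {
                "q_chrom": b.q_chrom, "q_start": b.q_start, "q_end": b.q_end,
                "t_chrom": b.t_chrom, "t_start": b.t_start, "t_end": b.t_end,
                "score": b.score, "strand": "+" if b.orientation == "same" else "-",
            }
            for b in bundle.blocks
        ]
    ).to_csv(out / "collinear_blocks.tsv", sep="\t", index=False)
    bundle.quartets.to_csv(out / "quartets.tsv", sep="\t", index=False)
    for sid, sample in samples.items():
        write_methratio(sample.calls, out / f"methratio_{sid}.tsv")
    for sid, ctl in controls.items():
        write_methratio(ctl, out / f"control_{sid}.tsv")
    for sp, mat in counts.items():
        merged = mat.copy()
        merged.insert(0, "length", bundle.genes.set_index("gene_id")["length"].reindex(mat.index))
        merged.to_csv(out / f"counts_{sp}.tsv", sep="\t")
    sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "config": asdict(bundle.config),
                "planted_dmrs": truth.planted_dmrs.to_dict(orient="records"),
                "pair_bias_label": truth.pair_bias_label.to_dict(orient="index"),
                "pair_eld_label": truth.pair_eld_label.to_dict(orient="index"),
                "planted_expression_means": truth.planted_expression_means.to_dict(
                    orient="index"
                ),
            },
            fh,
            indent=1,
            default=float,
        )
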