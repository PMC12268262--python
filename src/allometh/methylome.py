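"""Per-cytosine methylation calls and the summaries built on them.

Bisulfite sequencing reads unmethylated cytosines as thymines, so each
cytosine position carries a methylated-read count (#C) and a total
informative coverage (#C + #T).  Every regional statistic in this module is
the *weighted* methylation level — pooled (sum #C)/(sum #C + #T) over the
qualifying sites — never a mean of per-site ratios.

Coordinate convention: input files (methratio tables, GFF3) are 1-based
inclusive; every in-memory interval in this package is 0-based half-open.
The ``pos`` column of a call table stays 1-based exactly as read from disk;
interval selection converts internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests
from scipy import stats

from ._errors import FormatError, ParameterError, RowError

CONTEXTS = ("CG", "CHG", "CHH")

#: columns a methratio-style table must provide (extra columns are ignored)
METHRATIO_COLUMNS = ("chrom", "pos", "strand", "context", "ratio", "eff_CT", "C_count", "CT_count")

#: canonical in-memory call-table columns
CALL_COLUMNS = ("chrom", "pos", "strand", "context", "c_count", "ct_count")


@dataclass
class MethylomeSample:
    """One biological replicate's cytosine call table plus its metadata.

    ``calls`` holds one row per (chrom, pos, strand): chrom, pos (1-based),
    strand, context, c_count, ct_count.
    """

    sample_id: str
    species: str = ""
    genome: str = ""
    replicate: int = 0
    calls: pd.DataFrame = field(default_factory=lambda: empty_calls())
    conversion_rate: float | None = None

    def __post_init__(self) -> None:
        if self.conversion_rate is not None and not 0.5 < self.conversion_rate <= 1.0:
            raise ParameterError(
                f"conversion_rate must lie in (0.5, 1], got {self.conversion_rate}"
            )
        dup = self.calls.duplicated(subset=["chrom", "pos", "strand"])
        if dup.any():
            raise RowError(
                f"duplicate (chrom, pos, strand) keys in sample {self.sample_id!r}: "
                f"{self.calls.loc[dup, ['chrom', 'pos', 'strand']].iloc[0].tolist()}"
            )


@dataclass
class MetaProfile:
    """Binned methylation profile over features: flank | body | flank."""

    n_bins_flank: int
    n_bins_body: int
    flank_bp: int
    #: long-form table with columns context, bin_index, level (NaN = missing)
    table: pd.DataFrame

    @property
    def n_bins(self) -> int:
        return 2 * self.n_bins_flank + self.n_bins_body


def empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "c_count": pd.Series(dtype=np.int64),
            "ct_count": pd.Series(dtype=np.int64),
        }
    )


def read_methratio(path: str | Path, sample_id: str | None = None, **meta) -> MethylomeSample:
    """Read a methratio-style TSV into a :class:`MethylomeSample`.

    The file must be tab-separated with a header naming at least the columns
    in :data:`METHRATIO_COLUMNS`; extra columns are ignored.  Rows violating
    ``0 <= c_count <= ct_count``, an unknown context, or ``pos < 1`` raise a
    :class:`RowError` naming the first offending data line (1-based,
    counting the header as line 1).
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "context": str})
    missing = [c for c in METHRATIO_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    calls = table.loc[:, ["chrom", "pos", "strand", "context", "C_count", "CT_count"]].rename(
        columns={"C_count": "c_count", "CT_count": "ct_count"}
    )
    bad = (
        (calls["c_count"] < 0)
        | (calls["c_count"] > calls["ct_count"])
        | (calls["pos"] < 1)
        | ~calls["context"].isin(CONTEXTS)
        | ~calls["strand"].isin(("+", "-"))
    )
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
        raise RowError(f"{path}: invalid call at line {line}: {calls.loc[bad.idxmax()].tolist()}")
    calls = calls.astype({"pos": np.int64, "c_count": np.int64, "ct_count": np.int64})
    return MethylomeSample(sample_id=sample_id or path.stem, calls=calls.reset_index(drop=True), **meta)


def write_methratio(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a call table in the methratio dialect accepted by :func:`read_methratio`."""
    out = calls.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["ratio"] = np.where(out["ct_count"] > 0, out["c_count"] / out["ct_count"], np.nan)
    out["eff_CT"] = out["ct_count"]
    out = out.rename(columns={"c_count": "C_count", "ct_count": "CT_count"})
    out[list(METHRATIO_COLUMNS)].to_csv(path, sep="\t", index=False, float_format="%.6g")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def call_context(sequence: str, pos: int, strand: str) -> str | None:
    """Classify the cytosine at 1-based ``pos`` on ``strand`` as CG/CHG/CHH.

    Returns ``None`` when the addressed base is not a cytosine on that
    strand or when the two following bases run off the sequence end.
    """
    i = pos - 1
    if i < 0 or i >= len(sequence):
        return None
    if strand == "+":
        if sequence[i].upper() != "C":
            return None
        nxt = sequence[i + 1 : i + 3].upper()
    elif strand == "-":
        if sequence[i].upper() != "G":
            return None
        nxt = sequence[max(0, i - 2) : i].upper().translate(_COMPLEMENT)[::-1]
        if i - 2 < 0:
            nxt = nxt[: i]  # truncated at the sequence start
    else:
        raise ParameterError(f"strand must be '+' or '-', got {strand!r}")
    if len(nxt) < 1:
        return None
    if nxt[0] == "G":
        return "CG"
    if len(nxt) < 2:
        return None
    if nxt[1] == "G":
        return "CHG"
    if nxt[0] in "ACT" and nxt[1] in "ACT":
        return "CHH"
    return None  # ambiguous base (N) in the context


def _select(
    calls: pd.DataFrame,
    region: tuple[str, int, int] | str | None = None,
    context: str | Iterable[str] | None = None,
) -> pd.DataFrame:
    sel = calls
    if region is not None and region != "genome":
        chrom, start, end = region
        # pos is 1-based; [start, end) is 0-based half-open
        sel = sel[(sel["chrom"] == chrom) & (sel["pos"] > start) & (sel["pos"] <= end)]
    if context is not None:
        wanted = (context,) if isinstance(context, str) else tuple(context)
        unknown = set(wanted) - set(CONTEXTS)
        if unknown:
            raise ParameterError(f"unknown context(s) {sorted(unknown)}")
        sel = sel[sel["context"].isin(wanted)]
    return sel


def weighted_methylation(
    calls: pd.DataFrame,
    region: tuple[str, int, int] | str | None = None,
    context: str | Iterable[str] | None = None,
) -> float:
    """Pooled (sum #C)/(sum #C+#T) over covered sites of ``context`` in ``region``.

    Returns NaN ("missing") when no covered site qualifies — never zero.
    """
    sel = _select(calls, region, context)
    total = int(sel["ct_count"].sum())
    if total == 0:
        return math.nan
    return float(sel["c_count"].sum() / total)


def conversion_rate(control_calls: pd.DataFrame) -> float:
    """Bisulfite conversion rate from an unmethylated spike-in genome.

    rate = (sum #T)/(sum #C+#T): the fraction of reads over control
    cytosines that converted.  1 - rate is the false-methylation error rate
    fed to :func:`call_methylcytosines`.
    """
    total = int(control_calls["ct_count"].sum())
    if total == 0:
        raise ParameterError("conversion_rate: zero total coverage on the control genome")
    t_count = total - int(control_calls["c_count"].sum())
    return float(t_count / total)


def call_methylcytosines(
    sample: MethylomeSample,
    error_rate: float,
    q_threshold: float = 0.05,
    min_coverage: int = 4,
) -> set[tuple[str, int, str]]:
    """Binomial-test methylcytosine calls at FDR ``q_threshold``.

    Each site with ``ct_count >= min_coverage`` is tested against the
    null that all its C reads are bisulfite non-conversion failures:
    upper-tail P(X >= c_count | n = ct_count, p = error_rate).  P-values are
    Benjamini-Hochberg adjusted across all tested sites; a site is called
    methylated when its adjusted p <= q_threshold.
    """
    if not 0.0 < error_rate < 0.5:
        raise ParameterError(f"error_rate must lie in (0, 0.5), got {error_rate}")
    calls = sample.calls
    tested = calls[calls["ct_count"] >= min_coverage]
    if tested.empty:
        return set()
    # P(X >= c) = sf(c - 1); c == 0 gives p = 1 and is never called
    pvals = stats.binom.sf(tested["c_count"].to_numpy() - 1, tested["ct_count"].to_numpy(), error_rate)
    reject, _, _, _ = multipletests(pvals, alpha=q_threshold, method="fdr_bh")
    hits = tested.loc[reject]
    return set(zip(hits["chrom"], hits["pos"].astype(int), hits["strand"]))


def global_level(sample: MethylomeSample, context: str) -> float:
    """Genome-wide weighted methylation level for one context."""
    return weighted_methylation(sample.calls, "genome", context)


def chromosome_track(
    sample: MethylomeSample,
    window_bp: int,
    context: str,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Pooled weighted level in tiling windows per chromosome (bedGraph-ready).

    Returns columns chrom, start, end (0-based half-open), level; windows
    with no covered site carry NaN.  When ``chrom_lengths`` is omitted each
    chromosome extends to its last covered position.
    """
    if window_bp < 100:
        raise ParameterError(f"window_bp must be >= 100, got {window_bp}")
    calls = _select(sample.calls, context=context)
    rows = []
    for chrom, grp in calls.groupby("chrom", sort=True):
        length = (
            int(chrom_lengths[chrom]) if chrom_lengths is not None else int(grp["pos"].max())
        )
        n_win = max(1, -(-length // window_bp))
        idx = np.minimum((grp["pos"].to_numpy() - 1) // window_bp, n_win - 1)
        c = np.bincount(idx, weights=grp["c_count"].to_numpy(), minlength=n_win)
        ct = np.bincount(idx, weights=grp["ct_count"].to_numpy(), minlength=n_win)
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(ct > 0, c / np.maximum(ct, 1), np.nan)
        starts = np.arange(n_win) * window_bp
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + window_bp, length),
                    "level": level,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end", "level"])
    return pd.concat(rows, ignore_index=True)


def metaprofile(
    sample: MethylomeSample,
    features: pd.DataFrame,
    flank_bp: int = 2000,
    n_bins_body: int = 20,
    n_bins_flank: int = 20,
    contexts: Sequence[str] = CONTEXTS,
) -> MetaProfile:
    """Strand-oriented binned methylation profile over gene/TE features.

    ``features`` needs columns chrom, start, end (0-based half-open),
    strand.  Bin 0 is the 5'-most upstream flank bin; upstream and
    downstream flanks are fixed ``flank_bp`` windows split into
    ``n_bins_flank`` bins each, and the body is rescaled to ``n_bins_body``
    bins (a site at body fraction f lands in bin floor(f * n_bins_body), so
    features shorter than the bin count contribute by fractional overlap).
    Counts are pooled across all features before dividing, so each bin is a
    weighted methylation level.
    """
    n_total = 2 * n_bins_flank + n_bins_body
    pos = sample.calls["pos"].to_numpy() - 1  # 0-based site coordinate
    ctx = sample.calls["context"].to_numpy()
    c_cnt = sample.calls["c_count"].to_numpy(dtype=float)
    ct_cnt = sample.calls["ct_count"].to_numpy(dtype=float)
    chrom_arr = sample.calls["chrom"].to_numpy()

    c_sum = {k: np.zeros(n_total) for k in contexts}
    ct_sum = {k: np.zeros(n_total) for k in contexts}

    for feat in features.itertuples(index=False):
        lo, hi = int(feat.start), int(feat.end)
        m = (chrom_arr == feat.chrom) & (pos >= lo - flank_bp) & (pos < hi + flank_bp)
        if not m.any():
            continue
        p = pos[m]
        bins = np.empty(p.shape, dtype=int)
        up = p < lo
        down = p >= hi
        body = ~(up | down)
        bins[up] = ((p[up] - (lo - flank_bp)) * n_bins_flank) // flank_bp
        frac = (p[body] - lo) / max(hi - lo, 1)
        bins[body] = n_bins_flank + np.minimum((frac * n_bins_body).astype(int), n_bins_body - 1)
        bins[down] = (
            n_bins_flank + n_bins_body + ((p[down] - hi) * n_bins_flank) // flank_bp
        )
        if feat.strand == "-":
            bins = n_total - 1 - bins
        for k in contexts:
            sel = ctx[m] == k
            if sel.any():
                c_sum[k] += np.bincount(bins[sel], weights=c_cnt[m][sel], minlength=n_total)
                ct_sum[k] += np.bincount(bins[sel], weights=ct_cnt[m][sel], minlength=n_total)

    records = []
    for k in contexts:
        with np.errstate(invalid="ignore", divide="ignore"):
            level = np.where(ct_sum[k] > 0, c_sum[k] / np.maximum(ct_sum[k], 1), np.nan)
        for b in range(n_total):
            records.append({"context": k, "bin_index": b, "level": level[b]})
    return MetaProfile(
        n_bins_flank=n_bins_flank,
        n_bins_body=n_bins_body,
        flank_bp=flank_bp,
        table=pd.DataFrame(records),
    )


def pool_replicates(samples: Iterable[MethylomeSample | pd.DataFrame]) -> pd.DataFrame:
    """Sum counts of replicate call tables site-by-site (pooled, not averaged)."""
    frames = [s.calls if isinstance(s, MethylomeSample) else s for s in samples]
    cat = pd.concat(frames, ignore_index=True)
    return (
        cat.groupby(["chrom", "pos", "strand", "context"], as_index=False)[["c_count", "ct_count"]]
        .sum()
        .sort_values(["chrom", "pos", "strand"], ignore_index=True)
    )


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    out = track.dropna(subset=["level"])
    out.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


def write_metaprofile(profile: MetaProfile, path: str | Path) -> None:
    profile.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
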