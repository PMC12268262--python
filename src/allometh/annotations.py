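"""Readers for the annotation formats the pipeline consumes.

All returned intervals are 0-based half-open, matching the package-wide
in-memory convention (GFF3's 1-based inclusive coordinates are converted
on input).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

import gffutils

from ._errors import FormatError


def read_fasta(path: str | Path) -> dict[str, str]:
    """Chromosome name -> sequence."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_gff3_genes(path: str | Path, featuretype: str = "gene") -> pd.DataFrame:
    """Gene models from a GFF3 file: gene_id, chrom, start, end, strand, length."""
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    for feat in db.features_of_type(featuretype):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {
                "gene_id": gene_id,
                "chrom": feat.seqid,
                "start": feat.start - 1,  # to 0-based half-open
                "end": feat.end,
                "strand": feat.strand if feat.strand in "+-" else "+",
                "length": feat.end - feat.start + 1,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "length"])


def read_bed6(path: str | Path) -> pd.DataFrame:
    """BED6 intervals (already 0-based half-open): chrom, start, end, name, score, strand."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    if table.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    table = table.iloc[:, :6]
    table.columns = names[: table.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in table.columns:
            table[col] = default
    return table
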