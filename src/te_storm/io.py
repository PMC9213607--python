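"""Readers and writers for the plain-text formats the pipeline exchanges.

All genomic intervals are 0-based half-open in memory.  BED output keeps
that convention; the RepeatMasker-style annotation table is written 1-based
inclusive, matching how that format is printed in the wild.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen",
]


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    """Write a BED6 table; expects chrom/start/end/name/score/strand columns."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    return df


def write_bed4(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed4(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "state"],
        dtype={"chrom": str, "state": str},
    )


def write_blast_tabular(records: Iterable, path: str | Path) -> None:
    """Write alignment records as BLAST outfmt-6 plus a trailing qlen column."""
    rows = []
    for r in records:
        rows.append({
            "qseqid": r.transcript_id, "sseqid": r.locus_id,
            "pident": r.pident, "length": r.aln_len,
            "mismatch": r.mismatch, "gapopen": r.gapopen,
            "qstart": r.qstart, "qend": r.qend,
            "sstart": r.sstart, "send": r.send,
            "evalue": r.evalue, "bitscore": r.bitscore, "qlen": r.qlen,
        })
    pd.DataFrame(rows, columns=BLAST_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_blast_tabular(path: str | Path) -> pd.DataFrame:
    """Read 12-column BLAST outfmt 6 with one extra qlen column; '#' lines skipped."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", names=BLAST_COLUMNS,
        dtype={"qseqid": str, "sseqid": str},
    )
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="locus_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})


def write_repeatmasker_table(loci: pd.DataFrame, path: str | Path) -> None:
    """RepeatMasker-.out-like table, coordinates 1-based inclusive."""
    out = loci.copy()
    out["begin"] = out["start"] + 1
    out["end1"] = out["end"]
    out[["chrom", "begin", "end1", "strand", "family", "te_class", "locus_id"]].to_csv(
        path, sep="\t", index=False,
        header=["query", "begin", "end", "strand", "repeat", "class", "locus_id"],
    )


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
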