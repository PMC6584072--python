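"""Readers/writers for the plain-text formats the pipeline consumes.

Hit tables use the 12-column BLAST tabular layout (``-outfmt 6``); counts,
lengths and design tables are TSV; sequences are FASTA via Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from helix_ieg.containers import CountMatrix

#: Column names of BLAST tabular output format 6.
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(path, species: str | None = None) -> pd.DataFrame:
    """Read an outfmt-6 hit table; optionally tag rows with a species label."""
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS,
                     comment="#")
    if species is not None:
        df["species"] = species
    return df


def write_hit_table(df: pd.DataFrame, path) -> None:
    df[OUTFMT6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_counts(counts_path, lengths_path=None) -> CountMatrix | pd.DataFrame:
    """Read a counts TSV (first column contig_id, then one column per sample).

    With ``lengths_path`` given, returns a :class:`CountMatrix`; otherwise the
    bare counts DataFrame.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if lengths_path is None:
        return counts
    return CountMatrix(counts, read_lengths(lengths_path))


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("contig_id").to_csv(path, sep="\t")


def read_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length").rename_axis("contig_id").to_csv(path, sep="\t")


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {id: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
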