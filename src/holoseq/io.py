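"""Light I/O helpers around Biopython/pandas for the pipeline's formats."""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BLAST6_COLUMNS = ["query_id", "subject_id", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send",
                  "e_value", "score"]


def write_fasta(records, path):
    """Write (id, sequence) pairs or Transcript-like objects as FASTA."""
    seqrecs = []
    for r in records:
        if hasattr(r, "sequence"):
            seqrecs.append(SeqRecord(Seq(r.sequence), id=r.id, description=""))
        else:
            rid, seq = r
            seqrecs.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")


def read_fasta(path) -> dict:
    """FASTA file -> {id: uppercase sequence string}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq_pairs(reads, path1, path2):
    """Write [(read_id, mate1, mate2), ...] as a Phred+33 FASTQ pair."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, m1, m2 in reads:
            f1.write(f"@{rid}/1\n{m1}\n+\n{'I' * len(m1)}\n")
            f2.write(f"@{rid}/2\n{m2}\n+\n{'I' * len(m2)}\n")


def read_fastq_pairs(path1, path2):
    """FASTQ mate files -> [(read_id, mate1, mate2), ...]."""
    out = []
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for r1, r2 in zip(it1, it2):
        rid = r1.id.rsplit("/", 1)[0]
        out.append((rid, str(r1.seq).upper(), str(r2.seq).upper()))
    return out


def read_blast_tab(path, e_cutoff: float | None = None) -> pd.DataFrame:
    """BLAST tabular (-outfmt 6) reader, optionally filtered on e-value."""
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS,
                     comment="#")
    if e_cutoff is not None:
        df = df[df["e_value"] < e_cutoff].reset_index(drop=True)
    return df


def read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_table(df: pd.DataFrame, path, index=False):
    df.to_csv(path, sep="\t", index=index)
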