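"""FASTA/FASTQ reading and writing, backed by Biopython.

Only plain uncompressed text files are handled; everything in this
pipeline is desk-scale.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ESTRecord, FastaRecord, ReadRecord


def read_fasta(path: str | Path) -> list[FastaRecord]:
    return [
        FastaRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable, path: str | Path) -> None:
    """Write any records carrying an id and a sequence as FASTA."""
    seqrecs = []
    for rec in records:
        rec_id = getattr(rec, "seq_id", None) or getattr(rec, "est_id", None) or getattr(
            rec, "unigene_id", None
        )
        seqrecs.append(SeqRecord(Seq(rec.sequence), id=rec_id, description=""))
    SeqIO.write(seqrecs, str(path), "fasta")


def read_ests(path: str | Path) -> list[ESTRecord]:
    return [
        ESTRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_fastq(path: str | Path) -> list[ReadRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        out.append(
            ReadRecord(
                rec.id,
                str(rec.seq).upper(),
                "".join(chr(q + 33) for q in quals),
            )
        )
    return out


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{read.quality}\n")
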