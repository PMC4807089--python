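"""Thin FASTA/FASTQ readers (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def read_reads(path) -> list[tuple[str, str]]:
    """FASTA or FASTQ by extension."""
    p = Path(path)
    if p.suffix.lower() in (".fq", ".fastq"):
        return read_fastq(p)
    return read_fasta(p)
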