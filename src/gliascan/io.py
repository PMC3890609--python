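"""Sequence and table input/output shared by all pipeline stages.

FASTA/FASTQ parsing is delegated to Biopython's SeqIO; this module only
adds dialect auto-detection and a minimal read container so the rest of
the package never touches file formats directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class Read:
    """One sequencing read: id, nucleotide sequence, optional quality."""

    read_id: str
    sequence: str
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")


@dataclass
class BarcodedRead(Read):
    """A read with a sample assignment ('unassigned' until demultiplexed)."""

    assigned_sample: str = "unassigned"


def detect_format(path: str | Path) -> str:
    """Guess fasta/fastq from extension, falling back on first character."""
    suffix = Path(path).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    if suffix in {".fa", ".fasta", ".fna", ".ffn"}:
        return "fasta"
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return "fastq"
    if first == ">":
        return "fasta"
    raise ValueError(f"{path}: cannot determine sequence format")


def read_sequences(path: str | Path) -> list[Read]:
    fmt = detect_format(path)
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        qual = rec.letter_annotations.get("phred_quality")
        reads.append(Read(rec.id, str(rec.seq).upper(), list(qual) if qual else None))
    return reads


def _to_records(reads: Iterable[Read], with_quality: bool) -> list[SeqRecord]:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        if with_quality:
            qual = r.quality if r.quality is not None else [40] * len(r.sequence)
            rec.letter_annotations["phred_quality"] = qual
        records.append(rec)
    return records


def write_fasta(reads: Iterable[Read], path: str | Path) -> None:
    SeqIO.write(_to_records(reads, with_quality=False), str(path), "fasta")


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    SeqIO.write(_to_records(reads, with_quality=True), str(path), "fastq")


def write_table(df, path: str | Path) -> None:
    """Write a DataFrame as TSV (the package's tabular interchange format)."""
    df.to_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
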