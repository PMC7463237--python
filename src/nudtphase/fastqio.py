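"""Paired-end FASTQ records and file I/O (Phred+33)."""
from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import ValidationError

PHRED_OFFSET = 33


def quals_to_string(quals: Iterable[int]) -> str:
    return "".join(chr(min(q, 93) + PHRED_OFFSET) for q in quals)


def string_to_quals(s: str) -> list[int]:
    return [ord(c) - PHRED_OFFSET for c in s]


@dataclass
class ReadPair:
    """One sequenced fragment: mate sequences with Phred+33 quality strings.

    Mate 1 is the fragment's 5' end read on the forward strand; mate 2 is the
    3' end read reverse-complemented, as emitted by paired-end sequencing.
    """

    pair_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValidationError(f"{self.pair_id}: sequence/quality length mismatch")


def _open(path: str | Path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path: str | Path, r2_path: str | Path) -> int:
    """Write mates to R1/R2 FASTQ files; returns the number of pairs written."""
    n = 0
    with _open(r1_path, "w") as f1, _open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{p.qual2}\n")
            n += 1
    return n


def _strip_mate_suffix(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[ReadPair]:
    """Iterate mate pairs from R1/R2 FASTQ files (plain or gzipped)."""
    with _open(r1_path, "r") as f1, _open(r2_path, "r") as f2:
        for rec1, rec2 in zip(
            SeqIO.parse(f1, "fastq"), SeqIO.parse(f2, "fastq"), strict=True
        ):
            pid1 = _strip_mate_suffix(rec1.id)
            pid2 = _strip_mate_suffix(rec2.id)
            if pid1 != pid2:
                raise ValidationError(f"mate name mismatch: {rec1.id} vs {rec2.id}")
            yield ReadPair(
                pair_id=pid1,
                seq1=str(rec1.seq),
                qual1=quals_to_string(rec1.letter_annotations["phred_quality"]),
                seq2=str(rec2.seq),
                qual2=quals_to_string(rec2.letter_annotations["phred_quality"]),
            )
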