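"""cDNA reference handling for the amplicon.

The study design sequences one RT-PCR amplicon spanning the NUDT15 coding
sequence, so a single FASTA record is the whole reference. A ``Reference``
pairs that record with the 0-based offset of CDS position 1 within it, which
is all that is needed to translate HGVS "c." coordinates into record indices.

``surrogate_reference`` builds a synthetic stand-in for the real transcript
(NM_018283 is not redistributed here): a random sequence of the real CDS
length carrying the catalog's reference bases at every panel site, flanked by
short UTR stubs. Panel-site context around the insertion anchor is fixed so
the 6-bp insertion cannot be gap-shifted, which keeps alignment tests exact.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import Catalog, VariantKind
from .errors import ReferenceValidationError

#: Length of the real NUDT15 coding sequence in bp (164 codons + stop).
NUDT15_CDS_LENGTH = 495


@dataclass(frozen=True)
class Reference:
    """An amplicon reference record with its CDS anchor.

    ``cds_offset`` is the 0-based index of CDS position 1 in ``seq``.
    """

    name: str
    seq: str
    cds_offset: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    def cds_index(self, cds_position: int) -> int:
        """0-based record index of a 1-based CDS position."""
        return self.cds_offset + cds_position - 1

    def base_at(self, cds_position: int) -> str:
        return self.seq[self.cds_index(cds_position)]

    def validate_panel(self, catalog: Catalog) -> None:
        """Check the reference carries each substitution's reference base.

        Raises ReferenceValidationError naming the position and expected base
        on the first mismatch.
        """
        for v in catalog.panel:
            if v.kind is not VariantKind.SUBSTITUTION:
                if self.cds_index(v.cds_end) >= len(self.seq):
                    raise ReferenceValidationError(
                        f"reference too short for insertion anchor c.{v.cds_end}"
                    )
                continue
            idx = self.cds_index(v.cds_start)
            if idx < 0 or idx >= len(self.seq):
                raise ReferenceValidationError(
                    f"reference does not cover CDS position {v.cds_start}"
                )
            if self.seq[idx] != v.ref_allele:
                raise ReferenceValidationError(
                    f"expected {v.ref_allele} at CDS position {v.cds_start}, "
                    f"found {self.seq[idx]}"
                )


def surrogate_reference(
    flank: int = 30,
    cds_length: int = NUDT15_CDS_LENGTH,
    seed: int = 20200901,
    name: str = "NUDT15_cDNA_surrogate",
) -> Reference:
    """Deterministic synthetic cDNA surrogate for the NUDT15 amplicon.

    Random bases except: ATG at CDS 1-3, fixed non-repetitive context at
    CDS 31-42 flanking the c.36_37 insertion anchor (so GGAGTC inserted
    between 36 and 37 has a unique placement), and the catalog reference
    bases G/G/C at CDS 52/101/415.
    """
    rng = np.random.default_rng(seed)
    total = flank + cds_length + flank
    bases = rng.choice(list("ACGT"), size=total)
    seq = list("".join(bases))
    off = flank

    def set_cds(pos: int, value: str) -> None:
        for i, b in enumerate(value):
            seq[off + pos - 1 + i] = b

    set_cds(1, "ATG")
    set_cds(31, "TTACAT")   # CDS 31-36: ends in T, not C → no left-shift of insGGAGTC
    set_cds(37, "TTGGCA")   # CDS 37-42: starts with T, not G → no right-shift
    set_cds(52, "G")
    set_cds(101, "G")
    set_cds(415, "C")
    return Reference(name=name, seq="".join(seq), cds_offset=off)


def load_reference(path: str | Path, cds_offset: int) -> Reference:
    """Read a single-record FASTA and anchor its CDS at ``cds_offset`` (0-based)."""
    record = SeqIO.read(str(path), "fasta")
    return Reference(name=record.id, seq=str(record.seq), cds_offset=cds_offset)


def write_reference(reference: Reference, path: str | Path) -> None:
    record = SeqRecord(Seq(reference.seq), id=reference.name, description=f"cds_offset={reference.cds_offset}")
    SeqIO.write([record], str(path), "fasta")
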