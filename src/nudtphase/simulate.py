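"""Paired-end amplicon read simulator.

Generates MiSeq-style 300-bp paired-end reads from a chosen NUDT15 diplotype:
each fragment picks one of the two haplotype sequences with probability 1/2,
a start uniform within the amplicon, and an insert length from a truncated
normal (defaults: mean 562 bp, the study's reported average, sd 60 bp).
Sequencing noise is i.i.d. base substitution at ``per_base_error``; PCR
template switching is modelled by ``chimera_rate``, the probability that
mate 2 is drawn from the *other* allele (the realistic threat to cis/trans
phasing). Everything is deterministic given the seed. A truth table records
each pair's source allele so downstream phasing can be scored exactly.

Indel sequencing errors, quality decay along the read, and barcode
demultiplexing are deliberately not modelled.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .catalog import Diplotype, StarAllele, VariantKind
from .errors import ConfigError, ReferenceValidationError
from .fastqio import ReadPair, quals_to_string
from .refseq import Reference

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateMap:
    """Bidirectional map between reference-record and allele-sequence indices.

    Insertions applied to the reference shift all downstream positions; the
    map tracks those shifts. Indices are 0-based record positions. Allele
    positions that fall inside inserted sequence map back to ``None``.
    """

    def __init__(self, insertions: list[tuple[int, int]]):
        # (last reference index before the insertion, inserted length)
        self._insertions = sorted(insertions)

    def ref_to_allele(self, ref_index: int) -> int:
        shift = sum(l for pos, l in self._insertions if ref_index > pos)
        return ref_index + shift

    def allele_to_ref(self, allele_index: int) -> int | None:
        shift = 0
        for pos, l in self._insertions:
            a_start = pos + shift + 1          # first inserted base, allele coords
            if allele_index < a_start:
                break
            if allele_index < a_start + l:
                return None                    # inside inserted sequence
            shift += l
        return allele_index - shift

    def cds_to_allele_cds(self, reference: Reference, cds_position: int) -> int:
        """Map a 1-based CDS coordinate to its 1-based position in the allele CDS."""
        ref_idx = reference.cds_index(cds_position)
        return self.ref_to_allele(ref_idx) - reference.cds_offset + 1


def build_allele_sequence(
    reference: Reference, allele: StarAllele
) -> tuple[str, CoordinateMap]:
    """Apply a star allele's variants to the reference amplicon sequence.

    Returns the haplotype sequence and the coordinate map accounting for any
    insertion shift. Raises ReferenceValidationError if the reference does
    not carry a substitution's expected reference base.
    """
    seq = list(reference.seq)
    insertions: list[tuple[int, int]] = []
    # Apply 3'→5' so earlier coordinates stay valid while editing.
    for v in sorted(allele.variants, key=lambda v: -v.cds_start):
        idx = reference.cds_index(v.cds_start)
        if v.kind is VariantKind.SUBSTITUTION:
            if seq[idx] != v.ref_allele:
                raise ReferenceValidationError(
                    f"expected {v.ref_allele} at CDS position {v.cds_start}, "
                    f"found {seq[idx]}"
                )
            seq[idx] = v.alt_allele
        else:
            seq[idx + 1 : idx + 1] = list(v.alt_allele)
            insertions.append((idx, len(v.alt_allele)))
    return "".join(seq), CoordinateMap(insertions)


@dataclass(frozen=True)
class SimulationConfig:
    """Sequencing-design parameters for one simulated sample.

    ``insert_mean``/``insert_sd`` describe the fragment-length distribution in
    reference coordinates before the 6-bp insertion (a fragment spanning the
    junction on an insertion-bearing allele is 6 bp longer physically).
    ``amplicon_start``/``amplicon_end`` are 1-based positions in the reference
    record; ``None`` means the full record. Inserts are truncated to the
    amplicon, so with short flanks the realized mean sits below the nominal.
    """

    read_length: int = 300
    insert_mean: float = 562.0
    insert_sd: float = 60.0
    depth: int = 2000
    per_base_error: float = 0.0
    chimera_rate: float = 0.0
    seed: int = 0
    amplicon_start: int | None = None
    amplicon_end: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.per_base_error < 0.5):
            raise ConfigError(f"per_base_error must be in [0, 0.5), got {self.per_base_error}")
        if not (0 <= self.chimera_rate < 1):
            raise ConfigError(f"chimera_rate must be in [0, 1), got {self.chimera_rate}")
        if self.read_length < 1 or self.depth < 0:
            raise ConfigError("read_length must be >= 1 and depth >= 0")

    @property
    def quality_score(self) -> int:
        """Constant Phred quality consistent with the error model (capped at 40)."""
        if self.per_base_error <= 0:
            return 40
        return max(2, min(40, round(-10 * math.log10(self.per_base_error))))


@dataclass(frozen=True)
class PairTruth:
    pair_id: str
    source: str           # "allele_a" | "allele_b"
    ref_start: int        # 1-based reference record position
    insert_length: int    # physical fragment length on the source allele
    chimeric: bool


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated sample: diplotype plus per-pair sources."""

    sample_id: str
    diplotype: Diplotype
    config: SimulationConfig
    pairs: tuple[PairTruth, ...] = field(default=())


def _amplicon_bounds(reference: Reference, config: SimulationConfig) -> tuple[int, int]:
    a0 = 0 if config.amplicon_start is None else config.amplicon_start - 1
    a1 = len(reference.seq) - 1 if config.amplicon_end is None else config.amplicon_end - 1
    if not (0 <= a0 < a1 < len(reference.seq)):
        raise ConfigError(f"invalid amplicon bounds [{a0 + 1}, {a1 + 1}]")
    if a1 - a0 + 1 < config.read_length:
        raise ConfigError(
            f"amplicon ({a1 - a0 + 1} bp) shorter than read length ({config.read_length} bp)"
        )
    return a0, a1


def simulate_sample(
    diplotype: Diplotype,
    reference: Reference,
    config: SimulationConfig,
    sample_id: str = "sample",
) -> tuple[list[ReadPair], TruthRecord]:
    """Simulate ``config.depth`` read pairs from a diplotype.

    Fragments are drawn as reference-coordinate windows and materialized on
    each haplotype through its coordinate map, so a window spanning the
    c.36_37 junction picks up the 6 inserted bases on insertion-bearing
    alleles. Mate 1 reads the window's 5' end forward; mate 2 reads the 3'
    end reverse-complemented; read-through past a short insert is clipped to
    the insert.
    """
    a0, a1 = _amplicon_bounds(reference, config)
    rng = np.random.default_rng(config.seed)
    q = config.quality_score

    haps = [
        build_allele_sequence(reference, diplotype.allele_a),
        build_allele_sequence(reference, diplotype.allele_b),
    ]

    def fragment(which: int, s_ref: int, e_ref: int) -> str:
        seq, cmap = haps[which]
        return seq[cmap.ref_to_allele(s_ref) : cmap.ref_to_allele(e_ref) + 1]

    def add_errors(seq: str) -> str:
        if config.per_base_error <= 0:
            return seq
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        hits = np.nonzero(rng.random(len(arr)) < config.per_base_error)[0]
        for i in hits:
            choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
            arr[i] = choices[rng.integers(3)]
        return arr.tobytes().decode()

    pairs: list[ReadPair] = []
    truths: list[PairTruth] = []
    amp_len = a1 - a0 + 1
    for i in range(config.depth):
        which = int(rng.integers(2))
        length = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        length = max(1, min(length, amp_len))
        s_ref = a0 + int(rng.integers(0, amp_len - length + 1))
        e_ref = s_ref + length - 1
        chimeric = config.chimera_rate > 0 and rng.random() < config.chimera_rate

        frag1 = fragment(which, s_ref, e_ref)
        frag2 = fragment(1 - which if chimeric else which, s_ref, e_ref)
        mate1 = add_errors(frag1[: config.read_length])
        mate2 = add_errors(revcomp(frag2[-config.read_length :]))

        pid = f"{sample_id}:{i:06d}"
        pairs.append(
            ReadPair(
                pair_id=pid,
                seq1=mate1,
                qual1=quals_to_string([q] * len(mate1)),
                seq2=mate2,
                qual2=quals_to_string([q] * len(mate2)),
            )
        )
        truths.append(
            PairTruth(
                pair_id=pid,
                source="allele_a" if which == 0 else "allele_b",
                ref_start=s_ref + 1,
                insert_length=len(frag1),
                chimeric=chimeric,
            )
        )

    truth = TruthRecord(
        sample_id=sample_id, diplotype=diplotype, config=config, pairs=tuple(truths)
    )
    return pairs, truth


def write_truth_tsv(truths: list[TruthRecord], path) -> None:
    """Cohort-level truth table: one row per sample."""
    with open(path, "w") as fh:
        fh.write("sample_id\ttrue_diplotype\tn_pairs\tseed\n")
        for t in truths:
            fh.write(f"{t.sample_id}\t{t.diplotype}\t{len(t.pairs)}\t{t.config.seed}\n")


#: Per-patient true diplotypes of the 37-patient multiple-heterozygous cohort:
#: 35 carried both variants in cis (*1/*2); one was *3/*6 and one *2/*7.
STUDY_COHORT_DIPLOTYPES: tuple[str, ...] = ("*1/*2",) * 35 + ("*3/*6", "*2/*7")


def simulate_study_cohort(
    reference: Reference,
    catalog,
    depth: int = 2000,
    per_base_error: float = 0.003,
    seed: int = 0,
) -> tuple[dict[str, list[ReadPair]], list[TruthRecord]]:
    """Simulate the study cohort: one read set per patient from their true diplotype.

    Defaults mirror the sequencing design: 300-bp paired ends, 562-bp mean
    insert, 2,000 pairs per sample, 0.3% per-base error. Each sample gets a
    sub-seed derived from ``seed`` so the cohort is reproducible as a whole.
    """
    samples: dict[str, list[ReadPair]] = {}
    truths: list[TruthRecord] = []
    for i, spec in enumerate(STUDY_COHORT_DIPLOTYPES):
        sample_id = f"patient{i + 1:02d}"
        config = SimulationConfig(
            depth=depth, per_base_error=per_base_error, seed=seed * 1000 + i
        )
        pairs, truth = simulate_sample(
            catalog.diplotype(spec), reference, config, sample_id=sample_id
        )
        samples[sample_id] = pairs
        truths.append(truth)
    return samples, truths
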