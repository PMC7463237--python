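"""Read-pair alignment to the cDNA reference and per-site allele observation.

A generic gapped aligner can shift a 6-bp insertion near c.36_37 into several
equivalent placements, which would make insertion calls fragile. Instead each
mate is aligned glocally (read fully consumed, reference local) against BOTH
candidate templates — the plain reference and the reference with GGAGTC
inserted between CDS 36 and 37 — and the candidate with the higher summed
pair score wins; ties pick the no-insertion candidate and mark the fragment
ambiguous. The optimal edit path per candidate comes from edlib's glocal
(infix) mode and is scored with affine gap penalties (defaults: match +2,
mismatch −4, gap open −10, gap extend −1 per base). For the substitution-only
error model of amplicon reads the edit-optimal path against an explicit
candidate is also the affine-optimal one, so candidate choice is exact and
deterministic.

Both mate orientations are tried (reverse-complement supported for real
FASTQ); per-site base observations respect a Phred quality floor (default
Q13) below which a site is MISSING, and the insertion is only called from a
mate whose alignment spans the junction with at least two matched bases on
each side — reads merely ending inside the inserted sequence stay MISSING.

``read_sam_observations`` re-derives the same per-site observations from an
external aligner's SAM by a CIGAR walk (6-bp I operations are left-aligned
and matched against GGAGTC with at most one mismatch before being accepted
as the panel insertion).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import edlib
import pysam

from .catalog import Catalog, VariantDef, VariantKind
from .errors import ValidationError
from .fastqio import ReadPair, string_to_quals
from .refseq import Reference
from .simulate import revcomp

NO_INSERTION = "no_insertion"
WITH_INSERTION = "with_insertion"


class ObsCall(str, Enum):
    REF = "REF"
    ALT = "ALT"
    OTHER = "OTHER"
    MISSING = "MISSING"


@dataclass(frozen=True)
class SiteObservation:
    """One panel site's call from one read pair."""

    variant_id: str
    call: ObsCall
    min_base_quality: int = 0


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -10
    gap_extend: int = -1

    def score_ops(self, ops: Sequence[tuple[str, int]]) -> int:
        s = 0
        for op, length in ops:
            if op == "=":
                s += self.match * length
            elif op == "X":
                s += self.mismatch * length
            elif op in ("I", "D"):
                s += self.gap_open + self.gap_extend * length
        return s


@dataclass
class MateAlignment:
    seq: str                       # oriented to the reference strand
    quals: list[int]
    target_start: int              # 0-based start on the candidate template
    ops: list[tuple[str, int]]     # extended-CIGAR runs (=, X, I, D)
    reverse: bool
    edit_distance: int
    score: int = 0


@dataclass
class AlignedFragment:
    pair_id: str
    candidate: str                 # NO_INSERTION | WITH_INSERTION
    mates: list[MateAlignment]
    score: int
    mapped: bool = True
    ambiguous: bool = False


_CIGAR_OPS = {"=", "X", "I", "D"}


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops: list[tuple[str, int]] = []
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + int(ch)
        else:
            if ch not in _CIGAR_OPS:
                raise ValidationError(f"unexpected CIGAR op {ch!r}")
            ops.append((ch, n))
            n = 0
    return ops


@dataclass
class _MateEvidence:
    """Per-mate evidence at panel sites before mate merging."""

    sub_calls: dict[str, tuple[str, int]] = field(default_factory=dict)  # hgvs -> (base, qual)
    ins_call: tuple[ObsCall, int] | None = None                          # (REF|ALT, qual)


class PairAligner:
    """Aligns read pairs and extracts panel-site observations."""

    def __init__(
        self,
        reference: Reference,
        catalog: Catalog,
        scoring: Scoring = Scoring(),
        bq_floor: int = 13,
        max_edit_frac: float = 0.3,
    ):
        reference.validate_panel(catalog)
        self.reference = reference
        self.catalog = catalog
        self.scoring = scoring
        self.bq_floor = bq_floor
        self.max_edit_frac = max_edit_frac

        insertions = [v for v in catalog.panel if v.kind is VariantKind.INSERTION]
        if len(insertions) != 1:
            raise ValidationError("panel must contain exactly one insertion variant")
        self.ins_variant = insertions[0]
        self.ins_seq = self.ins_variant.alt_allele
        #: 0-based record index of the last base before the insertion (CDS 36).
        self.ins_after = reference.cds_index(self.ins_variant.cds_start)

        plain = reference.seq
        self.templates = {
            NO_INSERTION: plain,
            WITH_INSERTION: plain[: self.ins_after + 1]
            + self.ins_seq
            + plain[self.ins_after + 1 :],
        }
        self.substitutions = [
            v for v in catalog.panel if v.kind is VariantKind.SUBSTITUTION
        ]

    # ---- alignment -------------------------------------------------------

    def _site_index(self, cds_position: int, candidate: str) -> int:
        idx = self.reference.cds_index(cds_position)
        if candidate == WITH_INSERTION and idx > self.ins_after:
            idx += len(self.ins_seq)
        return idx

    def _align_oriented(self, seq: str, template: str) -> dict:
        return edlib.align(seq, template, mode="HW", task="path")

    def _align_mate(self, seq: str, quals: list[int], expect_reverse: bool) -> dict[str, MateAlignment]:
        """Best alignment of one mate against each candidate template.

        The expected orientation is tried first; the reverse complement is
        only attempted when the expected fit is poor, and kept if strictly
        better (ties keep the expected orientation).
        """
        out: dict[str, MateAlignment] = {}
        oriented = {False: (seq, quals), True: (revcomp(seq), quals[::-1])}
        for cand, template in self.templates.items():
            s, q = oriented[expect_reverse]
            res = self._align_oriented(s, template)
            best = (res, expect_reverse)
            if res["editDistance"] / max(len(seq), 1) > 0.1:
                s2, _ = oriented[not expect_reverse]
                res2 = self._align_oriented(s2, template)
                if res2["editDistance"] < res["editDistance"]:
                    best = (res2, not expect_reverse)
            res, rev = best
            s, q = oriented[rev]
            ops = _parse_cigar(res["cigar"])
            mate = MateAlignment(
                seq=s,
                quals=q,
                target_start=res["locations"][0][0],
                ops=ops,
                reverse=rev,
                edit_distance=res["editDistance"],
            )
            mate.score = self.scoring.score_ops(ops)
            out[cand] = mate
        return out

    def align_fragment(self, pair: ReadPair) -> AlignedFragment:
        """Align both mates against both candidates and pick the better candidate."""
        m1 = self._align_mate(pair.seq1, string_to_quals(pair.qual1), expect_reverse=False)
        m2 = self._align_mate(pair.seq2, string_to_quals(pair.qual2), expect_reverse=True)
        scores = {c: m1[c].score + m2[c].score for c in self.templates}
        ambiguous = scores[NO_INSERTION] == scores[WITH_INSERTION]
        candidate = (
            NO_INSERTION
            if scores[NO_INSERTION] >= scores[WITH_INSERTION]
            else WITH_INSERTION
        )
        frag = AlignedFragment(
            pair_id=pair.pair_id,
            candidate=candidate,
            mates=[m1[candidate], m2[candidate]],
            score=scores[candidate],
            ambiguous=ambiguous,
        )
        total_len = len(pair.seq1) + len(pair.seq2)
        total_ed = m1[candidate].edit_distance + m2[candidate].edit_distance
        if total_ed > self.max_edit_frac * total_len:
            frag.mapped = False
        return frag

    # ---- observation extraction -----------------------------------------

    def _mate_site_map(self, mate: MateAlignment, template: str) -> dict[int, tuple[str, int, bool]]:
        """target index -> (read base, qual, matches template) for aligned columns."""
        out: dict[int, tuple[str, int, bool]] = {}
        t = mate.target_start
        q = 0
        for op, length in mate.ops:
            if op in ("=", "X"):
                for k in range(length):
                    out[t + k] = (mate.seq[q + k], mate.quals[q + k], op == "=")
                t += length
                q += length
            elif op == "I":
                q += length
            elif op == "D":
                t += length
        return out

    def _mate_evidence(self, mate: MateAlignment, candidate: str) -> _MateEvidence:
        site_map = self._mate_site_map(mate, self.templates[candidate])
        ev = _MateEvidence()
        for v in self.substitutions:
            idx = self._site_index(v.cds_start, candidate)
            if idx in site_map:
                base, qual, _ = site_map[idx]
                ev.sub_calls[v.hgvs_c] = (base, qual)

        # Insertion junction: two matched flanking bases on each side.
        c36 = self.ins_variant.cds_start           # 36
        left = [self._site_index(p, candidate) for p in (c36 - 1, c36)]
        right = [self._site_index(p, candidate) for p in (c36 + 1, c36 + 2)]
        flanks = left + right
        if all(i in site_map and site_map[i][2] for i in flanks):
            quals = [site_map[i][1] for i in flanks]
            if candidate == WITH_INSERTION:
                ins_idx = [self.ins_after + 1 + k for k in range(len(self.ins_seq))]
                covered = [i for i in ins_idx if i in site_map]
                if len(covered) == len(ins_idx):
                    matched = sum(1 for i in ins_idx if site_map[i][2])
                    if matched >= len(ins_idx) - 1:
                        quals += [site_map[i][1] for i in ins_idx]
                        ev.ins_call = (ObsCall.ALT, min(quals))
            else:
                ev.ins_call = (ObsCall.REF, min(quals))
        return ev

    def _combine(self, evidences: list[_MateEvidence]) -> list[SiteObservation]:
        obs: list[SiteObservation] = []
        for v in self.catalog.panel:
            if v.kind is VariantKind.INSERTION:
                calls = [e.ins_call for e in evidences if e.ins_call is not None]
                calls = [c for c in calls if c[1] >= self.bq_floor]
                if not calls:
                    obs.append(SiteObservation(v.hgvs_c, ObsCall.MISSING))
                elif len({c[0] for c in calls}) > 1:
                    obs.append(
                        SiteObservation(v.hgvs_c, ObsCall.OTHER, min(c[1] for c in calls))
                    )
                else:
                    obs.append(
                        SiteObservation(v.hgvs_c, calls[0][0], min(c[1] for c in calls))
                    )
                continue
            seen = [
                e.sub_calls[v.hgvs_c]
                for e in evidences
                if v.hgvs_c in e.sub_calls and e.sub_calls[v.hgvs_c][1] >= self.bq_floor
            ]
            if not seen:
                obs.append(SiteObservation(v.hgvs_c, ObsCall.MISSING))
                continue
            bases = {b for b, _ in seen}
            qual = min(q for _, q in seen)
            if len(bases) > 1:
                obs.append(SiteObservation(v.hgvs_c, ObsCall.OTHER, qual))
                continue
            base = bases.pop()
            if base == v.ref_allele:
                call = ObsCall.REF
            elif base == v.alt_allele:
                call = ObsCall.ALT
            else:
                call = ObsCall.OTHER
            obs.append(SiteObservation(v.hgvs_c, call, qual))
        return obs

    def extract_observations(self, fragment: AlignedFragment) -> list[SiteObservation]:
        """Per-site observations for a mapped fragment (MISSING everywhere if unmapped)."""
        if not fragment.mapped:
            return [SiteObservation(v.hgvs_c, ObsCall.MISSING) for v in self.catalog.panel]
        evidences = [self._mate_evidence(m, fragment.candidate) for m in fragment.mates]
        return self._combine(evidences)

    def observe_pairs(
        self, pairs: Iterable[ReadPair]
    ) -> Iterator[tuple[AlignedFragment, list[SiteObservation]]]:
        for pair in pairs:
            frag = self.align_fragment(pair)
            yield frag, self.extract_observations(frag)


# ---- SAM export / import -------------------------------------------------

_OP_CODE = {"M": 0, "I": 1, "D": 2, "S": 4, "=": 7, "X": 8}


def _candidate_ops_to_reference(
    ops: list[tuple[str, int]], target_start: int, ins_after: int, ins_len: int
) -> tuple[int, list[tuple[str, int]]]:
    """Re-express a with-insertion-candidate alignment in plain-reference coords.

    Aligned columns that land on the inserted bases become I operations
    (leading/trailing runs are soft-clipped instead, as SAM requires an
    anchoring match).
    """
    ins_lo, ins_hi = ins_after + 1, ins_after + ins_len  # candidate indices of inserted bases
    out: list[tuple[str, int]] = []
    t = target_start
    ref_start: int | None = None

    def emit(op: str, n: int) -> None:
        if n <= 0:
            return
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))

    for op, length in ops:
        if op in ("=", "X"):
            pos = t
            remaining = length
            while remaining:
                if pos < ins_lo:
                    n = min(remaining, ins_lo - pos)
                    if ref_start is None:
                        ref_start = pos
                    emit(op, n)
                elif pos <= ins_hi:
                    n = min(remaining, ins_hi - pos + 1)
                    emit("I", n)
                else:
                    n = remaining
                    if ref_start is None:
                        ref_start = pos - ins_len
                    emit(op, n)
                pos += n
                remaining -= n
            t += length
        elif op == "I":
            emit("I", length)
        elif op == "D":
            pos = t
            remaining = length
            while remaining:
                if pos < ins_lo:
                    n = min(remaining, ins_lo - pos)
                    emit("D", n)
                elif pos <= ins_hi:
                    n = min(remaining, ins_hi - pos + 1)  # deleted inserted bases vanish
                else:
                    n = remaining
                    emit("D", n)
                pos += n
                remaining -= n
            t += length
    # SAM cannot start or end with I: soft-clip instead.
    if out and out[0][0] == "I":
        out[0] = ("S", out[0][1])
    if out and out[-1][0] == "I":
        out[-1] = ("S", out[-1][1])
    if ref_start is None:
        ref_start = max(target_start - ins_len, 0)
    return ref_start, out


def write_sam(
    fragments: Iterable[AlignedFragment],
    reference: Reference,
    aligner: PairAligner,
    path: str | Path,
) -> None:
    """Write aligned fragments as SAM against the plain reference.

    With-insertion alignments are converted so the 6 inserted bases appear as
    an I operation between CDS 36 and 37.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": reference.name, "LN": len(reference.seq)}],
        }
    )
    ins_len = len(aligner.ins_seq)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for frag in fragments:
            if not frag.mapped:
                continue
            for i, mate in enumerate(frag.mates):
                if frag.candidate == WITH_INSERTION:
                    ref_start, ops = _candidate_ops_to_reference(
                        mate.ops, mate.target_start, aligner.ins_after, ins_len
                    )
                else:
                    ref_start, ops = mate.target_start, mate.ops
                seg = pysam.AlignedSegment(header)
                seg.query_name = frag.pair_id
                seg.flag = 0x1 | 0x2 | (0x40 if i == 0 else 0x80) | (0x10 if mate.reverse else 0)
                seg.reference_id = 0
                seg.reference_start = ref_start
                seg.mapping_quality = 60
                seg.cigartuples = [(_OP_CODE[op], n) for op, n in ops]
                seg.query_sequence = mate.seq
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in mate.quals)
                )
                out.write(seg)


def _left_align_insertion(ref_seq: str, after_idx: int, ins: str) -> tuple[int, str]:
    """Shift an insertion (placed after ``after_idx``) to its leftmost placement."""
    a, s = after_idx, ins
    while a >= 0 and s[-1] == ref_seq[a]:
        s = s[-1] + s[:-1]
        a -= 1
    return a, s


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b)) + abs(len(a) - len(b))


def read_sam_observations(
    path: str | Path,
    reference: Reference,
    catalog: Catalog,
    bq_floor: int = 13,
) -> dict[str, list[SiteObservation]]:
    """Derive per-pair panel observations from an external SAM alignment.

    Observations come from a CIGAR walk against the plain reference, not from
    any flags or tags, so any aligner's output is acceptable. The panel
    insertion is recognized as an I operation of the catalog length whose
    bases match the inserted sequence with at most one mismatch once
    left-aligned to the c.36_37 anchor.
    """
    aligner = PairAligner(reference, catalog, bq_floor=bq_floor)
    ins_after, ins_seq = aligner.ins_after, aligner.ins_seq
    c36 = aligner.ins_variant.cds_start
    flank_idx = [reference.cds_index(p) for p in (c36 - 1, c36, c36 + 1, c36 + 2)]

    by_pair: dict[str, list[_MateEvidence]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            seq = seg.query_sequence
            quals = list(seg.query_qualities or [0] * len(seq))
            site_map: dict[int, tuple[str, int, bool]] = {}
            ins_found: tuple[int, str, int] | None = None  # (after_idx, seq, min qual)
            rpos = seg.reference_start
            qpos = 0
            for code, length in seg.cigartuples or []:
                if code in (0, 7, 8):  # M, =, X
                    for k in range(length):
                        base = seq[qpos + k]
                        site_map[rpos + k] = (
                            base,
                            quals[qpos + k],
                            base == reference.seq[rpos + k],
                        )
                    rpos += length
                    qpos += length
                elif code == 1:  # I
                    inserted = seq[qpos : qpos + length]
                    a, s = _left_align_insertion(reference.seq, rpos - 1, inserted)
                    if length == len(ins_seq) and a == ins_after and _hamming(s, ins_seq) <= 1:
                        ins_found = (a, s, min(quals[qpos : qpos + length]))
                    qpos += length
                elif code == 2:  # D
                    rpos += length
                elif code == 4:  # S
                    qpos += length
                elif code == 5:  # H
                    pass
                else:
                    raise ValidationError(f"unsupported CIGAR op code {code}")

            ev = _MateEvidence()
            for v in aligner.substitutions:
                idx = reference.cds_index(v.cds_start)
                if idx in site_map:
                    ev.sub_calls[v.hgvs_c] = site_map[idx][:2]
            if all(i in site_map and site_map[i][2] for i in flank_idx):
                fl_quals = [site_map[i][1] for i in flank_idx]
                if ins_found is not None:
                    ev.ins_call = (ObsCall.ALT, min(fl_quals + [ins_found[2]]))
                else:
                    ev.ins_call = (ObsCall.REF, min(fl_quals))
            by_pair.setdefault(seg.query_name, []).append(ev)

    return {pid: aligner._combine(evs) for pid, evs in by_pair.items()}


# ---- observation tables --------------------------------------------------

def observations_to_tsv(
    rows: Iterable[tuple[AlignedFragment, list[SiteObservation]]],
    catalog: Catalog,
    path: str | Path,
) -> None:
    """Per-fragment observation table: pair_id, candidate, one column per site."""
    with open(path, "w") as fh:
        cols = "\t".join(v.hgvs_c for v in catalog.panel)
        fh.write(f"pair_id\tcandidate\t{cols}\n")
        for frag, obs in rows:
            calls = "\t".join(o.call.value for o in obs)
            fh.write(f"{frag.pair_id}\t{frag.candidate}\t{calls}\n")


def observations_from_tsv(
    path: str | Path, catalog: Catalog
) -> dict[str, list[SiteObservation]]:
    out: dict[str, list[SiteObservation]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["pair_id", "candidate"] + [v.hgvs_c for v in catalog.panel]
        if header != expected:
            raise ValidationError(
                f"observation table columns {header} do not match panel {expected}"
            )
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            pid, calls = parts[0], parts[2:]
            out[pid] = [
                SiteObservation(v.hgvs_c, ObsCall(c))
                for v, c in zip(catalog.panel, calls)
            ]
    return out
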