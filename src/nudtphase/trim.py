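"""Sliding-window quality trimming.

Reimplements the classic SLIDINGWINDOW rule the study's preprocessing used:
scanning 5'→3', the read is clipped at the start of the first window of
``window`` bases whose mean Phred quality falls below ``q_threshold``
(defaults 4 and 20). Windows truncated by the read end use the mean of the
remaining bases. Reads shorter than ``min_length`` after clipping are
dropped. Adapter removal is out of scope for primer-defined amplicons; a
pass-through hook (``pre_clip``) exists for real data.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Iterator

from .errors import ValidationError
from .fastqio import ReadPair, string_to_quals


@dataclass(frozen=True)
class TrimPolicy:
    window: int = 4
    q_threshold: float = 20.0
    min_length: int = 36

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValidationError(f"window must be >= 1, got {self.window}")
        if self.q_threshold < 0:
            raise ValidationError(f"q_threshold must be >= 0, got {self.q_threshold}")


def _one_round_cut(quals: list[int], policy: TrimPolicy) -> int:
    """Cut point for one trimming round, or len(quals) if nothing fails.

    The cut starts at the first failing window and then advances past any
    leading bases of that window whose individual quality clears the
    threshold (the failing mean is caused by bases further in, which should
    not cost the good bases in front of them).
    """
    n = len(quals)
    for i in range(n):
        win = quals[i : i + policy.window]
        if sum(win) / len(win) < policy.q_threshold:
            cut = i
            while cut < n and quals[cut] >= policy.q_threshold:
                cut += 1
            return cut
    return n


def sliding_window_trim(
    seq: str, quals: list[int], policy: TrimPolicy
) -> tuple[str, list[int]] | None:
    """Trim one read; returns (seq, quals) or None if dropped.

    Rounds of (first failing window → clip → keep leading above-threshold
    bases of that window) are applied until no window fails, so the result
    is a fixed point: trimming a trimmed read changes nothing. A read whose
    windows all pass is returned unchanged.
    """
    if len(seq) != len(quals):
        raise ValidationError(
            f"sequence length {len(seq)} != quality length {len(quals)}"
        )
    cut = len(seq)
    while True:
        new_cut = _one_round_cut(quals[:cut], policy)
        if new_cut == cut:
            break
        cut = new_cut
    if cut < policy.min_length:
        return None
    return seq[:cut], quals[:cut]


@dataclass
class TrimReport:
    reads_in: int = 0
    reads_out: int = 0
    pairs_in: int = 0
    pairs_out: int = 0
    bases_in: int = 0
    bases_out: int = 0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for k, v in vars(self).items():
                fh.write(f"{k}\t{v}\n")


def trim_pairs(
    pairs: Iterable[ReadPair],
    policy: TrimPolicy = TrimPolicy(),
    report: TrimReport | None = None,
    pre_clip: Callable[[str, list[int]], tuple[str, list[int]]] | None = None,
) -> Iterator[ReadPair]:
    """Trim both mates of each pair; a pair with either mate dropped is dropped.

    A fragment needs both ends to phase across the amplicon, so an orphan
    mate is not propagated.
    """
    from .fastqio import quals_to_string

    for p in pairs:
        if report is not None:
            report.pairs_in += 1
            report.reads_in += 2
            report.bases_in += len(p.seq1) + len(p.seq2)
        mates = []
        ok = True
        for seq, qual in ((p.seq1, p.qual1), (p.seq2, p.qual2)):
            quals = string_to_quals(qual)
            if pre_clip is not None:
                seq, quals = pre_clip(seq, quals)
            trimmed = sliding_window_trim(seq, quals, policy)
            if trimmed is None:
                ok = False
                break
            mates.append(trimmed)
        if not ok:
            continue
        (s1, q1), (s2, q2) = mates
        if report is not None:
            report.pairs_out += 1
            report.reads_out += 2
            report.bases_out += len(s1) + len(s2)
        yield ReadPair(p.pair_id, s1, quals_to_string(q1), s2, quals_to_string(q2))
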