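"""Fragment-based haplotype phasing and star-allele diplotype calling.

Each read pair yields an observation vector over the four panel sites
(REF/ALT/OTHER/MISSING). Because the amplicon's ~562-bp inserts with 300-bp
mates span every panel site in most fragments, complete vectors (no MISSING)
carry the call: their distinct patterns are counted, patterns clearing both
an absolute support floor and a fraction of informative fragments are
"credible", and the top two credible patterns are the sample's haplotypes.
Partial vectors never found a haplotype on their own; one compatible with
exactly one credible pattern reinforces its support. The called haplotypes
are mapped to star alleles by exact variant-set lookup, so novel
combinations surface as ``unknown`` rather than being coerced.

This is deliberately a count-and-threshold method, not a genotype-likelihood
model — with two haplotypes at ~50/50 balance and per-base error well below
the credibility fraction, thresholds separate signal from noise cleanly.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .align import ObsCall, SiteObservation
from .catalog import Catalog, Diplotype, StarAllele
from .errors import AmbiguousCallError, LowDepthError, ValidationError


class Zygosity(str, Enum):
    ABSENT = "absent"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"


@dataclass(frozen=True)
class FragmentVector:
    """One read pair's ordered calls over the panel sites."""

    pair_id: str
    calls: tuple[ObsCall, ...]

    @classmethod
    def from_observations(cls, pair_id: str, obs: Sequence[SiteObservation]) -> "FragmentVector":
        return cls(pair_id, tuple(o.call for o in obs))

    @property
    def is_complete(self) -> bool:
        return ObsCall.MISSING not in self.calls and ObsCall.OTHER not in self.calls

    @property
    def has_other(self) -> bool:
        return ObsCall.OTHER in self.calls

    @property
    def is_informative_partial(self) -> bool:
        return (
            not self.has_other
            and ObsCall.MISSING in self.calls
            and any(c is not ObsCall.MISSING for c in self.calls)
        )


Pattern = tuple[ObsCall, ...]


@dataclass
class PatternCounts:
    """Aggregated fragment patterns for one sample."""

    complete: Counter = field(default_factory=Counter)   # Pattern -> count
    partial: Counter = field(default_factory=Counter)    # Pattern (with MISSING) -> count
    n_other: int = 0
    n_uninformative: int = 0

    @property
    def n_complete(self) -> int:
        return sum(self.complete.values())


def aggregate_vectors(vectors: Iterable[FragmentVector]) -> PatternCounts:
    """Count distinct complete patterns; tally partials and QC classes separately.

    Vectors containing any OTHER call are excluded from haplotype support but
    counted for QC; all-MISSING vectors are uninformative.
    """
    counts = PatternCounts()
    for v in vectors:
        if v.has_other:
            counts.n_other += 1
        elif v.is_complete:
            counts.complete[v.calls] += 1
        elif v.is_informative_partial:
            counts.partial[v.calls] += 1
        else:
            counts.n_uninformative += 1
    return counts


@dataclass
class PhaseCall:
    """The two called haplotypes of a sample with supporting fragment counts."""

    haplotype_a: frozenset          # variant sets
    haplotype_b: frozenset
    star_a: StarAllele
    star_b: StarAllele
    support_a: int
    support_b: int
    noise_fraction: float
    flags: set[str] = field(default_factory=set)

    @property
    def diplotype(self) -> Diplotype:
        return Diplotype.of(self.star_a, self.star_b)


def _pattern_to_variants(pattern: Pattern, catalog: Catalog) -> frozenset:
    return frozenset(
        v for v, call in zip(catalog.panel, pattern) if call is ObsCall.ALT
    )


def _compatible(partial: Pattern, complete: Pattern) -> bool:
    return all(
        p is ObsCall.MISSING or p is c for p, c in zip(partial, complete)
    )


def call_diplotype(
    counts: PatternCounts,
    catalog: Catalog,
    min_support: int = 10,
    min_fraction: float = 0.05,
) -> PhaseCall:
    """Call the sample's two haplotypes from aggregated pattern counts.

    Credibility requires ``count >= min_support`` and
    ``count/informative-complete >= min_fraction``. Two credible patterns →
    heterozygous-style call; one credible pattern with the remaining noise
    below ``min_fraction`` → homozygous call; more than two → the top two by
    support with the ``excess_haplotypes`` flag. Ties beyond rank ordering
    are broken lexicographically on the pattern tuple for reproducibility.

    Raises LowDepthError with zero informative complete fragments and
    AmbiguousCallError when no pattern is credible or a lone credible pattern
    is contradicted by too much residual signal.
    """
    n = counts.n_complete
    if n == 0:
        raise LowDepthError("no informative complete fragments; cannot call diplotype")

    credible = [
        p
        for p, c in counts.complete.items()
        if c >= min_support and c / n >= min_fraction
    ]
    if not credible:
        raise AmbiguousCallError(
            f"no pattern reaches min_support={min_support} and "
            f"min_fraction={min_fraction} among {n} informative fragments"
        )

    # Partials reinforce the unique credible pattern they are compatible with.
    support = {p: counts.complete[p] for p in credible}
    for partial, c in counts.partial.items():
        hits = [p for p in credible if _compatible(partial, p)]
        if len(hits) == 1:
            support[hits[0]] += c

    flags: set[str] = set()
    order = sorted(credible, key=lambda p: (-support[p], tuple(c.value for c in p)))
    if len(order) > 2:
        flags.add("excess_haplotypes")
        order = order[:2]

    if len(order) == 1:
        top = order[0]
        noise = (n - counts.complete[top]) / n
        if noise >= min_fraction:
            raise AmbiguousCallError(
                f"single credible haplotype but noise fraction {noise:.3f} "
                f">= min_fraction {min_fraction}; possible allele dropout"
            )
        incompatible_partials = sum(
            c for p, c in counts.partial.items() if not _compatible(p, top)
        )
        n_partial = sum(counts.partial.values())
        if n_partial and incompatible_partials / max(n_partial, 1) >= min_fraction:
            raise AmbiguousCallError(
                "partial fragments contradict the single credible haplotype"
            )
        order = [top, top]
        support_b = support[top]
    else:
        support_b = support[order[1]]

    pat_a, pat_b = order[0], order[1]
    matched = counts.complete[pat_a] + (
        counts.complete[pat_b] if pat_b != pat_a else 0
    )
    noise_fraction = (n - matched) / n
    hap_a = _pattern_to_variants(pat_a, catalog)
    hap_b = _pattern_to_variants(pat_b, catalog)
    return PhaseCall(
        haplotype_a=hap_a,
        haplotype_b=hap_b,
        star_a=catalog.star_from_variant_set(hap_a),
        star_b=catalog.star_from_variant_set(hap_b),
        support_a=support[pat_a],
        support_b=support_b,
        noise_fraction=noise_fraction,
        flags=flags,
    )


def check_genotype_concordance(
    call: PhaseCall, genotype: Mapping[str, Zygosity], catalog: Catalog
) -> bool:
    """Check the two called haplotypes reproduce an external unphased genotype.

    The genotype maps each panel variant's HGVS string to its zygosity; a
    mismatch sets the ``genotype_mismatch`` flag on the call and returns
    False.
    """
    for v in catalog.panel:
        zyg = genotype.get(v.hgvs_c)
        if zyg is None:
            raise ValidationError(f"genotype missing panel variant {v.hgvs_c}")
        dose = (v in call.haplotype_a) + (v in call.haplotype_b)
        expected = {Zygosity.ABSENT: 0, Zygosity.HETEROZYGOUS: 1, Zygosity.HOMOZYGOUS: 2}[
            Zygosity(zyg)
        ]
        if dose != expected:
            call.flags.add("genotype_mismatch")
            return False
    return True


def phase_sample(
    observations: Mapping[str, Sequence[SiteObservation]],
    catalog: Catalog,
    min_support: int = 10,
    min_fraction: float = 0.05,
) -> PhaseCall:
    """Convenience wrapper: observations per pair → PhaseCall."""
    vectors = [
        FragmentVector.from_observations(pid, obs)
        for pid, obs in observations.items()
    ]
    return call_diplotype(
        aggregate_vectors(vectors), catalog, min_support=min_support, min_fraction=min_fraction
    )
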