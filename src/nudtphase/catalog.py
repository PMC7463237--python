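"""The NUDT15 coding-variant panel and star-allele catalog.

NUDT15 haplotypes are named with star-allele numbers. The panel covered here
holds four coding variants — one 6-bp insertion (c.36_37insGGAGTC) and three
substitutions (c.52G>A, c.101G>C, c.415C>T) — which combine into six named
haplotypes: *1 (reference, no variant), *2 (insertion + c.415C>T in cis), and
the single-variant alleles *3 (c.415C>T), *5 (c.52G>A), *6 (insertion) and
*7 (c.101G>C). *4 is not part of this catalog. Allele definitions and their
functional status are loaded from a versioned TSV data file so the catalog can
be extended without code changes.

Coordinates are 1-based CDS positions (the HGVS "c." convention: the A of the
ATG start codon is position 1).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import HgvsParseError, ValidationError


class VariantKind(str, Enum):
    SUBSTITUTION = "substitution"
    INSERTION = "insertion"


class FunctionalStatus(str, Enum):
    NORMAL = "normal"
    NONFUNCTIONAL = "nonfunctional"
    UNCERTAIN = "uncertain"


class DiplotypeCategory(str, Enum):
    REFERENCE = "reference"
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS_VARIANT = "homozygous_variant"
    COMPOUND_HETEROZYGOUS = "compound_heterozygous"


class MetabolizerClass(str, Enum):
    NORMAL = "normal"
    INTERMEDIATE = "intermediate"
    POTENTIAL_INTERMEDIATE = "potential_intermediate"
    POOR = "poor"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class VariantDef:
    """One panel variant in cDNA (CDS) coordinates.

    A substitution has single-base ``ref_allele``/``alt_allele`` and
    ``cds_start == cds_end``; an insertion has an empty ``ref_allele``, the
    inserted sequence in ``alt_allele``, and ``cds_end == cds_start + 1``
    (the flanking base pair the sequence is inserted between).
    """

    hgvs_c: str
    kind: VariantKind
    cds_start: int
    cds_end: int
    ref_allele: str
    alt_allele: str
    rsid: str = field(default="", compare=False)
    protein_change: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.cds_start < 1:
            raise ValidationError(f"cds_start must be >= 1, got {self.cds_start}")
        if self.kind is VariantKind.SUBSTITUTION:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValidationError(
                    f"{self.hgvs_c}: substitution alleles must be single bases"
                )
            if self.cds_start != self.cds_end:
                raise ValidationError(
                    f"{self.hgvs_c}: substitution requires cds_start == cds_end"
                )
        else:
            if self.ref_allele != "" or not self.alt_allele:
                raise ValidationError(
                    f"{self.hgvs_c}: insertion requires empty ref and non-empty alt"
                )
            if self.cds_end != self.cds_start + 1:
                raise ValidationError(
                    f"{self.hgvs_c}: insertion anchors must be adjacent "
                    f"({self.cds_start}_{self.cds_end})"
                )

    def format(self) -> str:
        """Canonical HGVS cDNA string for this variant."""
        if self.kind is VariantKind.SUBSTITUTION:
            return f"c.{self.cds_start}{self.ref_allele}>{self.alt_allele}"
        return f"c.{self.cds_start}_{self.cds_end}ins{self.alt_allele}"


_SUB_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_INS_RE = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")


def parse_hgvs_c(text: str) -> VariantDef:
    """Parse a cDNA HGVS string ("c.415C>T", "c.36_37insGGAGTC") into a VariantDef.

    Only the two shapes the panel needs are accepted: single-base
    substitutions and insertions between adjacent positions. The result
    round-trips: ``parse_hgvs_c(v.format()) == v``.
    """
    text = text.strip()
    m = _SUB_RE.match(text)
    if m:
        pos = int(m.group(1))
        return VariantDef(
            hgvs_c=text,
            kind=VariantKind.SUBSTITUTION,
            cds_start=pos,
            cds_end=pos,
            ref_allele=m.group(2),
            alt_allele=m.group(3),
        )
    m = _INS_RE.match(text)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        if end != start + 1:
            raise ValidationError(
                f"insertion anchors must be adjacent: got {start}_{end} in {text!r}"
            )
        return VariantDef(
            hgvs_c=text,
            kind=VariantKind.INSERTION,
            cds_start=start,
            cds_end=end,
            ref_allele="",
            alt_allele=m.group(3),
        )
    # Name the first token that breaks the expected grammar.
    if not text.startswith("c."):
        raise HgvsParseError(f"expected 'c.' prefix in {text!r}")
    raise HgvsParseError(f"unparseable variant description {text[2:]!r} in {text!r}")


def codon_index(cds_position: int) -> int:
    """Codon (amino-acid) number for a 1-based CDS position.

    CDS positions 1-3 fall in codon 1, 4-6 in codon 2, ...; c.415 is in
    codon 139 (the Arg139Cys substitution site).
    """
    if cds_position < 1:
        raise ValidationError(f"CDS position must be >= 1, got {cds_position}")
    return (cds_position - 1) // 3 + 1


@dataclass(frozen=True)
class StarAllele:
    """A named haplotype: a set of panel variants plus a functional status.

    The sentinel ``unknown`` allele (``is_unknown``) carries an observed
    variant set that matches no catalog entry; it has no functional status.
    """

    name: str
    variants: frozenset[VariantDef]
    functional_status: FunctionalStatus | None

    @property
    def is_unknown(self) -> bool:
        return self.name == "unknown"

    def __str__(self) -> str:
        if self.is_unknown:
            inner = "+".join(sorted(v.hgvs_c for v in self.variants)) or "none"
            return f"unknown[{inner}]"
        return self.name


def unknown_allele(variants: Iterable[VariantDef]) -> StarAllele:
    """The sentinel returned for a variant set matching no catalog haplotype."""
    return StarAllele("unknown", frozenset(variants), None)


@dataclass(frozen=True)
class Diplotype:
    """An unordered pair of star alleles."""

    allele_a: StarAllele
    allele_b: StarAllele

    @classmethod
    def of(cls, a: StarAllele, b: StarAllele) -> "Diplotype":
        # Canonical order so *1/*2 and *2/*1 compare equal.
        a, b = sorted((a, b), key=lambda s: (s.name, sorted(v.hgvs_c for v in s.variants)))
        return cls(a, b)

    @property
    def alleles(self) -> tuple[StarAllele, StarAllele]:
        return (self.allele_a, self.allele_b)

    @property
    def category(self) -> DiplotypeCategory:
        a, b = self.allele_a, self.allele_b
        a_ref = not a.variants and not a.is_unknown
        b_ref = not b.variants and not b.is_unknown
        if a_ref and b_ref:
            return DiplotypeCategory.REFERENCE
        if a_ref or b_ref:
            return DiplotypeCategory.HETEROZYGOUS
        if a == b:
            return DiplotypeCategory.HOMOZYGOUS_VARIANT
        return DiplotypeCategory.COMPOUND_HETEROZYGOUS

    def __str__(self) -> str:
        return f"{self.allele_a}/{self.allele_b}"


class Catalog:
    """Loaded star-allele catalog with exact-set haplotype lookup."""

    def __init__(self, alleles: Mapping[str, StarAllele]):
        self.alleles: dict[str, StarAllele] = dict(alleles)
        self._by_set: dict[frozenset[VariantDef], StarAllele] = {}
        for allele in self.alleles.values():
            if allele.variants in self._by_set:
                raise ValidationError(
                    f"duplicate variant set for {allele.name} and "
                    f"{self._by_set[allele.variants].name}"
                )
            self._by_set[allele.variants] = allele
        panel = {v for a in self.alleles.values() for v in a.variants}
        #: Panel variants in genomic (CDS) order; this order defines the
        #: observation-vector layout used by align and phase.
        self.panel: tuple[VariantDef, ...] = tuple(
            sorted(panel, key=lambda v: (v.cds_start, v.hgvs_c))
        )
        self._variant_by_hgvs = {v.hgvs_c: v for v in self.panel}

    def __getitem__(self, name: str) -> StarAllele:
        return self.alleles[name]

    def variant(self, hgvs_c: str) -> VariantDef:
        return self._variant_by_hgvs[hgvs_c]

    def star_from_variant_set(self, variants: Iterable[VariantDef]) -> StarAllele:
        """Exact-set lookup; unmatched sets return the ``unknown`` sentinel.

        The sentinel echoes the observed set so novel haplotypes survive
        downstream reporting instead of being coerced to a catalog allele.
        """
        key = frozenset(variants)
        return self._by_set.get(key, unknown_allele(key))

    def diplotype(self, spec: str) -> Diplotype:
        """Parse a "*1/*2"-style diplotype string against this catalog."""
        try:
            a, b = spec.split("/")
        except ValueError:
            raise ValidationError(f"diplotype must be 'X/Y', got {spec!r}") from None
        try:
            return Diplotype.of(self[a.strip()], self[b.strip()])
        except KeyError as exc:
            raise ValidationError(f"unknown star allele {exc.args[0]!r} in {spec!r}") from None


def classify_metabolizer(diplotype: Diplotype) -> MetabolizerClass:
    """CPIC-style metabolizer phenotype from allele functional status.

    Two nonfunctional alleles → poor; uncertain + nonfunctional → potential
    intermediate; one nonfunctional with a normal allele → intermediate;
    two normal alleles → normal. Any unknown allele, and combinations the
    guideline language does not cover (e.g. normal + uncertain), are
    indeterminate.
    """
    statuses = sorted(
        (a.functional_status for a in diplotype.alleles),
        key=lambda s: "" if s is None else s.value,
    )
    if None in statuses:
        return MetabolizerClass.INDETERMINATE
    s = frozenset([statuses[0], statuses[1]])
    counts = {st: sum(1 for x in statuses if x is st) for st in set(statuses)}
    if counts.get(FunctionalStatus.NONFUNCTIONAL, 0) == 2:
        return MetabolizerClass.POOR
    if s == frozenset([FunctionalStatus.UNCERTAIN, FunctionalStatus.NONFUNCTIONAL]):
        return MetabolizerClass.POTENTIAL_INTERMEDIATE
    if s == frozenset([FunctionalStatus.NORMAL, FunctionalStatus.NONFUNCTIONAL]):
        return MetabolizerClass.INTERMEDIATE
    if counts.get(FunctionalStatus.NORMAL, 0) == 2:
        return MetabolizerClass.NORMAL
    return MetabolizerClass.INDETERMINATE


def load_catalog(
    alleles_path: str | Path | None = None,
    variants_path: str | Path | None = None,
) -> Catalog:
    """Load the star-allele catalog from TSV data files.

    Schema: ``star_alleles.tsv`` has columns ``allele`` (name),
    ``variants`` (comma-joined HGVS cDNA strings, "-" for none) and
    ``functional_status``; ``variants.tsv`` has ``hgvs_c``, ``rsid`` and
    optional ``protein_change`` used to annotate the parsed variants.
    Defaults to the packaged NUDT15 catalog.
    """
    data = resources.files("nudtphase.data")
    if alleles_path is None:
        alleles_path = Path(str(data / "star_alleles.tsv"))
    if variants_path is None:
        variants_path = Path(str(data / "variants.tsv"))

    vtab = pd.read_csv(variants_path, sep="\t", dtype=str).fillna("")
    annot: dict[str, VariantDef] = {}
    for row in vtab.itertuples(index=False):
        v = parse_hgvs_c(row.hgvs_c)
        annot[v.hgvs_c] = replace(
            v, rsid=row.rsid, protein_change=getattr(row, "protein_change", "") or None
        )

    atab = pd.read_csv(alleles_path, sep="\t", dtype=str).fillna("")
    alleles: dict[str, StarAllele] = {}
    for row in atab.itertuples(index=False):
        if row.variants.strip() in ("-", ""):
            vset: frozenset[VariantDef] = frozenset()
        else:
            parsed = [parse_hgvs_c(t) for t in row.variants.split(",")]
            vset = frozenset(annot.get(v.hgvs_c, v) for v in parsed)
        alleles[row.allele] = StarAllele(
            row.allele, vset, FunctionalStatus(row.functional_status)
        )
    return Catalog(alleles)
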