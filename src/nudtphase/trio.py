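"""Mendelian trio phase inference from unphased genotypes.

A genotype with several heterozygous variants is consistent with multiple
diplotypes (every 2-coloring of the het variants over the two haplotypes).
Parental genotypes prune that set: a child diplotype survives only if one of
its haplotypes can be transmitted by the mother and the other by the father.
This reproduces the pedigree deductions used to corroborate sequencing-based
calls — e.g. a double-het child of a *1/*6 mother and *1/*3 father can only
be *3/*6, and a triple-het child of a *2/*2 father must have received *2
from him, forcing c.101G>C onto the maternal haplotype (*2/*7, with the
triple-het mother then inferable as *2/*7 herself).

De novo variation is not modelled: an empty intersection is reported as a
Mendelian inconsistency (sample swap, de novo variant or genotyping error),
never repaired.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

from .catalog import Catalog, Diplotype, VariantDef
from .errors import ValidationError
from .phase import Zygosity

Haplotype = frozenset  # frozenset[VariantDef]


@dataclass(frozen=True)
class UnphasedGenotype:
    """Per-variant zygosity over the whole panel."""

    zygosity: Mapping[str, Zygosity]  # hgvs_c -> zygosity

    @classmethod
    def from_variants(
        cls,
        catalog: Catalog,
        heterozygous: tuple[str, ...] = (),
        homozygous: tuple[str, ...] = (),
    ) -> "UnphasedGenotype":
        zyg = {v.hgvs_c: Zygosity.ABSENT for v in catalog.panel}
        for h in heterozygous:
            zyg[catalog.variant(h).hgvs_c] = Zygosity.HETEROZYGOUS
        for h in homozygous:
            zyg[catalog.variant(h).hgvs_c] = Zygosity.HOMOZYGOUS
        return cls(zyg)

    def validate(self, catalog: Catalog) -> None:
        missing = [v.hgvs_c for v in catalog.panel if v.hgvs_c not in self.zygosity]
        if missing:
            raise ValidationError(f"genotype missing panel variants: {missing}")


def _haplotype_pairs(
    genotype: UnphasedGenotype, catalog: Catalog
) -> set[frozenset[Haplotype] | tuple[Haplotype, Haplotype]]:
    """All unordered haplotype pairs consistent with the zygosities."""
    genotype.validate(catalog)
    homs = [v for v in catalog.panel if Zygosity(genotype.zygosity[v.hgvs_c]) is Zygosity.HOMOZYGOUS]
    hets = [v for v in catalog.panel if Zygosity(genotype.zygosity[v.hgvs_c]) is Zygosity.HETEROZYGOUS]
    pairs: set[tuple[Haplotype, Haplotype]] = set()
    for mask in range(2 ** len(hets)):
        h1 = set(homs)
        h2 = set(homs)
        for bit, v in enumerate(hets):
            (h1 if (mask >> bit) & 1 else h2).add(v)
        key = tuple(
            sorted(
                (frozenset(h1), frozenset(h2)),
                key=lambda h: sorted(v.hgvs_c for v in h),
            )
        )
        pairs.add(key)
    return pairs


def enumerate_diplotypes(genotype: UnphasedGenotype, catalog: Catalog) -> set[Diplotype]:
    """All diplotypes consistent with an unphased genotype.

    A genotype with k >= 1 heterozygous variants (and any homozygous ones)
    yields 2**(k-1) unordered diplotypes. Haplotypes outside the catalog map
    to the ``unknown`` sentinel with their variant set retained.
    """
    out = set()
    for h1, h2 in _haplotype_pairs(genotype, catalog):
        out.add(
            Diplotype.of(
                catalog.star_from_variant_set(h1), catalog.star_from_variant_set(h2)
            )
        )
    return out


@dataclass
class TrioResult:
    consistent_child_diplotypes: set[Diplotype]
    mendelian_consistent: bool
    inferred_parent_diplotypes: dict[str, set[Diplotype]] = field(default_factory=dict)

    @property
    def unique(self) -> bool:
        return len(self.consistent_child_diplotypes) == 1


def mendelian_phase(
    child: UnphasedGenotype,
    mother: UnphasedGenotype,
    father: UnphasedGenotype,
    catalog: Catalog,
) -> TrioResult:
    """Intersect the child's candidate diplotypes with parental transmission.

    A child haplotype pair (h_m, h_f) survives when h_m occurs in some
    diplotype consistent with the mother and h_f in one consistent with the
    father. Parent diplotypes compatible with the surviving child calls are
    reported, which pins a parent down when transmission is forced (e.g. a
    homozygous parent).
    """
    child_pairs = _haplotype_pairs(child, catalog)
    mother_pairs = _haplotype_pairs(mother, catalog)
    father_pairs = _haplotype_pairs(father, catalog)
    mother_haps = {h for pair in mother_pairs for h in pair}
    father_haps = {h for pair in father_pairs for h in pair}

    surviving: set[Diplotype] = set()
    mother_compat: set[Diplotype] = set()
    father_compat: set[Diplotype] = set()
    for h1, h2 in child_pairs:
        orientations = [(h1, h2), (h2, h1)]
        ok = False
        for hm, hf in orientations:
            if hm in mother_haps and hf in father_haps:
                ok = True
                for pm in mother_pairs:
                    if hm in pm:
                        mother_compat.add(
                            Diplotype.of(*(catalog.star_from_variant_set(h) for h in pm))
                        )
                for pf in father_pairs:
                    if hf in pf:
                        father_compat.add(
                            Diplotype.of(*(catalog.star_from_variant_set(h) for h in pf))
                        )
        if ok:
            surviving.add(
                Diplotype.of(
                    catalog.star_from_variant_set(h1), catalog.star_from_variant_set(h2)
                )
            )

    if not surviving:
        return TrioResult(set(), mendelian_consistent=False)
    return TrioResult(
        surviving,
        mendelian_consistent=True,
        inferred_parent_diplotypes={"mother": mother_compat, "father": father_compat},
    )


def read_genotype_tsv(path, catalog: Catalog) -> UnphasedGenotype:
    """Two-column TSV (hgvs_c, zygosity) → UnphasedGenotype; panel must be covered."""
    zyg: dict[str, Zygosity] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["hgvs_c", "zygosity"]:
            raise ValidationError(f"expected columns hgvs_c, zygosity in {path}")
        for line in fh:
            name, z = line.rstrip("\n").split("\t")[:2]
            zyg[name] = Zygosity(z)
    g = UnphasedGenotype(zyg)
    g.validate(catalog)
    return g
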