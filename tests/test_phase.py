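import itertools

import pytest

from nudtphase.align import ObsCall
from nudtphase.catalog import Diplotype
from nudtphase.errors import AmbiguousCallError, LowDepthError
from nudtphase.phase import (
    FragmentVector,
    PhaseCall,
    Zygosity,
    aggregate_vectors,
    call_diplotype,
    check_genotype_concordance,
)
from nudtphase.simulate import SimulationConfig, simulate_sample

R, A, O, M = ObsCall.REF, ObsCall.ALT, ObsCall.OTHER, ObsCall.MISSING

# panel order: ins(36_37), 52, 101, 415
PAT_REF = (R, R, R, R)
PAT_STAR2 = (A, R, R, A)
PAT_STAR3 = (R, R, R, A)
PAT_STAR6 = (A, R, R, R)
PAT_STAR7 = (R, R, A, R)


def vectors(*patterns_counts):
    out = []
    i = 0
    for pattern, count in patterns_counts:
        for _ in range(count):
            out.append(FragmentVector(f"p{i}", pattern))
            i += 1
    return out


def simulate_vectors(catalog, reference, aligner, spec, depth=200, error=0.0, seed=1, chimera=0.0):
    d = catalog.diplotype(spec)
    pairs, _ = simulate_sample(
        d, reference,
        SimulationConfig(depth=depth, per_base_error=error, chimera_rate=chimera, seed=seed),
    )
    return [
        FragmentVector.from_observations(p.pair_id, aligner.extract_observations(aligner.align_fragment(p)))
        for p in pairs
    ], d


class TestAggregateVectors:
    def test_empty(self):
        counts = aggregate_vectors([])
        assert counts.n_complete == 0
        assert not counts.complete and not counts.partial

    def test_other_and_partial_segregated(self):
        vs = vectors(((A, R, R, A), 3), ((O, R, R, R), 2), ((M, R, R, A), 4), ((M, M, M, M), 1))
        counts = aggregate_vectors(vs)
        assert counts.complete == {(A, R, R, A): 3}
        assert counts.partial == {(M, R, R, A): 4}
        assert counts.n_other == 2
        assert counts.n_uninformative == 1

    def test_error_free_cis_sample_has_two_patterns(self, catalog, reference, aligner):
        vs, _ = simulate_vectors(catalog, reference, aligner, "*1/*2", depth=100)
        counts = aggregate_vectors(vs)
        assert set(counts.complete) == {PAT_REF, PAT_STAR2}

    def test_error_free_trans_sample_has_two_single_variant_patterns(self, catalog, reference, aligner):
        vs, _ = simulate_vectors(catalog, reference, aligner, "*3/*6", depth=100)
        counts = aggregate_vectors(vs)
        assert set(counts.complete) == {PAT_STAR3, PAT_STAR6}


class TestCallDiplotype:
    def test_cis_call(self, catalog):
        counts = aggregate_vectors(vectors((PAT_REF, 60), (PAT_STAR2, 55)))
        call = call_diplotype(counts, catalog)
        assert {call.star_a.name, call.star_b.name} == {"*1", "*2"}
        assert call.support_a >= call.support_b
        assert call.noise_fraction == 0.0

    def test_trans_call_distinct_from_cis(self, catalog):
        counts = aggregate_vectors(vectors((PAT_STAR3, 60), (PAT_STAR6, 55)))
        call = call_diplotype(counts, catalog)
        assert {call.star_a.name, call.star_b.name} == {"*3", "*6"}

    def test_homozygous_call(self, catalog):
        counts = aggregate_vectors(vectors((PAT_STAR2, 80)))
        call = call_diplotype(counts, catalog)
        assert call.star_a.name == call.star_b.name == "*2"
        assert call.diplotype == catalog.diplotype("*2/*2")

    def test_empty_input_low_depth(self, catalog):
        with pytest.raises(LowDepthError):
            call_diplotype(aggregate_vectors([]), catalog)

    def test_no_credible_pattern_ambiguous(self, catalog):
        # 30 distinct noisy singleton-ish patterns, none reaching support
        vs = vectors(*[(p, 3) for p in itertools.product([R, A], repeat=4)])
        with pytest.raises(AmbiguousCallError):
            call_diplotype(aggregate_vectors(vs), catalog, min_support=10, min_fraction=0.05)

    def test_homozygous_with_excess_noise_ambiguous(self, catalog):
        vs = vectors((PAT_STAR2, 80), (PAT_STAR3, 9))  # 9/89 > 5% but < min_support
        with pytest.raises(AmbiguousCallError):
            call_diplotype(aggregate_vectors(vs), catalog)

    def test_excess_haplotypes_flag_and_top_two(self, catalog):
        vs = vectors((PAT_REF, 100), (PAT_STAR2, 90), (PAT_STAR7, 20))
        call = call_diplotype(aggregate_vectors(vs), catalog)
        assert "excess_haplotypes" in call.flags
        assert {call.star_a.name, call.star_b.name} == {"*1", "*2"}
        assert call.noise_fraction == pytest.approx(20 / 210)

    def test_partials_reinforce_unique_compatible_pattern(self, catalog):
        vs = vectors((PAT_STAR3, 30), (PAT_STAR6, 20), ((M, R, R, A), 15))
        call = call_diplotype(aggregate_vectors(vs), catalog)
        # the partial (missing ins, ALT 415) only matches *3
        assert call.support_a == 45
        assert call.star_a.name == "*3"
        assert call.support_b == 20

    def test_ambiguous_partial_not_assigned(self, catalog):
        vs = vectors((PAT_REF, 30), (PAT_STAR3, 30), ((M, R, R, M), 15))
        call = call_diplotype(aggregate_vectors(vs), catalog)
        # (MISSING, REF, REF, MISSING) fits both haplotypes: no support added
        assert call.support_a == 30 and call.support_b == 30

    def test_novel_haplotype_reported_as_unknown(self, catalog):
        novel = (R, A, A, R)  # 52 and 101 in cis: not a catalog allele
        counts = aggregate_vectors(vectors((PAT_REF, 50), (novel, 40)))
        call = call_diplotype(counts, catalog)
        assert call.star_b.is_unknown
        assert {v.hgvs_c for v in call.star_b.variants} == {"c.52G>A", "c.101G>C"}


class TestEndToEndRecovery:
    def test_exhaustive_diplotype_sweep_error_free(self, catalog, reference, aligner):
        """All 21 unordered catalog diplotypes recovered exactly at zero error."""
        names = sorted(catalog.alleles)
        for a, b in itertools.combinations_with_replacement(names, 2):
            spec = f"{a}/{b}"
            vs, truth = simulate_vectors(catalog, reference, aligner, spec, depth=60, seed=13)
            call = call_diplotype(aggregate_vectors(vs), catalog)
            assert call.diplotype == truth, spec
            assert call.noise_fraction == 0.0, spec

    def test_recovery_with_sequencing_error(self, catalog, reference, aligner):
        vs, truth = simulate_vectors(
            catalog, reference, aligner, "*2/*7", depth=300, error=0.003, seed=21
        )
        call = call_diplotype(aggregate_vectors(vs), catalog)
        assert call.diplotype == truth

    def test_recovery_monotone_in_chimera_rate(self, catalog, reference, aligner):
        """Template switching erodes phasing accuracy monotonically."""
        rates = [0.0, 0.45, 0.9]
        recovery = []
        for rate in rates:
            ok = 0
            seeds = range(40, 46)
            for seed in seeds:
                vs, truth = simulate_vectors(
                    catalog, reference, aligner, "*3/*6",
                    depth=150, error=0.0, seed=seed, chimera=rate,
                )
                try:
                    call = call_diplotype(aggregate_vectors(vs), catalog)
                    ok += call.diplotype == truth
                except (LowDepthError, AmbiguousCallError):
                    pass
            recovery.append(ok / len(seeds))
        assert recovery[0] == 1.0
        assert recovery[0] >= recovery[1] >= recovery[2]


class TestGenotypeConcordance:
    def _call(self, catalog, spec):
        patterns = {
            "*1": PAT_REF, "*2": PAT_STAR2, "*3": PAT_STAR3,
            "*6": PAT_STAR6, "*7": PAT_STAR7,
        }
        a, b = spec.split("/")
        vs = vectors((patterns[a], 60), (patterns[b], 50))
        return call_diplotype(aggregate_vectors(vs), catalog)

    def test_concordant_trans_call(self, catalog):
        call = self._call(catalog, "*3/*6")
        genotype = {
            "c.36_37insGGAGTC": Zygosity.HETEROZYGOUS,
            "c.52G>A": Zygosity.ABSENT,
            "c.101G>C": Zygosity.ABSENT,
            "c.415C>T": Zygosity.HETEROZYGOUS,
        }
        assert check_genotype_concordance(call, genotype, catalog)
        assert "genotype_mismatch" not in call.flags

    def test_mismatch_flagged(self, catalog):
        call = self._call(catalog, "*1/*2")
        genotype = {
            "c.36_37insGGAGTC": Zygosity.HETEROZYGOUS,
            "c.52G>A": Zygosity.ABSENT,
            "c.101G>C": Zygosity.ABSENT,
            "c.415C>T": Zygosity.HOMOZYGOUS,
        }
        assert not check_genotype_concordance(call, genotype, catalog)
        assert "genotype_mismatch" in call.flags

    def test_triple_het_concordance(self, catalog):
        call = self._call(catalog, "*2/*7")
        genotype = {
            "c.36_37insGGAGTC": Zygosity.HETEROZYGOUS,
            "c.52G>A": Zygosity.ABSENT,
            "c.101G>C": Zygosity.HETEROZYGOUS,
            "c.415C>T": Zygosity.HETEROZYGOUS,
        }
        assert check_genotype_concordance(call, genotype, catalog)
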