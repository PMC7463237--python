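import pytest

from nudtphase.align import (
    NO_INSERTION,
    WITH_INSERTION,
    ObsCall,
    PairAligner,
    read_sam_observations,
    write_sam,
)
from nudtphase.fastqio import ReadPair, quals_to_string
from nudtphase.simulate import SimulationConfig, build_allele_sequence, revcomp, simulate_sample

INS = "c.36_37insGGAGTC"
SITES = [INS, "c.52G>A", "c.101G>C", "c.415C>T"]


def make_pair(hap_seq, start, length, read_len=300, qual=30, pid="frag"):
    frag = hap_seq[start : start + length]
    q1 = quals_to_string([qual] * min(read_len, len(frag)))
    q2 = quals_to_string([qual] * min(read_len, len(frag)))
    return ReadPair(pid, frag[:read_len], q1, revcomp(frag[-read_len:]), q2)


def calls(aligner, pair):
    frag = aligner.align_fragment(pair)
    return frag, {o.variant_id: o.call for o in aligner.extract_observations(frag)}


class TestAlignFragment:
    def test_reference_pair_all_ref(self, aligner, reference, catalog):
        hap, _ = build_allele_sequence(reference, catalog["*1"])
        frag, obs = calls(aligner, make_pair(hap, 0, len(hap)))
        assert frag.candidate == NO_INSERTION
        assert frag.mapped
        assert all(obs[s] is ObsCall.REF for s in SITES)

    def test_star6_fragment_over_junction(self, aligner, reference, catalog):
        # covers CDS 30-120 on the insertion-bearing haplotype
        hap, _ = build_allele_sequence(reference, catalog["*6"])
        start = reference.cds_index(30)
        frag, obs = calls(aligner, make_pair(hap, start, 97, read_len=97))
        assert frag.candidate == WITH_INSERTION
        assert obs[INS] is ObsCall.ALT

    def test_star2_long_insert_phases_both_variants(self, aligner, reference, catalog):
        # insert >= 420 anchored at CDS 1: mate 1 spans ins/52/101, mate 2 spans 415
        hap, _ = build_allele_sequence(reference, catalog["*2"])
        frag, obs = calls(aligner, make_pair(hap, reference.cds_offset, 440 + 6))
        assert frag.candidate == WITH_INSERTION
        assert obs[INS] is ObsCall.ALT
        assert obs["c.415C>T"] is ObsCall.ALT
        assert obs["c.52G>A"] is ObsCall.REF

    def test_three_prime_fragment_leaves_upstream_sites_missing(self, aligner, reference):
        start = reference.cds_index(350)
        frag, obs = calls(aligner, make_pair(reference.seq, start, len(reference.seq) - start))
        assert obs[INS] is ObsCall.MISSING
        assert obs["c.52G>A"] is ObsCall.MISSING
        assert obs["c.101G>C"] is ObsCall.MISSING
        assert obs["c.415C>T"] is ObsCall.REF

    def test_third_allele_reported_as_other(self, aligner, reference):
        idx = reference.cds_index(415)
        start = idx - 150
        frag_seq = list(reference.seq[start : start + 250])
        frag_seq[150] = "G"  # neither C (ref) nor T (alt)
        seq = "".join(frag_seq)
        q = quals_to_string([30] * len(seq))
        _, obs = calls(aligner, ReadPair("p", seq, q, revcomp(seq), q))
        assert obs["c.415C>T"] is ObsCall.OTHER

    def test_disagreeing_overlapping_mates_yield_other(self, aligner, reference):
        idx = reference.cds_index(415)
        start = idx - 150
        ref_window = reference.seq[start : start + 250]
        alt_window = ref_window[:150] + "T" + ref_window[151:]
        q = quals_to_string([30] * len(ref_window))
        _, obs = calls(aligner, ReadPair("p", ref_window, q, revcomp(alt_window), q))
        assert obs["c.415C>T"] is ObsCall.OTHER

    def test_low_quality_base_masked_to_missing(self, aligner, reference):
        idx = reference.cds_index(415)
        start = idx - 150
        window = reference.seq[start : start + 250]
        quals = [30] * len(window)
        quals[150] = 5  # below the Q13 floor
        q = quals_to_string(quals)
        _, obs = calls(aligner, ReadPair("p", window, q, revcomp(window), q[::-1]))
        assert obs["c.415C>T"] is ObsCall.MISSING

    def test_read_ending_inside_insertion_does_not_call_it(self, aligner, reference, catalog):
        # fragment stops 3 bases into the inserted hexamer: junction not spanned
        hap, _ = build_allele_sequence(reference, catalog["*6"])
        end = reference.cds_index(36) + 1 + 3
        frag, obs = calls(aligner, make_pair(hap, 0, end))
        assert obs[INS] is ObsCall.MISSING

    def test_garbage_read_unmapped(self, aligner):
        q = quals_to_string([30] * 100)
        junk = "AC" * 50
        frag = aligner.align_fragment(ReadPair("x", junk, q, junk, q))
        assert not frag.mapped

    def test_orientation_recovery(self, aligner, reference):
        # mates swapped in orientation relative to convention still align
        window = reference.seq[100:400]
        q = quals_to_string([30] * 300)
        frag, obs = calls(aligner, ReadPair("p", revcomp(window), q, window, q))
        assert frag.mapped
        assert obs["c.101G>C"] is ObsCall.REF


class TestTwoCandidateInvariant:
    def test_error_free_reads_recover_source_haplotype(self, aligner, reference, catalog):
        """Oracle: string slicing of the built haplotype = extracted observations."""
        for name, allele in catalog.alleles.items():
            hap, _ = build_allele_sequence(reference, allele)
            expected = {
                INS: ObsCall.ALT if any(v.hgvs_c == INS for v in allele.variants) else ObsCall.REF,
            }
            for hgvs in SITES[1:]:
                has = any(v.hgvs_c == hgvs for v in allele.variants)
                expected[hgvs] = ObsCall.ALT if has else ObsCall.REF
            _, obs = calls(aligner, make_pair(hap, 0, len(hap), pid=name))
            assert obs == expected, name

    def test_candidate_coordinate_shift(self, aligner, reference):
        # on the with-insertion template CDS 415 sits 6 bases downstream
        no_ins = aligner._site_index(415, NO_INSERTION)
        with_ins = aligner._site_index(415, WITH_INSERTION)
        assert with_ins - no_ins == 6
        assert with_ins - reference.cds_offset + 1 == 421


class TestSamPath:
    def test_round_trip_matches_internal_observations(self, tmp_path, aligner, reference, catalog):
        pairs, _ = simulate_sample(
            catalog.diplotype("*2/*7"),
            reference,
            SimulationConfig(depth=40, per_base_error=0.003, seed=8),
        )
        frags, internal = [], {}
        for p in pairs:
            f = aligner.align_fragment(p)
            frags.append(f)
            internal[p.pair_id] = tuple(o.call for o in aligner.extract_observations(f))
        sam = tmp_path / "sample.sam"
        write_sam(frags, reference, aligner, sam)
        imported = read_sam_observations(sam, reference, catalog)
        assert set(imported) == set(internal)
        for pid, obs in imported.items():
            assert tuple(o.call for o in obs) == internal[pid]

    def test_handwritten_sam_with_insertion_cigar(self, tmp_path, reference, catalog):
        """A minimal external-style SAM: 6I op between CDS 36/37 is the panel insertion."""
        j = reference.cds_index(36)  # 0-based; insertion after this base
        left = reference.seq[j - 59 : j + 1]
        right = reference.seq[j + 1 : j + 61]
        seq = left + "GGAGTC" + right
        qual = "I" * len(seq)
        pos = j - 59 + 1  # SAM 1-based
        sam = tmp_path / "hand.sam"
        sam.write_text(
            f"@HD\tVN:1.6\tSO:unsorted\n"
            f"@SQ\tSN:{reference.name}\tLN:{len(reference.seq)}\n"
            f"ins_read\t0\t{reference.name}\t{pos}\t60\t60M6I60M\t*\t0\t0\t{seq}\t{qual}\n"
            f"ref_read\t0\t{reference.name}\t{pos}\t60\t120M\t*\t0\t0\t{left + right}\t{'I' * 120}\n"
        )
        obs = read_sam_observations(sam, reference, catalog)
        ins_calls = {pid: o[0].call for pid, o in obs.items()}
        assert obs["ins_read"][0].variant_id == INS
        assert ins_calls == {"ins_read": ObsCall.ALT, "ref_read": ObsCall.REF}
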