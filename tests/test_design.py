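import random

import pytest
from hypothesis import given, strategies as st

from conftest import GENE_3, GENE_5, OVERLAP_3, OVERLAP_5
from soeprimer.design import (DesignConfig, OverlapPrimerParams,
                              PrimerCombination, enumerate_tetrads, k_score,
                              make_end_primers, make_overlap_forward,
                              make_overlap_reverse, overlap_duplex, rank)
from soeprimer.errors import ConfigError, DesignError
from soeprimer.fixtures import FixtureSpec, generate_pair
from soeprimer.seqio import FragmentPair, FragmentRecord, reverse_complement
from soeprimer.thermo import ThermoConditions


class TestPrimerConstruction:
    def test_reference_junction_primers(self, reference_pair):
        assert make_overlap_forward(reference_pair, 11, 15) == OVERLAP_5
        assert make_overlap_reverse(reference_pair, 15, 11) == OVERLAP_3

    def test_reference_end_primers(self, reference_pair):
        g5, g3 = make_end_primers(reference_pair, 30, 21)
        assert g5 == GENE_5
        assert g3 == GENE_3

    def test_boundary_single_base_parts(self, demo_pair):
        J = demo_pair.junction
        assert make_overlap_forward(demo_pair, 1, 1) == demo_pair.chimera[J - 1: J + 1]

    def test_homopolymer_end_primer(self):
        pair = FragmentPair(FragmentRecord("a", "A" * 45), FragmentRecord("b", "C" * 45))
        g5, g3 = make_end_primers(pair, 14, 14)
        assert g5 == "A" * 14
        assert g3 == "G" * 14

    @given(p1=st.integers(1, 40), p2=st.integers(1, 40))
    def test_forward_is_suffix_plus_prefix(self, demo_pair, p1, p2):
        primer = make_overlap_forward(demo_pair, p1, p2)
        assert primer == demo_pair.first.sequence[-p1:] + demo_pair.second.sequence[:p2]

    @given(q1=st.integers(1, 40), q2=st.integers(1, 40))
    def test_reverse_is_revcomp_of_forward(self, demo_pair, q1, q2):
        assert make_overlap_reverse(demo_pair, q1, q2) == reverse_complement(
            make_overlap_forward(demo_pair, q1, q2))

    def test_out_of_range_rejected(self, demo_pair):
        with pytest.raises(DesignError):
            make_overlap_forward(demo_pair, demo_pair.junction + 1, 5)
        with pytest.raises(DesignError):
            make_end_primers(demo_pair, 31, 21)


class TestOverlapDuplex:
    def test_reference_duplex_22nt(self, reference_pair):
        params = OverlapPrimerParams(p1=11, p2=15, q1=15, q2=11, i=3, j=3, k=3, l=3)
        dup = overlap_duplex(reference_pair, params)
        assert dup == "GGCGAGCATAAATGGACGCGGC"
        assert len(dup) == 22

    def test_equal_parts_duplex_is_forward_primer(self, demo_pair):
        params = OverlapPrimerParams(p1=10, p2=12, q1=10, q2=12, i=0, j=0, k=0, l=0)
        assert overlap_duplex(demo_pair, params) == make_overlap_forward(demo_pair, 10, 12)

    def test_duplex_is_shared_region_of_both_primers(self, demo_pair):
        params = OverlapPrimerParams(p1=9, p2=14, q1=13, q2=10, i=1, j=2, k=1, l=2)
        dup = overlap_duplex(demo_pair, params)
        fwd = make_overlap_forward(demo_pair, params.p1, params.p2)
        rev = make_overlap_reverse(demo_pair, params.q1, params.q2)
        assert dup in fwd
        assert dup in reverse_complement(rev)


class TestKScore:
    def test_perfectly_balanced_tetrad_scores_300(self):
        assert k_score(63, 63, 63, 63, 63, 63) == pytest.approx(300)

    def test_hand_evaluated_example(self):
        # terms: |66-64| + |62-66| + |66-66| + |66-63-3| + |63-63| + |66-63|
        assert k_score(66, 64, 62, 66, 63, 63) == pytest.approx(900)

    @given(st.lists(st.floats(20, 100), min_size=5, max_size=5),
           st.floats(40, 80))
    def test_floor_of_300(self, tms, favorite):
        """Triangle inequality on the last three terms gives K >= 300."""
        assert k_score(*tms, favorite) >= 300 - 1e-6


class TestEnumerate:
    def test_single_point_config(self, demo_pair):
        cfg = DesignConfig(offset_min=0, offset_max=0, end_len_min=14, end_len_max=14)
        combos = enumerate_tetrads(demo_pair, cfg)
        assert len(combos) == 1 == cfg.n_combinations

    @pytest.mark.parametrize("off_max,end_min,end_max", [
        (0, 14, 16), (1, 14, 15), (1, 20, 22),
    ])
    def test_count_law(self, demo_pair, off_max, end_min, end_max):
        cfg = DesignConfig(offset_min=0, offset_max=off_max,
                           end_len_min=end_min, end_len_max=end_max)
        span2 = (off_max + 1) ** 2
        ends = end_max - end_min + 1
        assert len(enumerate_tetrads(demo_pair, cfg)) == span2 ** 2 * ends ** 2

    def test_matches_bruteforce_oracle(self, demo_pair):
        """64-combination config rebuilt and rescored by direct slicing."""
        cfg = DesignConfig(offset_min=0, offset_max=1, end_len_min=14, end_len_max=15)
        cond = ThermoConditions()
        combos = enumerate_tetrads(demo_pair, cfg, cond)
        assert len(combos) == 64

        from soeprimer.thermo import tm_nearest_neighbor
        expected = []
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    for l in range(2):
                        p1, p2 = cfg.fwd_frag1_base + i, cfg.fwd_frag2_base + j
                        q1, q2 = cfg.rev_frag1_base + k, cfg.rev_frag2_base + l
                        J = demo_pair.junction
                        fwd = demo_pair.chimera[J - p1: J + p2]
                        rev = reverse_complement(demo_pair.chimera[J - q1: J + q2])
                        dup = demo_pair.chimera[J - min(p1, q1): J + min(p2, q2)]
                        for n5 in (14, 15):
                            for n3 in (14, 15):
                                g5 = demo_pair.chimera[:n5]
                                g3 = reverse_complement(demo_pair.chimera[-n3:])
                                score = k_score(
                                    tm_nearest_neighbor(g5, cond),
                                    tm_nearest_neighbor(rev, cond),
                                    tm_nearest_neighbor(fwd, cond),
                                    tm_nearest_neighbor(g3, cond),
                                    tm_nearest_neighbor(dup, cond),
                                    cfg.tm_favorite)
                                expected.append(
                                    (score, i + j + k + l, n5, n3, i, j, k, l,
                                     g5, rev, fwd, g3, dup))
        expected.sort()
        got = [(c.k_score, c.params.offset_sum, c.n5, c.n3,
                c.params.i, c.params.j, c.params.k, c.params.l,
                c.gene_5.sequence, c.overlap_3.sequence,
                c.overlap_5.sequence, c.gene_3.sequence, c.overlap_region)
               for c in combos]
        assert got == expected

    def test_reference_tetrad_emitted_at_max_offsets(self, reference_pair):
        cfg = DesignConfig()
        combos = enumerate_tetrads(reference_pair, cfg)
        match = [c for c in combos
                 if c.params == OverlapPrimerParams(11, 15, 15, 11, 3, 3, 3, 3)
                 and c.n5 == 30 and c.n3 == 21]
        assert len(match) == 1
        c = match[0]
        assert (c.gene_5.sequence, c.overlap_3.sequence,
                c.overlap_5.sequence, c.gene_3.sequence) == (
            GENE_5, OVERLAP_3, OVERLAP_5, GENE_3)

    def test_recomputability_and_overhang_law(self, demo_ranked, demo_pair):
        """Sampled tetrads re-derive exactly from (pair, params, n5, n3)."""
        J = demo_pair.junction
        for c in demo_ranked[::4000]:
            p = c.params
            assert c.gene_5.sequence == demo_pair.chimera[:c.n5]
            assert c.gene_3.sequence == reverse_complement(demo_pair.chimera[-c.n3:])
            assert c.overlap_5.sequence == demo_pair.chimera[J - p.p1: J + p.p2]
            assert c.overlap_3.sequence == reverse_complement(
                demo_pair.chimera[J - p.q1: J + p.q2])
            assert c.overlap_region == demo_pair.chimera[
                J - min(p.p1, p.q1): J + min(p.p2, p.q2)]
            # 3' overhangs and duplex length with default base part lengths
            assert p.q1 - p.p1 >= 0 and p.p2 - p.q2 >= 0
            assert len(c.overlap_region) == p.p1 + p.q2
            assert 16 <= len(c.overlap_region) <= 22

    def test_too_short_fragments_rejected(self):
        pair = FragmentPair(FragmentRecord("a", "ACGT" * 12),  # 48 nt
                            FragmentRecord("b", "ACGT" * 12))
        cfg = DesignConfig(end_len_min=49, end_len_max=49)
        with pytest.raises(DesignError, match="fragment 1"):
            enumerate_tetrads(pair, cfg)


class TestRank:
    def _combo(self, k, offsets=(0, 0, 0, 0), n5=14, n3=14):
        from soeprimer.design import PrimerCandidate
        cand = PrimerCandidate("gene_5", "ACGTACGTACGTAC", 14, 50.0, 45.0)
        params = OverlapPrimerParams(8 + offsets[0], 12 + offsets[1],
                                     12 + offsets[2], 8 + offsets[3], *offsets)
        return PrimerCombination(cand, cand, cand, cand, "ACGT" * 5, 60.0,
                                 k, params, n5, n3)

    def test_sorts_by_k(self):
        combos = [self._combo(k) for k in (900, 300, 583)]
        assert [c.k_score for c in rank(combos)] == [300, 583, 900]

    def test_tie_broken_by_offset_sum_then_lengths(self):
        a = self._combo(500, offsets=(2, 1, 1, 1))   # sum 5
        b = self._combo(500, offsets=(1, 1, 0, 0))   # sum 2
        c = self._combo(500, offsets=(1, 1, 0, 0), n5=15)
        assert rank([a, c, b]) == [b, c, a]

    def test_matches_reference_sort(self, demo_ranked):
        sample = list(demo_ranked[::1500])
        rng = random.Random(5)
        shuffled = sample[:]
        rng.shuffle(shuffled)
        assert rank(shuffled) == sorted(sample, key=lambda c: c.sort_key)

    def test_empty_rejected(self):
        with pytest.raises(DesignError):
            rank([])


class TestDesignConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"offset_min": 2, "offset_max": 1},
        {"end_len_min": 20, "end_len_max": 14},
        {"fwd_frag1_base": 0},
        {"fwd_frag1_base": 12},   # reverse junction primer would be 5'-recessed
        {"rev_frag2_base": 12},   # forward junction primer would be 5'-recessed
    ])
    def test_invalid_configs(self, kwargs):
        with pytest.raises(ConfigError):
            DesignConfig(**kwargs)

    def test_params_invariant(self):
        with pytest.raises(ConfigError, match="recessed"):
            OverlapPrimerParams(p1=12, p2=12, q1=11, q2=8, i=0, j=0, k=0, l=0)
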