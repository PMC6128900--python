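import math

import numpy as np
import pytest

from conftest import map_dataset, small_config
from oracles import allpairs_overlap_histogram, allpairs_participating
from pirnakit.align import Alignment, MappedReadSet
from pirnakit.pingpong import (
    OverlapHistogram,
    base_bias_bits,
    overlap_histogram,
    pingpong_matrix,
    bootstrap_pingpong,
    zscore_pvalue,
)
from pirnakit.reads import CollapsedRead
from pirnakit.synthetic import simulate_dataset


def _aln(seq, count, chrom, start, strand):
    return Alignment(CollapsedRead(seq, count), chrom, start, strand, (), 0, 0)


def _pair_set(plus_5p=100, minus_5p=109, c_plus=2, c_minus=3, L=20):
    """One plus read and one minus read with 5' ends at given positions."""
    return MappedReadSet(
        [
            _aln("A" * L, c_plus, "c", plus_5p, "+"),
            _aln("C" * L, c_minus, "c", minus_5p - L + 1, "-"),
        ],
        [],
    )


class TestOverlapHistogram:
    def test_ten_bp_overlap_pair(self):
        hist = overlap_histogram(_pair_set(100, 109, 2, 3))
        assert hist.S[10] == 6.0
        assert all(v == 0 for o, v in hist.S.items() if o != 10)

    def test_coincident_five_prime_ends_are_overlap_one(self):
        hist = overlap_histogram(_pair_set(100, 100))
        assert hist.S[1] == 6.0

    def test_no_opposite_strand_pairs_gives_zero_histogram(self):
        mapped = MappedReadSet([_aln("A" * 20, 5, "c", 0, "+")], [])
        hist = overlap_histogram(mapped)
        assert all(v == 0 for v in hist.S.values())

    def test_matches_allpairs_oracle_on_random_set(self):
        rng = np.random.default_rng(3)
        alns = []
        for i in range(400):
            strand = "+" if rng.random() < 0.5 else "-"
            L = int(rng.integers(20, 31))
            p = int(rng.integers(0, 500))
            seq = "".join(rng.choice(list("ACGT"), size=L))
            alns.append(
                Alignment(
                    CollapsedRead(seq, int(rng.integers(1, 5))),
                    f"chr{rng.integers(1, 3)}",
                    p,
                    strand,
                    (),
                    0,
                    0,
                )
            )
        # deduplicate sequences (counts differ per read, not per alignment)
        seen = {}
        uniq = []
        for a in alns:
            if a.read.sequence not in seen:
                seen[a.read.sequence] = a.read
                uniq.append(a)
        mapped = MappedReadSet(uniq, [])
        hist = overlap_histogram(mapped)
        oracle = allpairs_overlap_histogram(mapped)
        for o in hist.S:
            assert hist.S[o] == pytest.approx(oracle[o])


class TestZScore:
    def test_derived_arithmetic(self):
        S = {o: 1.0 for o in range(1, 10)}
        S.update({o: 3.0 for o in range(11, 21)})
        S[10] = 12.0
        z, p = zscore_pvalue(OverlapHistogram(S))
        bg = [1.0] * 9 + [3.0] * 10
        expected = (12 - np.mean(bg)) / np.std(bg, ddof=1)
        assert z == pytest.approx(expected)
        assert z == pytest.approx(9.70, abs=0.01)
        assert 0 < p < 1e-6

    def test_signal_equal_to_background_mean(self):
        S = {o: 2.0 for o in range(1, 21)}
        S[5] = 1.0
        S[15] = 3.0
        z, p = zscore_pvalue(OverlapHistogram(S))
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_degenerate_background_flagged(self):
        S = {o: 0.0 for o in range(1, 21)}
        z, p = zscore_pvalue(OverlapHistogram(S))
        assert math.isnan(z) and math.isnan(p)


class TestBootstrap:
    def test_full_pairing_saturates_ppr(self):
        stats = bootstrap_pingpong(
            _pair_set(), n_replicates=5, reads_per_replicate=1000, seed=1
        )
        # every drawn read participates -> ppr at the 1e6 ceiling
        assert stats.ppr_mbr == pytest.approx(1e6)

    def test_no_overlaps_gives_zero(self):
        mapped = MappedReadSet(
            [
                _aln("A" * 20, 5, "c", 0, "+"),
                _aln("C" * 20, 5, "c", 300, "-"),
            ],
            [],
        )
        stats = bootstrap_pingpong(
            mapped, n_replicates=5, reads_per_replicate=1000, seed=1
        )
        assert stats.ppr_mbr == 0.0
        assert stats.pps_mbr == 0.0

    def test_mean_pps_matches_exact_multinomial_expectation(self):
        """Replicate-mean S(10) converges to the closed-form expectation."""
        mapped = MappedReadSet(
            [
                _aln("A" * 20, 3, "c", 100, "+"),
                _aln("C" * 20, 2, "c", 90, "-"),   # 5' end 109: pairs with A
                _aln("G" * 20, 1, "c", 190, "-"),  # 5' end 209: pairs with T
                _aln("T" * 20, 4, "c", 200, "+"),
            ],
            [],
        )
        R = 50
        n = 1000
        counts = np.array([3, 2, 1, 4], dtype=float)
        p = counts / counts.sum()
        # S(10) = n1*n2 + n4*n3 with (n1..n4) multinomial(R, p);
        # E[ni*nj] = R(R-1) pi pj for i != j
        exact = R * (R - 1) * (p[0] * p[1] + p[3] * p[2])
        lin = (1e6 / R) ** 2
        stats = bootstrap_pingpong(
            mapped, n_replicates=n, reads_per_replicate=R, seed=9
        )
        se = stats.pps_sd / math.sqrt(n)
        assert abs(stats.pps_mbr - exact * lin) < 3 * se

    def test_seed_reproducibility(self):
        a = bootstrap_pingpong(_pair_set(), 10, 500, seed=4)
        b = bootstrap_pingpong(_pair_set(), 10, 500, seed=4)
        assert (a.pps_mbr, a.ppr_mbr) == (b.pps_mbr, b.ppr_mbr)

    def test_participating_mask_matches_oracle(self):
        ds = simulate_dataset(small_config(seed=21, n_reads=5000))
        mapped = map_dataset(ds)
        from pirnakit.pingpong import _PairIndex

        idx = _PairIndex(mapped)
        mask = idx.participating_reads(idx.read_counts)
        got = {idx.reads[i].sequence for i in np.nonzero(mask)[0]}
        assert got == allpairs_participating(mapped)


class TestMatrix:
    def test_single_heterotypic_pair(self):
        mapped = MappedReadSet(
            [
                _aln("A" * 25, 1, "c", 100, "+"),
                _aln("C" * 29, 1, "c", 109 - 28, "-"),
            ],
            [],
        )
        m = pingpong_matrix(mapped)
        assert m.mode_cell == (25, 29)
        assert m.total_weight == pytest.approx(1.0)

    def test_heterotypic_recovery(self):
        cfg = small_config(
            seed=31,
            pingpong_rate=0.6,
            primary_length_dist={29: 1.0},
            secondary_length_dist={25: 1.0},
        )
        m = pingpong_matrix(map_dataset(simulate_dataset(cfg)))
        assert m.mode_cell == (25, 29)

    def test_homotypic_recovery(self):
        cfg = small_config(
            seed=32,
            pingpong_rate=0.6,
            primary_length_dist={29: 1.0},
            secondary_length_dist={29: 1.0},
        )
        m = pingpong_matrix(map_dataset(simulate_dataset(cfg)))
        assert m.mode_cell == (29, 29)

    def test_empty_input(self):
        m = pingpong_matrix(MappedReadSet([], []))
        assert m.mode_cell is None


class TestBaseBias:
    def test_all_t_at_position_one_is_two_bits(self):
        reads = [CollapsedRead("T" + "ACG" * 5, 2) for _ in range(1)]
        bias = base_bias_bits(reads)
        assert bias.bits_1U == pytest.approx(2.0)

    def test_uniform_position_ten_is_zero_bits(self):
        reads = [
            CollapsedRead("ACGTACGTA" + b + "ACGTACGTAC", 1) for b in "ACGT"
        ]
        bias = base_bias_bits(reads)
        assert bias.bits_10A == pytest.approx(0.0)

    def test_half_t_half_a_gives_half_bit(self):
        reads = [
            CollapsedRead("T" + "ACG" * 5, 1),
            CollapsedRead("A" + "ACG" * 5, 1),
        ]
        bias = base_bias_bits(reads)
        # IC = 2 - 1 = 1 bit; height of T = 0.5 * 1
        assert bias.bits_1U == pytest.approx(0.5)

    def test_count_weighting(self):
        reads = [
            CollapsedRead("T" + "ACG" * 5, 3),
            CollapsedRead("A" + "ACG" * 5, 1),
        ]
        bias = base_bias_bits(reads)
        p = np.array([0.25, 0.75])  # A, T
        ic = 2 + (p * np.log2(p)).sum()
        assert bias.bits_1U == pytest.approx(0.75 * ic)
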