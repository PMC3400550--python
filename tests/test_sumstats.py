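"""Summary statistics against hand enumerations and brute force."""

import math
from itertools import combinations

import numpy as np
import pytest

from paraconv.seq_model import Alignment, AlignmentError
from paraconv.sumstats import (
    classify_cross_locus,
    fst_two_groups,
    fu_li_d,
    pi,
    sliding,
    summary_vector,
    tajimas_d,
    tajimas_d_from_counts,
    watterson,
)
from conftest import random_alignment


def brute_force_pi_total(aln: Alignment) -> float:
    """Per-column fraction of differing valid pairs, summed over columns."""
    total = 0.0
    for c in range(aln.L):
        col = [s[c] for s in aln.seqs]
        pairs = [(a, b) for a, b in combinations(col, 2) if a not in "-N" and b not in "-N"]
        if pairs:
            nv = sum(1 for x in col if x not in "-N")
            if nv >= 2:
                total += sum(a != b for a, b in pairs) / len(pairs)
    return total


class TestPi:
    def test_identical_sequences(self):
        assert pi(Alignment(["a", "b"], ["AAAA", "AAAA"])) == (0.0, 0.0)

    def test_fully_diverged_pair(self):
        assert pi(Alignment(["a", "b"], ["AAAA", "TTTT"])) == (4.0, 1.0)

    def test_toy_four_sample_case(self, toy_alignment):
        pi_total, _ = pi(toy_alignment)
        assert pi_total == pytest.approx(7 / 6)

    def test_single_sequence_rejected(self):
        with pytest.raises(AlignmentError):
            pi(Alignment(["a"], ["ACGT"]))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            aln = random_alignment(rng, n=10, L=50, missing_rate=0.05)
            assert pi(aln)[0] == pytest.approx(brute_force_pi_total(aln), abs=1e-9)

    def test_row_permutation_invariant(self):
        rng = np.random.default_rng(12)
        aln = random_alignment(rng, n=8, L=30)
        perm = rng.permutation(aln.n)
        aln2 = Alignment([aln.names[i] for i in perm], [aln.seqs[i] for i in perm])
        assert pi(aln) == pi(aln2)
        assert tajimas_d(aln) == pytest.approx(tajimas_d(aln2), nan_ok=True)


class TestWatterson:
    def test_no_segregation(self):
        assert watterson(Alignment(["a", "b"], ["AAAA", "AAAA"])) == 0.0

    def test_two_sequences(self):
        # n=2: a_1 = 1, S=3, L=100 -> 0.03
        s1 = "A" * 100
        s2 = "T" * 3 + "A" * 97
        assert watterson(Alignment(["a", "b"], [s1, s2])) == pytest.approx(0.03)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(13)
        aln = random_alignment(rng, n=10, L=50)
        S = sum(
            1
            for c in range(aln.L)
            if len({s[c] for s in aln.seqs} - set("-N")) > 1
        )
        a_n = sum(1 / i for i in range(1, aln.n))
        assert watterson(aln) == pytest.approx(S / (a_n * aln.L))


class TestTajimasD:
    def test_undefined_without_segregation(self):
        assert math.isnan(tajimas_d(Alignment(["a", "b", "c", "d"], ["AAAA"] * 4)))

    def test_hand_worked_example(self, toy_alignment):
        # n=4, S=2, pi_total=7/6 evaluates to ~+0.59
        assert tajimas_d(toy_alignment) == pytest.approx(0.59, abs=0.01)

    def test_sign_from_sfs_shape(self):
        # intermediate-frequency variants push D positive,
        # singletons push it negative (n=8, S=4)
        assert tajimas_d_from_counts(8, 4, 4 * 2 * 4 * 4 / (8 * 7 / 2) / 2) > 0
        pi_singletons = 4 * 1 * 7 / (8 * 7 / 2)
        assert tajimas_d_from_counts(8, 4, pi_singletons) < 0

    def test_near_zero_under_neutral_coalescent(self):
        from paraconv.coalsim import SimParams, simulate
        from paraconv.sumstats import _binary_locus_stats

        rng = np.random.default_rng(14)
        vals = []
        for _ in range(2000):
            rep = simulate(SimParams(n_A=20, n_B=0, L=800, theta=0.01), rng=rng)
            vals.append(_binary_locus_stats(rep.haplotypes_A, 800)[4])
        assert abs(np.nanmean(vals)) < 0.1


class TestFuLiD:
    def test_positive_without_derived_singletons(self):
        # doubleton polymorphism only: eta_e = 0 forces D > 0
        aln = Alignment(
            ["a", "b", "c", "d"], ["AATT", "AATT", "AAAA", "AAAA"]
        )
        assert fu_li_d(aln, "AAAA") > 0

    def test_negative_when_all_derived_singletons(self):
        n, S = 10, 5
        seqs = ["A" * S for _ in range(n)]
        for j in range(S):
            seqs[j] = seqs[j][:j] + "T" + seqs[j][j + 1 :]
        aln = Alignment([f"s{i}" for i in range(n)], seqs)
        assert fu_li_d(aln, "A" * S) < 0

    def test_frozen_hand_value(self):
        # n=4, eta=2, eta_e=1: a_n=11/6, b_n=49/36,
        # c_n=2*(4*a_n-6)/6, v_D and u_D per the 1993 constants
        aln = Alignment(["a", "b", "c", "d"], ["AT", "AA", "TA", "AA"])
        # col1: T singleton (derived); col2: T singleton (derived) -> eta=2, eta_e=2
        a_n = 11 / 6
        b_n = 49 / 36
        c_n = 2 * (4 * a_n - 2 * 3) / (3 * 2)
        v_D = 1 + (a_n**2 / (b_n + a_n**2)) * (c_n - 5 / 3)
        u_D = a_n - 1 - v_D
        eta, eta_e = 2, 2
        expect = (eta - a_n * eta_e) / math.sqrt(u_D * eta + v_D * eta**2)
        assert fu_li_d(aln, "AA") == pytest.approx(expect, abs=1e-9)

    def test_outgroup_missing_sites_excluded(self):
        aln = Alignment(["a", "b", "c"], ["TA", "AA", "AA"])
        # outgroup missing at the only segregating column -> no usable mutation
        assert math.isnan(fu_li_d(aln, "-A"))


class TestFst:
    def test_identical_sequences_everywhere(self):
        aln = Alignment(["a", "b", "c", "d"], ["ACGT"] * 4)
        assert fst_two_groups(aln, ["1", "1", "2", "2"]) == pytest.approx(0.0)

    def test_fixed_difference_no_within_variation(self):
        aln = Alignment(["a", "b", "c", "d"], ["AAAA", "AAAA", "TTTT", "TTTT"])
        assert fst_two_groups(aln, ["1", "1", "2", "2"]) == 1.0

    def test_hand_enumerated_half(self):
        # within pairs: (a,b)=1, (c,d)=1 -> Hw=1
        # between pairs: all four differ at both columns -> Hb=2 -> F_ST=0.5
        aln = Alignment(["a", "b", "c", "d"], ["AA", "AT", "GG", "GC"])
        assert fst_two_groups(aln, ["1", "1", "2", "2"]) == pytest.approx(0.5)

    def test_upper_bound_and_negative_values_possible(self):
        rng = np.random.default_rng(15)
        vals = []
        for _ in range(20):
            aln = random_alignment(rng, n=8, L=40)
            vals.append(fst_two_groups(aln, ["1"] * 4 + ["2"] * 4))
        assert all(v <= 1.0 for v in vals)

    def test_empty_group_rejected(self):
        aln = Alignment(["a", "b"], ["AA", "AT"])
        with pytest.raises(AlignmentError):
            fst_two_groups(aln, ["1", "1"])


class TestCrossLocusClassification:
    def test_identical_polymorphic_loci_share(self):
        aln = Alignment(["a", "b"], ["AT", "TT"])
        res = classify_cross_locus(aln, aln, "AT")
        assert res.n_shared == 1 and res.n_private_A == 0

    def test_fixed_difference(self):
        A = Alignment(["a1", "a2"], ["CC", "CC"])
        B = Alignment(["b1", "b2"], ["TC", "TC"])
        res = classify_cross_locus(A, B, "CC")
        assert res.n_fixed == 1

    def test_five_column_toy_one_of_each(self):
        # col1 shared, col2 private-A, col3 private-B, col4 fixed, col5 nothing
        A = Alignment(["a1", "a2"], ["ACACG", "TGACG"])
        B = Alignment(["b1", "b2"], ["ACTGG", "TCAGG"])
        out = "ACACG"
        res = classify_cross_locus(A, B, out)
        assert (res.n_shared, res.n_private_A, res.n_private_B, res.n_fixed) == (1, 1, 1, 1)
        # spectra bins sum to class counts
        assert sum(res.spectrum_shared.values()) == res.n_shared
        assert sum(res.spectrum_private_A.values()) == res.n_private_A

    def test_classes_partition_columns(self):
        rng = np.random.default_rng(16)
        A = random_alignment(rng, n=6, L=60)
        B = random_alignment(rng, n=5, L=60)
        out = random_alignment(rng, n=1, L=60).seqs[0]
        res = classify_cross_locus(A, B, out)
        # brute force recount
        counts = [0, 0, 0, 0]
        for c in range(60):
            sA = {s[c] for s in A.seqs} - set("-N")
            sB = {s[c] for s in B.seqs} - set("-N")
            if out[c] in "-N" or not sA or not sB:
                continue
            if len(sA) > 1 and len(sB) > 1:
                counts[0] += 1
            elif len(sA) > 1:
                counts[1] += 1
            elif len(sB) > 1:
                counts[2] += 1
            elif sA != sB:
                counts[3] += 1
        assert counts == [res.n_shared, res.n_private_A, res.n_private_B, res.n_fixed]

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            classify_cross_locus(
                Alignment(["a", "x"], ["AT", "AT"]), Alignment(["b", "y"], ["ATT", "ATT"]), "AT"
            )


class TestSliding:
    def test_window_spanning_alignment_equals_global(self):
        rng = np.random.default_rng(17)
        aln = random_alignment(rng, n=6, L=40)
        [(mid, val)] = sliding(aln, tajimas_d, window=40, step=10)
        assert val == pytest.approx(tajimas_d(aln), nan_ok=True)

    def test_window_count(self):
        rng = np.random.default_rng(18)
        aln = random_alignment(rng, n=4, L=100)
        assert len(sliding(aln, tajimas_d, 100, 25)) == 1
        assert len(sliding(aln, tajimas_d, 50, 25)) == 3

    def test_matches_per_window_recomputation(self):
        rng = np.random.default_rng(19)
        aln = random_alignment(rng, n=6, L=60)
        res = sliding(aln, lambda a: pi(a)[0], window=20, step=10)
        for i, (mid, val) in enumerate(res):
            start = 1 + i * 10
            sub = aln.columns(start, start + 19)
            assert val == pytest.approx(pi(sub)[0])

    def test_invalid_window(self):
        aln = Alignment(["a", "b"], ["AAAA", "AATA"])
        with pytest.raises(ValueError):
            sliding(aln, tajimas_d, 0, 1)
        with pytest.raises(ValueError):
            sliding(aln, tajimas_d, 5, 1)


class TestSummaryVector:
    def test_monomorphic_loci_all_zero_counts(self):
        A = Alignment(["a1", "a2"], ["AAAA", "AAAA"])
        B = Alignment(["b1", "b2"], ["AAAA", "AAAA"])
        sv = summary_vector((A, B), outgroup="AAAA")
        assert (sv.n_shared, sv.n_private_A, sv.n_private_B, sv.n_fixed) == (0, 0, 0, 0)
        assert sv.S_A == 0 and sv.pi_A == 0

    def test_symmetric_input_symmetric_fields(self):
        A = Alignment(["a1", "a2"], ["ATAA", "AAAA"])
        B = Alignment(["b1", "b2"], ["ATAA", "AAAA"])
        sv = summary_vector((A, B), outgroup="AAAA")
        assert sv.S_A == sv.S_B and sv.pi_A == sv.pi_B

    def test_matches_independent_per_stat_calls(self):
        rng = np.random.default_rng(20)
        A = random_alignment(rng, n=6, L=50)
        B = random_alignment(rng, n=5, L=50)
        out = random_alignment(rng, n=1, L=50).seqs[0]
        sv = summary_vector((A, B), outgroup=out)
        assert sv.pi_total_A == pytest.approx(pi(A)[0])
        assert sv.theta_W_B == pytest.approx(watterson(B))
        assert sv.D_A == pytest.approx(tajimas_d(A), nan_ok=True)
        cls = classify_cross_locus(A, B, out)
        assert sv.n_shared == cls.n_shared and sv.n_fixed == cls.n_fixed

    def test_binary_path_matches_alignment_path(self):
        # run a replicate through both the fast binary path and the
        # nucleotide-alignment path; statistics must agree
        from paraconv.coalsim import SimParams, simulate

        rep = simulate(SimParams(n_A=6, n_B=5, L=300, theta=0.02, C=1.0,
                                 lambda_tract=100.0, t_dup=1.0, seed=23))
        sv_bin = summary_vector(rep)
        # encode 0 -> A, 1 -> T; pad to full length so coordinates match
        seqs = []
        for row in rep.genotypes:
            s = ["A"] * rep.L
            for j, pos in enumerate(rep.positions):
                s[pos - 1] = "T" if row[j] else "A"
            seqs.append("".join(s))
        A = Alignment([f"a{i}" for i in range(6)], seqs[:6])
        B = Alignment([f"b{i}" for i in range(5)], seqs[6:])
        sv_aln = summary_vector((A, B), outgroup="A" * rep.L)
        assert sv_aln.S_A == sv_bin.S_A and sv_aln.S_B == sv_bin.S_B
        assert sv_aln.pi_total_A == pytest.approx(sv_bin.pi_total_A)
        assert sv_aln.D_B == pytest.approx(sv_bin.D_B, nan_ok=True)
        assert sv_aln.n_shared == sv_bin.n_shared
        assert sv_aln.n_fixed == sv_bin.n_fixed
        assert sv_aln.n_private == sv_bin.n_private
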