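"""AMOVA, pairwise phi_st, and Gst/Nst against independent oracles."""

import numpy as np
import pytest

from popgenflow.differentiation import amova, gst_nst, pairwise_phist
from popgenflow.errors import DataError
from popgenflow.io import call_haplotypes, pairwise_differences

from conftest import make_alignment


def amova_oracle(d2, labels):
    """Naive loop implementation of the one-level variance components."""
    labels = list(labels)
    N = len(labels)
    pops = sorted(set(labels))
    P = len(pops)
    ss_total = sum(d2[i][j] for i in range(N) for j in range(i + 1, N)) / N
    ss_within = 0.0
    for p in pops:
        idx = [i for i, l in enumerate(labels) if l == p]
        ss_within += sum(d2[i][j] for i in idx for j in idx if i < j) / len(idx)
    ss_among = ss_total - ss_within
    s2w = ss_within / (N - P)
    n_c = (N - sum(labels.count(p) ** 2 for p in pops) / N) / (P - 1)
    s2a = (ss_among / (P - 1) - s2w) / n_c
    phi = s2a / (s2a + s2w) if (s2a + s2w) else 0.0
    return s2a, s2w, phi


class TestAmova:
    def test_two_fixed_populations_phi_one(self):
        aln = make_alignment(["AAA", "AAA", "AAT", "AAT"],
                             pops=["P1", "P1", "P2", "P2"])
        res = amova(pairwise_differences(aln), n_perm=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)

    def test_degenerate_all_identical_phi_zero(self):
        aln = make_alignment(["AAA"] * 6, pops=["P1"] * 3 + ["P2"] * 3)
        res = amova(pairwise_differences(aln), n_perm=0)
        assert res.phi_st == 0.0
        assert res.sigma2_among == res.sigma2_within == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n_per = rng.integers(2, 6, size=3)
            labels = np.repeat([f"P{k}" for k in range(3)], n_per)
            seqs = ["".join(rng.choice(list("AG"), 12)) for _ in range(n_per.sum())]
            d = pairwise_differences(make_alignment(seqs, pops=list(labels)))
            res = amova(d, n_perm=0)
            s2a, s2w, phi = amova_oracle(d.d.tolist(), labels)
            assert res.sigma2_among == pytest.approx(s2a, abs=1e-10)
            assert res.sigma2_within == pytest.approx(s2w, abs=1e-10)
            assert res.phi_st == pytest.approx(phi, abs=1e-10)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), 10)) for _ in range(12)]
        res = amova(pairwise_differences(
            make_alignment(seqs, pops=["A"] * 6 + ["B"] * 6)), n_perm=0)
        assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-9)
        assert res.df_among == 1 and res.df_within == 10

    def test_permutation_p_reproducible_and_significant_structure(self):
        aln = make_alignment(["AAAA"] * 5 + ["TTTT"] * 5,
                             pops=["P1"] * 5 + ["P2"] * 5)
        d = pairwise_differences(aln)
        r1 = amova(d, n_perm=199, seed=42)
        r2 = amova(d, n_perm=199, seed=42)
        assert r1.p_value == r2.p_value
        assert r1.p_value < 0.05

    def test_empty_population_error(self):
        with pytest.raises(DataError):
            amova(np.zeros((3, 3)), ["P1", "P1", "P1"])


class TestPairwisePhist:
    def test_two_pop_amova_equals_pairwise_entry(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), 15)) for _ in range(18)]
        pops = [f"P{k}" for k in (1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2, 3, 3, 3, 3, 3, 3)]
        d = pairwise_differences(make_alignment(seqs, pops=pops))
        mat = pairwise_phist(d)
        idx = np.flatnonzero(np.isin(d.populations, ["P1", "P2"]))
        direct = amova(d.d[np.ix_(idx, idx)], d.populations[idx], n_perm=0)
        i, j = mat.codes.index("P1"), mat.codes.index("P2")
        assert mat.values[i, j] == pytest.approx(direct.phi_st)
        assert np.allclose(mat.values, mat.values.T)
        assert not np.diag(mat.values).any()

    def test_identical_distributions_near_zero_fixed_pops_one(self):
        aln = make_alignment(["AAAA", "AATT"] * 4,
                             pops=["P1", "P1", "P1", "P1", "P2", "P2", "P2", "P2"])
        mat = pairwise_phist(pairwise_differences(aln))
        assert abs(mat.values[0, 1]) < 0.35  # no true structure; noisy at n=4
        fixed = make_alignment(["AAAA"] * 3 + ["TTTT"] * 3,
                               pops=["P1"] * 3 + ["P2"] * 3)
        assert pairwise_phist(pairwise_differences(fixed)).values[0, 1] == pytest.approx(1.0)


class TestGstNst:
    def test_equal_distances_make_nst_equal_gst(self):
        aln = make_alignment(["AA", "AT", "TA", "AA", "AT", "TA"],
                             pops=["P1"] * 3 + ["P2"] * 3)
        hap = call_haplotypes(aln)
        dist = np.ones((3, 3)) - np.eye(3)
        res = gst_nst(hap, hap_dist=dist, n_perm=0)
        assert res.Nst == pytest.approx(res.Gst, abs=1e-12)

    def test_fixed_populations_gst_one(self):
        aln = make_alignment(["AA"] * 4 + ["TT"] * 5, pops=["P1"] * 4 + ["P2"] * 5)
        res = gst_nst(call_haplotypes(aln), n_perm=0)
        assert res.hS == 0.0
        assert res.Gst == pytest.approx(1.0)

    def test_permutation_p_reproducible(self):
        aln = make_alignment(["AAG", "ATG", "TAG", "TTG"] * 3,
                             pops=["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4)
        hap = call_haplotypes(aln)
        r1 = gst_nst(hap, n_perm=99, seed=0)
        r2 = gst_nst(hap, n_perm=99, seed=0)
        assert r1.p_nst_gt_gst == r2.p_nst_gt_gst

    def test_asymmetric_distance_rejected(self):
        aln = make_alignment(["AA", "AT"] * 3, pops=["P1", "P1", "P2", "P2", "P3", "P3"])
        hap = call_haplotypes(aln)
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(DataError):
            gst_nst(hap, hap_dist=bad, n_perm=0)

    def test_permutation_p_roughly_uniform_under_equal_distance_null(self):
        # with all inter-haplotype distances equal every permutation gives the
        # same Nst, so p should be 1 (the degenerate uniform case); perturb the
        # distances slightly and check p spreads over (0, 1] across datasets
        rng = np.random.default_rng(9)
        ps = []
        for rep in range(60):
            counts = rng.integers(0, 8, size=(3, 4)) + 1
            import pandas as pd
            from popgenflow.io import HaplotypeTable
            hap = HaplotypeTable([1, 2], ["AA", "AT", "TT"],
                                 pd.DataFrame(counts, index=["H1", "H2", "H3"],
                                              columns=list("WXYZ")),
                                 int(counts.sum()))
            base = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
            res = gst_nst(hap, hap_dist=base, n_perm=49, seed=rep)
            ps.append(res.p_nst_gt_gst)
        ps = np.asarray(ps)
        assert (ps > 0).all() and (ps <= 1).all()
        assert 0.2 < ps.mean() < 0.9
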