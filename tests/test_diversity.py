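import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import msatland as m
from msatland.diversity import rarefied_allelic_richness, unbiased_he

from conftest import matrix_from_indices, two_group_sample


def test_unbiased_he_hand_example():
    """Two individuals, both heterozygous A/B: Ho = 1, He = (4/3)(1-0.5)."""
    gm = matrix_from_indices([[[0, 1]], [[0, 1]]])
    rep = m.summary_stats(gm)
    row = rep.per_locus.iloc[0]
    assert row.H_O == 1.0
    assert row.H_E == pytest.approx(2 / 3, abs=1e-12)


def test_monomorphic_locus_reported_missing_fis():
    gm = matrix_from_indices(np.zeros((6, 1, 2), dtype=int))
    row = m.summary_stats(gm).per_locus.iloc[0]
    assert row.N_A == 1 and row.H_O == 0 and row.H_E == 0
    assert np.isnan(row.F_IS)


@given(st.integers(2, 40), st.integers(2, 6), st.integers(0, 10**6))
@settings(max_examples=30, deadline=None)
def test_unbiased_he_scales_plugin(n, k, seed):
    """Unbiased He equals the plug-in estimate times n/(n-1) (n = copies)."""
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(2 * n, np.ones(k) / k)
    counts = counts[counts > 0]
    p = counts / counts.sum()
    plugin = 1 - np.sum(p**2)
    assert unbiased_he(counts) == pytest.approx(
        2 * n / (2 * n - 1) * plugin, rel=1e-12)


def test_allelic_richness_limits():
    counts = np.array([5, 3, 2])
    n = counts.sum()
    assert rarefied_allelic_richness(counts, n) == pytest.approx(3.0)
    ar = [rarefied_allelic_richness(counts, g) for g in range(2, n + 1)]
    assert np.all(np.diff(ar) >= -1e-12)  # monotone in g
    with pytest.raises(ValueError):
        rarefied_allelic_richness(counts, n + 1)


def test_theta_null_and_maximal():
    gm, labels = two_group_sample(F=0.0, n_per_group=60, seed=4)
    fst = m.pairwise_fst(gm, labels, n_perm=99, seed=0)
    assert abs(fst.theta.iloc[0, 1]) < 0.02
    assert fst.p_values.iloc[0, 1] > 0.05
    # fixed opposite homozygotes at every locus -> theta = 1
    calls = np.zeros((10, 5, 2), dtype=int)
    calls[5:] = 1
    gm2 = matrix_from_indices(calls)
    assert m.wc_theta(gm2, ["A"] * 5 + ["B"] * 5) == pytest.approx(1.0)


def test_theta_recovers_balding_nichols_divergence():
    """Mean Weir-Cockerham theta across replicates at F=0.10 within 0.02."""
    vals = [
        m.wc_theta(*two_group_sample(F=0.10, n_per_group=50, seed=100 + r))
        for r in range(20)
    ]
    assert abs(np.mean(vals) - 0.10) < 0.02


def test_theta_invariances():
    gm, labels = two_group_sample(F=0.1, n_per_group=30, seed=9)
    base = m.wc_theta(gm, labels)
    # allele relabeling: add a constant to all sizes
    gm2 = m.GenotypeMatrix(gm.individual_ids, gm.loci, gm.calls + 10)
    assert m.wc_theta(gm2, labels) == pytest.approx(base)
    # group order
    flipped = ["B" if l == "A" else "A" for l in labels]
    assert m.wc_theta(gm, flipped) == pytest.approx(base)
    # locus order
    perm = np.random.default_rng(0).permutation(gm.n_loci)
    gm3 = m.GenotypeMatrix(gm.individual_ids, [gm.loci[l] for l in perm],
                           gm.calls[:, perm])
    assert m.wc_theta(gm3, labels) == pytest.approx(base)


def test_fis_matches_ho_he_ratio(landscape):
    gm = landscape[0]
    rep = m.summary_stats(gm)
    poly = rep.per_locus[rep.per_locus.H_E > 0]
    expect = 1 - poly.H_O.sum() / poly.H_E.sum()
    assert rep.means.loc["ALL", "F_IS"] == pytest.approx(expect)
    assert -1 <= rep.means.loc["ALL", "F_IS"] <= 1


def test_hwe_exact_conformant_and_all_het():
    # exact p^2 : 2pq : q^2 counts -> high p (most probable configuration)
    calls = np.concatenate([
        np.tile([0, 0], (36, 1)), np.tile([0, 1], (48, 1)),
        np.tile([1, 1], (16, 1))]).reshape(100, 1, 2)
    gm = matrix_from_indices(calls)
    res = m.hwe_test(gm, mc_reps=2000, seed=1)
    assert res.query("locus == 'L01'").p.iloc[0] > 0.5
    # every individual heterozygous, n=20 -> strong rejection
    gm2 = matrix_from_indices(np.tile([0, 1], (20, 1)).reshape(20, 1, 2))
    res2 = m.hwe_test(gm2, mc_reps=2000, seed=2)
    assert res2.query("locus == 'L01'").p.iloc[0] < 0.01
    assert res2.query("locus == 'L01'").p_het_excess.iloc[0] < 0.01


def test_hwe_monomorphic_reports_one():
    gm = matrix_from_indices(np.zeros((30, 1, 2), dtype=int))
    assert m.hwe_test(gm, mc_reps=1000, seed=0).p.iloc[0] == 1.0


def test_hwe_requires_enough_reps(panmictic_small):
    with pytest.raises(ValueError):
        m.hwe_test(panmictic_small, mc_reps=10)


def test_ld_pair_enumeration_and_duplicate(landscape):
    gm = landscape[0]
    res = m.ld_test(gm.subset_individuals(range(40)), mc_reps=50, seed=3)
    assert len(res) == 15 * 14 // 2 == 105
    assert res.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 105)
    # perfectly duplicated locus -> p at the permutation floor
    base = m.generate_panmictic(100, n_loci=2, seed=5)
    calls = base.calls.copy()
    calls[:, 1, :] = calls[:, 0, :]
    dup = m.GenotypeMatrix(base.individual_ids, base.loci, calls)
    res2 = m.ld_test(dup, mc_reps=500, seed=4)
    assert res2.p.iloc[0] == pytest.approx(1 / 501)


def test_ld_null_rate():
    """Independent loci: pre-correction significance near alpha, none after."""
    gm = m.generate_panmictic(120, n_loci=12, seed=21)
    res = m.ld_test(gm, mc_reps=200, seed=6)
    assert (res.p < 0.05).mean() < 0.18
    assert res.significant.sum() == 0
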