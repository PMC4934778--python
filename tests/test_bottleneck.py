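import numpy as np
import pytest

import msatland as m
from msatland.diversity import unbiased_he

from conftest import matrix_from_indices


def ewens_expected_heq_k2(n):
    """Exact E[Heq | k=2] under the infinite-alleles coalescent: allele
    split (j, n-j) has conditional probability proportional to 1/(j(n-j))."""
    j = np.arange(1, n)
    w = 1.0 / (j * (n - j))
    he = np.array([unbiased_he(np.array([jj, n - jj])) for jj in j])
    return float((w * he).sum() / w.sum())


def test_heq_iam_k2_matches_ewens_oracle():
    n = 100
    d = m.simulate_heq(2, n, "IAM", reps=4000, seed=7)
    oracle = ewens_expected_heq_k2(n)
    se = d.heq.std(ddof=1) / np.sqrt(len(d.heq))
    assert abs(d.mean_heq - oracle) < max(4 * se, 0.01)


def test_heq_limiting_and_ordering():
    # k = n: every gene distinct -> unbiased Heq is exactly 1
    dk = m.simulate_heq(12, 12, "IAM", reps=200, seed=10)
    assert dk.mean_heq >= 1 - 1 / 12
    # stepwise homoplasy -> equilibrium Heq(SMM) > Heq(IAM) at equal k
    d_smm = m.simulate_heq(6, 100, "SMM", reps=400, seed=8)
    d_iam = m.simulate_heq(6, 100, "IAM", reps=400, seed=9)
    assert d_smm.mean_heq > d_iam.mean_heq
    assert np.all((d_smm.heq >= 0) & (d_smm.heq <= 1))


def test_heq_validation():
    with pytest.raises(ValueError):
        m.simulate_heq(1, 10, "IAM")
    with pytest.raises(ValueError):
        m.simulate_heq(11, 10, "IAM")
    with pytest.raises(ValueError):
        m.simulate_heq(3, 10, "XXX")


def test_tpm_with_full_smm_proportion_reproduces_smm():
    """With p_smm = 1 every TPM mutation is a single step, so the Heq
    distribution coincides with SMM (same law, independent draws)."""
    a = m.simulate_heq(5, 80, "TPM", reps=600, tpm_p_smm=1.0, seed=5)
    b = m.simulate_heq(5, 80, "SMM", reps=600, seed=6)
    from scipy import stats
    assert stats.ks_2samp(a.heq, b.heq).pvalue > 0.01
    # and multi-step TPM (p_smm = 0, variance 36) is more IAM-like: lower Heq
    c = m.simulate_heq(5, 80, "TPM", reps=400, tpm_p_smm=0.0,
                       tpm_variance=36.0, seed=7)
    assert c.mean_heq < b.mean_heq


def test_sign_test_reports_consistent_counts(landscape):
    st = m.sign_test(landscape[0], "SMM", reps=100, seed=1)
    assert st.n_excess + st.n_deficiency == st.n_loci
    assert 0 < st.p_value <= 1
    assert 0 < st.expected_excess < st.n_loci
    assert st.p_two_tailed >= st.p_value or st.p_two_tailed == 1.0


def test_sign_test_detects_bottleneck_heterozygosity_excess():
    """A 95% collapse inflates He relative to the surviving allele count;
    the IAM sign test should flag excess within a few generations."""
    hits = 0
    for rep in range(6):
        gm = m.forward_bottleneck(
            [(0, 300), (3, 10)], n_loci=15, theta=5.0, model="SMM",
            sample_at=[5], sample_size=50, burn_in=1200, seed=1000 + rep)[-1][1]
        st = m.sign_test(gm, "IAM", reps=150, seed=rep)
        hits += (st.p_value < 0.05) and (st.n_excess > st.expected_excess)
    assert hits >= 4  # power > 0.5


def test_mode_shift_classes():
    gm, _, _ = m.generate_dataset(m.SimConfig(seed=3))
    res = m.mode_shift(gm)
    assert res.classification == "L-shaped"
    assert res.class_counts.sum() > 0
    # all alleles common (> 0.2) -> shifted
    calls = np.concatenate([np.tile([0, 1], (30, 5, 1)).reshape(30, 5, 2)])
    res2 = m.mode_shift(matrix_from_indices(calls))
    assert res2.classification == "shifted"


def test_garza_williamson_hand_values():
    # alleles {100, 108} at a dinucleotide locus: k=2, r=4, M=0.4
    gm = m.GenotypeMatrix(["a", "b"], [m.Locus("A", 2)],
                          np.array([[[100, 108]], [[100, 108]]]))
    gw = m.garza_williamson(gm)
    assert gw.M.iloc[0] == pytest.approx(2 / 5)
    # saturated range: alleles at every step -> M = 1
    calls = np.array([[[100, 102]], [[104, 106]], [[100, 106]]])
    gw2 = m.garza_williamson(m.GenotypeMatrix(["a", "b", "c"],
                                              [m.Locus("A", 2)], calls))
    assert gw2.M.iloc[0] == pytest.approx(1.0)
    # literal range convention (no +1 in the denominator)
    gw3 = m.garza_williamson(gm, plus_one=False)
    assert gw3.M.iloc[0] == pytest.approx(0.5)


def test_garza_williamson_invariants(landscape):
    gm = landscape[0]
    gw = m.garza_williamson(gm)
    assert ((gw.M > 0) & (gw.M <= 1)).all()
    shifted = m.GenotypeMatrix(gm.individual_ids, gm.loci, gm.calls + 20)
    gw2 = m.garza_williamson(shifted)
    assert gw2.M.to_numpy() == pytest.approx(gw.M.to_numpy())


def test_bottleneck_report_bundles_everything():
    gm, _, _ = m.generate_dataset(m.SimConfig(n_individuals=50, seed=5))
    rep = m.bottleneck_report(gm, models=("IAM", "SMM"), reps=80, seed=2)
    s = rep.summary()
    assert set(s.model) == {"IAM", "SMM"}
    assert rep.mode_shift.classification in ("L-shaped", "shifted")
    assert 0 < rep.gw.attrs["mean_M"] <= 1
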