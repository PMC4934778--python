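import numpy as np
import pandas as pd
import pytest

import msatland as m


def lik_table(means, sd_offsets=(-5.0, 0.0, 5.0)):
    rows = [(K, r, mu + off) for K, mu in means.items()
            for r, off in enumerate(sd_offsets)]
    return m.LikelihoodTable(pd.DataFrame(rows, columns=["K", "replicate", "lnP"]))


def test_evanno_linear_sequence_gives_zero():
    lt = lik_table({k: -6000 + 500 * k for k in range(1, 6)})
    dk = m.evanno_delta_k(lt)
    inner = dk.dropna(subset=["delta_K"])
    assert np.allclose(inner.delta_K, 0.0, atol=1e-9)


def test_evanno_elbow_and_shift_invariance():
    means = {2: -5000, 3: -4400, 4: -4000, 5: -3950, 6: -3930}
    dk = m.evanno_delta_k(lik_table(means))
    assert dk.attrs["suggested_K"] == 4
    shifted = lik_table({k: v + 1234.5 for k, v in means.items()})
    dk2 = m.evanno_delta_k(shifted)
    a = dk.dropna(subset=["delta_K"]).delta_K.to_numpy()
    b = dk2.dropna(subset=["delta_K"]).delta_K.to_numpy()
    assert a == pytest.approx(b)


def test_evanno_zero_sd_reported_missing():
    lt = lik_table({2: -100, 3: -90, 4: -85}, sd_offsets=(0.0, 0.0))
    dk = m.evanno_delta_k(lt)
    assert np.isnan(dk.loc[dk.K == 3, "delta_K"]).all()


def test_qmatrix_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        m.QMatrix(["a"], np.array([[0.6, 0.2]]))
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        m.QMatrix(["a"], np.array([[1.4, -0.4]]))


def test_filter_hybrids_planted_rows():
    rng = np.random.default_rng(5)
    n_pure, n_hyb = 40, 10
    q_pure = rng.uniform(0.985, 1.0, n_pure)
    q_hyb = rng.uniform(0.6, 0.9, n_hyb)
    qf = np.concatenate([q_pure, q_hyb])
    q = m.QMatrix([f"i{i}" for i in range(n_pure + n_hyb)],
                  np.column_stack([qf, 1 - qf]))
    res = m.filter_hybrids(q, focal_cluster=0, threshold=0.98)
    assert res.removed_ids == [f"i{i}" for i in range(n_pure, n_pure + n_hyb)]
    assert len(res.kept_ids) == n_pure
    assert res.ci90_q_kept[0] <= res.mean_q_kept <= res.ci90_q_kept[1]
    # all pure -> nobody removed
    q1 = m.QMatrix(["a", "b"], np.array([[1.0, 0.0], [1.0, 0.0]]))
    assert m.filter_hybrids(q1, 0, 0.98).removed_ids == []
    # dog-clustered individual (focal q = 0.003) is removed
    qd = m.QMatrix(["dog"], np.array([[0.003, 0.997]]))
    assert m.filter_hybrids(qd, 0, 0.98).removed_ids == ["dog"]
    with pytest.raises(ValueError):
        m.filter_hybrids(q1, 0, 1.5)


def test_assign_groups_argmax_and_ties():
    q = m.QMatrix(["a", "b"], np.array([[0.1, 0.7, 0.1, 0.1],
                                        [0.25, 0.25, 0.25, 0.25]]))
    with pytest.warns(UserWarning, match="tied"):
        labels, per_group = m.assign_groups(q)
    assert labels == [1, 0]
    assert per_group.loc[1, "mean_q"] == pytest.approx(0.7)


def test_pca_separates_discrete_clusters():
    calls = np.zeros((10, 6, 2), dtype=int)
    calls[5:] = 1
    from conftest import matrix_from_indices
    gm = matrix_from_indices(calls)
    ids, scores, eig = m.pca_genotypes(gm)
    assert np.ptp(np.sign(scores[:5, 0])) == 0
    assert np.ptp(np.sign(scores[5:, 0])) == 0
    assert np.sign(scores[0, 0]) != np.sign(scores[-1, 0])
    assert eig[1] == pytest.approx(0.0, abs=1e-12)


def test_pca_group_separation_on_landscape(landscape):
    gm, q, truth = landscape
    ids, scores, eig = m.pca_genotypes(gm, q=q, min_q=0.7, n_components=3)
    labels = np.array([truth.group_labels[gm.individual_ids.index(i)]
                       for i in ids])
    centroids = np.stack([scores[labels == g].mean(axis=0)
                          for g in np.unique(labels)])
    within = np.mean([scores[labels == g].std(axis=0).mean()
                      for g in np.unique(labels)])
    between = np.linalg.norm(centroids - centroids.mean(0), axis=1).mean()
    assert between > within


def test_pca_order_invariance(landscape):
    gm = landscape[0]
    sub = gm.subset_individuals(range(30))
    _, s1, _ = m.pca_genotypes(sub)
    order = np.random.default_rng(1).permutation(30)
    _, s2, _ = m.pca_genotypes(sub.subset_individuals(order))
    for c in range(3):
        assert abs(abs(np.corrcoef(s1[order, c], s2[:, c])[0, 1]) - 1) < 1e-8


def test_read_structure_native_outputs(tmp_path):
    txt = """STRUCTURE output
4 populations assumed

Inferred ancestry of individuals:
 Label (%Miss) :  Inferred clusters
  1 ind_1  (0)  :  0.981 0.009 0.005 0.005
  2 ind_2  (0)  :  0.010 0.970 0.010 0.010

Estimated Ln Prob of Data = -4123.5
"""
    p = tmp_path / "run_k4.txt"
    p.write_text(txt)
    q = m.read_structure_q(p)
    assert q.individual_ids == ["ind_1", "ind_2"] and q.k == 4
    lt = m.read_structure_likelihoods([p])
    assert lt.table.iloc[0].K == 4
    assert lt.table.iloc[0].lnP == pytest.approx(-4123.5)
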