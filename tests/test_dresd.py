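import numpy as np
import pytest

import msatland as m
from msatland.dresd import UniversalKriging, Variogram, fit_variogram

from conftest import matrix_from_indices


def test_nei_d_self_and_identical_twins():
    calls = np.array([[[101, 101], [140, 142]],
                      [[101, 101], [140, 142]]])
    gm = m.GenotypeMatrix(["a", "b"], [m.Locus("A"), m.Locus("B")], calls)
    D = m.nei_d_matrix(gm)
    assert D[0, 0] == 0.0
    assert D[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_nei_d_two_locus_hand_value():
    """Individual x: AA at locus 1, AB at locus 2; individual y: AB, BB.
    J_x = 1 + 0.5 = 1.5; J_y = 0.5 + 1 = 1.5;
    J_xy = (1)(0.5) + (0.5)(1) = 1.0; D = -ln(1.0 / 1.5)."""
    calls = np.array([[[101, 101], [140, 142]],
                      [[101, 103], [142, 142]]])
    gm = m.GenotypeMatrix(["x", "y"], [m.Locus("A"), m.Locus("B")], calls)
    D = m.nei_d_matrix(gm)
    expect = -np.log(1.0 / np.sqrt(1.5 * 1.5))
    assert D[0, 1] == pytest.approx(expect)


def test_nei_d_no_shared_alleles_capped():
    calls = np.array([[[101, 101]], [[105, 105]]])
    gm = m.GenotypeMatrix(["x", "y"], [m.Locus("A")], calls)
    D = m.nei_d_matrix(gm, cap=7.5)
    assert D[0, 1] == 7.5


def test_nei_d_invariants(landscape):
    gm = landscape[0].subset_individuals(range(40))
    D = m.nei_d_matrix(gm)
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0)
    perm = np.random.default_rng(0).permutation(gm.n_loci)
    gm2 = m.GenotypeMatrix(gm.individual_ids, [gm.loci[l] for l in perm],
                           gm.calls[:, perm], coordinates=gm.coordinates)
    assert np.allclose(m.nei_d_matrix(gm2), D)


def test_ibd_fit_exact_line_and_residual_sum(landscape):
    gm = landscape[0].subset_individuals(range(30))
    pairs = m.build_pairs(gm)
    fit, resid = m.ibd_fit(pairs)
    assert resid.sum() == pytest.approx(0.0, abs=1e-8)
    # exactly linear genetic ~ geographic distance -> all residuals 0
    lin = pairs.copy()
    lin["gen_d"] = 0.01 * lin.geo_km + 0.3
    fit2, resid2 = m.ibd_fit(lin)
    assert fit2.slope == pytest.approx(0.01)
    assert np.allclose(resid2, 0, atol=1e-10)


def test_ibd_slope_null_under_genotype_permutation():
    """Spatially random genotypes: observed slope sits inside the
    permutation envelope of slopes."""
    gm = m.generate_panmictic(60, seed=33)
    D = m.nei_d_matrix(gm)
    pairs = m.build_pairs(gm, D)
    slope_obs, _ = m.ibd_fit(pairs)
    rng = np.random.default_rng(0)
    iu, ju = pairs.i.to_numpy(), pairs.j.to_numpy()
    slopes = []
    for _ in range(99):
        perm = rng.permutation(gm.n)
        p2 = pairs.copy()
        p2["gen_d"] = D[perm[iu], perm[ju]]
        slopes.append(m.ibd_fit(p2)[0].slope)
    lo, hi = np.percentile(slopes, [1, 99])
    assert lo <= slope_obs.slope <= hi


def test_kriging_exact_at_data_points():
    rng = np.random.default_rng(4)
    coords = rng.uniform(0, 100, size=(40, 2))
    values = np.sin(coords[:, 0] / 15) + 0.01 * coords[:, 1]
    vgm = fit_variogram(coords, values, nugget=0.0)
    uk = UniversalKriging(coords, values, vgm)
    pred = uk.predict(coords)
    assert np.max(np.abs(pred - values)) < 1e-6


def test_kriging_rejects_collinear_support():
    coords = np.column_stack([np.arange(10.0), np.arange(10.0)])
    with pytest.raises(ValueError, match="collinear"):
        UniversalKriging(coords, np.ones(10), Variogram("linear", slope=1.0))


def test_proportion_heterozygous_bounds():
    calls = np.array([[[101, 103], [140, 142]],   # fully heterozygous
                      [[101, 101], [140, 140]]])  # fully homozygous
    gm = m.GenotypeMatrix(["a", "b"], [m.Locus("A"), m.Locus("B")], calls)
    pht = m.proportion_heterozygous(gm)
    assert pht[0] == 1.0 and pht[1] == 0.0


def test_dresd_surface_structure_and_metadata(landscape):
    gm = landscape[0]
    surf = m.dresd_surface(gm, n_boot=49, cell_km=8.0, seed=1)
    assert surf.values.shape == surf.p.shape == surf.mask.shape
    ok = ~surf.nodata
    assert np.isnan(surf.values[~ok]).all()
    assert ((surf.p[ok] > 0) & (surf.p[ok] <= 1)).all()
    assert not (surf.mask_low & surf.mask_high).any()
    md = surf.metadata
    assert md["n_pairs_retained"] >= 20
    assert np.isfinite(md["median_residual"])
    # mask true iff p <= alpha (on the side of its deviation)
    both = surf.mask_low | surf.mask_high
    assert np.array_equal(both[ok], (surf.p[ok] <= surf.alpha)
                          & (surf.values[ok] != surf.reference))


def test_dresd_translation_invariance(landscape):
    gm = landscape[0].subset_individuals(range(80))
    s1 = m.dresd_surface(gm, n_boot=29, cell_km=10.0, seed=3)
    shifted = m.GenotypeMatrix(gm.individual_ids, gm.loci, gm.calls,
                               coordinates=gm.coordinates + [1000.0, -500.0])
    s2 = m.dresd_surface(shifted, n_boot=29, cell_km=10.0, seed=3)
    assert np.allclose(np.nan_to_num(s1.values), np.nan_to_num(s2.values),
                       atol=1e-5)
    assert s2.origin[0] == pytest.approx(s1.origin[0] + 1000.0)


def test_dresd_rotation_summary_invariance(landscape):
    gm = landscape[0].subset_individuals(range(80))
    s1 = m.dresd_surface(gm, n_boot=29, cell_km=10.0, seed=3)
    th = np.deg2rad(90.0)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    rot = m.GenotypeMatrix(gm.individual_ids, gm.loci, gm.calls,
                           coordinates=gm.coordinates @ R.T)
    s2 = m.dresd_surface(rot, n_boot=29, cell_km=10.0, seed=3)
    assert s2.metadata["median_residual"] == pytest.approx(
        s1.metadata["median_residual"])
    assert s2.metadata["n_pairs_retained"] == s1.metadata["n_pairs_retained"]


def test_scalar_surface_constant_is_flat():
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 100, size=(30, 2))
    surf = m.scalar_surface(np.full(30, 0.5), coords, n_boot=19, seed=1)
    ok = ~surf.nodata
    assert np.allclose(surf.values[ok], 0.5)
    assert not surf.mask.any()


def test_scalar_surface_logit_island_low_heterozygosity(landscape):
    gm, _, truth = landscape
    pht = m.proportion_heterozygous(gm)
    surf = m.scalar_surface(pht, gm.coordinates, n_boot=99,
                            reference="median", cell_km=8.0,
                            clamp_eps=1 / (2 * gm.n_loci), seed=2)
    ok = ~surf.nodata
    assert np.nanmin(surf.values[ok]) >= 0
    assert np.nanmax(surf.values[ok]) <= 1
    xs, ys = surf.cell_centers()
    gx, _ = np.meshgrid(xs, ys)
    island = (gx < 66) & ok
    mainland = (gx >= 66) & ok
    assert surf.mask_low[island].mean() > surf.mask_low[mainland].mean()


def test_surface_export_round_trip(tmp_path, landscape):
    gm = landscape[0].subset_individuals(range(60))
    surf = m.dresd_surface(gm, n_boot=19, cell_km=12.0, seed=5)
    surf.to_csv(tmp_path / "s.csv")
    surf.to_ascii_grid(tmp_path / "s.asc")
    import pandas as pd
    df = pd.read_csv(tmp_path / "s.csv")
    assert len(df) == surf.nx * surf.ny
    head = (tmp_path / "s.asc").read_text().splitlines()
    assert head[0] == f"ncols {surf.nx}"
    assert len(head) == 6 + surf.ny
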