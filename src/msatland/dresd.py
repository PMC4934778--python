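"""Spatially explicit analysis of isolation-by-distance residuals (DResD)
and kriged scalar surfaces.

DResD ("distribution of residual dissimilarity") asks *where* on a
landscape genetic distance between neighbouring individuals departs from
the global isolation-by-distance (IBD) expectation.  The pipeline:

1. pairwise genetic distance between individuals (Nei's standard D with
   each individual treated as a population of one);
2. ordinary least squares of genetic on geographic distance over all pairs
   (the global IBD null) with residuals attached to each pair;
3. pairs within a neighbour distance band (default 17-33 km) are retained,
   each residual placed at the pair midpoint;
4. universal kriging (first-order spatial trend + fitted variogram) of the
   residuals onto a regular grid;
5. bootstrap of the midpoint-residual set; per-cell significance relative
   to the retained-pair reference (median residual by default): cells
   significantly below are population *core* areas (neighbours more
   similar than IBD predicts), cells above are *transition/contact* zones.

The same kriging-plus-bootstrap engine serves bounded per-individual
scalars (proportion of heterozygous loci, admixture membership
coefficients) through a logit link.

No geostatistics dependency is used: the empirical semivariogram, the WLS
exponential-model fit, and the universal-kriging system are implemented
here with numpy/scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist
from scipy.special import expit, logit

from .genotype_io import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# genetic distance
# ---------------------------------------------------------------------------

def nei_d_matrix(gm: GenotypeMatrix, cap: float = 10.0) -> np.ndarray:
    """Nei's standard genetic distance between individuals.

    Each individual is a population of one, so per-locus allele
    "frequencies" are 0, 0.5 or 1.  With J_x = sum_l sum_a p_xa^2 (and
    J_y, J_xy alike) accumulated over the loci typed in both individuals,
    D = -ln( J_xy / sqrt(J_x J_y) ).  A pair sharing no allele anywhere
    has J_xy = 0 and is reported at the configured ``cap``.
    """
    n, L = gm.n, gm.n_loci
    typed = ~gm.missing_mask()                       # (n, L)
    s2 = np.zeros((n, L))                            # per-ind per-locus sum p^2
    blocks = []
    for l in range(L):
        calls_l = gm.calls[:, l, :]
        alleles = np.unique(calls_l[calls_l != MISSING])
        if alleles.size == 0:
            continue
        freq = (calls_l[:, :, None] == alleles[None, None, :]).sum(axis=1) / 2.0
        freq[~typed[:, l]] = 0.0
        s2[:, l] = (freq**2).sum(axis=1)
        blocks.append(freq)
    F = np.concatenate(blocks, axis=1)
    jxy = F @ F.T
    T = typed.astype(float)
    jx_pair = (s2 * T) @ T.T                         # J_x over shared loci
    jy_pair = jx_pair.T
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = jxy / np.sqrt(jx_pair * jy_pair)
        D = -np.log(ratio)
    D[jxy <= 0] = cap
    np.fill_diagonal(D, 0.0)
    D = np.minimum(D, cap)
    return 0.5 * (D + D.T)


def proportion_heterozygous(gm: GenotypeMatrix) -> np.ndarray:
    """Per-individual PHt: heterozygous loci / typed loci (nan if none)."""
    typed = ~gm.missing_mask()
    het = (gm.calls[:, :, 0] != gm.calls[:, :, 1]) & typed
    with np.errstate(invalid="ignore"):
        return np.where(typed.sum(1) > 0,
                        het.sum(1) / typed.sum(1), np.nan)


# ---------------------------------------------------------------------------
# pair records and the global IBD fit
# ---------------------------------------------------------------------------

def build_pairs(gm: GenotypeMatrix, D: np.ndarray | None = None) -> pd.DataFrame:
    """One row per unordered individual pair: geographic distance (km),
    genetic distance, and the pair midpoint."""
    if gm.coordinates is None:
        raise ValueError("spatial analysis requires sample coordinates")
    if D is None:
        D = nei_d_matrix(gm)
    xy = gm.coordinates
    iu, ju = np.triu_indices(gm.n, k=1)
    geo = np.hypot(*(xy[iu] - xy[ju]).T)
    mid = 0.5 * (xy[iu] + xy[ju])
    return pd.DataFrame({
        "i": iu, "j": ju,
        "id_a": [gm.individual_ids[i] for i in iu],
        "id_b": [gm.individual_ids[j] for j in ju],
        "geo_km": geo, "gen_d": D[iu, ju],
        "mid_x": mid[:, 0], "mid_y": mid[:, 1],
    })


@dataclass
class IbdFit:
    slope: float
    intercept: float
    n_pairs: int


def ibd_fit(pairs: pd.DataFrame) -> tuple[IbdFit, np.ndarray]:
    """OLS of genetic on geographic distance over all pairs; returns the
    fit and the residuals (observed - predicted)."""
    if len(pairs) < 3:
        raise ValueError("need >=3 pairs for the IBD fit")
    x = pairs.geo_km.to_numpy()
    y = pairs.gen_d.to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("zero variance in geographic distance")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return IbdFit(float(slope), float(intercept), len(pairs)), resid


# ---------------------------------------------------------------------------
# variogram + universal kriging
# ---------------------------------------------------------------------------

@dataclass
class Variogram:
    """Semivariogram model gamma(h); 'exponential' uses the practical
    range (gamma reaches ~95% of the sill at ``range_km``)."""

    kind: str            # 'exponential' | 'linear'
    nugget: float = 0.0
    sill: float = 1.0
    range_km: float = 1.0
    slope: float = 1.0   # linear model only

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        if self.kind == "exponential":
            g = self.nugget + self.sill * (1.0 - np.exp(-3.0 * h / self.range_km))
        elif self.kind == "linear":
            g = self.nugget + self.slope * h
        else:
            raise ValueError(f"unknown variogram kind {self.kind!r}")
        return np.where(h == 0, 0.0, g)


def fit_variogram(coords: np.ndarray, values: np.ndarray, n_bins: int = 12,
                  nugget: float = 0.0) -> Variogram:
    """Empirical semivariogram of trend-removed values, fitted with an
    exponential model by weighted least squares (bin counts as weights);
    falls back to a linear model through the origin if the fit fails."""
    X = np.column_stack([np.ones(len(coords)), coords])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    h = cdist(coords, coords)
    iu = np.triu_indices(len(coords), k=1)
    hv = h[iu]
    gv = 0.5 * (resid[iu[0]] - resid[iu[1]]) ** 2
    hmax = hv.max() * 0.6
    edges = np.linspace(0, hmax, n_bins + 1)
    centers, gammas, counts = [], [], []
    for b in range(n_bins):
        m = (hv > edges[b]) & (hv <= edges[b + 1])
        if m.sum() >= 3:
            centers.append(hv[m].mean())
            gammas.append(gv[m].mean())
            counts.append(m.sum())
    centers, gammas, counts = map(np.asarray, (centers, gammas, counts))
    if len(centers) < 3 or np.all(gammas == 0):
        slope = float(np.sum(gammas * centers) / np.sum(centers**2)) if len(centers) else 1.0
        return Variogram("linear", nugget, slope=max(slope, 1e-12))
    try:
        f = lambda hh, c1, a: nugget + c1 * (1.0 - np.exp(-3.0 * hh / a))
        p0 = (max(gammas.max() - nugget, 1e-9), max(centers.mean(), 1e-6))
        popt, _ = curve_fit(f, centers, gammas, p0=p0,
                            sigma=1.0 / np.sqrt(counts), maxfev=5000,
                            bounds=([1e-12, 1e-6], [np.inf, np.inf]))
        return Variogram("exponential", nugget, float(popt[0]), float(popt[1]))
    except Exception:
        slope = float(np.sum(counts * gammas * centers) / np.sum(counts * centers**2))
        return Variogram("linear", nugget, slope=max(slope, 1e-12))


def _trend_matrix(xy: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(len(xy)), xy])


class UniversalKriging:
    """Universal kriging with a first-order (planar) trend.

    Solves the standard UK system in variogram form once per data
    configuration; prediction at any set of targets is a single linear
    solve via the dual weights, so bootstrap re-kriging over a fixed grid
    is cheap.  With zero nugget the predictor interpolates the data
    exactly.
    """

    def __init__(self, coords: np.ndarray, values: np.ndarray,
                 variogram: Variogram, jitter: float = 1e-10):
        self.coords = np.asarray(coords, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.vgm = variogram
        F = _trend_matrix(self.coords)
        if np.linalg.matrix_rank(F) < F.shape[1]:
            raise ValueError(
                "kriging failed: data locations are collinear/degenerate "
                "(first-order trend is not identifiable)"
            )
        m = len(self.coords)
        G = variogram(cdist(self.coords, self.coords))
        G[np.diag_indices(m)] = 0.0
        A = np.zeros((m + 3, m + 3))
        A[:m, :m] = G + jitter * np.eye(m)
        A[:m, m:] = F
        A[m:, :m] = F.T
        rhs = np.concatenate([self.values, np.zeros(3)])
        self._A = A
        self._dual = np.linalg.solve(A, rhs)

    def predict(self, targets: np.ndarray,
                gamma_to_data: np.ndarray | None = None) -> np.ndarray:
        """Predict at (q, 2) targets; ``gamma_to_data`` may supply a
        precomputed (q, m) semivariance block to skip the distance work."""
        if gamma_to_data is None:
            gamma_to_data = self.vgm(cdist(targets, self.coords))
        B = np.concatenate([gamma_to_data, _trend_matrix(targets)], axis=1)
        return B @ self._dual


# ---------------------------------------------------------------------------
# raster surfaces
# ---------------------------------------------------------------------------

@dataclass
class RasterSurface:
    """Regular grid of interpolated values with bootstrap significance.

    ``values`` is (ny, nx), row 0 at the grid origin (south-west corner).
    ``p`` holds the two-sided bootstrap p-value per cell
    (2 * min(tail fractions), add-one corrected); ``mask`` is p <= alpha,
    split into ``mask_low``/``mask_high`` by the side of the reference.
    Cells beyond the data buffer are no-data (nan values, p = nan).
    """

    origin: tuple[float, float]
    cell_km: float
    values: np.ndarray
    p: np.ndarray
    mask_low: np.ndarray
    mask_high: np.ndarray
    nodata: np.ndarray
    reference: float
    alpha: float
    metadata: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        return self.mask_low | self.mask_high

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.nx) + 0.5) * self.cell_km
        ys = y0 + (np.arange(self.ny) + 0.5) * self.cell_km
        return xs, ys

    def to_dataframe(self) -> pd.DataFrame:
        xs, ys = self.cell_centers()
        gx, gy = np.meshgrid(xs, ys)
        return pd.DataFrame({
            "x": gx.ravel(), "y": gy.ravel(),
            "value": self.values.ravel(), "p": self.p.ravel(),
            "mask_low": self.mask_low.ravel(),
            "mask_high": self.mask_high.ravel(),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_ascii_grid(self, path, nodata_value: float = -9999.0) -> None:
        """ESRI ASCII grid of the interpolated values."""
        vals = np.where(self.nodata, nodata_value, self.values)
        header = (
            f"ncols {self.nx}\nnrows {self.ny}\n"
            f"xllcorner {self.origin[0]}\nyllcorner {self.origin[1]}\n"
            f"cellsize {self.cell_km}\nNODATA_value {nodata_value}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for row in vals[::-1]:          # ASCII grids are north-up
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def _make_grid(sample_xy: np.ndarray, cell_km: float, pad_km: float,
               buffer_km: float):
    x0 = sample_xy[:, 0].min() - pad_km
    y0 = sample_xy[:, 1].min() - pad_km
    x1 = sample_xy[:, 0].max() + pad_km
    y1 = sample_xy[:, 1].max() + pad_km
    nx = max(int(np.ceil((x1 - x0) / cell_km)), 1)
    ny = max(int(np.ceil((y1 - y0) / cell_km)), 1)
    xs = x0 + (np.arange(nx) + 0.5) * cell_km
    ys = y0 + (np.arange(ny) + 0.5) * cell_km
    gx, gy = np.meshgrid(xs, ys)
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    dist, _ = cKDTree(sample_xy).query(cells)
    nodata = dist > buffer_km
    return (x0, y0), nx, ny, cells, nodata


def _krige_bootstrap(coords: np.ndarray, values: np.ndarray, grid_cells: np.ndarray,
                     reference: float, n_boot: int, alpha: float,
                     rng: np.random.Generator, nugget: float = 0.0,
                     scheme: str = "permute"):
    """Krige values onto grid cells and attach Monte-Carlo significance.

    The variogram is fitted once on the observed data and held fixed, so
    the kriging predictor is a fixed linear smoother and each replicate is
    a single triangular solve.  Two resampling schemes:

    * ``permute`` (default): values are shuffled among the support
      locations; per-cell p compares the observed surface with the
      permutation distribution (two-sided, add-one).  Under spatial
      exchangeability this calibrates at the nominal level.
    * ``resample``: points are resampled with replacement (duplicates
      collapse to the unique support, which is what an exact interpolator
      uses) and the per-cell p is the fraction of replicate surfaces on
      the opposite side of the reference; this measures the stability of
      a deviation rather than its size against a null.
    """
    from scipy.linalg import lu_factor, lu_solve

    vgm = fit_variogram(coords, values, nugget=nugget)
    uk = UniversalKriging(coords, values, vgm)
    gamma_full = vgm(cdist(grid_cells, coords))
    B = np.concatenate([gamma_full, _trend_matrix(grid_cells)], axis=1)
    pred = B @ uk._dual

    m = len(coords)
    if scheme == "permute":
        lu = lu_factor(uk._A)
        rhs = np.concatenate([values, np.zeros(3)])
        ge = np.zeros(len(grid_cells))
        le = np.zeros(len(grid_cells))
        for _ in range(n_boot):
            rhs[:m] = rng.permutation(values)
            pb = B @ lu_solve(lu, rhs)
            ge += pb >= pred
            le += pb <= pred
        n_ok = n_boot
        p_hi = (ge + 1) / (n_boot + 1)   # small when the cell is high
        p_lo = (le + 1) / (n_boot + 1)
    elif scheme == "resample":
        above = np.zeros(len(grid_cells))
        below = np.zeros(len(grid_cells))
        n_ok = 0
        for _ in range(n_boot):
            idx = np.unique(rng.integers(0, m, size=m))
            if len(idx) < 4:
                continue
            try:
                uk_b = UniversalKriging(coords[idx], values[idx], vgm)
            except ValueError:
                continue
            pb = uk_b.predict(grid_cells, gamma_full[:, idx])
            above += pb > reference
            below += pb < reference
            n_ok += 1
        if n_ok == 0:
            raise RuntimeError("all bootstrap replicates failed")
        p_hi = (n_ok - above + 1) / (n_ok + 1)
        p_lo = (n_ok - below + 1) / (n_ok + 1)
    else:
        raise ValueError("scheme must be 'permute' or 'resample'")
    p = np.minimum(2.0 * np.minimum(p_hi, p_lo), 1.0)
    mask_high = (p <= alpha) & (pred > reference)
    mask_low = (p <= alpha) & (pred < reference)
    return pred, p, mask_low, mask_high, vgm, n_ok


def _dresd_individual_permutation(gm, pairs, keep_mask, coords, values, cells,
                                  reference, n_boot, alpha, rng):
    """Monte-Carlo significance for the DResD surface by permuting the
    genotype-to-location assignment of whole individuals.

    Each replicate relabels individuals across the sampled locations,
    rebuilds every pair's genetic distance, refits the global IBD
    regression and re-kriges the retained-band residuals on the unchanged
    midpoint support (geography, band membership and the kriging operator
    are location properties, so they are fixed).  Permuting individuals -
    not single pair residuals - preserves the dependence created by each
    individual appearing in many pairs, which is what calibrates the test
    under a spatially random null.  Per-cell two-sided p compares the
    observed surface with the permutation distribution (add-one).
    """
    from scipy.linalg import lu_factor, lu_solve

    D = nei_d_matrix(gm)
    vgm = fit_variogram(coords, values)
    uk = UniversalKriging(coords, values, vgm)
    gamma_full = vgm(cdist(cells, coords))
    B = np.concatenate([gamma_full, _trend_matrix(cells)], axis=1)
    pred = B @ uk._dual
    lu = lu_factor(uk._A)

    x = pairs.geo_km.to_numpy()
    Xd = np.column_stack([np.ones(len(x)), x])
    pinv = np.linalg.pinv(Xd)
    iu = pairs.i.to_numpy()
    ju = pairs.j.to_numpy()
    keep_pos = np.flatnonzero(keep_mask)
    m = len(coords)
    rhs = np.zeros(m + 3)
    ge = np.zeros(len(cells))
    le = np.zeros(len(cells))
    for _ in range(n_boot):
        perm = rng.permutation(gm.n)
        y = D[perm[iu], perm[ju]]
        resid = y - Xd @ (pinv @ y)
        rhs[:m] = resid[keep_pos]
        pb = B @ lu_solve(lu, rhs)
        ge += pb >= pred
        le += pb <= pred
    p_hi = (ge + 1) / (n_boot + 1)
    p_lo = (le + 1) / (n_boot + 1)
    p = np.minimum(2.0 * np.minimum(p_hi, p_lo), 1.0)
    mask_high = (p <= alpha) & (pred > reference)
    mask_low = (p <= alpha) & (pred < reference)
    return pred, p, mask_low, mask_high, vgm, n_boot


def dresd_surface(gm: GenotypeMatrix, d_min: float = 17.0, d_max: float = 33.0,
                  n_boot: int = 499, alpha: float = 0.05, cell_km: float = 2.0,
                  pad_km: float = 10.0, buffer_km: float = 40.0,
                  seed=None, reference: str = "median",
                  scheme: str = "permute_individuals",
                  log_distance: bool = False) -> RasterSurface:
    """The DResD residual surface.

    Fits the global IBD regression on ALL pairs, retains the pairs whose
    geographic distance lies in [d_min, d_max] km, places their residuals
    at the pair midpoints, kriges, and bootstraps significance against the
    retained-pair reference (``median`` residual by default, ``zero`` for
    the raw IBD prediction).  Cells in the low mask are homogeneous core
    areas; cells in the high mask are contrasting transition areas.
    ``log_distance`` switches the IBD regressor to log(km).
    """
    import warnings

    pairs = build_pairs(gm)
    if log_distance:
        pairs = pairs.assign(geo_km_raw=pairs.geo_km,
                             geo_km=np.log(np.maximum(pairs.geo_km, 1e-6)))
    fit, resid = ibd_fit(pairs)
    pairs["residual"] = resid
    band_lo, band_hi = d_min, d_max
    geo_for_band = pairs["geo_km_raw"] if log_distance else pairs["geo_km"]
    keep = (geo_for_band >= band_lo) & (geo_for_band <= band_hi)
    retained = pairs[keep]
    if len(retained) < 20:
        warnings.warn(f"only {len(retained)} pairs in the {d_min}-{d_max} km band")
    if len(retained) < 4:
        raise ValueError("too few pairs in the neighbour band to krige")

    coords = retained[["mid_x", "mid_y"]].to_numpy()
    values = retained["residual"].to_numpy()
    med = float(np.median(values))
    ref = med if reference == "median" else 0.0

    origin, nx, ny, cells, nodata = _make_grid(gm.coordinates, cell_km,
                                               pad_km, buffer_km)
    rng = np.random.default_rng(seed)
    if scheme == "permute_individuals":
        pred, p, mlo, mhi, vgm, n_ok = _dresd_individual_permutation(
            gm, pairs, keep.to_numpy(), coords, values, cells, ref,
            n_boot, alpha, rng)
    else:
        pred, p, mlo, mhi, vgm, n_ok = _krige_bootstrap(coords, values, cells,
                                                        ref, n_boot, alpha, rng,
                                                        scheme=scheme)
    shape = (ny, nx)
    vals = pred.reshape(shape).astype(float)
    pgrid = p.reshape(shape)
    nod = nodata.reshape(shape)
    vals[nod] = np.nan
    pgrid[nod] = np.nan
    surf = RasterSurface(origin, cell_km, vals, pgrid,
                         mlo.reshape(shape) & ~nod, mhi.reshape(shape) & ~nod,
                         nod, ref, alpha,
                         metadata=dict(
                             analysis="dresd", ibd_slope=fit.slope,
                             ibd_intercept=fit.intercept,
                             n_pairs_total=fit.n_pairs,
                             n_pairs_retained=int(len(retained)),
                             median_residual=med, d_min=d_min, d_max=d_max,
                             n_boot_effective=n_ok, scheme=scheme,
                             variogram=vars(vgm), reference_mode=reference))
    surf.metadata["pairs"] = retained.reset_index(drop=True)
    return surf


def scalar_surface(values: np.ndarray, coords: np.ndarray, link: str = "logit",
                   n_boot: int = 499, reference: str = "median",
                   alpha: float = 0.05, cell_km: float = 2.0,
                   pad_km: float = 10.0, buffer_km: float = 40.0,
                   clamp_eps: float | None = None, seed=None,
                   scheme: str = "permute",
                   analysis: str = "scalar") -> RasterSurface:
    """Kriged surface of a bounded per-individual scalar (heterozygosity,
    membership coefficient) with bootstrap significance.

    Values in (0, 1) are logit-transformed before kriging (0 and 1 are
    clamped to ``clamp_eps`` / 1 - clamp_eps; for a proportion over m loci
    pass clamp_eps = 1/(2m)), kriging and the bootstrap run on the link
    scale, and the displayed surface is back-transformed.  The reference
    is the global ``median`` or ``mean`` of the input values.
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    ok = ~np.isnan(values)
    values, coords = values[ok], coords[ok]
    if len(values) < 4:
        raise ValueError("need >=4 finite values")
    ref_raw = float(np.median(values) if reference == "median" else np.mean(values))
    if link == "logit":
        eps = clamp_eps if clamp_eps is not None else 0.01
        z = logit(np.clip(values, eps, 1.0 - eps))
        ref = float(logit(np.clip(ref_raw, eps, 1.0 - eps)))
        back = expit
    elif link == "identity":
        z, ref, back = values, ref_raw, lambda x: x
    else:
        raise ValueError("link must be 'logit' or 'identity'")

    if np.ptp(z) == 0:
        origin, nx, ny, cells, nodata = _make_grid(coords, cell_km, pad_km, buffer_km)
        shape = (ny, nx)
        vals = np.full(shape, back(ref))
        nod = nodata.reshape(shape)
        vals[nod] = np.nan
        return RasterSurface(origin, cell_km, vals, np.full(shape, 1.0),
                             np.zeros(shape, bool), np.zeros(shape, bool),
                             nod, ref_raw, alpha,
                             metadata=dict(analysis=analysis, constant=True))

    origin, nx, ny, cells, nodata = _make_grid(coords, cell_km, pad_km, buffer_km)
    rng = np.random.default_rng(seed)
    pred, p, mlo, mhi, vgm, n_ok = _krige_bootstrap(coords, z, cells, ref,
                                                    n_boot, alpha, rng,
                                                    scheme=scheme)
    shape = (ny, nx)
    vals = back(pred).reshape(shape).astype(float)
    pgrid = p.reshape(shape)
    nod = nodata.reshape(shape)
    vals[nod] = np.nan
    pgrid[nod] = np.nan
    return RasterSurface(origin, cell_km, vals, pgrid,
                         mlo.reshape(shape) & ~nod, mhi.reshape(shape) & ~nod,
                         nod, ref_raw, alpha,
                         metadata=dict(analysis=analysis, link=link,
                                       reference_mode=reference, scheme=scheme,
                                       n_boot_effective=n_ok,
                                       variogram=vars(vgm)))
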