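"""Per-locus and per-group diversity and differentiation statistics.

Implements the classic microsatellite summary panel: observed and Nei's
unbiased expected heterozygosity, allele counts, rarefied allelic richness,
Weir & Cockerham (1984) F-statistics with permutation p-values, and exact
Hardy-Weinberg and linkage-disequilibrium tests by Monte-Carlo permutation.

F_IS and pairwise theta (FST) accumulate Weir-Cockerham variance components
as ratios of sums across alleles and loci, matching ARLEQUIN/FSTAT, not as
averages of per-locus ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# per-locus primitives
# ---------------------------------------------------------------------------

def _locus_counts(calls_l: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Allele values, copy counts, gene copies n and #heterozygotes for one
    locus (calls_l: (n_ind, 2), missing rows excluded)."""
    ok = calls_l[:, 0] != MISSING
    g = calls_l[ok]
    copies = g.ravel()
    vals, counts = np.unique(copies, return_counts=True)
    het = int((g[:, 0] != g[:, 1]).sum())
    return vals, counts, copies.size, het


def unbiased_he(counts: np.ndarray) -> float:
    """Nei's unbiased expected heterozygosity, n/(n-1) * (1 - sum p_i^2),
    with n = gene copies."""
    n = counts.sum()
    if n < 2:
        return np.nan
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def rarefied_allelic_richness(counts: np.ndarray, g: int) -> float:
    """Hypergeometric rarefaction to g gene copies:
    A_R = sum_i [1 - C(n - n_i, g) / C(n, g)]."""
    n = int(counts.sum())
    if g > n:
        raise ValueError(f"rarefaction size g={g} exceeds gene copies n={n}")
    logc_n_g = gammaln(n + 1) - gammaln(g + 1) - gammaln(n - g + 1)
    out = 0.0
    for ni in counts:
        rem = n - int(ni)
        if rem < g:
            out += 1.0
        else:
            logc = gammaln(rem + 1) - gammaln(g + 1) - gammaln(rem - g + 1)
            out += 1.0 - np.exp(logc - logc_n_g)
    return float(out)


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

@dataclass
class DiversityReport:
    """Per-locus table (one block per analysed unit) and across-loci means.

    ``per_locus`` columns: unit, locus, n (individuals typed), N_A, A_R,
    H_O, H_E, F_IS.  ``means`` is indexed by unit with unweighted across-loci
    means; mean F_IS is the ratio-of-sums estimator 1 - sum(Ho)/sum(He)
    over polymorphic loci.
    """

    per_locus: pd.DataFrame
    means: pd.DataFrame
    rarefaction_g: dict[str, int]

    def to_csv(self, path) -> None:
        self.per_locus.to_csv(path, index=False)


def _units(gm: GenotypeMatrix, groups) -> dict[str, np.ndarray]:
    units: dict[str, np.ndarray] = {"ALL": np.arange(gm.n)}
    if groups is not None:
        labels = np.asarray(list(groups))
        for gname in pd.unique(labels):
            units[str(gname)] = np.flatnonzero(labels == gname)
    return units


def summary_stats(gm: GenotypeMatrix, groups=None,
                  rarefaction_g: int | None = None) -> DiversityReport:
    """Diversity summary for the whole sample and (optionally) per group.

    ``groups`` is a per-individual label sequence (defaults to none: only
    the pooled "ALL" unit).  ``rarefaction_g`` is the gene-copy count for
    allelic richness; default is the smallest per-unit, per-locus typed
    gene-copy count (FSTAT convention).  Monomorphic loci report
    N_A=1, H_O=H_E=0 and missing F_IS.
    """
    units = _units(gm, groups)
    for name in [u for u, idx in units.items() if idx.size < 2]:
        warnings.warn(f"unit {name!r} has <2 individuals; skipped")
        del units[name]
    if not units:
        raise ValueError("no analysable unit with >=2 individuals")

    min_copies = {
        name: min(
            _locus_counts(gm.calls[idx, l])[2] for l in range(gm.n_loci)
        )
        for name, idx in units.items()
    }
    g_by_unit = {}
    for name in units:
        g = rarefaction_g if rarefaction_g is not None else min_copies[name]
        if g > min_copies[name]:
            raise ValueError(
                f"rarefaction_g={g} exceeds smallest gene-copy count "
                f"{min_copies[name]} in unit {name!r}"
            )
        g_by_unit[name] = max(g, 2)

    rows = []
    for name, idx in units.items():
        for l, loc in enumerate(gm.loci):
            vals, counts, n_copies, het = _locus_counts(gm.calls[idx, l])
            n_ind = n_copies // 2
            if n_ind == 0:
                rows.append((name, loc.name, 0, 0, np.nan, np.nan, np.nan, np.nan))
                continue
            ho = het / n_ind
            he = unbiased_he(counts)
            na = len(vals)
            ar = rarefied_allelic_richness(counts, g_by_unit[name])
            if na < 2 or he == 0:
                he = 0.0 if na == 1 else he
                fis = np.nan
            else:
                fis = 1.0 - ho / he
            if na == 1:
                ho, he = 0.0, 0.0
            rows.append((name, loc.name, n_ind, na, ar, ho, he, fis))
    per_locus = pd.DataFrame(
        rows, columns=["unit", "locus", "n", "N_A", "A_R", "H_O", "H_E", "F_IS"]
    )

    means = []
    for name in units:
        sub = per_locus[per_locus.unit == name]
        poly = sub[sub.H_E > 0]
        fis_overall = (
            1.0 - poly.H_O.sum() / poly.H_E.sum() if len(poly) else np.nan
        )
        means.append(
            dict(unit=name, N_A=sub.N_A.mean(), A_R=sub.A_R.mean(),
                 H_O=sub.H_O.mean(), H_E=sub.H_E.mean(), F_IS=fis_overall)
        )
    return DiversityReport(per_locus, pd.DataFrame(means).set_index("unit"),
                           g_by_unit)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components
# ---------------------------------------------------------------------------

def _wc_components(gm: GenotypeMatrix, labels: np.ndarray) -> tuple[float, float, float]:
    """Sums of the a (among-population), b (among-individual) and c
    (within-individual) components over all alleles and loci."""
    group_idx = {g: np.flatnonzero(labels == g) for g in pd.unique(labels)}
    r = len(group_idx)
    if r < 2:
        raise ValueError("need >=2 groups for theta")
    A = B = C = 0.0
    for l in range(gm.n_loci):
        per_group = []
        for idx in group_idx.values():
            calls = gm.calls[idx, l]
            ok = calls[:, 0] != MISSING
            g = calls[ok]
            if len(g) == 0:
                continue
            per_group.append(g)
        if len(per_group) < 2:
            continue
        nj = np.array([len(g) for g in per_group], dtype=float)
        alleles = np.unique(np.concatenate([g.ravel() for g in per_group]))
        if len(alleles) < 2:
            continue
        nbar = nj.mean()
        rr = len(per_group)
        nc = (rr * nbar - np.sum(nj**2) / (rr * nbar)) / (rr - 1)
        for a in alleles:
            pj = np.array([np.mean(g == a) for g in per_group])
            hj = np.array([np.mean((g[:, 0] != g[:, 1]) &
                                   np.any(g == a, axis=1)) for g in per_group])
            pbar = np.sum(nj * pj) / (rr * nbar)
            s2 = np.sum(nj * (pj - pbar) ** 2) / ((rr - 1) * nbar)
            hbar = np.sum(nj * hj) / (rr * nbar)
            if nbar <= 1 or nc == 0:
                continue
            a_comp = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (rr - 1) / rr * s2 - hbar / 4) / (nbar - 1)
            )
            b_comp = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (rr - 1) / rr * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c_comp = hbar / 2
            A += a_comp
            B += b_comp
            C += c_comp
    return A, B, C


def wc_theta(gm: GenotypeMatrix, labels) -> float:
    """Multi-allelic, multi-locus Weir-Cockerham theta (ratio of sums)."""
    A, B, C = _wc_components(gm, np.asarray(list(labels)))
    denom = A + B + C
    return float(A / denom) if denom != 0 else np.nan


@dataclass
class FstMatrix:
    groups: list[str]
    theta: pd.DataFrame
    p_values: pd.DataFrame

    def to_csv(self, path) -> None:
        self.theta.to_csv(path)


def pairwise_fst(gm: GenotypeMatrix, groups, n_perm: int = 999,
                 seed: int | None = None) -> FstMatrix:
    """Pairwise Weir-Cockerham theta between groups with permutation
    p-values (fraction of label permutations with theta >= observed,
    add-one corrected)."""
    labels = np.asarray([str(g) for g in groups])
    names = [str(g) for g in pd.unique(labels)]
    if len(names) < 2:
        raise ValueError("need >=2 groups")
    for g in names:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} has <2 individuals")
    rng = np.random.default_rng(seed)
    k = len(names)
    th = np.zeros((k, k))
    pv = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            idx = np.flatnonzero(np.isin(labels, [names[i], names[j]]))
            sub = gm.subset_individuals(idx)
            sub_labels = labels[idx]
            obs = wc_theta(sub, sub_labels)
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(sub_labels)
                if wc_theta(sub, perm) >= obs:
                    exceed += 1
            p = (exceed + 1) / (n_perm + 1)
            th[i, j] = th[j, i] = obs
            pv[i, j] = pv[j, i] = p
    return FstMatrix(
        names,
        pd.DataFrame(th, index=names, columns=names),
        pd.DataFrame(pv, index=names, columns=names),
    )


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Monte-Carlo)
# ---------------------------------------------------------------------------

def _genotype_log_prob(g: np.ndarray) -> float:
    """Log conditional probability of a genotype configuration given its
    allele counts (Levene's exact distribution)."""
    n = len(g)
    vals, acounts = np.unique(g.ravel(), return_counts=True)
    het = int((g[:, 0] != g[:, 1]).sum())
    codes = g[:, 0] * 100000 + g[:, 1]
    _, gcounts = np.unique(codes, return_counts=True)
    return float(
        gammaln(n + 1) + np.sum(gammaln(acounts + 1)) + het * np.log(2)
        - gammaln(2 * n + 1) - np.sum(gammaln(gcounts + 1))
    )


def hwe_test(gm: GenotypeMatrix, per_group: bool = False, groups=None,
             mc_reps: int = 10_000, seed: int | None = None) -> pd.DataFrame:
    """Exact Hardy-Weinberg test per locus by Monte-Carlo shuffling of
    alleles among individuals (probability-ordering criterion), plus
    one-sided heterozygote-excess / deficit p-values and a Fisher-combined
    global p across loci.

    Returns a tidy frame with columns unit, locus, p (two-sided exact),
    p_het_excess, p_het_deficit; the global rows carry locus="GLOBAL".
    Monomorphic loci report p = 1.
    """
    if mc_reps < 1000:
        raise ValueError("mc_reps must be >= 1000")
    rng = np.random.default_rng(seed)
    units = _units(gm, groups) if (per_group and groups is not None) else {"ALL": np.arange(gm.n)}
    rows = []
    for uname, idx in units.items():
        plist, pex_list, pdef_list = [], [], []
        for l, loc in enumerate(gm.loci):
            calls = gm.calls[idx, l]
            g = calls[calls[:, 0] != MISSING]
            vals = np.unique(g.ravel())
            if len(vals) < 2 or len(g) < 2:
                rows.append((uname, loc.name, 1.0, 1.0, 1.0))
                plist.append(1.0); pex_list.append(1.0); pdef_list.append(1.0)
                continue
            obs_lp = _genotype_log_prob(g)
            obs_het = int((g[:, 0] != g[:, 1]).sum())
            pool = g.ravel().copy()
            le = ge_het = le_het = 0
            for _ in range(mc_reps):
                rng.shuffle(pool)
                sim = np.sort(pool.reshape(-1, 2), axis=1)
                if _genotype_log_prob(sim) <= obs_lp + 1e-12:
                    le += 1
                h = int((sim[:, 0] != sim[:, 1]).sum())
                if h >= obs_het:
                    ge_het += 1
                if h <= obs_het:
                    le_het += 1
            p = (le + 1) / (mc_reps + 1)
            # excess: simulated Ho rarely reaches the observed Ho
            p_ex = (ge_het + 1) / (mc_reps + 1)
            p_def = (le_het + 1) / (mc_reps + 1)
            rows.append((uname, loc.name, p, p_ex, p_def))
            plist.append(p); pex_list.append(p_ex); pdef_list.append(p_def)
        combine = lambda ps: float(stats.combine_pvalues(ps, method="fisher").pvalue)
        rows.append((uname, "GLOBAL", combine(plist), combine(pex_list),
                     combine(pdef_list)))
    return pd.DataFrame(rows, columns=["unit", "locus", "p",
                                       "p_het_excess", "p_het_deficit"])


# ---------------------------------------------------------------------------
# linkage disequilibrium test
# ---------------------------------------------------------------------------

def _g_statistic(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Log-likelihood-ratio G on the genotype x genotype contingency table."""
    tab = pd.crosstab(codes_a, codes_b).to_numpy(dtype=float)
    n = tab.sum()
    exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(tab > 0, tab * np.log(tab / exp), 0.0)
    return float(2.0 * terms.sum())


def ld_test(gm: GenotypeMatrix, mc_reps: int = 1000,
            alpha_bonferroni: float = 0.05, seed: int | None = None) -> pd.DataFrame:
    """Genotypic-association permutation test for every locus pair.

    One locus's genotype column is shuffled across individuals; the p-value
    is the add-one fraction of permutations whose G statistic reaches the
    observed one.  The Bonferroni threshold is alpha / C(L, 2); with 15
    loci that is alpha / 105.
    """
    L = gm.n_loci
    if L < 2:
        raise ValueError("need >=2 loci")
    rng = np.random.default_rng(seed)
    n_pairs = L * (L - 1) // 2
    threshold = alpha_bonferroni / n_pairs
    rows = []
    for a in range(L):
        for b in range(a + 1, L):
            ok = (gm.calls[:, a, 0] != MISSING) & (gm.calls[:, b, 0] != MISSING)
            ga = gm.calls[ok, a, 0] * 100000 + gm.calls[ok, a, 1]
            gb = gm.calls[ok, b, 0] * 100000 + gm.calls[ok, b, 1]
            if len(np.unique(ga)) < 2 or len(np.unique(gb)) < 2 or len(ga) < 2:
                rows.append((gm.loci[a].name, gm.loci[b].name, np.nan, 1.0, False))
                continue
            obs = _g_statistic(ga, gb)
            ge = 0
            gb_perm = gb.copy()
            for _ in range(mc_reps):
                rng.shuffle(gb_perm)
                if _g_statistic(ga, gb_perm) >= obs - 1e-12:
                    ge += 1
            p = (ge + 1) / (mc_reps + 1)
            rows.append((gm.loci[a].name, gm.loci[b].name, obs, p, p < threshold))
    df = pd.DataFrame(rows, columns=["locus_a", "locus_b", "G", "p", "significant"])
    df.attrs["bonferroni_threshold"] = threshold
    df.attrs["n_pairs"] = n_pairs
    return df
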