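"""Linkage-disequilibrium effective population size (single-sample).

In a closed population of effective size Ne, genetic drift generates
low-level associations (linkage disequilibrium) between physically
unlinked loci; the expected squared correlation r^2 of allele frequencies,
after removing the part created by finite sampling, is inversely
proportional to Ne.  This module measures r^2 with Burrows' composite
disequilibrium on unphased diploid genotypes, subtracts the Waples (2006)
second-order sampling expectation E[r^2 | S], and inverts the drift
relation under either random mating or lifetime monogamy, following the
published LDNe estimator (Waples & Do 2008).

Coefficients used (Waples 2006 eqs. 12-13; Waples & Do 2008 Table 1):

    S >= 30:  E[r^2|S] = 1/S + 3.19/S^2
              random:   Ne = (1/3 + sqrt(1/9 - 2.76 r2'))  / (2 r2')
              monogamy: Ne = (2/3 + sqrt(4/9 - 7.2  r2'))  / (2 r2')
    S < 30:   E[r^2|S] = 0.0018 + 0.907/S + 4.44/S^2
              random:   Ne = (0.308 + sqrt(0.308^2 - 2.08 r2')) / (2 r2')
              monogamy: Ne = (0.618 + sqrt(0.618^2 - 5.24 r2')) / (2 r2')

where r2' is the drift component (weighted mean r^2 minus the sampling
expectation at the harmonic mean S).  Alleles rarer than ``min_freq``
(default 0.02) are screened out before computing r^2; missing data are
handled pairwise (individuals complete at both loci of a pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# Burrows composite r^2
# ---------------------------------------------------------------------------

def _usable_alleles(dosage: np.ndarray, min_freq: float) -> list[int]:
    """Columns (alleles) passing the frequency screen; a diallelic locus
    contributes a single allele (the second is redundant, r^2 identical)."""
    p = dosage.mean(axis=0) / 2.0
    ok = [j for j in range(dosage.shape[1]) if min_freq <= p[j] <= 1 - min_freq]
    if len(ok) == 2 and dosage.shape[1] == 2:
        ok = ok[:1]
    return ok


def _dosage(calls_l: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """(n, k) allele-count (0/1/2) matrix for one locus."""
    return (calls_l[:, :, None] == alleles[None, None, :]).sum(axis=1)


def burrows_r2(gm: GenotypeMatrix, min_freq: float = 0.02) -> pd.DataFrame:
    """Burrows composite-disequilibrium r^2 for every allele pair at every
    locus pair.

    For alleles A, B with per-individual dosages X, Y in a pairwise-complete
    sample of S individuals:

        Delta = S/(S-1) * [ sum(X*Y)/(2S) - 2 pA pB ]
        r^2   = Delta^2 / (pA(1-pA) pB(1-pB))

    Columns: locus_a, locus_b, allele_a, allele_b, S, r2.
    """
    L = gm.n_loci
    per_locus = []
    for l in range(L):
        calls_l = gm.calls[:, l, :]
        alleles = np.unique(calls_l[calls_l != MISSING])
        per_locus.append((alleles, calls_l))
    rows = []
    for a in range(L):
        for b in range(a + 1, L):
            ok = (gm.calls[:, a, 0] != MISSING) & (gm.calls[:, b, 0] != MISSING)
            S = int(ok.sum())
            if S < 2:
                continue
            al_a, calls_a = per_locus[a]
            al_b, calls_b = per_locus[b]
            da = _dosage(calls_a[ok], al_a)
            db = _dosage(calls_b[ok], al_b)
            ia = _usable_alleles(da, min_freq)
            ib = _usable_alleles(db, min_freq)
            if not ia or not ib:
                continue
            for j in ia:
                X = da[:, j].astype(float)
                pA = X.mean() / 2.0
                for k in ib:
                    Y = db[:, k].astype(float)
                    pB = Y.mean() / 2.0
                    delta = (X @ Y) / (2.0 * S) - 2.0 * pA * pB
                    delta *= S / (S - 1.0)
                    denom = pA * (1 - pA) * pB * (1 - pB)
                    if denom <= 0:
                        continue
                    rows.append((gm.loci[a].name, gm.loci[b].name,
                                 int(al_a[j]), int(al_b[k]), S,
                                 delta * delta / denom))
    if not rows:
        raise ValueError("no locus pair with qualifying alleles after screening")
    return pd.DataFrame(rows, columns=["locus_a", "locus_b", "allele_a",
                                       "allele_b", "S", "r2"])


# ---------------------------------------------------------------------------
# Ne estimation
# ---------------------------------------------------------------------------

def expected_r2_sample(S: float) -> float:
    """Sampling expectation of Burrows r^2 for unphased diploid data."""
    if S >= 30:
        return 1.0 / S + 3.19 / S**2
    return 0.0018 + 0.907 / S + 4.44 / S**2


def _ne_from_r2prime(r2p: float, S: float, mating: str) -> float:
    if r2p <= 0:
        return np.inf
    if mating == "monogamy":
        a, b = (2.0 / 3.0, 7.2) if S >= 30 else (0.618, 5.24)
    elif mating == "random":
        a, b = (1.0 / 3.0, 2.76) if S >= 30 else (0.308, 2.08)
    else:
        raise ValueError("mating must be 'monogamy' or 'random'")
    disc = max(a * a - b * r2p, 0.0)
    return float((a + np.sqrt(disc)) / (2.0 * r2p))


@dataclass
class NeEstimate:
    ne: float
    ci_parametric: tuple[float, float]
    ci_jackknife: tuple[float, float]
    mean_r2: float
    expected_r2: float
    n_comparisons: int
    harmonic_S: float
    mating: str
    min_freq: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "Ne": self.ne,
            "CI_param_low": self.ci_parametric[0],
            "CI_param_high": self.ci_parametric[1],
            "CI_jack_low": self.ci_jackknife[0],
            "CI_jack_high": self.ci_jackknife[1],
            "mean_r2": self.mean_r2,
            "expected_r2": self.expected_r2,
            "n_comparisons": self.n_comparisons,
            "harmonic_S": self.harmonic_S,
            "mating": self.mating,
            "min_freq": self.min_freq,
        }])


def _chi2_ci_ne(mean_r2: float, df: float, S: float, mating: str,
                alpha: float = 0.05) -> tuple[float, float]:
    """Chi-square CI on the mean r^2 with the given degrees of freedom,
    mapped through the drift equation (Ne decreasing in r^2)."""
    df = max(df, 1.0)
    er2 = expected_r2_sample(S)
    hi_r2 = df * mean_r2 / stats.chi2.ppf(0.5 * alpha, df)
    lo_r2 = df * mean_r2 / stats.chi2.ppf(1 - 0.5 * alpha, df)
    lo_ne = _ne_from_r2prime(hi_r2 - er2, S, mating)
    hi_ne = _ne_from_r2prime(lo_r2 - er2, S, mating)
    return (lo_ne, hi_ne)


def ldne(gm: GenotypeMatrix, min_freq: float = 0.02,
         mating: str = "monogamy", alpha: float = 0.05) -> NeEstimate:
    """LD-based effective population size with parametric (chi-square) and
    jackknife-over-locus-pairs confidence intervals.

    The point estimate uses the comparison-weighted mean r^2 (each
    allele-pair comparison weighted equally, so locus pairs are weighted by
    their number of comparisons), the harmonic-mean pairwise S, and the
    mating-model drift equation above.  A corrected r^2 at or below zero
    yields an infinite estimate with a finite lower bound.
    """
    tab = burrows_r2(gm, min_freq)
    mean_r2 = float(tab.r2.mean())
    n_comp = len(tab)
    harm_S = float(len(tab) / np.sum(1.0 / tab.S))
    er2 = expected_r2_sample(harm_S)
    r2p = mean_r2 - er2
    ne = _ne_from_r2prime(r2p, harm_S, mating)

    # parametric CI: chi-square with df = the number of *independent*
    # comparisons, sum over locus pairs of (k1 - 1)(k2 - 1)
    df_indep = 0
    for _, sub in tab.groupby(["locus_a", "locus_b"], sort=False):
        ka = sub.allele_a.nunique()
        kb = sub.allele_b.nunique()
        df_indep += max(ka - 1, 1) * max(kb - 1, 1)
    ci_param = _chi2_ci_ne(mean_r2, df_indep, harm_S, mating, alpha)

    # delete-one-locus jackknife -> effective df, then chi-square CI.
    # Jackknifing whole loci (not locus pairs) respects the dependence
    # among all pairs sharing a locus, which otherwise understates the
    # variance of the mean r^2.
    loci = list(dict.fromkeys(tab.locus_a.tolist() + tab.locus_b.tolist()))
    if len(loci) > 2:
        loo = []
        for loc in loci:
            sub = tab[(tab.locus_a != loc) & (tab.locus_b != loc)]
            if len(sub):
                loo.append(float(sub.r2.mean()))
        loo = np.asarray(loo)
        J = len(loo)
        var_jack = (J - 1) / J * np.sum((loo - loo.mean()) ** 2)
        if var_jack > 0:
            df_eff = 2.0 * mean_r2**2 / var_jack
            ci_jack = _chi2_ci_ne(mean_r2, df_eff, harm_S, mating, alpha)
        else:
            ci_jack = ci_param
    else:
        ci_jack = ci_param
    return NeEstimate(ne, ci_param, ci_jack, mean_r2, er2, n_comp,
                      harm_S, mating, min_freq)
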