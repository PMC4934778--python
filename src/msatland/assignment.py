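"""Bayesian exclusion test for immigrants from unsampled populations.

Each individual is scored by the Rannala-Mountain posterior-predictive
likelihood of its multilocus genotype given the sampled reference
population, and that score is ranked against scores of genotypes simulated
from the reference allele frequencies (Paetkau's Monte-Carlo resampling).
Individuals whose score falls in the extreme lower tail (p below alpha)
are unlikely to originate from the sampled population.

The Rannala-Mountain score places a Dirichlet prior with pseudo-count 1/k
per allele (k = distinct alleles at the locus) on the reference
frequencies, so no genotype ever has zero probability.  When scoring a
member of the reference sample itself, that individual's own alleles are
removed from the reference counts first (leave-one-out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


def _locus_count_arrays(gm: GenotypeMatrix):
    """Per locus: (allele values, copy counts over the whole sample)."""
    out = []
    for l in range(gm.n_loci):
        col = gm.calls[:, l, :].ravel()
        col = col[col != MISSING]
        vals, counts = np.unique(col, return_counts=True)
        out.append((vals, counts.astype(float)))
    return out


def _rm_locus_logp(a: int, b: int, vals: np.ndarray, counts: np.ndarray) -> float:
    """Posterior-predictive log-probability of an unordered genotype (a, b)
    under Dirichlet(1/k, ..., 1/k) + multinomial reference counts.

    With n = total copies and k alleles (union of reference alleles and the
    genotype's own), pseudo-count tau = 1/k:
        P(aa) = (n_a+tau)(n_a+tau+1) / ((n+1)(n+2))
        P(ab) = 2 (n_a+tau)(n_b+tau) / ((n+1)(n+2)),  a != b
    (the prior masses sum to k*tau = 1, hence the n+1, n+2 denominators).
    """
    pool = dict(zip(vals.tolist(), counts.tolist()))
    for x in (a, b):
        pool.setdefault(x, 0.0)
    k = len(pool)
    tau = 1.0 / k
    n = sum(pool.values())
    denom = (n + 1.0) * (n + 2.0)
    na = pool[a] + tau
    if a == b:
        num = na * (na + 1.0)
    else:
        num = 2.0 * na * (pool[b] + tau)
    return float(np.log(num) - np.log(denom))


def rm_score(genotype: np.ndarray, ref_counts) -> float:
    """Log-likelihood of one individual's (L, 2) genotype against reference
    allele-count arrays (as produced internally from a GenotypeMatrix).
    Missing loci are skipped."""
    total = 0.0
    for l, (vals, counts) in enumerate(ref_counts):
        a, b = int(genotype[l, 0]), int(genotype[l, 1])
        if a == MISSING:
            continue
        total += _rm_locus_logp(a, b, vals, counts)
    return total


@dataclass
class ExclusionResult:
    individual_id: str
    score: float
    p: float
    flagged: bool


def exclusion_test(gm: GenotypeMatrix, n_sim: int = 10_000, alpha: float = 0.01,
                   seed=None, leave_one_out: bool = True) -> pd.DataFrame:
    """Monte-Carlo exclusion test of every individual against the sample.

    ``n_sim`` genotypes are simulated from the reference allele frequencies
    assuming Hardy-Weinberg and inter-locus independence, scored with the
    same Rannala-Mountain likelihood, and each observed individual's
    p-value is the add-one rank of its score among the simulated ones:
    p = (1 + #{simulated <= observed}) / (n_sim + 1).  With
    ``leave_one_out`` (default) the focal individual's alleles are removed
    from the reference before scoring it.

    Returns a frame with columns id, score, p, flagged (p < alpha).
    """
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    rng = np.random.default_rng(seed)
    ref = _locus_count_arrays(gm)

    # simulate reference genotypes under HWE / linkage equilibrium
    sim_scores = np.zeros(n_sim)
    for l, (vals, counts) in enumerate(ref):
        p = counts / counts.sum()
        draws = rng.choice(len(vals), size=(n_sim, 2), p=p)
        va, vb = vals[draws[:, 0]], vals[draws[:, 1]]
        for s in range(n_sim):
            sim_scores[s] += _rm_locus_logp(int(min(va[s], vb[s])),
                                            int(max(va[s], vb[s])), vals, counts)

    rows = []
    for i in range(gm.n):
        if leave_one_out:
            loo = []
            for l, (vals, counts) in enumerate(ref):
                c = counts.copy()
                a, b = gm.calls[i, l]
                if a != MISSING:
                    for x in (a, b):
                        j = np.searchsorted(vals, x)
                        c[j] -= 1.0
                loo.append((vals, c))
            score = rm_score(gm.calls[i], loo)
        else:
            score = rm_score(gm.calls[i], ref)
        p = (1 + int(np.sum(sim_scores <= score + 1e-12))) / (n_sim + 1)
        rows.append(dict(id=gm.individual_ids[i], score=score, p=p,
                         flagged=p < alpha))
    return pd.DataFrame(rows)
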