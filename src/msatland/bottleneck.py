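"""Heterozygosity-excess bottleneck tests and the Garza-Williamson index.

A recently bottlenecked population transiently shows *heterozygosity
excess*: the expected heterozygosity computed from allele frequencies
exceeds the mutation-drift-equilibrium value expected for the number of
alleles that survived the bottleneck (rare alleles are lost faster than
heterozygosity).  The test simulates, for each locus, the coalescent
distribution of equilibrium heterozygosity conditioned on the observed
allele count k in a sample of n gene copies, under one of three mutation
models:

* IAM  - infinite alleles: every mutation creates a novel allele;
* SMM  - strict stepwise: every mutation changes the repeat count by +-1;
* TPM  - two-phase: single steps with probability ``p_smm``, otherwise a
  multi-step geometric jump whose variance is configurable.

The per-replicate genealogy is generated by the backward coalescent event
chain (with j lineages the most recent event is a mutation with probability
theta/(theta + j - 1), else a coalescence), which does not require event
times.  Conditioning on exactly k alleles uses rejection with an adaptive
theta random-walk between attempts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import unbiased_he
from .genotype_io import MISSING, GenotypeMatrix

MODELS = ("IAM", "SMM", "TPM")


# ---------------------------------------------------------------------------
# coalescent simulation conditioned on allele count
# ---------------------------------------------------------------------------

def _geometric_p_for_variance(variance: float) -> float:
    """Parameter p of a geometric step-magnitude law (support 1, 2, ...)
    with the requested variance: (1-p)/p^2 = variance."""
    if variance <= 0:
        return 1.0
    return float((-1.0 + np.sqrt(1.0 + 4.0 * variance)) / (2.0 * variance))


def _iam_urn_counts(n: int, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Hoppe-urn (Chinese-restaurant) draw of IAM allele counts: the i-th
    gene founds a new allele with probability theta/(theta + i), else
    copies a uniformly chosen earlier gene.  Exact for the infinite-alleles
    coalescent and O(n) regardless of theta."""
    new = rng.random(n) * (theta + np.arange(n)) < theta
    parent = (rng.random(n) * np.arange(n)).astype(np.int64)
    allele = np.empty(n, dtype=np.int64)
    nxt = 0
    for i in range(n):
        if new[i] or i == 0:
            allele[i] = nxt
            nxt += 1
        else:
            allele[i] = allele[parent[i]]
    return np.bincount(allele, minlength=nxt)[:nxt]


def _simulate_allele_counts(n: int, theta: float, model: str,
                            rng: np.random.Generator,
                            p_smm: float, geom_p: float) -> np.ndarray:
    """One coalescent replicate; returns allele copy counts (sums to n).

    IAM uses the exact Hoppe urn.  Stepwise models (SMM/TPM) simulate the
    backward coalescent event chain without times (with j lineages the
    most recent event is a mutation w.p. theta/(theta + j - 1)); signed
    steps are accumulated per genealogy node and summed root-to-leaf.
    """
    if model == "IAM":
        return _iam_urn_counts(n, theta, rng)
    parent = np.full(2 * n, -1, dtype=np.int64)
    acc = np.zeros(2 * n)            # summed steps per node
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        j = len(active)
        if rng.random() < theta / (theta + j - 1):
            node = active[int(rng.integers(j))]
            if model == "SMM" or rng.random() < p_smm:
                step = 1.0
            else:
                step = float(rng.geometric(geom_p))
            acc[node] += step if rng.random() < 0.5 else -step
        else:
            i2 = int(rng.integers(j - 1))
            a = active.pop()
            parent[a] = nxt
            parent[active[i2]] = nxt
            active[i2] = nxt
            nxt += 1
    # resolve states top-down: parents always have larger node ids
    total = acc[:nxt].copy()
    for node in range(nxt - 2, -1, -1):
        total[node] += total[parent[node]]
    _, counts = np.unique(total[:n], return_counts=True)
    return counts


def _ewens_theta_guess(k: int, n: int) -> float:
    """Theta with Ewens expected allele count k in a sample of n copies."""
    i = np.arange(n, dtype=float)
    f = lambda t: np.sum(t / (t + i)) - k
    lo, hi = 1e-6, 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return float(np.sqrt(lo * hi))


@dataclass
class HeqDistribution:
    """Simulated equilibrium heterozygosity for one locus, conditioned on
    exactly k alleles in n gene copies."""

    locus: str
    k: int
    n: int
    model: str
    he_observed: float | None
    heq: np.ndarray
    theta_final: float

    @property
    def mean_heq(self) -> float:
        return float(self.heq.mean())

    @property
    def p_excess_null(self) -> float:
        """Null probability that an equilibrium draw exceeds the mean Heq."""
        return float(np.mean(self.heq > self.mean_heq))

    @property
    def excess(self) -> bool | None:
        if self.he_observed is None:
            return None
        return bool(self.he_observed > self.mean_heq)


def simulate_heq(k: int, n: int, model: str = "SMM", reps: int = 1000,
                 tpm_variance: float = 36.0, tpm_p_smm: float = 0.0,
                 seed=None, locus: str = "", he_observed: float | None = None,
                 max_attempt_factor: int = 500) -> HeqDistribution:
    """Distribution of equilibrium heterozygosity given k alleles among n
    gene copies, under IAM, SMM or TPM.

    Each accepted replicate has exactly k distinct alleles; theta is
    adapted multiplicatively between attempts (Cornuet-Luikart style
    conditioning by rejection).  Heq per replicate is Nei's unbiased
    heterozygosity of the simulated allele counts.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if not (2 <= k <= n):
        raise ValueError(f"need 2 <= k <= n (got k={k}, n={n})")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    p_smm = 1.0 if model == "SMM" else float(tpm_p_smm)
    geom_p = _geometric_p_for_variance(tpm_variance)
    theta = _ewens_theta_guess(k, n)
    if model != "IAM":
        theta *= 1.5  # stepwise homoplasy needs more mutations per allele
    out = np.empty(reps)
    got = 0
    attempts = 0
    max_attempts = max_attempt_factor * reps
    while got < reps:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"conditioning on k={k} alleles failed after {attempts} attempts"
            )
        counts = _simulate_allele_counts(n, theta, model, rng, p_smm, geom_p)
        k_sim = len(counts)
        if k_sim == k:
            out[got] = unbiased_he(counts)
            got += 1
        theta *= float(np.exp(0.04 * np.clip(k - k_sim, -5, 5)))
        theta = float(np.clip(theta, 1e-4, 1e5))
    return HeqDistribution(locus, k, n, model, he_observed, out, theta)


# ---------------------------------------------------------------------------
# sign test
# ---------------------------------------------------------------------------

def _poisson_binomial_pmf(ps: np.ndarray) -> np.ndarray:
    """PMF of a sum of independent Bernoulli(p_l) by dynamic programming."""
    pmf = np.array([1.0])
    for p in ps:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


@dataclass
class SignTestResult:
    model: str
    n_loci: int
    n_excess: int
    n_deficiency: int
    expected_excess: float
    #: one-tailed exact probability of the observed deviation direction
    #: (the conventional sign-test report)
    p_value: float
    #: doubled-tail two-sided companion
    p_two_tailed: float
    per_locus: pd.DataFrame
    distributions: list[HeqDistribution] = field(repr=False, default_factory=list)


def sign_test(gm: GenotypeMatrix, model: str = "SMM", reps: int = 1000,
              tpm_variance: float = 36.0, tpm_p_smm: float = 0.0,
              seed=None) -> SignTestResult:
    """Heterozygosity-excess sign test across loci under one mutation model.

    A locus is in *excess* when its observed unbiased heterozygosity lies
    above the mean of its conditioned equilibrium distribution.  The
    expected number of excess loci is the sum over loci of the null excess
    probabilities; the reported p is the exact Poisson-binomial tail
    probability of the excess count in the observed deviation direction
    (one-tailed, the conventional sign-test report); a doubled-tail
    two-sided value is also returned.  Monomorphic loci are excluded with
    a warning.
    """
    rng = np.random.default_rng(seed)
    dists: list[HeqDistribution] = []
    rows = []
    for l, loc in enumerate(gm.loci):
        col = gm.calls[:, l, :].ravel()
        col = col[col != MISSING]
        vals, counts = np.unique(col, return_counts=True)
        if len(vals) < 2:
            warnings.warn(f"locus {loc.name!r} monomorphic; excluded from sign test")
            continue
        he_obs = unbiased_he(counts)
        d = simulate_heq(len(vals), int(col.size), model, reps,
                         tpm_variance, tpm_p_smm,
                         seed=rng.integers(2**31), locus=loc.name,
                         he_observed=he_obs)
        dists.append(d)
        rows.append(dict(locus=loc.name, k=d.k, n=d.n, He=he_obs,
                         mean_Heq=d.mean_heq, sd_Heq=float(d.heq.std(ddof=1)),
                         excess=d.excess, p_excess_null=d.p_excess_null))
    if len(rows) < 5:
        warnings.warn("fewer than 5 polymorphic loci; sign test is weak")
    per_locus = pd.DataFrame(rows)
    if per_locus.empty:
        raise ValueError("no polymorphic loci")
    n_excess = int(per_locus.excess.sum())
    ps = per_locus.p_excess_null.to_numpy()
    expected = float(ps.sum())
    pmf = _poisson_binomial_pmf(ps)
    p_hi = float(pmf[n_excess:].sum())
    p_lo = float(pmf[: n_excess + 1].sum())
    p_one = p_hi if n_excess >= expected else p_lo
    p_two = min(1.0, 2.0 * min(p_hi, p_lo))
    return SignTestResult(model, len(per_locus), n_excess,
                          len(per_locus) - n_excess, expected, p_one, p_two,
                          per_locus, dists)


# ---------------------------------------------------------------------------
# mode-shift and Garza-Williamson
# ---------------------------------------------------------------------------

@dataclass
class ModeShiftResult:
    classification: str          # "L-shaped" or "shifted"
    class_edges: np.ndarray
    class_counts: np.ndarray


def mode_shift(gm: GenotypeMatrix) -> ModeShiftResult:
    """Allele-frequency mode-shift test on pooled population frequencies.

    Alleles are binned into ten frequency classes (0-0.1, ..., 0.9-1.0).
    The distribution is "L-shaped" (no bottleneck signal) iff the lowest
    class holds strictly the most alleles; otherwise "shifted".
    """
    freqs = []
    aft = gm.allele_frequencies()
    for locus in aft.locus_names:
        freqs.extend(aft.freqs[locus].values())
    freqs = np.asarray(freqs)
    edges = np.linspace(0, 1, 11)
    counts, _ = np.histogram(freqs, bins=edges)
    cls = "L-shaped" if counts[0] > counts[1:].max() else "shifted"
    return ModeShiftResult(cls, edges, counts)


def garza_williamson(gm: GenotypeMatrix, plus_one: bool = True) -> pd.DataFrame:
    """Garza-Williamson M per locus: allele count over allelic range.

    The range r is (max - min allele size) in repeat units (fragment-size
    span divided by the locus motif length).  With ``plus_one`` (default,
    ARLEQUIN convention) M = k / (r + 1), which is 1 for a locus occupying
    every step of its range; without it M = k / r (undefined for
    monomorphic loci).  Means below the 0.68 critical value indicate a
    historical bottleneck.
    """
    rows = []
    for l, loc in enumerate(gm.loci):
        col = gm.calls[:, l, :].ravel()
        col = col[col != MISSING]
        if col.size == 0:
            continue
        vals = np.unique(col)
        r = (vals.max() - vals.min()) / loc.repeat_motif_length
        if plus_one:
            m = len(vals) / (r + 1.0)
        else:
            m = np.nan if r == 0 else len(vals) / r
        rows.append(dict(locus=loc.name, k=len(vals), r=float(r), M=float(m)))
    df = pd.DataFrame(rows)
    df.attrs["mean_M"] = float(df.M.mean())
    df.attrs["below_critical_0.68"] = bool(df.M.mean() < 0.68)
    return df


@dataclass
class BottleneckReport:
    """Sign tests under the requested models plus mode-shift and M."""

    sign_tests: dict[str, SignTestResult]
    mode_shift: ModeShiftResult
    gw: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        rows = [
            dict(model=m, n_loci=r.n_loci, n_excess=r.n_excess,
                 n_deficiency=r.n_deficiency,
                 expected_excess=r.expected_excess, p=r.p_value)
            for m, r in self.sign_tests.items()
        ]
        return pd.DataFrame(rows)


def bottleneck_report(gm: GenotypeMatrix, models=MODELS, reps: int = 1000,
                      tpm_variance: float = 36.0, tpm_p_smm: float = 0.0,
                      seed=None) -> BottleneckReport:
    rng = np.random.default_rng(seed)
    tests = {
        m: sign_test(gm, m, reps, tpm_variance, tpm_p_smm,
                     seed=rng.integers(2**31))
        for m in models
    }
    return BottleneckReport(tests, mode_shift(gm), garza_williamson(gm))
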