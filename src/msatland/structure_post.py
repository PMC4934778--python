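"""Post-processing of external admixture-clustering output.

The Bayesian clustering itself (STRUCTURE-style MCMC) is consumed as
input, not run here: this module takes per-individual membership
coefficient (Q) matrices and per-K log-likelihood tables and provides

* the Evanno delta-K criterion for choosing the number of clusters,
* hybrid filtering by membership threshold (e.g. keep q_wolf >= 0.98),
* hard group assignment by highest membership coefficient,
* principal component analysis of genotypes on centred (not scaled)
  allele dosages.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass
class QMatrix:
    """Per-individual admixture membership coefficients across K clusters."""

    individual_ids: list[str]
    q: np.ndarray  # (n, K)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.individual_ids):
            raise ValueError("q must be n x K")
        if (self.q < -1e-9).any() or (self.q > 1 + 1e-9).any():
            raise ValueError("membership coefficients must lie in [0, 1]")
        if not np.allclose(self.q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each q row must sum to 1 (tol 1e-6)")

    @property
    def n(self) -> int:
        return self.q.shape[0]

    @property
    def k(self) -> int:
        return self.q.shape[1]

    @classmethod
    def from_csv(cls, path) -> "QMatrix":
        """Plain CSV dialect: an `id` column plus one column per cluster."""
        df = pd.read_csv(path)
        ids = [str(v) for v in df.iloc[:, 0]]
        return cls(ids, df.iloc[:, 1:].to_numpy(dtype=float))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.q, columns=[f"Q{j + 1}" for j in range(self.k)])
        df.insert(0, "id", self.individual_ids)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# native clustering-program output
# ---------------------------------------------------------------------------

_Q_LINE = re.compile(
    r"^\s*\d+\s+(\S+)\s+\(\d+\)\s*(?::\s*)?.*?:\s*((?:[01]\.\d+\s*)+)$"
)


def read_structure_q(path) -> QMatrix:
    """Parse the inferred-ancestry block of a clustering-program results
    file (rows like ``  1 ind_1  (0)  1 :  0.981 0.019``)."""
    ids, rows = [], []
    in_block = False
    for line in Path(path).read_text().splitlines():
        if "Inferred ancestry of individuals" in line:
            in_block = True
            continue
        if in_block:
            m = _Q_LINE.match(line)
            if m:
                ids.append(m.group(1))
                rows.append([float(x) for x in m.group(2).split()])
            elif rows and line.strip() == "":
                break
    if not rows:
        raise ValueError(f"{path}: no inferred-ancestry rows found")
    return QMatrix(ids, np.array(rows))


def read_structure_likelihoods(paths_or_rows) -> "LikelihoodTable":
    """Build a likelihood table either from (K, replicate, lnP) rows or
    from native result files containing 'Estimated Ln Prob of Data'."""
    rows = []
    for item in paths_or_rows:
        if isinstance(item, (tuple, list)) and len(item) == 3:
            rows.append(tuple(item))
            continue
        text = Path(item).read_text()
        k = re.search(r"(\d+)\s+populations assumed", text)
        lnp = re.search(r"Estimated Ln Prob of Data\s*=\s*(-?\d+\.?\d*)", text)
        if not (k and lnp):
            raise ValueError(f"{item}: could not find K / Ln Prob of Data")
        rows.append((int(k.group(1)), len(rows), float(lnp.group(1))))
    return LikelihoodTable(pd.DataFrame(rows, columns=["K", "replicate", "lnP"]))


@dataclass
class LikelihoodTable:
    """Rows of (K, replicate, log-probability of data)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"K", "replicate", "lnP"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"likelihood table needs columns {sorted(need)}")

    @classmethod
    def from_csv(cls, path) -> "LikelihoodTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def evanno_delta_k(lt: LikelihoodTable) -> pd.DataFrame:
    """Evanno et al. delta-K table.

    For each interior K with replicates at K-1, K and K+1:
    deltaK = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)).
    The result frame (columns K, mean_lnP, sd_lnP, delta_K) carries the
    argmax in ``df.attrs['suggested_K']``.  Zero sd leaves delta-K missing
    at that K.  Invariant to adding a constant to all log-likelihoods.
    """
    g = lt.table.groupby("K")["lnP"]
    ks = sorted(g.groups)
    mean = g.mean()
    sd = g.std(ddof=1)
    rows = []
    for K in ks:
        dk = np.nan
        if (K - 1 in mean.index) and (K + 1 in mean.index):
            second = abs(mean[K + 1] - 2 * mean[K] + mean[K - 1])
            if sd[K] and sd[K] > 0:
                dk = second / sd[K]
        rows.append(dict(K=K, mean_lnP=mean[K], sd_lnP=sd[K], delta_K=dk))
    df = pd.DataFrame(rows)
    valid = df.dropna(subset=["delta_K"])
    df.attrs["suggested_K"] = (
        int(valid.loc[valid.delta_K.idxmax(), "K"]) if len(valid) else None
    )
    return df


@dataclass
class HybridFilterResult:
    kept_ids: list[str]
    removed_ids: list[str]
    mean_q_kept: float
    ci90_q_kept: tuple[float, float]  # percentile CI


def filter_hybrids(q: QMatrix, focal_cluster: int,
                   threshold: float = 0.98) -> HybridFilterResult:
    """Exclude putative hybrids: individuals whose membership in the focal
    cluster falls below ``threshold`` (default 0.98, the conservative
    canid purity threshold).  The summary reports the mean and the 90%
    percentile interval of the kept members' focal-cluster q."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if not (0 <= focal_cluster < q.k):
        raise IndexError(f"focal cluster {focal_cluster} out of range")
    qf = q.q[:, focal_cluster]
    keep = qf >= threshold
    kept = [i for i, k in zip(q.individual_ids, keep) if k]
    removed = [i for i, k in zip(q.individual_ids, keep) if not k]
    if kept:
        vals = qf[keep]
        ci = (float(np.percentile(vals, 5)), float(np.percentile(vals, 95)))
        mean = float(vals.mean())
    else:
        ci, mean = (np.nan, np.nan), np.nan
    return HybridFilterResult(kept, removed, mean, ci)


def assign_groups(q: QMatrix) -> tuple[list[int], pd.DataFrame]:
    """Hard labels by highest membership coefficient (0-based cluster
    index; ties broken toward the lowest index with a warning), plus the
    per-group mean q of its members."""
    labels = []
    for row in q.q:
        top = np.flatnonzero(row == row.max())
        if len(top) > 1:
            warnings.warn("tied membership coefficients; lowest cluster index used")
        labels.append(int(top[0]))
    labels_arr = np.asarray(labels)
    rows = []
    for j in range(q.k):
        members = labels_arr == j
        rows.append(dict(cluster=j, n=int(members.sum()),
                         mean_q=float(q.q[members, j].mean()) if members.any() else np.nan))
    return labels, pd.DataFrame(rows)


def pca_genotypes(gm: GenotypeMatrix, q: QMatrix | None = None,
                  min_q: float | None = None, n_components: int = 10):
    """PCA of individual genotypes on the allele-dosage matrix.

    Each allele at each locus contributes a column of per-individual allele
    counts divided by 2 (individual allele frequencies); columns are
    centred but not variance-scaled; constant columns are dropped.  When a
    Q matrix and ``min_q`` are given, only individuals whose top membership
    reaches ``min_q`` enter the analysis.

    Returns (ids, scores, eigenvalues).
    """
    idx = np.arange(gm.n)
    if q is not None and min_q is not None:
        top = q.q.max(axis=1)
        pos = {iid: i for i, iid in enumerate(q.individual_ids)}
        keep = [i for i in idx
                if gm.individual_ids[i] in pos and top[pos[gm.individual_ids[i]]] > min_q]
        idx = np.asarray(keep)
    if idx.size < 3:
        raise ValueError("need >=3 individuals for PCA")
    cols = []
    for l in range(gm.n_loci):
        calls_l = gm.calls[idx, l, :]
        alleles = np.unique(calls_l[calls_l != MISSING])
        for a in alleles:
            dos = (calls_l == a).sum(axis=1) / 2.0
            miss = calls_l[:, 0] == MISSING
            if miss.any():  # mean-impute missing genotypes
                dos = dos.astype(float)
                dos[miss] = dos[~miss].mean() if (~miss).any() else 0.0
            cols.append(dos)
    X = np.column_stack(cols)
    X = X - X.mean(axis=0, keepdims=True)
    X = X[:, X.std(axis=0) > 0]
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (X.shape[0] - 1)
    ncomp = min(n_components, len(s))
    scores = u[:, :ncomp] * s[:ncomp]
    ids = [gm.individual_ids[i] for i in idx]
    return ids, scores, eig[:ncomp]
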