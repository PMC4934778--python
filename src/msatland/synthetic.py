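"""Spatially explicit microsatellite data simulator with known truth.

Emulates the sampling design of a mainland-plus-islands carnivore study:
~170 diploid individuals at 15 dinucleotide loci, four genetic groups of
moderate divergence (Balding-Nichols F per group around a shared ancestral
frequency set), one island group founded by a handful of colonists
(founder effect: reduced heterozygosity), spatial clustering of groups on
a 250 x 150 km landscape (which yields global isolation by distance), and
optional planted wolf-dog-like hybrids with intermediate ancestry for
filter testing.

Also provides a pure isolation-by-distance cline generator (for spatial
null calibration), a panmictic generator, and a discrete-generation
Wright-Fisher forward simulator with IAM/SMM/TPM mutation for bottleneck
and effective-size test harnesses.  Everything is bit-reproducible under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix, Locus
from .structure_post import QMatrix

_LADDER_START = 100  # bp of the shortest allele


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Generator parameters; defaults emulate the study design."""

    n_individuals: int = 168
    n_loci: int = 15
    n_alleles: int = 8
    #: Dirichlet concentration of ancestral allele frequencies; 0.6 gives
    #: the skewed frequency spectra typical of moderately diverse
    #: microsatellite panels (mean He ~0.67, observed Na ~6-7 of 8).
    allele_conc: float = 0.6
    motif_length: int = 2
    k_groups: int = 4
    #: Balding-Nichols divergence per group; pairwise theta between groups
    #: i and j realises near (F_i + F_j) / 2, spanning ~0.06-0.12.
    group_f: tuple = (0.05, 0.08, 0.10, 0.12)
    group_weights: tuple = (0.18, 0.28, 0.28, 0.26)
    #: km; group 0 sits on the western island block of the 250 x 150 box
    group_centers: tuple = ((35.0, 45.0), (110.0, 90.0), (170.0, 100.0), (200.0, 40.0))
    dispersal_km: float = 28.0
    island_group: int = 0
    island_box: tuple = (5.0, 10.0, 65.0, 80.0)  # x0, y0, x1, y1
    #: one breeding pair: island recolonization by a single pack
    founder_count: int = 2
    n_hybrids: int = 0
    hybrid_q_range: tuple = (0.6, 0.9)
    dog_f: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_groups != len(self.group_f) or self.k_groups != len(self.group_centers):
            raise ValueError("group_f / group_centers must match k_groups")
        if self.founder_count < 2:
            raise ValueError("founder_count must be >= 2")
        gsize = self._group_sizes()
        if self.founder_count > gsize[self.island_group]:
            raise ValueError("founders exceed island group size")

    def _group_sizes(self) -> np.ndarray:
        w = np.asarray(self.group_weights, dtype=float)
        w = w / w.sum()
        n_pure = self.n_individuals - self.n_hybrids
        sizes = np.floor(w * n_pure).astype(int)
        sizes[0] += n_pure - sizes.sum()
        return sizes


@dataclass
class SyntheticTruth:
    """Ground truth retained for parameter-recovery tests."""

    config: SimConfig
    group_labels: list[str]
    ancestral_freqs: np.ndarray      # (L, A)
    group_freqs: np.ndarray          # (K, L, A)
    dog_freqs: np.ndarray | None
    hybrid_ids: list[str]
    island_ids: list[str]
    founder_pool_freqs: np.ndarray | None = None
    ne_trajectory: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# frequency machinery
# ---------------------------------------------------------------------------

def _ancestral_freqs(rng, n_loci, n_alleles, conc: float = 0.6) -> np.ndarray:
    """Dirichlet broken-stick frequencies over a stepwise allele ladder."""
    return rng.dirichlet(np.full(n_alleles, conc), size=n_loci)


def balding_nichols(rng, p_anc: np.ndarray, F: float) -> np.ndarray:
    """Group frequencies given ancestral ones: Dirichlet(p (1-F)/F)."""
    if F <= 0:
        return p_anc.copy()
    out = np.empty_like(p_anc)
    scale = (1.0 - F) / F
    for l in range(p_anc.shape[0]):
        alpha = np.maximum(p_anc[l] * scale, 1e-6)
        out[l] = rng.dirichlet(alpha)
    return out


def _draw_genotypes(rng, freqs: np.ndarray, n: int) -> np.ndarray:
    """(n, L, 2) allele-index draws under HWE from (L, A) frequencies."""
    L, A = freqs.shape
    out = np.empty((n, L, 2), dtype=np.int64)
    for l in range(L):
        out[:, l, :] = rng.choice(A, size=(n, 2), p=freqs[l])
    return out


def _ladder(cfg_motif: int, n_alleles: int) -> np.ndarray:
    return _LADDER_START + cfg_motif * np.arange(n_alleles)


def _to_matrix(idx_calls: np.ndarray, ids, loci, coords) -> GenotypeMatrix:
    ladder = np.array([_LADDER_START + loci[0].repeat_motif_length * a
                       for a in range(int(idx_calls.max()) + 1)])
    calls = ladder[idx_calls]
    return GenotypeMatrix(list(ids), list(loci), calls, coordinates=coords)


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, QMatrix, SyntheticTruth]:
    """Generate the landscape dataset.

    Returns the genotype matrix (ids, calls, coordinates only - truth
    labels travel exclusively through the returned ``QMatrix`` of true
    ancestry proportions and the :class:`SyntheticTruth`).  Ancestry
    columns are the K groups plus, when hybrids are planted, a final
    dog column.
    """
    rng = np.random.default_rng(cfg.seed)
    L, A, K = cfg.n_loci, cfg.n_alleles, cfg.k_groups
    loci = [Locus(f"L{l + 1:02d}", cfg.motif_length) for l in range(L)]
    ladder = _ladder(cfg.motif_length, A)

    p_anc = _ancestral_freqs(rng, L, A, cfg.allele_conc)
    group_freqs = np.stack([balding_nichols(rng, p_anc, f) for f in cfg.group_f])
    dog_freqs = None
    if cfg.n_hybrids > 0:
        dog_anc = _ancestral_freqs(rng, L, A, cfg.allele_conc)
        dog_freqs = balding_nichols(rng, dog_anc, cfg.dog_f)

    sizes = cfg._group_sizes()
    ids, labels, coords_list, call_blocks = [], [], [], []
    q_rows = []
    island_ids: list[str] = []
    founder_pool = None
    n_q_cols = K + (1 if cfg.n_hybrids > 0 else 0)

    counter = 0
    for g in range(K):
        ng = int(sizes[g])
        if ng == 0:
            continue
        if g == cfg.island_group and cfg.founder_count < 2 * ng:
            # founder effect: the island group descends from a small
            # founder pool drawn from its source-group frequencies
            founders = _draw_genotypes(rng, group_freqs[g], cfg.founder_count)
            pool = founders.reshape(-1, L, 2).transpose(1, 0, 2).reshape(L, -1)
            founder_pool = np.stack([
                np.bincount(pool[l], minlength=A) / pool.shape[1] for l in range(L)
            ])
            calls = _draw_genotypes(rng, founder_pool, ng)
        else:
            calls = _draw_genotypes(rng, group_freqs[g], ng)
        cx, cy = cfg.group_centers[g]
        pos = rng.normal([cx, cy], cfg.dispersal_km, size=(ng, 2))
        if g == cfg.island_group:
            x0, y0, x1, y1 = cfg.island_box
            pos[:, 0] = np.clip(pos[:, 0], x0, x1)
            pos[:, 1] = np.clip(pos[:, 1], y0, y1)
        for _ in range(ng):
            counter += 1
            iid = f"ind_{counter:03d}"
            ids.append(iid)
            labels.append(f"G{g + 1}")
            if g == cfg.island_group:
                island_ids.append(iid)
        coords_list.append(pos)
        call_blocks.append(calls)
        q = np.zeros((ng, n_q_cols))
        q[:, g] = 1.0
        q_rows.append(q)

    hybrid_ids: list[str] = []
    for h in range(cfg.n_hybrids):
        counter += 1
        iid = f"hyb_{counter:03d}"
        hybrid_ids.append(iid)
        ids.append(iid)
        g = int(rng.integers(1, K))  # hybrids occur on the mainland
        labels.append("HYB")
        qw = rng.uniform(*cfg.hybrid_q_range)
        mix = qw * group_freqs[g] + (1 - qw) * dog_freqs
        call_blocks.append(_draw_genotypes(rng, mix, 1))
        cx, cy = cfg.group_centers[g]
        coords_list.append(rng.normal([cx, cy], cfg.dispersal_km, size=(1, 2)))
        q = np.zeros((1, n_q_cols))
        q[0, g] = qw
        q[0, -1] = 1 - qw
        q_rows.append(q)

    idx_calls = np.concatenate(call_blocks, axis=0)
    coords = np.concatenate(coords_list, axis=0)
    gm = GenotypeMatrix(ids, loci, ladder[idx_calls], coordinates=coords)
    q_true = QMatrix(list(ids), np.concatenate(q_rows, axis=0))
    truth = SyntheticTruth(cfg, labels, p_anc, group_freqs, dog_freqs,
                           hybrid_ids, island_ids, founder_pool)
    return gm, q_true, truth


def generate_panmictic(n: int, n_loci: int = 15, n_alleles: int = 8,
                       motif_length: int = 2, seed=None,
                       coords_box: tuple = (0.0, 0.0, 250.0, 150.0)) -> GenotypeMatrix:
    """One random-mating population, individuals scattered uniformly: the
    spatial and structural null."""
    rng = np.random.default_rng(seed)
    p = _ancestral_freqs(rng, n_loci, n_alleles)
    calls = _draw_genotypes(rng, p, n)
    loci = [Locus(f"L{l + 1:02d}", motif_length) for l in range(n_loci)]
    x0, y0, x1, y1 = coords_box
    coords = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
    ladder = _ladder(motif_length, n_alleles)
    return GenotypeMatrix([f"ind_{i + 1:03d}" for i in range(n)], loci,
                          ladder[calls], coordinates=coords)


def generate_ibd_cline(n: int, n_loci: int = 15, n_alleles: int = 8,
                       cline_f: float = 0.15, motif_length: int = 2,
                       seed=None,
                       coords_box: tuple = (0.0, 0.0, 250.0, 150.0)) -> GenotypeMatrix:
    """Smooth isolation-by-distance landscape without discrete clusters.

    Two divergent anchor frequency sets (Balding-Nichols at ``cline_f``)
    sit at the western and eastern edges; each individual draws its
    genotype from the linear mixture given by its position along the
    diagonal.  Genetic distance then increases smoothly with geographic
    distance - the IBD-only null for DResD calibration.
    """
    rng = np.random.default_rng(seed)
    p_anc = _ancestral_freqs(rng, n_loci, n_alleles)
    west = balding_nichols(rng, p_anc, cline_f)
    east = balding_nichols(rng, p_anc, cline_f)
    x0, y0, x1, y1 = coords_box
    coords = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
    w = ((coords[:, 0] - x0) / (x1 - x0) + (coords[:, 1] - y0) / (y1 - y0)) / 2.0
    calls = np.empty((n, n_loci, 2), dtype=np.int64)
    for i in range(n):
        mix = (1 - w[i]) * west + w[i] * east
        calls[i] = _draw_genotypes(rng, mix, 1)[0]
    loci = [Locus(f"L{l + 1:02d}", motif_length) for l in range(n_loci)]
    ladder = _ladder(motif_length, n_alleles)
    return GenotypeMatrix([f"ind_{i + 1:03d}" for i in range(n)], loci,
                          ladder[calls], coordinates=coords)


# ---------------------------------------------------------------------------
# forward Wright-Fisher simulator
# ---------------------------------------------------------------------------

def _mutate(pop: np.ndarray, mu: float, model: str, rng,
            tpm_p_smm: float, geom_p: float) -> np.ndarray:
    """Apply one generation of mutation to an (L, 2N) integer-state pool.

    Stepwise states are repeat counts (can drift over the ladder); IAM
    states are fresh labels drawn from a large namespace.
    """
    hit = rng.random(pop.shape) < mu
    n_hit = int(hit.sum())
    if n_hit == 0:
        return pop
    if model == "IAM":
        pop[hit] = rng.integers(10**6, 10**9, size=n_hit)
    else:
        if model == "SMM":
            mag = np.ones(n_hit, dtype=np.int64)
        else:
            single = rng.random(n_hit) < tpm_p_smm
            mag = np.where(single, 1, rng.geometric(geom_p, size=n_hit))
        sign = np.where(rng.random(n_hit) < 0.5, 1, -1)
        pop[hit] = pop[hit] + sign * mag
    return pop


def forward_bottleneck(ne_schedule, n_loci: int = 15, theta: float = 3.0,
                       model: str = "SMM", tpm_variance: float = 36.0,
                       tpm_p_smm: float = 0.0, sample_at=None,
                       sample_size: int = 50, burn_in: int | None = None,
                       motif_length: int = 2, init_freqs: np.ndarray | None = None,
                       mu: float | None = None, seed=None,
                       ) -> list[tuple[int, GenotypeMatrix]]:
    """Discrete-generation Wright-Fisher propagation of multilocus
    genotypes with the configured mutation model.

    ``ne_schedule`` is a list of (generation, N) change points (generation
    0 must be present); ``sample_at`` lists the generations at which a
    GenotypeMatrix of ``sample_size`` diploids is emitted (default: the
    last scheduled generation).  ``theta`` = 4 N0 mu fixes the mutation
    rate from the initial size.  Burn-in (default 10 N0 generations) runs
    at N0 before generation 0.
    """
    from .genotype_io import GenotypeMatrix as GM

    sched = sorted(ne_schedule)
    if not sched or sched[0][0] != 0:
        raise ValueError("ne_schedule must start at generation 0")
    rng = np.random.default_rng(seed)
    n0 = sched[0][1]
    geom_p = 1.0
    if model == "TPM":
        v = max(tpm_variance, 1e-9)
        geom_p = float((-1.0 + np.sqrt(1.0 + 4.0 * v)) / (2.0 * v))
    if mu is None:
        mu = theta / (4.0 * n0)
    last_gen = sched[-1][0]
    sample_at = sorted(sample_at) if sample_at else [last_gen]
    horizon = max(last_gen, sample_at[-1])

    def next_generation(pop: np.ndarray, n_new: int) -> np.ndarray:
        # diploid pedigree: each offspring draws two parents and inherits
        # one random allele per locus from each; unlinked loci stay
        # correlated through shared parentage (the LD drift signal)
        n_par = pop.shape[0]
        mothers = rng.integers(0, n_par, size=n_new)
        fathers = rng.integers(0, n_par, size=n_new)
        child = np.empty((n_new, pop.shape[1], 2), dtype=np.int64)
        pick_m = rng.integers(0, 2, size=(n_new, pop.shape[1]))
        pick_f = rng.integers(0, 2, size=(n_new, pop.shape[1]))
        child[:, :, 0] = np.take_along_axis(pop[mothers], pick_m[:, :, None], 2)[:, :, 0]
        child[:, :, 1] = np.take_along_axis(pop[fathers], pick_f[:, :, None], 2)[:, :, 0]
        flat = child.reshape(n_new, -1).T          # (L*2, n) view for mutation
        flat = _mutate(flat, mu, model, rng, tpm_p_smm, geom_p)
        return flat.T.reshape(n_new, pop.shape[1], 2)

    if init_freqs is not None:
        # start from supplied allele frequencies (ladder states), in HWE
        # and linkage equilibrium: drift LD then accumulates forward
        A = init_freqs.shape[1]
        pop = np.empty((n0, n_loci, 2), dtype=np.int64)
        for l in range(n_loci):
            pop[:, l, :] = 120 + rng.choice(A, size=(n0, 2), p=init_freqs[l])
    else:
        pop = np.full((n0, n_loci, 2), 120, dtype=np.int64)  # repeat state
    bi = burn_in if burn_in is not None else (10 * n0 if init_freqs is None else 0)
    for _ in range(bi):
        pop = next_generation(pop, n0)

    out = []
    sizes = dict(sched)
    current_n = n0
    sample_set = set(sample_at)
    for gen in range(0, horizon + 1):
        if gen in sizes:
            current_n = sizes[gen]
        if gen > 0:
            pop = next_generation(pop, current_n)
        if gen in sample_set:
            s = min(sample_size, pop.shape[0])
            rows_s = rng.choice(pop.shape[0], size=s, replace=False)
            calls = pop[rows_s].copy()             # (s, L, 2)
            # map states locus-wise onto a positive fragment-size ladder:
            # stepwise states keep their spacing (range is meaningful),
            # IAM labels are ranked (range is arbitrary under IAM)
            for l in range(n_loci):
                if model == "IAM":
                    _, inv = np.unique(calls[:, l, :], return_inverse=True)
                    calls[:, l, :] = inv.reshape(s, 2)
                calls[:, l, :] -= calls[:, l, :].min()
            calls = calls * motif_length + _LADDER_START
            gm = GM([f"g{gen}_ind{i + 1}" for i in range(s)],
                    [Locus(f"L{l + 1:02d}", motif_length) for l in range(n_loci)],
                    np.sort(calls, axis=2))
            out.append((gen, gm))
    return out
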