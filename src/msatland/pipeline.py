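"""End-to-end orchestration: ingest -> hybrid filter -> diversity ->
bottleneck -> Ne -> exclusion -> structure post-processing -> spatial
surfaces, with deterministic seeding and a run manifest.

A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(seed).spawn``, so any stage can be re-run in
isolation with its recorded seed.  Every output file name is listed in
``manifest.json`` together with the configuration echo, its hash, and the
per-stage status; a failing stage aborts the stages downstream of it but
partial outputs are kept and the failure is recorded with a FAILED marker.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import assignment, bottleneck, diversity, dresd, ne_ld, structure_post
from .genotype_io import GenotypeMatrix, exclude_loci, read_genepop, \
    read_sample_table, write_sample_table
from .structure_post import LikelihoodTable, QMatrix

STAGES = ("ingest", "hybrid_filter", "exclude_loci", "diversity",
          "bottleneck", "ne", "exclusion", "structure", "spatial")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults are the study settings."""

    genotypes: str | None = None            # GenePop path (or use table_*)
    sample_table: str | None = None
    q_matrix: str | None = None             # CSV Q matrix
    likelihood_table: str | None = None     # CSV (K, replicate, lnP)
    out_dir: str = "msatland_out"
    locus_exclusions: list = field(default_factory=list)
    hybrid_threshold: float = 0.98
    focal_cluster: int = 0
    dresd_band: tuple = (17.0, 33.0)
    n_boot_residual: int = 499
    n_boot_heterozygosity: int = 499
    n_boot_membership: int = 199
    ldne_min_freq: float = 0.02
    ldne_mating: str = "monogamy"
    bottleneck_reps: int = 1000
    tpm_variance: float = 36.0
    tpm_p_smm: float = 0.0
    hwe_reps: int = 10_000
    ld_reps: int = 1000
    exclusion_sims: int = 10_000
    exclusion_alpha: float = 0.01
    alpha: float = 0.05
    fst_permutations: int = 199
    grid_cell_km: float = 2.0
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0] % 2**31)
            for name, c in zip(STAGES, children)}


def run_pipeline(cfg: PipelineConfig, gm: GenotypeMatrix | None = None,
                 q: QMatrix | None = None,
                 lt: LikelihoodTable | None = None) -> dict:
    """Run all applicable stages; returns (and writes) the run manifest.

    Inputs may be given as file paths in the config or directly as
    in-memory objects (``gm``, ``q``, ``lt``); in-memory objects win.
    Stages whose inputs are absent (no Q matrix, no coordinates, ...) are
    marked "skipped".  Input files are never modified.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "artifacts": [],
        "log": [],
    }
    log = manifest["log"].append

    def artifact(name: str):
        manifest["artifacts"].append(name)
        return out / name

    failed = False
    for stage in STAGES:
        if failed:
            manifest["stages"][stage] = "aborted (upstream FAILED)"
            continue
        try:
            status = "ok"
            if stage == "ingest":
                if gm is None:
                    if cfg.genotypes:
                        gm = read_genepop(cfg.genotypes)
                    elif cfg.sample_table:
                        raise ValueError(
                            "sample_table ingest needs an explicit layout; "
                            "use genotype_io.read_sample_table and pass gm="
                        )
                    else:
                        raise ValueError("no genotype input configured")
                if q is None and cfg.q_matrix:
                    q = QMatrix.from_csv(cfg.q_matrix)
                if lt is None and cfg.likelihood_table:
                    lt = LikelihoodTable.from_csv(cfg.likelihood_table)
                log(f"ingest: {gm.n} individuals x {gm.n_loci} loci")
            elif stage == "hybrid_filter":
                if q is None:
                    status = "skipped (no Q matrix)"
                else:
                    res = structure_post.filter_hybrids(
                        q, cfg.focal_cluster, cfg.hybrid_threshold)
                    n_in = gm.n
                    gm = gm.subset_by_ids(
                        [i for i in gm.individual_ids if i in set(res.kept_ids)])
                    keep_rows = [k for k, iid in enumerate(q.individual_ids)
                                 if iid in set(gm.individual_ids)]
                    q = QMatrix([q.individual_ids[k] for k in keep_rows],
                                q.q[keep_rows])
                    log(f"hybrid_filter: {n_in} in, {gm.n} retained, "
                        f"{n_in - gm.n} removed (q < {cfg.hybrid_threshold})")
                    manifest["hybrid_filter"] = {
                        "n_removed": n_in - gm.n, "n_kept": gm.n,
                        "mean_q_kept": res.mean_q_kept,
                        "ci90_q_kept": res.ci90_q_kept,
                    }
            elif stage == "exclude_loci":
                if cfg.locus_exclusions:
                    gm = exclude_loci(gm, cfg.locus_exclusions)
                    log(f"exclude_loci: removed {cfg.locus_exclusions}; "
                        f"{gm.n_loci} loci remain")
                write_sample_table(gm, artifact("analysis_dataset.csv"))
            elif stage == "diversity":
                groups = None
                if q is not None:
                    labels, _ = structure_post.assign_groups(q)
                    groups = [f"G{j + 1}" for j in labels]
                rep = diversity.summary_stats(gm, groups=groups)
                rep.to_csv(artifact("diversity_report.csv"))
                rep.means.to_csv(artifact("diversity_means.csv"))
                if groups is not None and len(set(groups)) > 1:
                    fst = diversity.pairwise_fst(
                        gm, groups, cfg.fst_permutations, seed=seeds["diversity"])
                    fst.to_csv(artifact("fst_matrix.csv"))
                hwe = diversity.hwe_test(gm, mc_reps=cfg.hwe_reps,
                                         seed=seeds["diversity"])
                hwe.to_csv(artifact("hwe.csv"), index=False)
                ld = diversity.ld_test(gm, mc_reps=cfg.ld_reps,
                                       alpha_bonferroni=cfg.alpha,
                                       seed=seeds["diversity"])
                ld.to_csv(artifact("ld_pairs.csv"), index=False)
                manifest["diversity"] = rep.means.to_dict()
            elif stage == "bottleneck":
                rep = bottleneck.bottleneck_report(
                    gm, reps=cfg.bottleneck_reps, tpm_variance=cfg.tpm_variance,
                    tpm_p_smm=cfg.tpm_p_smm, seed=seeds["bottleneck"])
                rep.summary().to_csv(artifact("bottleneck_report.csv"), index=False)
                rep.gw.to_csv(artifact("garza_williamson.csv"), index=False)
                manifest["bottleneck"] = {
                    "sign_p": {m: r.p_value for m, r in rep.sign_tests.items()},
                    "mode_shift": rep.mode_shift.classification,
                    "gw_mean": rep.gw.attrs["mean_M"],
                }
            elif stage == "ne":
                est = ne_ld.ldne(gm, cfg.ldne_min_freq, cfg.ldne_mating)
                est.to_frame().to_csv(artifact("ne_estimate.csv"), index=False)
                manifest["ne"] = {"Ne": est.ne,
                                  "ci_parametric": est.ci_parametric,
                                  "ci_jackknife": est.ci_jackknife}
            elif stage == "exclusion":
                res = assignment.exclusion_test(
                    gm, cfg.exclusion_sims, cfg.exclusion_alpha,
                    seed=seeds["exclusion"])
                res.to_csv(artifact("exclusion_results.csv"), index=False)
                n_flag = int(res.flagged.sum())
                log(f"exclusion: {n_flag} putative immigrants at "
                    f"alpha={cfg.exclusion_alpha}")
                manifest["exclusion"] = {"n_flagged": n_flag}
            elif stage == "structure":
                if lt is not None:
                    dk = structure_post.evanno_delta_k(lt)
                    dk.to_csv(artifact("evanno_delta_k.csv"), index=False)
                    manifest["evanno"] = {"suggested_K": dk.attrs["suggested_K"]}
                if q is not None:
                    labels, per_group = structure_post.assign_groups(q)
                    per_group.to_csv(artifact("group_assignment.csv"), index=False)
                if lt is None and q is None:
                    status = "skipped (no clustering output)"
            elif stage == "spatial":
                if gm.coordinates is None:
                    status = "skipped (no coordinates)"
                else:
                    surf = dresd.dresd_surface(
                        gm, *cfg.dresd_band, n_boot=cfg.n_boot_residual,
                        alpha=cfg.alpha, cell_km=cfg.grid_cell_km,
                        seed=seeds["spatial"])
                    surf.to_csv(artifact("dresd_surface.csv"))
                    surf.to_ascii_grid(artifact("dresd_surface.asc"))
                    surf.metadata["pairs"].to_csv(
                        artifact("dresd_pairs.csv"), index=False)
                    manifest["dresd"] = {
                        "median_residual": surf.metadata["median_residual"],
                        "n_pairs_retained": surf.metadata["n_pairs_retained"],
                        "ibd_slope": surf.metadata["ibd_slope"],
                    }
                    pht = dresd.proportion_heterozygous(gm)
                    hs = dresd.scalar_surface(
                        pht, gm.coordinates, n_boot=cfg.n_boot_heterozygosity,
                        reference="median", alpha=cfg.alpha,
                        cell_km=cfg.grid_cell_km,
                        clamp_eps=1.0 / (2 * gm.n_loci),
                        seed=seeds["spatial"] + 1, analysis="heterozygosity")
                    hs.to_csv(artifact("heterozygosity_surface.csv"))
                    manifest["heterozygosity"] = {"global_median": hs.reference}
                    if q is not None:
                        for j in range(q.k):
                            ms = dresd.scalar_surface(
                                q.q[:, j], gm.coordinates,
                                n_boot=cfg.n_boot_membership,
                                reference="mean", alpha=cfg.alpha,
                                cell_km=cfg.grid_cell_km,
                                seed=seeds["spatial"] + 2 + j,
                                analysis=f"membership_Q{j + 1}")
                            ms.to_csv(artifact(f"membership_Q{j + 1}_surface.csv"))
            manifest["stages"][stage] = status
        except Exception as exc:  # noqa: BLE001 - stage isolation
            manifest["stages"][stage] = f"FAILED: {exc}"
            log(f"{stage}: FAILED: {exc}")
            failed = True
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return manifest
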