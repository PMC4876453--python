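"""End-to-end orchestration: read counts -> CCFs -> clusters -> tree -> kinetics.

One :func:`run_pipeline` call processes every patient in the input tables
through all stages and assembles a :class:`PatientReport` per patient. All
randomness flows from the single configured seed, so a rerun with the same
config reproduces the report byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import __version__
from .ccf import ccf_log_likelihood_grid, make_grid
from .cluster import ClusteringResult, cluster_ccf
from .io import PipelineConfig, lookup_copy_number, read_samples, read_segments, read_variants, write_table, write_tree
from .kinetics import (
    CloneTrajectory,
    GrowthFit,
    InsufficientDataError,
    SampleMeta,
    clone_cell_counts,
    extrapolate_initial_size,
    fit_growth_rate,
    predict_alc,
    total_cll_cells,
)
from .phylogeny import CloneTree, select_tree

logger = logging.getLogger("clonekin")

__all__ = ["PatientReport", "run_pipeline"]


@dataclass
class PatientReport:
    """Everything computed for one patient, plus provenance."""

    patient: str
    samples: list[SampleMeta]
    clustering: ClusteringResult
    tree: CloneTree | None
    trajectories: dict[int, CloneTrajectory] = field(default_factory=dict)
    fits: dict[int, GrowthFit] = field(default_factory=dict)
    fit_status: dict[int, str] = field(default_factory=dict)
    alc_log_rmse: float | None = None
    ccf_table: pd.DataFrame | None = None
    kinetics_table: pd.DataFrame | None = None
    trajectory_table: pd.DataFrame | None = None
    cluster_table: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)


def _mutation_matrix(
    muts: pd.DataFrame, metas: list[SampleMeta], segments: pd.DataFrame | None
):
    """Align mutations across samples -> (keys, alt, depth, q, m) arrays.

    A mutation unobserved in some sample is treated as alt = 0 at that
    sample's median depth (absence evidence at typical power).
    """
    muts = muts.copy()
    muts["key"] = (
        muts["chrom"].astype(str) + ":" + muts["pos"].astype(str)
        + ":" + muts["ref"] + ">" + muts["alt"]
    )
    keys = sorted(muts["key"].unique())
    sample_ids = [m.sample for m in metas]
    n_mut, n_samp = len(keys), len(sample_ids)
    alt = np.zeros((n_mut, n_samp), dtype=int)
    depth = np.zeros((n_mut, n_samp), dtype=int)
    median_depth = {
        s: max(int((muts.loc[muts["sample"] == s, ["t_alt_count", "t_ref_count"]]
                    .sum(axis=1)).median() or 0), 1)
        for s in sample_ids
    }
    key_idx = {k: i for i, k in enumerate(keys)}
    for r in muts.itertuples():
        if r.sample not in sample_ids:
            continue
        j = sample_ids.index(r.sample)
        i = key_idx[r.key]
        alt[i, j] = r.t_alt_count
        depth[i, j] = r.t_alt_count + r.t_ref_count
    for j, s in enumerate(sample_ids):
        missing = depth[:, j] == 0
        depth[missing, j] = median_depth[s]

    first = muts.drop_duplicates("key").set_index("key").loc[keys]
    q = np.full(n_mut, 2, dtype=int)
    m = np.ones(n_mut, dtype=int)
    if "total_cn" in muts.columns:
        q = first["total_cn"].to_numpy(dtype=int)
        if "multiplicity" in muts.columns:
            m = first["multiplicity"].to_numpy(dtype=int)
    elif segments is not None:
        for i, k in enumerate(keys):
            row = first.loc[k]
            q[i], _minor = lookup_copy_number(segments, sample_ids[0], row["chrom"], row["pos"])
    genes = first["gene"].to_numpy()
    return keys, genes, alt, depth, q, m


def _sample_grid_posterior(
    log_liks: np.ndarray, grid: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw CCFs from a (n_samples, n_grid) log-likelihood block."""
    probs = np.exp(log_liks - logsumexp(log_liks, axis=1, keepdims=True))
    cdf = np.cumsum(probs, axis=1)
    u = rng.random((n_draws, len(log_liks)))
    idx = np.empty_like(u, dtype=int)
    for s in range(len(log_liks)):
        idx[:, s] = np.searchsorted(cdf[s], u[:, s])
    return grid[np.minimum(idx, len(grid) - 1)]


def run_patient(
    patient: str,
    muts: pd.DataFrame,
    metas: list[SampleMeta],
    segments: pd.DataFrame | None,
    config: PipelineConfig,
) -> PatientReport:
    metas = sorted(metas, key=lambda m: m.day)
    sample_ids = [m.sample for m in metas]
    grid = make_grid(config.grid_step)
    keys, genes, alt, depth, q, m = _mutation_matrix(muts, metas, segments)

    # per-sample binomial log-likelihood tensor (n_mut, n_samples, n_grid)
    ll = np.stack([
        ccf_log_likelihood_grid(alt[:, j], depth[:, j], metas[j].purity, grid, q, m,
                                error_rate=config.error_rate)
        for j in range(len(metas))
    ], axis=1)

    clustering = cluster_ccf(
        ll, grid, keys, sample_ids, k_max=config.k_max, seed=config.seed
    )
    post = np.exp(ll - logsumexp(ll, axis=2, keepdims=True))
    ccf_table = pd.DataFrame({
        "patient": patient,
        "mutation": np.repeat(keys, len(metas)),
        "gene": np.repeat(genes, len(metas)),
        "sample": sample_ids * len(keys),
        "ccf_mean": (post @ grid).ravel(),
        "ccf_mode": grid[np.argmax(post[..., ::-1], axis=2) * -1 + len(grid) - 1].ravel(),
        "cluster": np.repeat(clustering.assignments + 1, len(metas)),
    })
    cluster_table = pd.DataFrame({
        "mutation": keys,
        "cluster": clustering.assignments + 1,
        "responsibility": clustering.responsibilities[
            np.arange(len(keys)), clustering.assignments
        ],
    })

    tree, _scores = select_tree(
        clustering.clusters, epsilon=config.epsilon,
        n_draws=config.mc_draws, seed=config.seed,
    )

    report = PatientReport(
        patient=patient, samples=metas, clustering=clustering, tree=tree,
        ccf_table=ccf_table, cluster_table=cluster_table,
    )
    if len(metas) < 2:
        logger.warning("%s: single sample; kinetics skipped", patient)
        report.provenance = _provenance(config)
        return report

    rng = np.random.default_rng(config.seed + 7)
    incl_draws = {
        c.cluster_id: _sample_grid_posterior(c.log_liks, grid, config.mc_draws, rng)
        for c in clustering.clusters
    }
    incl_point = {c.cluster_id: c.point_ccf("mean") for c in clustering.clusters}
    if config.ccf_mode == "inclusive":
        frac_point, frac_draws = incl_point, incl_draws
    else:
        frac_point, frac_draws = {}, {}
        for node in tree.nodes:
            kids = tree.children(node)
            kid_p = np.sum([incl_point[k] for k in kids], axis=0) if kids else 0.0
            kid_d = np.sum([incl_draws[k] for k in kids], axis=0) if kids else 0.0
            frac_point[node] = np.maximum(incl_point[node] - kid_p, 0.0)
            frac_draws[node] = np.maximum(incl_draws[node] - kid_d, 0.0)

    report.trajectories = clone_cell_counts(
        frac_point, metas, fraction_draws=frac_draws,
        detection_ccf=config.detection_ccf,
        upper_bound_fraction=config.upper_bound_fraction,
        blood_volume_l=config.blood_volume_l,
    )

    totals = np.array([total_cll_cells(mt, config.blood_volume_l) for mt in metas])
    days = np.array([mt.day for mt in metas], dtype=float)
    day0 = totals[np.argmin(np.abs(days))] if np.min(np.abs(days)) == 0 else None
    for clone, traj in report.trajectories.items():
        det = np.array([p.detected for p in traj.points])
        try:
            draws = frac_draws[clone][:, det] * totals[det]
            fit = fit_growth_rate(traj, count_draws=draws)
            fit = extrapolate_initial_size(
                fit, days=days[det], count_draws=draws, day0_total_cells=day0
            )
            report.fits[clone] = fit
            report.fit_status[clone] = "ok"
        except InsufficientDataError:
            report.fit_status[clone] = "insufficient_data"
        except ValueError as err:
            report.fit_status[clone] = f"failed: {err}"

    if report.fits:
        _pred, report.alc_log_rmse = predict_alc(
            list(report.fits.values()), days, config.blood_volume_l,
            observed_alc_per_ul=np.array([mt.alc_per_ul for mt in metas]),
        )

    report.kinetics_table = pd.DataFrame([
        {
            "patient": patient,
            "clone": clone,
            "status": report.fit_status[clone],
            "method": f.method if f else "",
            "rate_per_day": f.rate if f else np.nan,
            "rate_sd_or_se": f.rate_sd if f else np.nan,
            "rate_ci_low": f.rate_ci[0] if f and f.rate_ci else np.nan,
            "rate_ci_high": f.rate_ci[1] if f and f.rate_ci else np.nan,
            "rate_is_lower_bound": f.rate_is_lower_bound if f else False,
            "N0": f.n0 if f else np.nan,
            "N0_ci_low": f.n0_ci[0] if f and f.n0_ci else np.nan,
            "N0_ci_high": f.n0_ci[1] if f and f.n0_ci else np.nan,
            "one_in_N_at_day0": f.one_in_n_at_day0 if f else np.nan,
        }
        for clone in sorted(report.trajectories)
        for f in [report.fits.get(clone)]
    ])
    report.trajectory_table = pd.DataFrame([
        {
            "patient": patient, "clone": clone, "day": p.day, "cells": p.cells,
            "ci_low": p.ci_low, "ci_high": p.ci_high, "detected": p.detected,
            "upper_bound": p.upper_bound if p.upper_bound is not None else np.nan,
        }
        for clone, traj in sorted(report.trajectories.items())
        for p in traj.points
    ])
    report.provenance = _provenance(config)
    return report


def _provenance(config: PipelineConfig) -> dict:
    return {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "clonekin_version": __version__,
    }


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> dict[str, PatientReport]:
    """Run every stage for every patient in the configured inputs."""
    config.validate()
    muts = read_variants(config.mutations)
    metas = read_samples(config.samples)
    segments = read_segments(config.segments) if config.segments else None

    reports: dict[str, PatientReport] = {}
    for patient in sorted({m.patient for m in metas}):
        p_metas = [m for m in metas if m.patient == patient]
        p_muts = muts[muts["patient"] == patient]
        if len(p_muts) == 0:
            logger.warning("%s: no mutations; skipped", patient)
            continue
        logger.info("processing %s (%d samples, %d mutation rows)",
                    patient, len(p_metas), len(p_muts))
        reports[patient] = run_patient(patient, p_muts, p_metas, segments, config)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for patient, rep in reports.items():
            base = out / patient
            base.mkdir(exist_ok=True)
            if rep.ccf_table is not None:
                write_table(rep.ccf_table, base / "ccf.tsv")
            if rep.cluster_table is not None:
                write_table(rep.cluster_table, base / "clusters.tsv")
            if rep.tree is not None:
                write_tree(rep.tree, base / "tree.json", base / "tree.nwk")
            if rep.kinetics_table is not None:
                write_table(rep.kinetics_table, base / "kinetics.tsv")
            if rep.trajectory_table is not None:
                write_table(rep.trajectory_table, base / "trajectories.tsv")
            with open(base / "provenance.json", "w") as fh:
                json.dump(rep.provenance, fh, indent=2)
    return reports
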