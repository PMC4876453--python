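"""Simulation experiments that measure how well each stage recovers truth.

These are the package's own benchmarks, reused by the test suite and the
acceptance script: rate and initial-size recovery on a realistic
resistant-CLL scenario, the exhaustive tree oracle, clustering accuracy,
and the coverage of the rare-cell frequency intervals.

The reference scenario mirrors a patient relapsing on a kinase inhibitor:
a dominant trunk clone declining slowly on therapy (-0.2%/day) while two
small resistant subclones, thousands of cells at treatment start, expand at
+1.5%/day and +1.9%/day until they dominate the final sample. Four blood
draws over 985 days, sequencing depth 1000x, purity 0.9.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .assays import estimate_mutant_frequency
from .ccf import ccf_log_likelihood_grid, make_grid
from .cluster import CloneCluster, cluster_ccf
from .kinetics import (
    InsufficientDataError,
    SampleMeta,
    clone_cell_counts,
    extrapolate_initial_size,
    fit_growth_rate,
)
from .phylogeny import GERMLINE, enumerate_valid_trees, score_and_select_tree, verify_constraints
from .simulate import SimConfig, simulate_clonal_dynamics, simulate_sequencing

__all__ = [
    "reference_scenario",
    "rate_recovery_experiment",
    "summarize_rate_recovery",
    "tree_oracle_experiment",
    "clustering_experiment",
    "bic_parsimony_experiment",
    "frequency_ci_coverage",
    "simulate_ccf_group_counts",
]

TRUNK, CHILD_A, CHILD_B = 1, 2, 3

#: grid pitch for the recovery experiment; at depth 1000 x 10 mutations the
#: cluster posterior s.d. is ~1e-3, so the default 0.01 grid would quantise
#: it to a point mass and destroy posterior-based intervals
RECOVERY_GRID_STEP = 0.001


def reference_scenario(seed: int) -> SimConfig:
    """The resistant-relapse study conditions used by the recovery benchmarks.

    Trunk N0 = 5e11 cells (ALC 100,000/ul at 5 l), resistant subclones at
    27,000 and 4,000 cells — sizes in the range back-extrapolation infers
    for real resistant clones. The subclones cross the 1% detection
    threshold only at the last two draws, so they get two-point fits while
    the trunk gets a four-point regression.
    """
    return SimConfig(
        parent={TRUNK: None, CHILD_A: TRUNK, CHILD_B: TRUNK},
        initial_sizes={TRUNK: 5e11, CHILD_A: 27_000, CHILD_B: 4_000},
        rates_per_day={TRUNK: -0.002, CHILD_A: 0.015, CHILD_B: 0.019},
        sample_days=(0, 365, 730, 985),
        depth=1000,
        purity_per_sample=0.9,
        muts_per_clone=10,
        seed=seed,
    )


def _draw_from_loglik(
    ll: np.ndarray, grid: np.ndarray, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Posterior draws from per-sample log-likelihood rows -> (n_draws, n_samples)."""
    probs = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
    cdf = np.cumsum(probs, axis=1)
    out = np.empty((n_draws, len(ll)))
    for s in range(len(ll)):
        idx = np.searchsorted(cdf[s], rng.random(n_draws))
        out[:, s] = grid[np.minimum(idx, len(grid) - 1)]
    return out


def rate_recovery_experiment(
    n_seeds: int = 200,
    base_seed: int = 1,
    mc_draws: int = 400,
    grid_step: float = RECOVERY_GRID_STEP,
    detection_ccf: float = 0.01,
) -> pd.DataFrame:
    """Recover per-clone rates and initial sizes across simulated replicates.

    Mutations are grouped by their true clone (this benchmarks the CCF +
    kinetics machinery, not the clustering stage, whose resolution limits
    are probed separately); cluster posteriors are member products, counts
    are posterior draws times the exact tumour burden, and rates/N0 come
    from :func:`fit_growth_rate` / :func:`extrapolate_initial_size` exactly
    as in the pipeline. Returns one row per (seed, clone) with truth,
    estimates and interval endpoints.
    """
    grid = make_grid(grid_step)
    rows = []
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = reference_scenario(seed)
        truth = simulate_clonal_dynamics(cfg)
        obs = simulate_sequencing(truth, seed=seed * 2 + 1)
        rng = np.random.default_rng(seed * 2 + 2)

        days = np.asarray(cfg.sample_days, dtype=float)
        totals = truth.total_cells().to_numpy(dtype=float)
        metas = [
            SampleMeta(sample=s, patient="SIM", day=int(d), purity=0.9,
                       alc_per_ul=float(truth.alc_per_ul.iloc[j]))
            for j, (s, d) in enumerate(zip(truth.sample_ids, cfg.sample_days))
        ]

        # clone-level log-likelihood: sum over member mutations, per sample
        incl_ll, incl_point, incl_draws = {}, {}, {}
        for clone in cfg.clones:
            sub = obs[obs["clone"] == clone]
            ll = np.zeros((len(days), len(grid)))
            for j, s in enumerate(truth.sample_ids):
                rows_s = sub[sub["sample"] == s]
                alt = rows_s["t_alt_count"].to_numpy()
                depth = alt + rows_s["t_ref_count"].to_numpy()
                ll[j] = ccf_log_likelihood_grid(alt, depth, 0.9, grid).sum(axis=0)
            incl_ll[clone] = ll
            probs = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
            incl_point[clone] = probs @ grid
            incl_draws[clone] = _draw_from_loglik(ll, grid, mc_draws, rng)

        # exclusive accounting on the known topology (trunk -> two leaves)
        frac_point = {
            TRUNK: np.maximum(incl_point[TRUNK] - incl_point[CHILD_A] - incl_point[CHILD_B], 0.0),
            CHILD_A: incl_point[CHILD_A],
            CHILD_B: incl_point[CHILD_B],
        }
        frac_draws = {
            TRUNK: np.maximum(incl_draws[TRUNK] - incl_draws[CHILD_A] - incl_draws[CHILD_B], 0.0),
            CHILD_A: incl_draws[CHILD_A],
            CHILD_B: incl_draws[CHILD_B],
        }
        trajs = clone_cell_counts(
            frac_point, metas, fraction_draws=frac_draws, detection_ccf=detection_ccf
        )
        excl_truth = truth.exclusive_fraction()
        for clone in cfg.clones:
            det = np.array([p.detected for p in trajs[clone].points])
            g_true = cfg.rates_per_day[clone]
            n0_true = (
                cfg.initial_sizes[TRUNK] if clone == TRUNK
                else cfg.initial_sizes[clone]
            )
            row = {
                "seed": seed, "clone": clone, "g_true": g_true, "n0_true": n0_true,
                "n_detected": int(det.sum()), "fitted": False,
            }
            try:
                draws = frac_draws[clone][:, det] * totals[det]
                fit = fit_growth_rate(trajs[clone], count_draws=draws)
                fit = extrapolate_initial_size(
                    fit, days=days[det], count_draws=draws, day0_total_cells=totals[0]
                )
            except (InsufficientDataError, ValueError):
                rows.append(row)
                continue
            # trunk truth for exclusive accounting: its exclusive trajectory is
            # not a single exponential; compare against the effective two-end slope
            if clone == TRUNK:
                n_first = excl_truth.iloc[0, 0] * totals[0]
                n_last = excl_truth.iloc[0, -1] * totals[-1]
                g_true = float(np.log(n_last / n_first) / (days[-1] - days[0]))
                n0_true = float(n_first)
                row.update(g_true=g_true, n0_true=n0_true)
            row.update(
                fitted=True,
                g_hat=fit.rate,
                g_err=abs(fit.rate - g_true),
                g_ci_low=fit.rate_ci[0], g_ci_high=fit.rate_ci[1],
                g_covered=bool(fit.rate_ci[0] <= g_true <= fit.rate_ci[1]),
                n0_hat=fit.n0,
                n0_factor=max(fit.n0 / n0_true, n0_true / fit.n0),
                method=fit.method,
            )
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_rate_recovery(df: pd.DataFrame) -> dict[str, float]:
    """Headline numbers: median |g_hat - g|, CI coverage, N0 factor-of-3 rate."""
    fitted = df[df["fitted"]]
    big_n0 = fitted[fitted["n0_true"] >= 100]
    return {
        "median_abs_rate_error_per_day": float(fitted["g_err"].median()),
        "rate_ci_coverage_percent": float(100.0 * fitted["g_covered"].mean()),
        "n0_within_factor3_percent": float(100.0 * (big_n0["n0_factor"] <= 3.0).mean()),
        "fitted_fraction_percent": float(100.0 * df["fitted"].mean()),
        "n_fits": int(len(fitted)),
    }


def _random_tree_instance(
    rng: np.random.Generator, n_samples: int = 3, depth: int = 500, muts: int = 5
) -> tuple[dict[int, int], list[CloneCluster]]:
    """A random valid clone tree with noisy cluster CCF evidence.

    CCFs are generated top-down: each node's children split a random
    sub-fraction of the parent's CCF, so both pigeonhole constraints hold
    by construction with margin. Read counts are binomial at depth 500 per
    mutation, 5 mutations per cluster.
    """
    k = int(rng.integers(2, 6))
    parent = {1: GERMLINE}
    for c in range(2, k + 1):
        parent[c] = int(rng.integers(1, c))
    ccfs = {1: np.ones(n_samples)}
    for c in range(2, k + 1):
        kids_so_far = np.sum([ccfs[j] for j in range(2, c) if parent[j] == parent[c]], axis=0)
        avail = np.maximum(ccfs[parent[c]] - kids_so_far, 0.0)
        ccfs[c] = avail * rng.uniform(0.2, 0.8, size=n_samples)

    grid = make_grid(0.01)
    clusters = []
    for c in range(1, k + 1):
        ll = np.zeros((n_samples, len(grid)))
        for s in range(n_samples):
            af = ccfs[c][s] / 2.0  # purity 1, diploid het
            alt = rng.binomial(depth, af, size=muts)
            ll[s] = ccf_log_likelihood_grid(
                alt, np.full(muts, depth), 1.0, grid
            ).sum(axis=0)
        clusters.append(CloneCluster(
            cluster_id=c,
            members=[f"c{c}m{j}" for j in range(muts)],
            samples=[f"S{s + 1}" for s in range(n_samples)],
            grid=grid,
            log_liks=ll,
        ))
    return parent, clusters


def tree_oracle_experiment(
    n_instances: int = 100, base_seed: int = 1, epsilon: float = 0.10, n_draws: int = 400
) -> dict[str, float]:
    """Check tree selection against exhaustive enumeration on random instances.

    For each instance the selected tree must (a) belong to the exhaustively
    enumerated valid set, (b) attain the maximal Monte-Carlo score among
    candidates, and (c) satisfy the lineage invariants under the epsilon
    tolerance. Also reports how often the true topology is recovered.
    """
    ok_member = ok_score = ok_invariant = ok_topology = 0
    n_scored = 0
    for i in range(n_instances):
        rng = np.random.default_rng(base_seed + i)
        true_parent, clusters = _random_tree_instance(rng)
        candidates = enumerate_valid_trees(clusters, epsilon=epsilon)
        if not candidates:
            continue
        n_scored += 1
        selected, scores = score_and_select_tree(
            candidates, clusters, n_draws=n_draws, seed=base_seed + i
        )
        in_set = any(selected.parent_tuple() == t.parent_tuple() for t in candidates)
        ok_member += in_set
        ok_score += bool(
            scores[[t.parent_tuple() for t in candidates].index(selected.parent_tuple())]
            >= scores.max() - 1e-12
        ) if in_set else 0
        ok_invariant += not verify_constraints(selected, epsilon)
        ok_topology += selected.parent_tuple() == tuple(sorted(true_parent.items()))
    return {
        "oracle_agreement_percent": 100.0 * ok_member / max(n_scored, 1),
        "max_score_percent": 100.0 * ok_score / max(n_scored, 1),
        "invariants_percent": 100.0 * ok_invariant / max(n_scored, 1),
        "topology_recovered_percent": 100.0 * ok_topology / max(n_scored, 1),
        "n_instances_with_candidates": float(n_scored),
        "n_instances": float(n_instances),
    }


#: a 4-clone topology whose CCF patterns over three samples admit exactly
#: one valid tree: trunk -> {2, 4}, 2 -> 3. Sibling or re-attached variants
#: violate either the pigeonhole sum or the parent-dominance constraint.
IDENTIFIABLE_PARENT = {1: GERMLINE, 2: 1, 3: 2, 4: 1}
IDENTIFIABLE_CCFS = {
    1: np.array([1.0, 1.0, 1.0]),
    2: np.array([0.7, 0.5, 0.3]),
    3: np.array([0.5, 0.3, 0.1]),
    4: np.array([0.2, 0.4, 0.6]),
}


def topology_recovery_experiment(
    n_seeds: int = 50,
    base_seed: int = 1,
    depth: int = 1000,
    muts: int = 5,
    epsilon: float = 0.10,
    n_draws: int = 400,
) -> dict[str, float]:
    """How often the uniquely identifiable 4-clone topology is recovered."""
    grid = make_grid(0.01)
    hits = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + i)
        clusters = []
        for c, ccf in IDENTIFIABLE_CCFS.items():
            ll = np.zeros((3, len(grid)))
            for s in range(3):
                alt = rng.binomial(depth, ccf[s] / 2.0, size=muts)
                ll[s] = ccf_log_likelihood_grid(
                    alt, np.full(muts, depth), 1.0, grid
                ).sum(axis=0)
            clusters.append(CloneCluster(
                cluster_id=c, members=[f"c{c}m{j}" for j in range(muts)],
                samples=["S1", "S2", "S3"], grid=grid, log_liks=ll,
            ))
        candidates = enumerate_valid_trees(clusters, epsilon=epsilon)
        if not candidates:
            continue
        selected, _ = score_and_select_tree(
            candidates, clusters, n_draws=n_draws, seed=base_seed + i
        )
        hits += selected.parent_tuple() == tuple(sorted(IDENTIFIABLE_PARENT.items()))
    return {"topology_recovered_percent": 100.0 * hits / n_seeds, "n_seeds": float(n_seeds)}


def simulate_ccf_group_counts(
    centres: np.ndarray,
    muts_per_group: int,
    depth: int,
    rng: np.random.Generator,
    purity: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binomial read counts for mutation groups at fixed CCF vectors.

    Returns (alt, depth, labels) with shapes (n_mut, n_samples) x2 and
    (n_mut,). Used by the clustering benchmarks.
    """
    centres = np.asarray(centres, dtype=float)
    n_groups, n_samples = centres.shape
    af = purity * centres / 2.0
    labels = np.repeat(np.arange(n_groups), muts_per_group)
    depths = np.maximum(rng.poisson(depth, size=(len(labels), n_samples)), 1)
    alt = rng.binomial(depths, af[labels])
    return alt, depths, labels


def clustering_experiment(
    n_seeds: int = 50,
    base_seed: int = 1,
    centres: np.ndarray | None = None,
    muts_per_group: int = 20,
    depth: int = 1000,
    k_max: int = 4,
) -> dict[str, float]:
    """Assignment accuracy on well-separated two-cluster data.

    Default truth: a clonal group at CCF (1.0, 1.0) and a subclonal group
    at (0.3, 0.05) — separation >= 0.2 in the first sample. Accuracy maps
    each inferred cluster to its majority truth label.
    """
    centres = np.array([[1.0, 1.0], [0.3, 0.05]]) if centres is None else np.asarray(centres)
    grid = make_grid(0.01)
    accs, ks = [], []
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + i)
        alt, depths, labels = simulate_ccf_group_counts(centres, muts_per_group, depth, rng)
        ll = np.stack([
            ccf_log_likelihood_grid(alt[:, s], depths[:, s], 1.0, grid)
            for s in range(centres.shape[1])
        ], axis=1)
        keys = [f"m{j}" for j in range(len(labels))]
        res = cluster_ccf(ll, grid, keys, [f"S{s+1}" for s in range(centres.shape[1])],
                          k_max=k_max, seed=base_seed + i)
        correct = 0
        for c in np.unique(res.assignments):
            member_labels = labels[res.assignments == c]
            correct += np.bincount(member_labels).max()
        accs.append(correct / len(labels))
        ks.append(res.k)
    return {
        "assignment_accuracy_percent": float(100.0 * np.mean(accs)),
        "mean_k": float(np.mean(ks)),
        "n_seeds": float(n_seeds),
    }


def bic_parsimony_experiment(
    n_seeds: int = 100, base_seed: int = 1, muts: int = 20, depth: int = 500
) -> dict[str, float]:
    """How often BIC selects k=1 when the data really form one cluster."""
    grid = make_grid(0.01)
    hits = 0
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + i)
        alt, depths, _ = simulate_ccf_group_counts(
            np.array([[0.6, 0.6]]), muts, depth, rng
        )
        ll = np.stack([
            ccf_log_likelihood_grid(alt[:, s], depths[:, s], 1.0, grid)
            for s in range(2)
        ], axis=1)
        res = cluster_ccf(ll, grid, [f"m{j}" for j in range(muts)], ["S1", "S2"],
                          k_max=4, seed=base_seed + i)
        hits += res.k == 1
    return {"k1_selected_percent": 100.0 * hits / n_seeds, "n_seeds": float(n_seeds)}


def frequency_ci_coverage(
    true_freq: float, n_cells: int, n_seeds: int = 500, base_seed: int = 1, level: float = 0.95
) -> dict[str, float]:
    """Empirical coverage of the exact binomial frequency intervals."""
    rng = np.random.default_rng(base_seed)
    k = rng.binomial(n_cells, true_freq, size=n_seeds)
    covered = np.empty(n_seeds, dtype=bool)
    for i, ki in enumerate(k):
        est = estimate_mutant_frequency(int(ki), n_cells, level=level)
        covered[i] = est["ci_low"] <= true_freq <= est["ci_high"]
    return {
        "coverage_percent": float(100.0 * covered.mean()),
        "true_freq": true_freq,
        "n_cells": float(n_cells),
        "n_seeds": float(n_seeds),
    }
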