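"""Cluster mutations into subclonal populations by their multi-sample CCFs.

Mutations acquired in the same clone share one CCF trajectory across serial
samples, so clustering the per-mutation CCF evidence recovers the clonal
composition. The model is a finite mixture whose component "centres" are
CCF vectors living on the same discrete grid the posteriors use; a mutation's
likelihood under a component is the product over samples of its binomial
grid likelihood evaluated at the centre. The mixture is fitted by EM for
k = 1..k_max and the number of clusters chosen by BIC.

The M-step is exact: for fixed responsibilities the optimal centre in each
sample is a 1-D grid search over the responsibility-weighted log-likelihood,
so EM monotonicity holds without any continuous optimisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .ccf import CCFPosterior

__all__ = ["CloneCluster", "ClusteringResult", "cluster_ccf", "cluster_ccf_posterior"]

_LOG_FLOOR = -1e8


@dataclass
class CloneCluster:
    """A mutation cluster with its per-sample CCF evidence.

    ``log_liks`` is the summed member log-likelihood on the grid, one row
    per sample; exponentiating a row (with a uniform prior) gives the
    cluster-level CCF posterior for that sample.
    """

    cluster_id: int
    members: list[str]
    samples: list[str]
    grid: np.ndarray
    log_liks: np.ndarray                      # (n_samples, n_grid)
    responsibilities: np.ndarray | None = None  # per-member weight for this cluster

    def posterior(self, sample: str | int) -> CCFPosterior:
        return cluster_ccf_posterior(self, sample)

    def point_ccf(self, kind: str = "mode") -> np.ndarray:
        return np.array([
            getattr(self.posterior(i), kind) for i in range(len(self.samples))
        ])


@dataclass
class ClusteringResult:
    clusters: list[CloneCluster]
    assignments: np.ndarray            # cluster index per mutation
    responsibilities: np.ndarray       # (n_mut, k)
    bic_by_k: dict[int, float] = field(default_factory=dict)
    log_likelihood: float = float("nan")

    @property
    def k(self) -> int:
        return len(self.clusters)


def cluster_ccf_posterior(cluster: CloneCluster, sample: str | int) -> CCFPosterior:
    """Grid-wise product of member posteriors for one sample, renormalised.

    Multiplying member posteriors (equivalently summing log-likelihoods
    under the shared uniform prior) concentrates the cluster posterior:
    on concordant data it is never wider than any single member's.
    """
    if not cluster.members:
        raise ValueError("empty cluster has no posterior")
    idx = cluster.samples.index(sample) if isinstance(sample, str) else sample
    ll = cluster.log_liks[idx]
    probs = np.exp(ll - logsumexp(ll))
    return CCFPosterior(grid=cluster.grid, probs=probs)


def _kmeanspp_indices(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding on point CCF vectors; returns row indices."""
    n = len(points)
    chosen = [int(rng.integers(n))]
    for _ in range(1, k):
        d2 = np.min(
            ((points[:, None, :] - points[chosen][None, :, :]) ** 2).sum(-1), axis=1
        )
        total = d2.sum()
        if total <= 0:
            chosen.append(int(rng.integers(n)))
        else:
            chosen.append(int(rng.choice(n, p=d2 / total)))
    return np.asarray(chosen)


def _em_once(
    ll: np.ndarray,  # (n_mut, n_samples, n_grid)
    centre_idx: np.ndarray,  # (k, n_samples) initial grid indices
    max_iter: int,
    tol: float,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    n_mut, n_samples, n_grid = ll.shape
    k = len(centre_idx)
    log_pi = np.full(k, -np.log(k))
    # floor -inf log-pmfs: keeps 0-responsibility x impossible-point products
    # finite in the M-step without affecting any argmax
    ll = np.maximum(ll, _LOG_FLOOR)
    flat = ll.reshape(n_mut, n_samples * n_grid)
    prev = -np.inf
    for _ in range(max_iter):
        # E-step: log p(m | component) at current centres
        comp_ll = np.empty((n_mut, k))
        for j in range(k):
            comp_ll[:, j] = ll[:, np.arange(n_samples), centre_idx[j]].sum(axis=1)
        joint = comp_ll + log_pi
        norm = logsumexp(joint, axis=1)
        loglik = float(norm.sum())
        resp = np.exp(joint - norm[:, None])
        # M-step: weights and exact 1-D grid search per sample
        weights = resp.sum(axis=0)
        log_pi = np.log(np.maximum(weights, 1e-300)) - np.log(n_mut)
        weighted = (resp.T @ flat).reshape(k, n_samples, n_grid)
        centre_idx = np.argmax(weighted, axis=2)
        if loglik - prev < tol and np.isfinite(prev):
            break
        prev = loglik
    return loglik, centre_idx, resp, np.exp(log_pi)


def cluster_ccf(
    log_lik: np.ndarray,
    grid: np.ndarray,
    mutation_keys: list[str],
    sample_ids: list[str],
    k_max: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> ClusteringResult:
    """Fit the grid mixture for k = 1..k_max and select k by BIC.

    Parameters
    ----------
    log_lik
        ``(n_mut, n_samples, n_grid)`` binomial log-likelihoods, e.g. from
        :func:`clonekin.ccf.ccf_log_likelihood_grid` stacked over samples.
        Mutations missing from a sample should be encoded upstream as
        alt = 0 at that sample's median depth.
    k_max
        Largest number of clusters considered (>= 1).
    seed
        Drives the k-means++ restarts; identical seeds give identical output.

    Ties in BIC are broken toward the smaller k; ties across restarts toward
    the earlier restart, so the procedure is fully deterministic.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    ll = np.asarray(log_lik, dtype=float)
    if ll.ndim != 3:
        raise ValueError("log_lik must have shape (n_mut, n_samples, n_grid)")
    n_mut, n_samples, n_grid = ll.shape
    if n_mut < 1:
        raise ValueError("at least one mutation required")
    # point CCF vectors (posterior mean per mutation/sample) for seeding
    post = np.exp(ll - logsumexp(ll, axis=2, keepdims=True))
    points = post @ grid

    rng = np.random.default_rng(seed)
    best = None  # (bic, k, loglik, centre_idx, resp)
    bic_by_k: dict[int, float] = {}
    for k in range(1, min(k_max, n_mut) + 1):
        best_k = None
        for _ in range(n_restarts if k > 1 else 1):
            init = np.round(points[_kmeanspp_indices(points, k, rng)] * (n_grid - 1) /
                            grid[-1]).astype(int) if grid[-1] > 0 else np.zeros((k, n_samples), int)
            init = np.clip(init, 0, n_grid - 1)
            loglik, centres, resp, _pi = _em_once(ll, init, max_iter, tol)
            if best_k is None or loglik > best_k[0] + 1e-12:
                best_k = (loglik, centres, resp)
        loglik, centres, resp = best_k
        n_params = k * n_samples + (k - 1)
        bic = -2.0 * loglik + n_params * np.log(n_mut)
        bic_by_k[k] = bic
        if best is None or bic < best[0] - 1e-12:
            best = (bic, k, loglik, centres, resp)

    _bic, k, loglik, _centres, resp = best
    assignments = np.argmax(resp, axis=1)
    # drop empty components, renumber compactly
    kept = [j for j in range(k) if np.any(assignments == j)]
    remap = {j: i for i, j in enumerate(kept)}
    assignments = np.array([remap[a] for a in assignments])
    resp = resp[:, kept]

    clusters = []
    keys = np.asarray(mutation_keys)
    for i in range(len(kept)):
        mask = assignments == i
        clusters.append(CloneCluster(
            cluster_id=i + 1,
            members=list(keys[mask]),
            samples=list(sample_ids),
            grid=np.asarray(grid, dtype=float),
            log_liks=ll[mask].sum(axis=0),
            responsibilities=resp[mask, i],
        ))
    # order clusters by descending mean CCF so the trunk is cluster 1
    order = np.argsort([-c.point_ccf("mean").mean() for c in clusters], kind="stable")
    clusters = [clusters[j] for j in order]
    inverse = {int(old): new for new, old in enumerate(order)}
    assignments = np.array([inverse[int(a)] for a in assignments])
    for new_id, c in enumerate(clusters, start=1):
        c.cluster_id = new_id
    return ClusteringResult(
        clusters=clusters,
        assignments=assignments,
        responsibilities=resp[:, order],
        bic_by_k=bic_by_k,
        log_likelihood=loglik,
    )
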