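"""Rooted clone trees from cluster CCFs under lineage (pigeonhole) constraints.

A valid clone tree must satisfy, in every sample: (i) a child's inclusive
CCF cannot exceed its parent's (a subclone is a subset of its ancestor's
cells), and (ii) the inclusive CCFs of sibling subclones cannot sum above
their parent's CCF (disjoint sublineages partition the parent — the
pigeonhole principle). The trunk is the cluster carried by essentially all
tumour cells (CCF >= 1 - epsilon in every sample) and hangs off a germline
root.

With at most eight clusters all rooted trees can be enumerated exhaustively;
candidates are scored by the posterior probability mass of CCF
configurations that satisfy the constraints, estimated by Monte-Carlo draws
from the cluster CCF posteriors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .cluster import CloneCluster

__all__ = [
    "GERMLINE",
    "CloneTree",
    "NoTrunkError",
    "NoValidTreeError",
    "enumerate_valid_trees",
    "score_and_select_tree",
    "select_tree",
    "exclusive_fractions",
    "verify_constraints",
]

#: node id of the germline root (not a tumour clone; inclusive CCF == 1)
GERMLINE = 0

MAX_ENUMERATION_CLUSTERS = 8


class NoTrunkError(ValueError):
    """No cluster is clonal (CCF >= 1 - epsilon) in every sample."""


class NoValidTreeError(ValueError):
    """No tree over the clusters satisfies the lineage constraints."""


@dataclass
class CloneTree:
    """Rooted tree over cluster ids, with per-sample CCF accounting.

    ``inclusive`` maps node -> per-sample inclusive CCF (germline is fixed
    at 1 everywhere). ``constraint_flag`` is set when the tree was emitted
    as a least-violating fallback rather than a fully valid topology.
    """

    parent: dict[int, int]                 # cluster -> parent (GERMLINE for trunk)
    inclusive: dict[int, np.ndarray]
    samples: list[str] = field(default_factory=list)
    constraint_flag: bool = False
    total_violation: float = 0.0

    @property
    def nodes(self) -> list[int]:
        return sorted(self.parent)

    def children(self, node: int) -> list[int]:
        return sorted(c for c, p in self.parent.items() if p == node)

    @property
    def trunk(self) -> int:
        (t,) = [c for c, p in self.parent.items() if p == GERMLINE]
        return t

    def depth(self, node: int) -> int:
        d = 0
        while node != GERMLINE:
            node = self.parent[node]
            d += 1
        return d

    def n_samples(self) -> int:
        return len(next(iter(self.inclusive.values())))

    def exclusive(self) -> tuple[dict[int, np.ndarray], float]:
        return exclusive_fractions(self)

    def parent_tuple(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(self.parent.items()))

    def to_dict(self) -> dict:
        excl, clipped = self.exclusive()
        return {
            "samples": list(self.samples),
            "parent": {str(k): v for k, v in self.parent.items()},
            "inclusive_ccf": {str(k): list(map(float, v)) for k, v in self.inclusive.items()},
            "exclusive_fraction": {str(k): list(map(float, v)) for k, v in excl.items()},
            "constraint_flag": self.constraint_flag,
            "total_violation": float(self.total_violation),
            "clip_magnitude": float(clipped),
        }

    def to_newick(self) -> str:
        """Newick string with clone labels, rooted at the germline."""
        from skbio import TreeNode

        nodes = {GERMLINE: TreeNode(name="germline")}
        for c in self.nodes:
            nodes[c] = TreeNode(name=f"clone{c}")
        for c in self.nodes:
            nodes[self.parent[c]].append(nodes[c])
        out = str(nodes[GERMLINE]).strip()
        return out


def exclusive_fractions(tree: CloneTree) -> tuple[dict[int, np.ndarray], float]:
    """Per-sample exclusive fraction of each clone.

    exclusive = inclusive - sum(children inclusive); negative values
    (possible under noise within the epsilon tolerance) are clipped to 0
    and the total clip magnitude is returned alongside.
    """
    excl: dict[int, np.ndarray] = {}
    clipped = 0.0
    for node in tree.nodes:
        kids = tree.children(node)
        val = tree.inclusive[node] - (
            np.sum([tree.inclusive[k] for k in kids], axis=0) if kids else 0.0
        )
        clipped += float(np.sum(np.maximum(-val, 0.0)))
        excl[node] = np.maximum(val, 0.0)
    return excl, clipped


def verify_constraints(tree: CloneTree, epsilon: float) -> list[str]:
    """Return human-readable violations of the lineage constraints (empty if valid)."""
    problems = []
    for c in tree.nodes:
        p = tree.parent[c]
        p_ccf = np.ones(tree.n_samples()) if p == GERMLINE else tree.inclusive[p]
        bad = tree.inclusive[c] > p_ccf + epsilon
        if np.any(bad):
            problems.append(f"child {c} exceeds parent {p} in samples {np.where(bad)[0].tolist()}")
    for node in [GERMLINE] + tree.nodes:
        kids = tree.children(node)
        if not kids:
            continue
        ccf = np.ones(tree.n_samples()) if node == GERMLINE else tree.inclusive[node]
        kid_sum = np.sum([tree.inclusive[k] for k in kids], axis=0)
        bad = kid_sum > ccf + epsilon
        if np.any(bad):
            problems.append(
                f"children of {node} sum above it in samples {np.where(bad)[0].tolist()}"
            )
    return problems


def _violation(parent: dict[int, int], ccfs: dict[int, np.ndarray], n_samples: int) -> float:
    """Total constraint-violation magnitude (0 for a valid tree, epsilon=0)."""
    total = 0.0
    for c, p in parent.items():
        p_ccf = np.ones(n_samples) if p == GERMLINE else ccfs[p]
        total += float(np.sum(np.maximum(ccfs[c] - p_ccf, 0.0)))
    for node in set(parent.values()):
        kids = [c for c, p in parent.items() if p == node]
        ccf = np.ones(n_samples) if node == GERMLINE else ccfs[node]
        kid_sum = np.sum([ccfs[k] for k in kids], axis=0)
        total += float(np.sum(np.maximum(kid_sum - ccf, 0.0)))
    return total


def _point_ccfs(clusters: list[CloneCluster], kind: str = "mean") -> dict[int, np.ndarray]:
    return {c.cluster_id: c.point_ccf(kind) for c in clusters}


def find_trunk(ccfs: dict[int, np.ndarray], epsilon: float) -> int:
    """The clonal cluster: CCF >= 1 - epsilon in every sample.

    If several qualify, the one with the highest mean CCF is the trunk and
    the rest are treated as ordinary (necessarily child) clusters.
    """
    qualifying = [c for c, v in ccfs.items() if np.all(v >= 1.0 - epsilon)]
    if not qualifying:
        detail = {c: np.round(v, 3).tolist() for c, v in ccfs.items()}
        raise NoTrunkError(
            f"no cluster has CCF >= {1 - epsilon:.2f} in all samples; CCFs: {detail}"
        )
    return max(qualifying, key=lambda c: (float(np.mean(ccfs[c])), -c))


def _all_parent_maps(trunk: int, others: list[int]) -> "itertools.product":
    """All acyclic parent assignments: each non-trunk node picks any other node."""
    choices = [[p for p in [trunk, *others] if p != c] for c in others]
    for combo in itertools.product(*choices):
        parent = {trunk: GERMLINE, **dict(zip(others, combo))}
        # acyclicity: walk up from every node, must reach GERMLINE
        ok = True
        for node in others:
            seen = set()
            cur = node
            while cur != GERMLINE:
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = parent[cur]
            if not ok:
                break
        if ok:
            yield parent


def enumerate_valid_trees(
    clusters: list[CloneCluster] | dict[int, np.ndarray],
    epsilon: float = 0.10,
    samples: list[str] | None = None,
) -> list[CloneTree]:
    """All rooted trees over the clusters satisfying the pigeonhole constraints.

    Accepts either fitted :class:`CloneCluster` objects (point CCF = posterior
    mean) or a plain ``{cluster_id: per-sample CCF array}`` mapping. Returns
    the empty list when no topology is consistent with the CCFs.
    """
    if isinstance(clusters, dict):
        ccfs = {c: np.asarray(v, dtype=float) for c, v in clusters.items()}
        sample_ids = samples or [f"S{i + 1}" for i in range(len(next(iter(ccfs.values()))))]
    else:
        ccfs = _point_ccfs(clusters)
        sample_ids = clusters[0].samples
    if GERMLINE in ccfs:
        raise ValueError(f"cluster id {GERMLINE} is reserved for the germline root")
    if len(ccfs) > MAX_ENUMERATION_CLUSTERS:
        raise ValueError(
            f"exhaustive enumeration supports at most {MAX_ENUMERATION_CLUSTERS} clusters"
        )
    trunk = find_trunk(ccfs, epsilon)
    others = sorted(c for c in ccfs if c != trunk)
    n_samples = len(sample_ids)

    out = []
    for parent in _all_parent_maps(trunk, others):
        ok = True
        for c, p in parent.items():
            p_ccf = np.ones(n_samples) if p == GERMLINE else ccfs[p]
            if np.any(ccfs[c] > p_ccf + epsilon):
                ok = False
                break
        if ok:
            for node in set(parent.values()):
                kids = [c for c, p in parent.items() if p == node]
                ccf = np.ones(n_samples) if node == GERMLINE else ccfs[node]
                if np.any(np.sum([ccfs[k] for k in kids], axis=0) > ccf + epsilon):
                    ok = False
                    break
        if ok:
            out.append(CloneTree(parent=dict(parent), inclusive=dict(ccfs), samples=sample_ids))
    return out


def score_and_select_tree(
    trees: list[CloneTree],
    clusters: list[CloneCluster],
    n_draws: int = 500,
    seed: int = 0,
) -> tuple[CloneTree, np.ndarray]:
    """Pick the candidate maximising posterior constraint-satisfaction mass.

    CCF configurations are drawn jointly from the cluster posteriors
    (``n_draws`` per cluster per sample, fixed seed); a tree's score is the
    fraction of draws in which every lineage constraint holds. Ties are
    broken by smaller mean violation, then by fewer total edges from the
    trunk (shallower topology), then by lexicographic parent map.
    """
    if not trees:
        raise NoValidTreeError("no valid tree to select from")
    rng = np.random.default_rng(seed)
    draws: dict[int, np.ndarray] = {}
    for c in clusters:
        if c.cluster_id not in trees[0].inclusive:
            continue
        per_sample = [c.posterior(i).sample(n_draws, rng) for i in range(len(c.samples))]
        draws[c.cluster_id] = np.stack(per_sample, axis=1)  # (n_draws, n_samples)

    scores = np.empty(len(trees))
    mean_viol = np.empty(len(trees))
    for i, tree in enumerate(trees):
        ok = np.ones(n_draws, dtype=bool)
        viol = np.zeros(n_draws)
        for c, p in tree.parent.items():
            p_ccf = 1.0 if p == GERMLINE else draws[p]
            over = np.maximum(draws[c] - p_ccf, 0.0)
            ok &= ~np.any(over > 1e-12, axis=1)
            viol += over.sum(axis=1)
        for node in set(tree.parent.values()):
            kids = [c for c, p in tree.parent.items() if p == node]
            ccf = 1.0 if node == GERMLINE else draws[node]
            kid_sum = np.sum([draws[k] for k in kids], axis=0)
            over = np.maximum(kid_sum - ccf, 0.0)
            ok &= ~np.any(over > 1e-12, axis=1)
            viol += over.sum(axis=1)
        scores[i] = ok.mean()
        mean_viol[i] = viol.mean()

    def sort_key(i: int):
        t = trees[i]
        return (
            -scores[i],
            mean_viol[i],
            sum(t.depth(n) for n in t.nodes),
            t.parent_tuple(),
        )

    best = min(range(len(trees)), key=sort_key)
    return trees[best], scores


def select_tree(
    clusters: list[CloneCluster],
    epsilon: float = 0.10,
    n_draws: int = 500,
    seed: int = 0,
) -> tuple[CloneTree, np.ndarray]:
    """Enumerate + score; fall back to the least-violating tree if none valid.

    The fallback tree carries ``constraint_flag=True`` and its total
    violation magnitude, so noisy data yield a diagnosable result instead
    of a hard failure.
    """
    candidates = enumerate_valid_trees(clusters, epsilon=epsilon)
    if candidates:
        return score_and_select_tree(candidates, clusters, n_draws=n_draws, seed=seed)
    ccfs = _point_ccfs(clusters)
    trunk = find_trunk(ccfs, epsilon)
    others = sorted(c for c in ccfs if c != trunk)
    n_samples = len(clusters[0].samples)
    best_parent, best_viol = None, np.inf
    for parent in _all_parent_maps(trunk, others):
        v = _violation(parent, ccfs, n_samples)
        if v < best_viol - 1e-15:
            best_parent, best_viol = dict(parent), v
    tree = CloneTree(
        parent=best_parent,
        inclusive=ccfs,
        samples=clusters[0].samples,
        constraint_flag=True,
        total_violation=best_viol,
    )
    return tree, np.array([])
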