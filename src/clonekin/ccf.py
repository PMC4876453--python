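"""Cancer cell fraction (CCF) posteriors from somatic read counts.

A mutation observed with ``alt`` of ``alt + ref`` reads in a sample of
purity ``rho``, sitting at local total copy number ``q`` with ``m`` mutant
copies per tumour cell, has expected allele fraction

    af(c) = rho * m * c / (rho * q + (1 - rho) * 2)

for CCF ``c``. We place a uniform prior on a discrete CCF grid over [0, 1]
and score each grid point with the binomial likelihood of the observed alt
count, which is the standard simplification of purity/copy-number-aware CCF
estimation when purity and copy number are known inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import binom

__all__ = [
    "MutationObservation",
    "CCFPosterior",
    "expected_af",
    "af_to_ccf_posterior",
    "ccf_log_likelihood_grid",
    "ccf_point_estimate",
    "best_multiplicity",
    "make_grid",
]

DEFAULT_GRID_STEP = 0.01


@dataclass
class MutationObservation:
    """One somatic variant in one sample, with its copy-number context."""

    patient: str
    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    alt_count: int
    ref_count: int
    total_cn: int = 2
    multiplicity: int = 1

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")
        if self.alt_count < 0 or self.ref_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.total_cn < 1:
            raise ValueError("total copy number must be >= 1")
        if not 1 <= self.multiplicity <= self.total_cn:
            raise ValueError("multiplicity must lie in 1..total_cn")

    @property
    def depth(self) -> int:
        return self.alt_count + self.ref_count

    @property
    def af(self) -> float:
        return self.alt_count / self.depth

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class CCFPosterior:
    """Discretised posterior over CCF in [0, 1]."""

    grid: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.grid.shape != self.probs.shape:
            raise ValueError("grid and probs must have the same shape")
        if self.grid.min() < 0 or self.grid.max() > 1:
            raise ValueError("grid must lie within [0, 1]")
        total = self.probs.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("posterior mass must be positive and finite")
        if abs(total - 1.0) > 1e-9:
            self.probs = self.probs / total

    @property
    def mode(self) -> float:
        # ties broken toward the larger CCF
        rev = self.probs[::-1]
        return float(self.grid[len(self.grid) - 1 - int(np.argmax(rev))])

    @property
    def mean(self) -> float:
        return float(self.grid @ self.probs)

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Central credible interval from the discrete CDF."""
        a = (1.0 - level) / 2.0
        cdf = np.cumsum(self.probs)
        lo = self.grid[int(np.searchsorted(cdf, a))]
        hi = self.grid[min(int(np.searchsorted(cdf, 1.0 - a)), len(self.grid) - 1)]
        return float(lo), float(hi)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.grid, size=n, p=self.probs)


def make_grid(step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    if not 0 < step <= 0.5:
        raise ValueError("grid step must lie in (0, 0.5]")
    n = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n + 1)


def expected_af(
    ccf: np.ndarray | float, purity: float, total_cn: int = 2, multiplicity: int = 1
) -> np.ndarray | float:
    """Expected allele fraction of a mutation at the given CCF."""
    denom = purity * total_cn + (1.0 - purity) * 2.0
    return np.clip(purity * multiplicity * np.asarray(ccf, dtype=float) / denom, 0.0, 1.0)


def ccf_log_likelihood_grid(
    alt: np.ndarray,
    depth: np.ndarray,
    purity: float,
    grid: np.ndarray,
    total_cn: np.ndarray | int = 2,
    multiplicity: np.ndarray | int = 1,
    error_rate: float = 0.0,
) -> np.ndarray:
    """Binomial log-likelihood of each mutation at each grid CCF.

    Vectorised workhorse shared by the posterior constructor, the clustering
    stage and the Monte-Carlo machinery. Returns shape ``(n_mut, n_grid)``.

    ``error_rate`` is a per-base sequencing error epsilon perturbing the
    expected fraction to ``af + eps * (1 - 2 af)``; without it a single
    stray alt read makes CCF = 0 impossible (-inf), which in turn shatters
    low-CCF clusters. Zero by default so the clean model stays exact.
    """
    alt = np.atleast_1d(np.asarray(alt))
    depth = np.atleast_1d(np.asarray(depth))
    q = np.broadcast_to(np.asarray(total_cn), alt.shape)
    m = np.broadcast_to(np.asarray(multiplicity), alt.shape)
    denom = purity * q + (1.0 - purity) * 2.0
    af = np.clip(purity * m[:, None] * grid[None, :] / denom[:, None], 0.0, 1.0)
    if error_rate:
        af = np.clip(af + error_rate * (1.0 - 2.0 * af), 0.0, 1.0)
    return binom.logpmf(alt[:, None], depth[:, None], af)


def af_to_ccf_posterior(
    obs: MutationObservation,
    purity: float,
    grid_step: float = DEFAULT_GRID_STEP,
) -> CCFPosterior:
    """Posterior over CCF for one observation, uniform prior on the grid."""
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    if obs.depth == 0:
        raise ValueError("observation has zero depth")
    if expected_af(1.0, purity, obs.total_cn, obs.multiplicity) <= 0:
        raise ValueError("model is degenerate: af(CCF=1) = 0")
    grid = make_grid(grid_step)
    ll = ccf_log_likelihood_grid(
        np.array([obs.alt_count]), np.array([obs.depth]), purity, grid,
        np.array([obs.total_cn]), np.array([obs.multiplicity]),
    )[0]
    probs = np.exp(ll - logsumexp(ll))
    return CCFPosterior(grid=grid, probs=probs)


def ccf_point_estimate(post: CCFPosterior, kind: str = "mode") -> float:
    if kind == "mode":
        return post.mode
    if kind == "mean":
        return post.mean
    raise ValueError(f"unknown point-estimate kind {kind!r}")


def best_multiplicity(
    alt: int, depth: int, purity: float, total_cn: int, grid_step: float = DEFAULT_GRID_STEP
) -> int:
    """Integer multiplicity in 1..q maximising the marginal likelihood.

    The marginal integrates the binomial likelihood over the uniform CCF
    grid; this is the simple surrogate for allele-specific multiplicity
    assignment when the minor copy number admits m > 1.
    """
    if total_cn < 1:
        raise ValueError("total copy number must be >= 1")
    grid = make_grid(grid_step)
    scores = []
    for m in range(1, total_cn + 1):
        ll = ccf_log_likelihood_grid(
            np.array([alt]), np.array([depth]), purity, grid,
            np.array([total_cn]), np.array([m]),
        )[0]
        scores.append(logsumexp(ll))
    return int(np.argmax(scores)) + 1
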