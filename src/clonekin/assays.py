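"""Statistics for the two orthogonal rare-cell validation assays.

Droplet-digital quantification: cells (or pooled amplicons) are
compartmentalised in emulsion droplets, so template occupancy follows a
Poisson law in the loading concentration and positive-droplet counts give
exact binomial frequency estimates — usable down to one mutant cell in
hundreds of thousands. A standard curve of known spike-in frequencies lets
an observed fluorescence signal be inverted to an input frequency.

Single-cell allele-specific genotyping: each cell reports a mutant-allele
and a normal-allele expression level. The mutant channel has a background
(leakage proportional to the normal signal) learned by linear regression on
known-negative cells; the background-corrected fractional mutant level is
then thresholded — below 0.15 called normal, above 0.3 called mutant,
anything in between unclear, and cells with no signal in either channel
(0/0) excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta

__all__ = [
    "DropletExperiment",
    "BackgroundModel",
    "poisson_occupancy",
    "occupancy_to_lambda",
    "estimate_mutant_frequency",
    "standard_curve_quantify",
    "fit_background_model",
    "call_single_cell_genotype",
    "call_genotypes",
    "consolidate_replicates",
    "NORMAL_THRESHOLD",
    "MUTANT_THRESHOLD",
]

#: fractional mutant level below which a cell is called normal
NORMAL_THRESHOLD = 0.15
#: fractional mutant level above which a cell is called mutant
MUTANT_THRESHOLD = 0.30


@dataclass
class DropletExperiment:
    """Counts from one droplet-digital screening run."""

    n_droplets: int
    n_positive: int
    cells_screened: int
    loading_lambda: float | None = None
    standard_curve: list[tuple[float, float]] | None = None  # (input freq, signal)

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= self.n_droplets:
            raise ValueError("need 0 <= n_positive <= n_droplets")
        if self.cells_screened <= 0:
            raise ValueError("cells_screened must be positive")


def poisson_occupancy(lam: float | np.ndarray) -> float | np.ndarray:
    """Fraction of droplets containing >= 1 template at loading lambda.

    Encapsulation is Poisson, so occupancy = 1 - exp(-lambda); keeping
    occupancy under ~30% keeps most positive droplets single-template.
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lambda must be non-negative")
    out = 1.0 - np.exp(-lam)
    return float(out) if out.ndim == 0 else out


def occupancy_to_lambda(occupancy: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`poisson_occupancy`."""
    occ = np.asarray(occupancy, dtype=float)
    if np.any((occ < 0) | (occ >= 1)):
        raise ValueError("occupancy must lie in [0, 1)")
    out = -np.log1p(-occ)
    return float(out) if out.ndim == 0 else out


def estimate_mutant_frequency(
    n_positive: int | DropletExperiment,
    cells_screened: int | None = None,
    level: float = 0.95,
) -> dict[str, float]:
    """Mutant-cell frequency with an exact (Clopper-Pearson) binomial CI.

    Exact intervals matter here: the frequencies of interest reach 10^-6,
    far outside the validity of normal approximations. Zero positives give
    CI [0, 1 - alpha/2 ** (1/n)].
    """
    if isinstance(n_positive, DropletExperiment):
        exp = n_positive
        k, n = exp.n_positive, exp.cells_screened
    else:
        k, n = n_positive, cells_screened
    if n is None or n <= 0:
        raise ValueError("cells_screened must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= n_positive <= cells_screened")
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1.0 - a, k + 1, n - k))
    return {"frequency": k / n, "ci_low": lo, "ci_high": hi, "n": float(n)}


def standard_curve_quantify(
    curve: list[tuple[float, float]],
    observed_signal: float,
) -> dict[str, float]:
    """Invert an observed signal through a log-log standard curve.

    The curve is known (input frequency, signal) pairs from spike-in
    dilutions (e.g. 1 in 10^4, 10^5, 10^6 engineered mutant cells); a
    least-squares line of log signal on log input frequency is fitted and
    solved for the frequency producing the observed signal. Signals outside
    the fitted range are still inverted but flagged as extrapolations.
    """
    pts = [(f, s) for f, s in curve]
    if len(pts) < 2:
        raise ValueError("need >= 2 standard-curve points")
    freqs = np.array([f for f, _ in pts], dtype=float)
    sigs = np.array([s for _, s in pts], dtype=float)
    if np.any(freqs <= 0) or np.any(sigs <= 0):
        raise ValueError("curve frequencies and signals must be positive")
    if np.ptp(np.log(freqs)) == 0:
        raise ValueError("all curve inputs identical; cannot fit a line")
    if observed_signal <= 0:
        raise ValueError("observed signal must be positive")
    x, y = np.log(freqs), np.log(sigs)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    intercept = y.mean() - slope * x.mean()
    if slope == 0:
        raise ValueError("flat standard curve; signal carries no information")
    est = float(np.exp((np.log(observed_signal) - intercept) / slope))
    return {
        "frequency": est,
        "slope": float(slope),
        "intercept": float(intercept),
        "extrapolated": bool(est < freqs.min() or est > freqs.max()),
    }


@dataclass
class BackgroundModel:
    """Mutant-channel background as a linear function of the normal signal."""

    slope: float
    intercept: float
    residual_sd: float
    n_cells: int

    def predict(self, normal_level: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(normal_level, dtype=float)


def fit_background_model(
    normal_cells: pd.DataFrame | np.ndarray,
    mutant_levels: np.ndarray | None = None,
) -> BackgroundModel:
    """Regress mutant-allele level on normal-allele level in known negatives.

    Accepts a frame with ``mutant_level``/``normal_level`` columns or two
    arrays (normal levels, mutant levels). Requires >= 3 usable cells.
    """
    if isinstance(normal_cells, pd.DataFrame):
        df = normal_cells.dropna(subset=["mutant_level", "normal_level"])
        x = df["normal_level"].to_numpy(dtype=float)
        y = df["mutant_level"].to_numpy(dtype=float)
    else:
        x = np.asarray(normal_cells, dtype=float)
        y = np.asarray(mutant_levels, dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need >= 3 usable negative cells, got {len(x)}")
    sxx = np.sum((x - x.mean()) ** 2)
    slope = 0.0 if sxx == 0 else float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sd = float(np.sqrt(np.sum(resid**2) / max(len(x) - 2, 1)))
    return BackgroundModel(slope=slope, intercept=intercept, residual_sd=sd, n_cells=len(x))


def call_single_cell_genotype(
    mutant_level: float,
    normal_level: float,
    background: BackgroundModel | None = None,
) -> str:
    """Call one cell as normal / mutant / unclear / excluded.

    The mutant level is background-corrected, m' = max(0, m - predicted
    background), and the fractional mutant level f = m' / (normal + m')
    thresholded: f < 0.15 normal, f > 0.3 mutant, the closed interval
    [0.15, 0.3] unclear. Cells with neither allele detected (0/0) are
    excluded.
    """
    if mutant_level < 0 or normal_level < 0:
        raise ValueError("allele levels must be non-negative")
    m = mutant_level
    if background is not None:
        m = max(0.0, mutant_level - float(background.predict(normal_level)))
    if m == 0 and normal_level == 0:
        return "excluded"
    f = m / (normal_level + m)
    if f < NORMAL_THRESHOLD:
        return "normal"
    if f > MUTANT_THRESHOLD:
        return "mutant"
    return "unclear"


def consolidate_replicates(replicates: list[pd.DataFrame]) -> pd.DataFrame:
    """Average allele levels across technical replicates, per cell."""
    if not replicates:
        raise ValueError("no replicates supplied")
    merged = pd.concat(replicates, ignore_index=True)
    return (
        merged.groupby("cell_id", as_index=False, sort=False)[
            ["mutant_level", "normal_level"]
        ].mean()
    )


def call_genotypes(
    cells: pd.DataFrame,
    background: BackgroundModel | None = None,
) -> pd.DataFrame:
    """Vector form of :func:`call_single_cell_genotype` over a signal table."""
    calls = [
        call_single_cell_genotype(m, n, background)
        for m, n in zip(cells["mutant_level"], cells["normal_level"])
    ]
    out = cells.copy()
    out["call"] = calls
    return out
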