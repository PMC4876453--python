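"""Absolute clone sizes and per-clone exponential growth/decline kinetics.

Clone fractions become absolute circulating cell counts by multiplying by
the total tumour burden, itself the absolute lymphocyte count (ALC, cells
per microlitre) times the blood volume (default 5 l). Each clone is then
assumed to grow or decline exponentially at a constant rate g during
therapy:

    N_c(t) = N_c(0) * exp(g_c * t)

so ln N is linear in time. Clones observed at exactly two time points get
the closed-form rate ln(N2/N1)/(t2-t1) with an uncertainty propagated by
Monte-Carlo resampling of the CCF posteriors; clones with more points get
ordinary least squares of ln(count) on day with the regression s.e. of the
slope. Back-extrapolating the fitted line to day 0 (therapy initiation)
estimates how large the clone was before treatment selected for it, with
CIs again from posterior resampling. Clones below the sequencing detection
threshold are capped by an upper bound (default 1% of total tumour cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SampleMeta",
    "TrajectoryPoint",
    "CloneTrajectory",
    "GrowthFit",
    "InsufficientDataError",
    "NoResidualError",
    "total_cll_cells",
    "clone_cell_counts",
    "undetected_upper_bound",
    "fit_growth_rate",
    "fit_shared_rate",
    "fit_rate_from_alc",
    "extrapolate_initial_size",
    "predict_alc",
    "frequency_formats",
]

DEFAULT_BLOOD_VOLUME_L = 5.0
DEFAULT_DETECTION_CCF = 0.01
DEFAULT_UPPER_BOUND_FRACTION = 0.01
#: counts are floored at one cell before taking logs in Monte-Carlo refits
LOG_FLOOR_CELLS = 1.0


class InsufficientDataError(ValueError):
    """Fewer than two detected positive observations; rate not identifiable."""


class NoResidualError(ValueError):
    """All ALC residuals are non-positive; no unexplained population to fit."""


@dataclass
class SampleMeta:
    """Per-sample clinical metadata (day relative to therapy start)."""

    sample: str
    patient: str
    day: int
    purity: float
    alc_per_ul: float

    def __post_init__(self) -> None:
        if self.alc_per_ul < 0:
            raise ValueError("ALC must be non-negative")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must lie in (0, 1]")


@dataclass
class TrajectoryPoint:
    day: float
    cells: float
    ci_low: float
    ci_high: float
    detected: bool
    upper_bound: float | None = None  # cap for undetected days

    def __post_init__(self) -> None:
        if self.cells < 0:
            raise ValueError("cell counts must be non-negative")
        if not self.ci_low <= self.cells <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


@dataclass
class CloneTrajectory:
    """Time series of absolute cell counts for one clone."""

    clone_id: int
    points: list[TrajectoryPoint] = field(default_factory=list)

    def detected(self) -> list[TrajectoryPoint]:
        return [p for p in self.points if p.detected]

    def detected_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        pts = self.detected()
        return (np.array([p.day for p in pts]), np.array([p.cells for p in pts]))


@dataclass
class GrowthFit:
    """Fitted exponential kinetics for one clone.

    ``rate_sd`` is a Monte-Carlo s.d. for two-point fits and the regression
    s.e. of the slope for >2-point fits (``method`` records which).
    ``rate_is_lower_bound`` flags fits whose earliest point was an upper
    bound, so the true rate can only be larger.
    """

    clone_id: int
    rate: float
    rate_sd: float
    intercept: float               # ln(cells) at day 0
    n_points: int
    method: str                    # two_point | regression | alc_fit | shared
    rate_ci: tuple[float, float] | None = None
    n0: float = float("nan")
    n0_ci: tuple[float, float] | None = None
    one_in_n_at_day0: float | None = None
    rate_is_lower_bound: bool = False

    def predict(self, days: np.ndarray) -> np.ndarray:
        return np.exp(self.intercept + self.rate * np.asarray(days, dtype=float))


def total_cll_cells(
    meta: SampleMeta | float, blood_volume_l: float = DEFAULT_BLOOD_VOLUME_L
) -> float:
    """Total circulating tumour cells: ALC/ul x blood volume in ul."""
    alc = meta.alc_per_ul if isinstance(meta, SampleMeta) else float(meta)
    if alc < 0:
        raise ValueError("ALC must be non-negative")
    if blood_volume_l <= 0:
        raise ValueError("blood volume must be positive")
    return alc * blood_volume_l * 1e6


def undetected_upper_bound(
    meta: SampleMeta | float,
    bound_fraction: float = DEFAULT_UPPER_BOUND_FRACTION,
    blood_volume_l: float = DEFAULT_BLOOD_VOLUME_L,
) -> float:
    """Cap on an undetected clone's size: a fixed fraction of all tumour cells."""
    if not 0 < bound_fraction < 1:
        raise ValueError("bound_fraction must lie in (0, 1)")
    return bound_fraction * total_cll_cells(meta, blood_volume_l)


def clone_cell_counts(
    fractions: dict[int, np.ndarray],
    metas: list[SampleMeta],
    fraction_draws: dict[int, np.ndarray] | None = None,
    detection_ccf: float = DEFAULT_DETECTION_CCF,
    upper_bound_fraction: float = DEFAULT_UPPER_BOUND_FRACTION,
    blood_volume_l: float = DEFAULT_BLOOD_VOLUME_L,
) -> dict[int, CloneTrajectory]:
    """Convert per-sample clone fractions to absolute-count trajectories.

    ``fractions[c]`` holds clone c's fraction at each sample (exclusive or
    inclusive, per the caller's accounting mode). ``fraction_draws[c]`` may
    supply posterior draws ``(n_draws, n_samples)`` from which 95% CIs are
    taken; without draws the CI degenerates to the point estimate. A day is
    flagged undetected when the fraction falls below ``detection_ccf``, and
    carries the upper-bound cap instead.
    """
    metas = sorted(metas, key=lambda m: m.day)
    totals = np.array([total_cll_cells(m, blood_volume_l) for m in metas])
    out: dict[int, CloneTrajectory] = {}
    for clone, frac in fractions.items():
        frac = np.asarray(frac, dtype=float)
        if len(frac) != len(metas):
            raise ValueError("fraction vector length must match sample metadata")
        draws = None if fraction_draws is None else np.asarray(fraction_draws[clone])
        traj = CloneTrajectory(clone_id=clone)
        for i, m in enumerate(metas):
            cells = frac[i] * totals[i]
            if draws is not None:
                lo, hi = np.percentile(draws[:, i] * totals[i], [2.5, 97.5])
                lo, hi = min(lo, cells), max(hi, cells)
            else:
                lo = hi = cells
            detected = frac[i] >= detection_ccf
            traj.points.append(TrajectoryPoint(
                day=m.day,
                cells=cells,
                ci_low=lo,
                ci_high=hi,
                detected=bool(detected),
                upper_bound=None if detected else undetected_upper_bound(
                    m, upper_bound_fraction, blood_volume_l
                ),
            ))
        out[clone] = traj
    return out


def _ols_line(days: np.ndarray, logs: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and s.e.(slope) of ln(count) on day."""
    t = np.asarray(days, dtype=float)
    y = np.asarray(logs, dtype=float)
    tbar = t.mean()
    sxx = np.sum((t - tbar) ** 2)
    if sxx == 0:
        raise ValueError("degenerate design: all observations on the same day")
    slope = np.sum((t - tbar) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * tbar
    n = len(t)
    if n > 2:
        resid = y - (intercept + slope * t)
        se = float(np.sqrt(np.sum(resid**2) / (n - 2) / sxx))
    else:
        se = float("nan")
    return float(slope), float(intercept), se


def _ols_draws(days: np.ndarray, count_draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-draw OLS: slopes and intercepts, one per draw row."""
    t = np.asarray(days, dtype=float)
    y = np.log(np.maximum(count_draws, LOG_FLOOR_CELLS))
    tbar = t.mean()
    sxx = np.sum((t - tbar) ** 2)
    slopes = ((t - tbar) * (y - y.mean(axis=1, keepdims=True))).sum(axis=1) / sxx
    intercepts = y.mean(axis=1) - slopes * tbar
    return slopes, intercepts


def fit_growth_rate(
    traj: CloneTrajectory,
    count_draws: np.ndarray | None = None,
    include_upper_bounds: bool = False,
) -> GrowthFit:
    """Fit a constant exponential rate to one clone's detected counts.

    Two points: the closed form g = ln(N2/N1)/(t2-t1), with s.d. and 95% CI
    from ``count_draws`` (posterior resamples of the counts, shape
    ``(n_draws, n_detected_points)``) when supplied. More points: OLS of
    ln(count) on day, reporting the regression s.e. of the slope; the CI
    again comes from draws when available, else from normal theory.

    ``include_upper_bounds`` additionally uses upper-bound entries as if
    they were measurements; if the earliest point used is a bound, the
    fitted rate is flagged as a lower bound on the true rate.
    """
    pts = traj.detected()
    used = list(pts)
    lower_bound_flag = False
    if include_upper_bounds:
        bounds = [p for p in traj.points if not p.detected and p.upper_bound]
        used = sorted(used + bounds, key=lambda p: p.day)
        if used and not used[0].detected:
            lower_bound_flag = True
    if len(used) < 2:
        raise InsufficientDataError(
            f"clone {traj.clone_id}: {len(used)} usable points; need >= 2 "
            "(consider upper bounds or fitting to the ALC residual)"
        )
    days = np.array([p.day for p in used], dtype=float)
    cells = np.array([p.cells if p.detected else p.upper_bound for p in used], dtype=float)
    if np.any(cells[np.array([p.detected for p in used])] <= 0):
        raise ValueError(
            f"clone {traj.clone_id}: zero count among detected points; "
            "use upper bounds instead"
        )

    if len(used) == 2:
        if days[1] == days[0]:
            raise ValueError("degenerate design: both observations on the same day")
        g = float(np.log(cells[1] / cells[0]) / (days[1] - days[0]))
        intercept = float(np.log(cells[0]) - g * days[0])
        method = "two_point"
        se = float("nan")
    else:
        g, intercept, se = _ols_line(days, np.log(cells))
        method = "regression"

    rate_sd, rate_ci, n0_ci = se, None, None
    if count_draws is not None:
        count_draws = np.asarray(count_draws, dtype=float)
        if count_draws.shape[1] != len(used):
            raise ValueError("count_draws must have one column per fitted point")
        slopes, intercepts = _ols_draws(days, count_draws)
        rate_sd = float(np.std(slopes, ddof=1))
        rate_ci = tuple(np.percentile(slopes, [2.5, 97.5]))
        n0_ci = tuple(np.exp(np.percentile(intercepts, [2.5, 97.5])))
    elif np.isfinite(se):
        rate_ci = (g - 1.96 * se, g + 1.96 * se)

    n0 = float(np.exp(intercept))
    if n0_ci is not None:
        n0_ci = (min(n0_ci[0], n0), max(n0_ci[1], n0))
    return GrowthFit(
        clone_id=traj.clone_id,
        rate=g,
        rate_sd=rate_sd,
        intercept=intercept,
        n_points=len(used),
        method=method,
        rate_ci=rate_ci,
        n0=n0,
        n0_ci=n0_ci,
        rate_is_lower_bound=lower_bound_flag,
    )


def fit_shared_rate(
    trajectories: dict[int, CloneTrajectory],
    groups: list[list[int]] | None = None,
) -> dict[int, GrowthFit]:
    """Fit one common rate per clone group, clone-specific intercepts.

    In the log domain the model is a set of parallel lines: ln N_c(t) =
    a_c + g * t for every clone c in a group. Used when biologically
    related clones (e.g. a parent and its sibling progeny) are assumed to
    share kinetics, which stabilises rates estimated from few points each.
    Singleton groups reduce exactly to :func:`fit_growth_rate`.
    """
    groups = groups or [list(trajectories)]
    fits: dict[int, GrowthFit] = {}
    for group in groups:
        if len(group) == 1:
            c = group[0]
            f = fit_growth_rate(trajectories[c])
            f.method = "shared"
            fits[c] = f
            continue
        rows_t, rows_y, rows_c = [], [], []
        for c in group:
            t, n = trajectories[c].detected_arrays()
            if np.any(n <= 0):
                raise ValueError(f"clone {c}: non-positive detected count")
            rows_t.append(t)
            rows_y.append(np.log(n))
            rows_c.append(np.full(len(t), c))
        t = np.concatenate(rows_t)
        y = np.concatenate(rows_y)
        who = np.concatenate(rows_c)
        if len(t) < 2 or np.ptp(t) == 0:
            raise ValueError("degenerate design: need observations spanning >= 2 days")
        # design: one intercept dummy per clone + shared slope column
        X = np.column_stack([(who == c).astype(float) for c in group] + [t])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        g = float(beta[-1])
        resid = y - X @ beta
        dof = max(len(y) - X.shape[1], 1)
        cov = np.linalg.pinv(X.T @ X) * float(resid @ resid) / dof
        se = float(np.sqrt(cov[-1, -1]))
        for i, c in enumerate(group):
            a = float(beta[i])
            fits[c] = GrowthFit(
                clone_id=c,
                rate=g,
                rate_sd=se,
                intercept=a,
                n_points=int(np.sum(who == c)),
                method="shared",
                rate_ci=(g - 1.96 * se, g + 1.96 * se),
                n0=float(np.exp(a)),
            )
    return fits


def fit_rate_from_alc(
    days: np.ndarray,
    alc_per_ul: np.ndarray,
    other_fits: list[GrowthFit],
    clone_id: int = -1,
    blood_volume_l: float = DEFAULT_BLOOD_VOLUME_L,
    floor_cells: float = LOG_FLOOR_CELLS,
) -> GrowthFit:
    """Fit a clone seen too rarely to regress directly, from the ALC residual.

    The total burden ALC x V minus the summed predictions of all fitted
    clones leaves an unexplained residual population; that residual is
    fitted as a single exponential in the log domain. Negative residuals
    are floored at ``floor_cells`` with a warning.
    """
    days = np.asarray(days, dtype=float)
    totals = np.array([total_cll_cells(a, blood_volume_l) for a in np.asarray(alc_per_ul)])
    explained = np.zeros_like(totals)
    for f in other_fits:
        explained += f.predict(days)
    resid = totals - explained
    if np.all(resid <= 0):
        raise NoResidualError("no residual population: fitted clones explain the ALC")
    if np.any(resid <= 0):
        warnings.warn(
            f"{int(np.sum(resid <= 0))} non-positive ALC residuals floored at "
            f"{floor_cells} cells",
            stacklevel=2,
        )
        resid = np.maximum(resid, floor_cells)
    g, intercept, se = (
        _ols_line(days, np.log(resid)) if len(days) > 2
        else (*_two_point(days, resid), float("nan"))
    )
    return GrowthFit(
        clone_id=clone_id,
        rate=g,
        rate_sd=se,
        intercept=intercept,
        n_points=len(days),
        method="alc_fit",
        rate_ci=None if not np.isfinite(se) else (g - 1.96 * se, g + 1.96 * se),
        n0=float(np.exp(intercept)),
    )


def _two_point(days: np.ndarray, cells: np.ndarray) -> tuple[float, float]:
    g = float(np.log(cells[1] / cells[0]) / (days[1] - days[0]))
    return g, float(np.log(cells[0]) - g * days[0])


EXTRAPOLATION_WINDOW_DAYS = 1e4


def extrapolate_initial_size(
    fit: GrowthFit,
    days: np.ndarray | None = None,
    count_draws: np.ndarray | None = None,
    day0_total_cells: float | None = None,
) -> GrowthFit:
    """Back-extrapolate the fitted exponential to therapy initiation (day 0).

    N0 = exp(intercept). When posterior ``count_draws`` (aligned with
    ``days``) are given, the fit is repeated per draw and the 2.5/97.5
    percentiles of the per-draw N0 form the 95% CI — the CCF-posterior
    uncertainty propagated through the whole fit. With a day-0 tumour
    burden available the size is also expressed as "1 in N" of all cells.
    Returns an updated copy of ``fit``.
    """
    if not np.isfinite(fit.rate):
        raise ValueError("cannot extrapolate a non-finite rate")
    if days is not None and np.min(np.abs(np.asarray(days))) > EXTRAPOLATION_WINDOW_DAYS:
        warnings.warn("day 0 is far outside the observation window", stacklevel=2)
    n0 = float(np.exp(fit.intercept))
    n0_ci = fit.n0_ci
    if count_draws is not None:
        if days is None:
            raise ValueError("days required alongside count_draws")
        _slopes, intercepts = _ols_draws(np.asarray(days, dtype=float), np.asarray(count_draws))
        lo, hi = np.exp(np.percentile(intercepts, [2.5, 97.5]))
        n0_ci = (min(float(lo), n0), max(float(hi), n0))
    one_in_n = None
    if day0_total_cells is not None and n0 > 0:
        one_in_n = float(round(day0_total_cells / n0))
    return GrowthFit(
        clone_id=fit.clone_id,
        rate=fit.rate,
        rate_sd=fit.rate_sd,
        intercept=fit.intercept,
        n_points=fit.n_points,
        method=fit.method,
        rate_ci=fit.rate_ci,
        n0=n0,
        n0_ci=n0_ci,
        one_in_n_at_day0=one_in_n,
        rate_is_lower_bound=fit.rate_is_lower_bound,
    )


def predict_alc(
    fits: list[GrowthFit],
    days: np.ndarray,
    blood_volume_l: float = DEFAULT_BLOOD_VOLUME_L,
    observed_alc_per_ul: np.ndarray | None = None,
) -> tuple[np.ndarray, float | None]:
    """Predicted ALC(t) = sum_c N0_c e^{g_c t} / (V x 10^6), plus log-RMSE.

    A good fit of the summed fitted clones to the observed lymphocyte
    counts is the consistency check that constant per-clone rates explain
    the whole-blood dynamics.
    """
    days = np.asarray(days, dtype=float)
    total = np.zeros_like(days)
    for f in fits:
        total += f.predict(days)
    pred = total / (blood_volume_l * 1e6)
    rmse = None
    if observed_alc_per_ul is not None:
        obs = np.asarray(observed_alc_per_ul, dtype=float)
        rmse = float(np.sqrt(np.mean((np.log(pred) - np.log(obs)) ** 2)))
    return pred, rmse


def frequency_formats(cells: float, total_cells: float) -> dict[str, float]:
    """A clone size as fraction, percent and "1 in N" of the total population."""
    if total_cells <= 0:
        raise ValueError("total_cells must be positive")
    if not 0 <= cells <= total_cells:
        raise ValueError("cells must lie in [0, total_cells]")
    fraction = cells / total_cells
    return {
        "fraction": fraction,
        "percent": 100.0 * fraction,
        "one_in_N": float(round(total_cells / cells)) if cells > 0 else float("inf"),
    }
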