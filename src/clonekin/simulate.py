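"""Synthetic longitudinal patients with known clonal ground truth.

The generator produces everything the downstream stages consume: a rooted
clone tree whose clones grow or decline exponentially at constant per-day
rates, serial absolute lymphocyte counts (ALC) derived from the summed clone
sizes, per-mutation read counts at a given depth and purity, and assay-level
signals (droplet positives, single-cell allele levels).

Clone sizes are accounted *exclusively*: ``TruthSet.cells`` holds the number
of cells belonging to each clone and to none of its descendants, so clone
sizes sum exactly to the circulating tumour burden. Inclusive cancer cell
fractions (the CCF a sequenced mutation reports, which covers the clone and
all its descendants) are derived, never stored as primary truth.

Time is measured in days; day 0 is therapy initiation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "TruthSet",
    "AssaySignalParams",
    "simulate_clonal_dynamics",
    "simulate_sequencing",
    "simulate_assay_data",
]

_BASES = np.array(list("ACGT"))

#: litres of peripheral blood assumed when converting ALC to absolute counts
DEFAULT_BLOOD_VOLUME_L = 5.0


@dataclass
class SimConfig:
    """Full specification of one synthetic patient.

    Parameters
    ----------
    parent
        ``clone_id -> parent_id`` mapping; exactly one clone has parent
        ``None`` (the root / trunk, the clone carried by all tumour cells).
    initial_sizes
        Cells per clone at day 0 (exclusive counts), all > 0.
    rates_per_day
        Per-clone constant exponential rate g (1/day). Declines around
        -0.002/day and growths of 0.015-0.045/day are the realistic range
        for kinase-inhibitor-resistant CLL clones.
    sample_days
        Days from therapy start at which blood is drawn; strictly increasing.
    depth
        Mean sequencing depth (reads) for the read-count simulator.
    purity_per_sample
        Tumour purity of each sample, each in (0, 1]. A scalar is broadcast.
    muts_per_clone
        Somatic mutations private to each clone (they mark its lineage).
    blood_volume_l
        Peripheral blood volume in litres (default 5).
    seed
        Seed for all randomness derived from this configuration.
    """

    parent: Mapping[int, int | None]
    initial_sizes: Mapping[int, float]
    rates_per_day: Mapping[int, float]
    sample_days: Sequence[int]
    depth: float = 150.0
    purity_per_sample: Sequence[float] | float = 0.9
    muts_per_clone: int = 10
    blood_volume_l: float = DEFAULT_BLOOD_VOLUME_L
    seed: int = 0
    sequencing_error_rate: float = 0.0  # per-base error added to E[af]; off by default

    @property
    def clones(self) -> list[int]:
        return sorted(self.parent)

    @property
    def n_clones(self) -> int:
        return len(self.parent)

    def purities(self) -> np.ndarray:
        p = self.purity_per_sample
        if np.isscalar(p):
            p = [float(p)] * len(self.sample_days)
        return np.asarray(p, dtype=float)

    def validate(self) -> None:
        roots = [c for c, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"exactly one root clone required, found {len(roots)}")
        for c in self.clones:
            seen = {c}
            node = self.parent[c]
            while node is not None:
                if node not in self.parent:
                    raise ValueError(f"parent {node} of clone {c} is not a clone")
                if node in seen:
                    raise ValueError(f"cycle in parent map involving clone {node}")
                seen.add(node)
                node = self.parent[node]
        for c in self.clones:
            if not self.initial_sizes.get(c, 0) > 0:
                raise ValueError(f"initial size of clone {c} must be positive")
            if c not in self.rates_per_day:
                raise ValueError(f"missing rate for clone {c}")
        days = np.asarray(self.sample_days)
        if len(days) == 0 or np.any(np.diff(days) <= 0):
            raise ValueError("sample_days must be non-empty and strictly increasing")
        pur = self.purities()
        if len(pur) != len(days):
            raise ValueError("purity_per_sample length must match sample_days")
        if np.any((pur <= 0) | (pur > 1)):
            raise ValueError("purities must lie in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.muts_per_clone < 1:
            raise ValueError("muts_per_clone must be >= 1")
        if self.blood_volume_l <= 0:
            raise ValueError("blood volume must be positive")


@dataclass
class TruthSet:
    """Ground truth for one synthetic patient (bookkeeping container).

    ``cells`` is a clones x days table of *exclusive* cell counts; at each
    sampled day the column sum equals ``alc_per_ul * blood volume in ul``.
    A mutation's true CCF equals the *inclusive* fraction of its clone, i.e.
    the summed exclusive fraction of the clone and all of its descendants.
    """

    config: SimConfig
    cells: pd.DataFrame          # index: clone id, columns: day
    alc_per_ul: pd.Series        # index: day
    inclusive_ccf: pd.DataFrame  # index: clone id, columns: day
    mutations: pd.DataFrame      # mut_id, clone, chrom, pos, ref, alt, gene
    sample_ids: list[str] = field(default_factory=list)

    @property
    def days(self) -> np.ndarray:
        return np.asarray(self.cells.columns)

    def total_cells(self) -> pd.Series:
        return self.cells.sum(axis=0)

    def exclusive_fraction(self) -> pd.DataFrame:
        return self.cells / self.total_cells()

    def descendants(self, clone: int) -> list[int]:
        out, stack = [], [clone]
        children = {c: [k for k, p in self.config.parent.items() if p == c]
                    for c in self.config.clones}
        while stack:
            for ch in children[stack.pop()]:
                out.append(ch)
                stack.append(ch)
        return out

    def mutation_ccf(self) -> pd.DataFrame:
        """True CCF per mutation (rows) per day (columns)."""
        return self.inclusive_ccf.loc[self.mutations["clone"].to_numpy()].set_axis(
            self.mutations["mut_id"], axis=0
        )


def simulate_clonal_dynamics(config: SimConfig) -> TruthSet:
    """Evolve every clone as N_c(t) = N_c(0) * exp(g_c * t).

    Deterministic apart from the cosmetic mutation coordinates, which are
    drawn from ``config.seed``. ALC(t) is the summed exclusive clone sizes
    divided by the blood volume in microlitres.
    """
    config.validate()
    clones = config.clones
    days = np.asarray(config.sample_days, dtype=float)

    n0 = np.array([config.initial_sizes[c] for c in clones], dtype=float)
    g = np.array([config.rates_per_day[c] for c in clones], dtype=float)
    cells = pd.DataFrame(
        n0[:, None] * np.exp(g[:, None] * days[None, :]),
        index=clones, columns=config.sample_days,
    )
    total = cells.sum(axis=0)
    alc = total / (config.blood_volume_l * 1e6)

    truth = TruthSet(
        config=config,
        cells=cells,
        alc_per_ul=alc,
        inclusive_ccf=pd.DataFrame(index=clones, columns=config.sample_days, dtype=float),
        mutations=pd.DataFrame(),
        sample_ids=[f"S{i + 1}" for i in range(len(config.sample_days))],
    )
    for c in clones:
        lineage = [c] + truth.descendants(c)
        truth.inclusive_ccf.loc[c] = cells.loc[lineage].sum(axis=0) / total

    rng = np.random.default_rng(config.seed)
    rows = []
    for c in clones:
        for j in range(config.muts_per_clone):
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append({
                "mut_id": f"c{c}m{j}",
                "clone": c,
                "chrom": str(rng.integers(1, 23)),
                "pos": int(rng.integers(1, 200_000_000)),
                "ref": _BASES[ref],
                "alt": _BASES[alt],
                "gene": f"GENE_c{c}_{j}",
            })
    truth.mutations = pd.DataFrame(rows)
    return truth


def simulate_sequencing(
    truth: TruthSet,
    depth: float | None = None,
    purity: Sequence[float] | float | None = None,
    seed: int | None = None,
    total_cn: int = 2,
    multiplicity: int = 1,
    error_rate: float | None = None,
    patient: str = "P1",
) -> pd.DataFrame:
    """Draw alt/ref read counts for every mutation in every sample.

    The expected allele fraction inverts the CCF model used downstream:
    ``af = purity * m * CCF / (purity * q + (1 - purity) * 2)`` with
    multiplicity ``m`` and local total copy number ``q``. Per-site depth is
    Poisson around the mean depth (floored at 1 read); the alt count is
    binomial. An optional per-base error rate epsilon perturbs the expected
    fraction to ``af + eps * (1 - 2 af)``.
    """
    cfg = truth.config
    depth = cfg.depth if depth is None else depth
    if depth <= 0:
        raise ValueError("depth must be positive")
    purities = cfg.purities() if purity is None else (
        np.full(len(cfg.sample_days), purity) if np.isscalar(purity)
        else np.asarray(purity, dtype=float)
    )
    eps = cfg.sequencing_error_rate if error_rate is None else error_rate
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)

    ccf = truth.mutation_ccf().to_numpy()          # (n_mut, n_days)
    n_mut, n_days = ccf.shape
    denom = purities * total_cn + (1 - purities) * 2.0
    af = np.clip(purities * multiplicity * ccf / denom, 0.0, 1.0)
    if eps:
        af = np.clip(af + eps * (1 - 2 * af), 0.0, 1.0)
    site_depth = np.maximum(rng.poisson(depth, size=(n_mut, n_days)), 1)
    alt = rng.binomial(site_depth, af)

    muts = truth.mutations
    frames = []
    for i, (day, sample) in enumerate(zip(cfg.sample_days, truth.sample_ids)):
        frames.append(pd.DataFrame({
            "patient": patient,
            "sample": sample,
            "day": day,
            "chrom": muts["chrom"],
            "pos": muts["pos"],
            "ref": muts["ref"],
            "alt": muts["alt"],
            "gene": muts["gene"],
            "mut_id": muts["mut_id"],
            "clone": muts["clone"],
            "t_alt_count": alt[:, i],
            "t_ref_count": site_depth[:, i] - alt[:, i],
            "total_cn": total_cn,
            "multiplicity": multiplicity,
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class AssaySignalParams:
    """Signal model for the single-cell genotyping simulator.

    ``mutant_level`` is the expression added by a true mutant allele;
    ``background_slope`` leaks a fraction of the normal-allele signal into
    the mutant channel (what the background regression must learn);
    ``dropout`` is the probability that a cell yields no signal at all
    (the 0/0 exclusion case).
    """

    mutant_level: float = 1.0
    normal_level: float = 1.0
    background_slope: float = 0.02
    noise_sd: float = 0.05
    dropout: float = 0.02


def simulate_assay_data(
    truth: TruthSet,
    day: int,
    target_clone: int,
    n_cells_droplet: int,
    n_cells_singlecell: int = 200,
    params: AssaySignalParams | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulate the two validation assays against a target clone's mutation.

    Returns ``(droplets, cells)``: a one-row droplet count table (positives
    among ``n_cells_droplet`` screened cells at the clone's true inclusive
    prevalence) and a single-cell signal table with mutant/normal allele
    levels under the configured background model.
    """
    if n_cells_droplet <= 0:
        raise ValueError("n_cells_screened must be positive")
    params = params or AssaySignalParams()
    rng = np.random.default_rng(seed)
    prevalence = float(truth.inclusive_ccf.loc[target_clone, day])
    # prevalence among *all* circulating cells; samples here are pure tumour

    n_pos = rng.binomial(n_cells_droplet, prevalence)
    droplets = pd.DataFrame([{
        "assay": f"clone{target_clone}_d{day}",
        "cells_screened": n_cells_droplet,
        "n_positive": int(n_pos),
        "true_prevalence": prevalence,
    }])

    is_mut = rng.random(n_cells_singlecell) < prevalence
    normal = np.maximum(rng.normal(params.normal_level, params.noise_sd, n_cells_singlecell), 0.0)
    mutant = np.maximum(
        params.background_slope * normal
        + np.where(is_mut, params.mutant_level, 0.0)
        + rng.normal(0.0, params.noise_sd, n_cells_singlecell),
        0.0,
    )
    dropped = rng.random(n_cells_singlecell) < params.dropout
    normal[dropped] = 0.0
    mutant[dropped] = 0.0
    cells = pd.DataFrame({
        "cell_id": [f"cell{i}" for i in range(n_cells_singlecell)],
        "assay": f"clone{target_clone}_d{day}",
        "mutant_level": mutant,
        "normal_level": normal,
        "true_mutant": is_mut,
    })
    return droplets, cells
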