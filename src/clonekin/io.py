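"""Readers, writers and configuration for the pipeline's table formats.

Conventions: all coordinates are 1-based (MAF/VCF style) and segment
intervals are end-inclusive. Mutation tables may arrive as TSV or VCF
(allele depths taken from AD-style fields); everything written out is
plain TSV/JSON/newick so results stay diffable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import SampleMeta
from .phylogeny import CloneTree

__all__ = [
    "MUTATION_COLUMNS",
    "SAMPLE_COLUMNS",
    "SEGMENT_COLUMNS",
    "PipelineConfig",
    "parse_config",
    "read_mutations_tsv",
    "read_mutations_vcf",
    "read_variants",
    "read_samples",
    "read_segments",
    "write_table",
    "write_tree",
    "read_tree_json",
]

MUTATION_COLUMNS = [
    "patient", "sample", "chrom", "pos", "ref", "alt", "gene",
    "t_alt_count", "t_ref_count",
]
SAMPLE_COLUMNS = ["sample", "patient", "day", "purity", "alc_per_ul"]
SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn"]


def _require_columns(df: pd.DataFrame, required: list[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required columns {missing}; expected at least {required}"
        )


def read_mutations_tsv(path: str | Path) -> pd.DataFrame:
    """Read a MAF-like mutation TSV; 1-based positions are enforced."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, MUTATION_COLUMNS, path)
    if len(df) == 0:
        raise ValueError(f"{path}: empty mutation table (columns {MUTATION_COLUMNS})")
    bad = df.index[df["pos"] < 1]
    if len(bad):
        raise ValueError(
            f"{path}: rows {bad.tolist()} have pos < 1; coordinates are 1-based"
        )
    if (df[["t_alt_count", "t_ref_count"]] < 0).any().any():
        raise ValueError(f"{path}: negative read counts")
    return df


def read_mutations_vcf(
    path: str | Path, patient: str | None = None, sample: str | None = None
) -> pd.DataFrame:
    """Read somatic variants from a VCF, one row per (record, alt allele).

    Allele depths come from the per-sample AD field (ref first, then one
    entry per alt allele); multiallelic records are split. Records without
    usable depths are skipped with a warning giving the count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_name = sample or (vcf.samples[0] if vcf.samples else "S1")
    sample_idx = vcf.samples.index(sample_name) if vcf.samples else None
    rows, skipped = [], 0
    for var in vcf:
        ad = None
        if sample_idx is not None:
            try:
                ad = var.format("AD")
            except Exception:
                ad = None
        if ad is None:
            skipped += 1
            continue
        depths = np.asarray(ad[sample_idx]).ravel()
        if len(depths) < 1 + len(var.ALT) or np.any(depths < 0):
            skipped += 1
            continue
        for i, alt in enumerate(var.ALT):
            rows.append({
                "patient": patient or sample_name,
                "sample": sample_name,
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": alt,
                "gene": (var.INFO.get("GENE") or ""),
                "t_alt_count": int(depths[1 + i]),
                "t_ref_count": int(depths[0]),
            })
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} records without usable AD depths",
                      stacklevel=2)
    if not rows:
        raise ValueError(f"{path}: no usable variant records")
    return pd.DataFrame(rows)


def read_variants(path: str | Path, fmt: str | None = None, **kwargs) -> pd.DataFrame:
    """Dispatch on format (``tsv`` or ``vcf``; inferred from the suffix)."""
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "tsv":
        return read_mutations_tsv(path)
    if fmt == "vcf":
        return read_mutations_vcf(path, **kwargs)
    raise ValueError(f"unknown mutation format {fmt!r}")


def read_samples(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, SAMPLE_COLUMNS, path)
    if df.duplicated(["patient", "day"]).any():
        raise ValueError(f"{path}: duplicate (patient, day) entries")
    return [
        SampleMeta(
            sample=str(r["sample"]), patient=str(r["patient"]), day=int(r["day"]),
            purity=float(r["purity"]), alc_per_ul=float(r["alc_per_ul"]),
        )
        for r in df.to_dict("records")
    ]


def read_segments(path: str | Path) -> pd.DataFrame:
    """Allele-specific copy-number segments; 1-based end-inclusive intervals."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, SEGMENT_COLUMNS, path)
    if (df["start"] < 1).any() or (df["end"] < df["start"]).any():
        raise ValueError(f"{path}: segments must satisfy 1 <= start <= end")
    return df


def lookup_copy_number(
    segments: pd.DataFrame | None, sample: str, chrom: str, pos: int
) -> tuple[int, int]:
    """(total_cn, minor_cn) at a locus; diploid heterozygous if uncovered."""
    if segments is None or len(segments) == 0:
        return 2, 1
    hit = segments[
        (segments["sample"] == sample)
        & (segments["chrom"] == str(chrom))
        & (segments["start"] <= pos)
        & (segments["end"] >= pos)
    ]
    if len(hit) == 0:
        return 2, 1
    row = hit.iloc[0]
    return int(row["total_cn"]), int(row["minor_cn"])


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_tree(tree: CloneTree, json_path: str | Path, newick_path: str | Path | None = None) -> None:
    Path(json_path).parent.mkdir(parents=True, exist_ok=True)
    with open(json_path, "w") as fh:
        json.dump(tree.to_dict(), fh, indent=2)
    if newick_path is not None:
        Path(newick_path).write_text(tree.to_newick() + "\n")


def read_tree_json(path: str | Path) -> CloneTree:
    with open(path) as fh:
        d = json.load(fh)
    return CloneTree(
        parent={int(k): int(v) for k, v in d["parent"].items()},
        inclusive={int(k): np.asarray(v, dtype=float) for k, v in d["inclusive_ccf"].items()},
        samples=list(d["samples"]),
        constraint_flag=bool(d.get("constraint_flag", False)),
        total_violation=float(d.get("total_violation", 0.0)),
    )


@dataclass
class PipelineConfig:
    """End-to-end run configuration (plain key = value file)."""

    mutations: str = ""
    samples: str = ""
    segments: str = ""            # optional; empty = diploid everywhere
    seed: int = 0
    blood_volume_l: float = 5.0
    grid_step: float = 0.01
    k_max: int = 6
    epsilon: float = 0.10
    detection_ccf: float = 0.01
    upper_bound_fraction: float = 0.01
    mc_draws: int = 1000
    ccf_mode: str = "exclusive"   # exclusive | inclusive
    error_rate: float = 0.001     # per-base sequencing error in the read model

    def validate(self) -> None:
        for name in ("grid_step", "epsilon", "detection_ccf", "upper_bound_fraction"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.ccf_mode not in ("exclusive", "inclusive"):
            raise ValueError("ccf_mode must be 'exclusive' or 'inclusive'")
        if self.k_max < 1 or self.mc_draws < 1:
            raise ValueError("k_max and mc_draws must be >= 1")
        if self.blood_volume_l <= 0:
            raise ValueError("blood_volume_l must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")

    def content_hash(self) -> str:
        payload = json.dumps(
            {f.name: getattr(self, f.name) for f in fields(self)}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def parse_config(path: str | Path) -> PipelineConfig:
    """Parse a ``key = value`` config file; unknown keys are errors."""
    casts = {f.name: type(getattr(PipelineConfig(), f.name)) for f in fields(PipelineConfig)}
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        if key not in casts:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        values[key] = casts[key](val)
    cfg = PipelineConfig(**values)
    cfg.validate()
    return cfg
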