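"""Readers, writers and run configuration.

Expression matrices travel as genes x samples TSV/CSV (first column gene
IDs, header of sample IDs); clinical tables as TSV keyed by sample_id;
gene lists as one-ID-per-line text; rank-NB models as JSON.  Every
pipeline run writes a manifest (config echo, seed, package versions,
input checksums) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datagen import SyntheticConfig
from .selection import RegressionConfig

__all__ = [
    "PipelineConfig",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_gene_list",
    "write_gene_list",
    "write_manifest",
]


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    if dialect is None:
        return "," if path.suffix.lower() == ".csv" else "\t"
    raise ValueError(f"unknown dialect {dialect!r}")


def read_expression(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a genes x samples matrix; reject duplicates and missing values."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed expression file {path}: {exc}") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in {path}: {dupes[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"duplicate sample IDs in {path}")
    if df.isna().any().any():
        bad = [
            (g, s)
            for g in df.index[df.isna().any(axis=1)]
            for s in df.columns[df.loc[g].isna()]
        ]
        raise ValueError(f"missing values in {path} at (gene, sample): {bad[:5]}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    df.index.name = "gene"
    return df


def write_expression(expr: pd.DataFrame, path, dialect: str | None = None) -> None:
    path = Path(path)
    expr.to_csv(path, sep=_sep_for(path, dialect), index_label="gene")


def read_clinical(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"clinical table {path} lacks a sample_id column")
    df = df.set_index("sample_id")
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table {path} lacks required column {col!r}")
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(Path(path), sep="\t", index_label="sample_id")


def read_gene_list(path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


@dataclass
class PipelineConfig:
    """End-to-end run settings.

    Either ``expression_path``/``clinical_path`` point at on-disk inputs,
    or ``synthetic`` describes a generated dataset.  ``test_cohorts``
    names the cohorts held out entirely from training; the log-rank-driven
    flow splits their samples 50/50 into validation and test halves.
    """

    expression_path: str | None = None
    raw_expression_path: str | None = None
    clinical_path: str | None = None
    synthetic: SyntheticConfig | None = None
    test_cohorts: list[str] = field(default_factory=list)
    validation_fraction: float = 0.2
    test_cohort_validation_fraction: float = 0.5
    wrs_alpha: float = 0.1
    phase1_threshold: int = 900
    phase2_floor: int = 50
    removal_rate: float = 0.1
    regression: RegressionConfig = field(default_factory=RegressionConfig)
    n_deciles: int = 10
    smoothing_alpha: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("validation_fraction", "test_cohort_validation_fraction"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.phase1_threshold <= self.phase2_floor:
            raise ValueError("phase1_threshold must exceed phase2_floor")
        if not 0.0 < self.removal_rate < 1.0:
            raise ValueError("removal_rate must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in obj and obj["synthetic"] is not None:
            obj["synthetic"] = SyntheticConfig(**obj["synthetic"])
        if "regression" in obj and obj["regression"] is not None:
            obj["regression"] = RegressionConfig(**obj["regression"])
        return cls(**obj)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir, config: PipelineConfig, input_paths=()) -> Path:
    """Record everything needed to reproduce a run byte-identically."""
    import immunosig

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "immunosig": immunosig.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "input_checksums": {str(p): _sha256(Path(p)) for p in input_paths},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
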