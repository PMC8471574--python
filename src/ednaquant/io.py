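"""Plate-table readers/writers and pipeline configuration.

Plate tables are delimited text (TSV or CSV by extension) with a header
matching the canonical column names; a non-detect Cq is an empty cell or
the literal ``ND``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .records import (
    PLATE_COLUMNS,
    PipelineConfigError,
    PlateSchemaError,
    REQUIRED_COLUMNS,
    VolumeConfig,
    validate_plate_table,
)

ND_VALUES = ["ND", "nd", ""]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_plate_table(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read a plate table from delimited text.

    ``ND`` or empty Cq cells become the non-detect sentinel (NaN). With
    ``strict`` (default) any malformed row raises; otherwise the issues are
    attached to the frame as ``df.attrs['validation']``.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        na_values={"cq": ND_VALUES, "known_copies": ND_VALUES, "salinity": ND_VALUES},
        keep_default_na=True,
    )
    missing = REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise PlateSchemaError(
            f"{path.name}: missing required column(s): " + ", ".join(sorted(missing))
        )
    for col in PLATE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[PLATE_COLUMNS]
    for col in ("cq", "known_copies", "salinity"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    issues = validate_plate_table(df)
    if issues and strict:
        raise PlateSchemaError(f"{path.name}: " + "; ".join(issues))
    df.attrs["validation"] = issues
    return df


def write_plate_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a plate table; non-detect Cq serializes as ``ND``."""
    path = Path(path)
    out = df.copy()
    out["cq"] = out["cq"].map(lambda v: "ND" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, sep=_sep_for(path), index=False)


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Deterministic TSV writer used for all report tables."""
    df.to_csv(Path(path), sep="\t", index=False, float_format=float_format)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


@dataclass
class PipelineConfig:
    """All thresholds, rules and paths of one pipeline run."""

    volumes: VolumeConfig = field(default_factory=VolumeConfig)
    lod_probability: float = 0.95
    loq_cv_threshold: float = 0.35
    inhibition_threshold: float = 3.0  # cycles
    negative_fill: str = "zero_fill"  # zero_fill | omit
    p_adjust: str = "holm"  # holm | bonferroni | none
    clip_negative_delta: bool = False
    ipc_assay: str = "IPC"
    seed: Optional[int] = None
    input: Optional[str] = None
    out_dir: str = "ednaquant-out"

    def __post_init__(self):
        if not 0 < self.lod_probability < 1:
            raise PipelineConfigError("lod_probability must be in (0, 1)")
        if self.loq_cv_threshold <= 0:
            raise PipelineConfigError("loq_cv_threshold must be positive")
        if self.inhibition_threshold <= 0:
            raise PipelineConfigError("inhibition_threshold must be positive")
        if self.negative_fill not in ("zero_fill", "omit"):
            raise PipelineConfigError(f"unknown negative_fill {self.negative_fill!r}")
        if self.p_adjust not in ("holm", "bonferroni", "none"):
            raise PipelineConfigError(f"unknown p_adjust {self.p_adjust!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["volumes"] = dataclasses.asdict(self.volumes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "volumes" in d and isinstance(d["volumes"], dict):
            d["volumes"] = VolumeConfig(**d["volumes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in the run log."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
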