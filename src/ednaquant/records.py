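"""Domain record types and the plate-table schema.

A qPCR run is represented as a tidy table with one row per reaction well.
The canonical in-memory form is a :class:`pandas.DataFrame` with the columns
of :data:`PLATE_COLUMNS`; :class:`PlateRecord` is the typed row used when
building tables programmatically. Non-detects (no amplification within the
run's cycle limit) are encoded as a missing ``cq`` value (NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional

import numpy as np
import pandas as pd

REACTION_TYPES = ("standard", "unknown", "ntc", "ipc_control", "ipc_sample")
SEASONS = ("spawning", "non_spawning")
STREAM_CLASSES = ("mainstem", "tributary")

#: Column order of the plate-table dialect. ``site``, ``season``,
#: ``stream_class``, ``known_copies`` and ``salinity`` may be empty.
PLATE_COLUMNS = [
    "sample_id",
    "site",
    "season",
    "stream_class",
    "replicate",
    "assay",
    "reaction_type",
    "known_copies",
    "cq",
    "salinity",
]

REQUIRED_COLUMNS = {"sample_id", "replicate", "assay", "reaction_type", "cq"}


class PlateSchemaError(ValueError):
    """The plate table is missing required columns or uses unknown categories."""


class PlateValidationError(ValueError):
    """One or more plate rows violate the record invariants."""


class CalibrationError(ValueError):
    """The dilution series cannot support a standard-curve fit."""


class SensitivityError(ValueError):
    """LOD/LOQ estimation is undefined for the given data."""


class InhibitionError(ValueError):
    """The IPC assay pair is invalid (e.g. missing control Cq)."""


class PipelineConfigError(ValueError):
    """A pipeline configuration value is out of its valid range."""


@dataclass
class PlateRecord:
    """One qPCR reaction well.

    ``cq`` is NaN for a non-detect. ``known_copies`` must be present iff the
    reaction is a standard.
    """

    sample_id: str
    replicate: int
    assay: str
    reaction_type: str
    cq: float = math.nan
    known_copies: float = math.nan
    site: Optional[str] = None
    season: Optional[str] = None
    stream_class: Optional[str] = None
    salinity: float = math.nan

    def __post_init__(self) -> None:
        if self.reaction_type not in REACTION_TYPES:
            raise PlateValidationError(
                f"unknown reaction_type {self.reaction_type!r}; "
                f"expected one of {REACTION_TYPES}"
            )
        if self.replicate < 1:
            raise PlateValidationError("replicate must be >= 1")
        has_known = not _isnan(self.known_copies)
        if self.reaction_type == "standard" and not has_known:
            raise PlateValidationError("standard wells require known_copies")
        if self.reaction_type != "standard" and has_known:
            raise PlateValidationError("known_copies only valid on standard wells")
        if has_known and self.known_copies <= 0:
            raise PlateValidationError("known_copies must be positive")
        if not _isnan(self.cq) and (self.cq <= 0 or not math.isfinite(self.cq)):
            raise PlateValidationError("cq must be finite and > 0 when present")
        if self.season is not None and self.season not in SEASONS:
            raise PlateValidationError(f"unknown season {self.season!r}")
        if self.stream_class is not None and self.stream_class not in STREAM_CLASSES:
            raise PlateValidationError(f"unknown stream_class {self.stream_class!r}")


def _isnan(x: object) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class VolumeConfig:
    """Volumes linking a reaction to the original water sample.

    Defaults follow a 2 uL template drawn from a 50 uL elution of DNA
    filtered from 0.5 L of water, giving a x50 reaction-to-liter factor.
    """

    template_volume: float = 2.0  # uL per reaction
    elution_volume: float = 50.0  # uL
    filtration_volume: float = 0.5  # L

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise PipelineConfigError(f"{f.name} must be strictly positive")
        if self.template_volume > self.elution_volume:
            raise PipelineConfigError("template_volume must not exceed elution_volume")

    @property
    def liters_factor(self) -> float:
        """Multiplier converting copies/reaction to copies/L."""
        return (self.elution_volume / self.template_volume) / self.filtration_volume


def records_to_frame(records: Iterable[PlateRecord]) -> pd.DataFrame:
    """Assemble typed records into a plate table in canonical column order."""
    rows = [
        {
            "sample_id": r.sample_id,
            "site": r.site,
            "season": r.season,
            "stream_class": r.stream_class,
            "replicate": r.replicate,
            "assay": r.assay,
            "reaction_type": r.reaction_type,
            "known_copies": r.known_copies,
            "cq": r.cq,
            "salinity": r.salinity,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def validate_plate_table(df: pd.DataFrame) -> list[str]:
    """Check a plate table against the record invariants.

    Returns a list of human-readable issues (empty when the table is valid);
    missing required columns raise :class:`PlateSchemaError` immediately.
    """
    missing = REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise PlateSchemaError(
            "plate table is missing required column(s): " + ", ".join(sorted(missing))
        )
    issues: list[str] = []
    bad_type = ~df["reaction_type"].isin(REACTION_TYPES)
    for idx in df.index[bad_type]:
        issues.append(f"row {idx}: unknown reaction_type {df.at[idx, 'reaction_type']!r}")
    cq = pd.to_numeric(df["cq"], errors="coerce")
    bad_cq = df["cq"].notna() & (cq.isna() | (cq <= 0) | ~np.isfinite(cq.fillna(1.0)))
    for idx in df.index[bad_cq]:
        issues.append(f"row {idx}: cq must be finite and > 0 (got {df.at[idx, 'cq']!r})")
    is_std = df["reaction_type"] == "standard"
    if "known_copies" in df.columns:
        kc = pd.to_numeric(df["known_copies"], errors="coerce")
        for idx in df.index[is_std & (kc.isna() | (kc <= 0))]:
            issues.append(f"row {idx}: standard well requires positive known_copies")
        for idx in df.index[~is_std & kc.notna()]:
            issues.append(f"row {idx}: known_copies set on non-standard well")
    elif is_std.any():
        raise PlateSchemaError("plate table with standards requires a known_copies column")
    if "replicate" in df.columns:
        rep = pd.to_numeric(df["replicate"], errors="coerce")
        for idx in df.index[rep.isna() | (rep < 1)]:
            issues.append(f"row {idx}: replicate must be an integer >= 1")
    return issues
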