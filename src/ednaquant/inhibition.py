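"""Internal-positive-control (IPC) inhibition assay.

A fixed amount of exogenous template is amplified alone (``ipc_control``)
and spiked into each environmental extract (``ipc_sample``). Inhibitors in
the extract delay amplification, shifting the IPC's Cq upward; the delay

    dCq = cq_sample - cq_control

implies the extract's copy numbers are underestimated by a factor of
``2**dCq``, which is multiplied back onto raw copy estimates. A delay of
more than three cycles (or a failure of the spiked IPC to amplify at all)
marks significant inhibition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import InhibitionError, PlateValidationError

#: Cq delay beyond which inhibition is considered significant (cycles).
SIGNIFICANT_DELTA_CQ = 3.0


@dataclass(frozen=True)
class InhibitionAssay:
    """IPC Cq pair for one sample, with the derived correction."""

    sample_id: str
    cq_control: float
    cq_sample: float
    delta_cq: float
    factor: float
    significant: bool


def compute_inhibition(
    cq_sample: float,
    cq_control: float,
    sample_id: str = "",
    threshold: float = SIGNIFICANT_DELTA_CQ,
) -> InhibitionAssay:
    """Inhibition metrics from one IPC Cq pair.

    A missing (non-amplified) sample IPC yields dCq = +inf and a significant
    flag: no finite correction exists and the sample must be excluded from
    quantification. A missing control Cq invalidates the assay.
    """
    if cq_control is None or (isinstance(cq_control, float) and math.isnan(cq_control)):
        raise InhibitionError(f"sample {sample_id!r}: IPC control Cq is missing")
    if cq_sample is None or (isinstance(cq_sample, float) and math.isnan(cq_sample)):
        return InhibitionAssay(
            sample_id=sample_id,
            cq_control=float(cq_control),
            cq_sample=math.nan,
            delta_cq=math.inf,
            factor=math.inf,
            significant=True,
        )
    delta = float(cq_sample) - float(cq_control)
    return InhibitionAssay(
        sample_id=sample_id,
        cq_control=float(cq_control),
        cq_sample=float(cq_sample),
        delta_cq=delta,
        factor=2.0**delta,
        significant=delta > threshold,
    )


def normalize_copies(raw_copies, delta_cq, clip_negative_delta: bool = False):
    """Inhibition-corrected copy number: ``raw * 2**dCq``.

    A positive delay inflates the estimate back to its uninhibited value;
    a negative delay (apparent facilitation) shrinks it, unless
    ``clip_negative_delta`` floors the delay at zero.
    """
    raw = np.asarray(raw_copies, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw copies must be non-negative")
    d = np.asarray(delta_cq, dtype=float)
    if clip_negative_delta:
        d = np.maximum(d, 0.0)
    out = raw * 2.0**d
    return float(out) if out.ndim == 0 else out


def validate_ipc_controls(plate: pd.DataFrame) -> None:
    """Reject plates whose no-template control wells amplify.

    Amplification in an NTC well indicates contamination or IPC primer
    cross-reactivity; the whole plate is considered invalid.
    """
    ntc = plate[plate["reaction_type"] == "ntc"]
    bad = ntc[ntc["cq"].notna()]
    if not bad.empty:
        wells = ", ".join(bad["sample_id"].astype(str))
        raise PlateValidationError(
            f"NTC well(s) amplified ({wells}); plate rejected for contamination "
            "or IPC cross-reactivity"
        )


def inhibition_from_plate(
    plate: pd.DataFrame,
    threshold: float = SIGNIFICANT_DELTA_CQ,
    control_group: str | None = "season",
) -> pd.DataFrame:
    """Site-level inhibition table from a plate's IPC wells.

    The control Cq is the mean over ``ipc_control`` wells, grouped by
    ``control_group`` when that column is present (each sampling event run
    as its own plate); the sample Cq is averaged over each site's replicate
    ``ipc_sample`` wells. Non-amplified sample IPC replicates propagate a
    +inf delay (significant, unquantifiable).

    Returns one row per (site, season) with columns ``site``, ``season``,
    ``delta_cq``, ``factor``, ``significant``, ``n_replicates``,
    ``salinity``.
    """
    controls = plate[plate["reaction_type"] == "ipc_control"]
    samples = plate[plate["reaction_type"] == "ipc_sample"]
    if controls.empty:
        raise InhibitionError("plate has no ipc_control wells")
    if controls["cq"].isna().all():
        raise InhibitionError("all ipc_control wells failed to amplify")
    if samples.empty:
        raise InhibitionError("plate has no ipc_sample wells")

    def control_mean(season) -> float:
        if control_group and control_group in controls.columns:
            grp = controls[controls[control_group] == season]
            if not grp.empty and grp["cq"].notna().any():
                return float(grp["cq"].mean())
        return float(controls["cq"].mean())

    rows = []
    keys = [k for k in ("site", "season") if k in samples.columns]
    for key, grp in samples.groupby(keys, dropna=False, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        info = dict(zip(keys, key))
        season = info.get("season")
        ref = control_mean(season)
        if grp["cq"].isna().any():
            delta = math.inf
        else:
            delta = float(grp["cq"].mean()) - ref
        rows.append(
            {
                "site": info.get("site"),
                "season": season,
                "delta_cq": delta,
                "factor": 2.0**delta,
                "significant": bool(delta > threshold),
                "n_replicates": int(len(grp)),
                "salinity": float(grp["salinity"].mean())
                if "salinity" in grp.columns
                else math.nan,
            }
        )
    return pd.DataFrame(rows)


def season_summary(inhibition: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the site-level Cq delays per season."""
    finite = inhibition[np.isfinite(inhibition["delta_cq"])]
    return (
        finite.groupby("season", dropna=False)["delta_cq"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="size")
        .reset_index()
    )
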