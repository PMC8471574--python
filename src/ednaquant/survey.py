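"""Field-sample quantification: gating, copies per liter, aggregation.

Each unknown reaction is back-calculated against its assay's standard
curve, corrected for inhibition, and gated against the assay's modeled
limits: copies at or below the LOD are negative; copies between the LOD and
LOQ are detections too imprecise to quantify; copies at or above the LOQ
are quantifiable. Quantifiable copies per reaction convert to copies per
liter of sampled water through the template/elution/filtration volumes, and
concentrations are compared on the log10(x + 1) scale.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import StandardCurve, cq_to_copies
from .inhibition import normalize_copies
from .records import PipelineConfigError, VolumeConfig
from .sensitivity import SensitivityResult

STATUS_ORDER = ("negative", "detected_below_loq", "quantifiable")


def classify_detection(normalized_copies, lod: float, loq: float):
    """Three-way detection status of inhibition-corrected copy numbers.

    negative: copies <= LOD; detected_below_loq: LOD < copies < LOQ;
    quantifiable: copies >= LOQ. Vectorized over ``normalized_copies``.
    """
    if lod > loq:
        raise PipelineConfigError(f"LOD ({lod}) exceeds LOQ ({loq})")
    q = np.asarray(normalized_copies, dtype=float)
    status = np.select(
        [q <= lod, q < loq],
        ["negative", "detected_below_loq"],
        default="quantifiable",
    )
    return str(status) if status.ndim == 0 else status.astype(object)


def site_detection(statuses: Iterable[str]) -> bool:
    """A site is a detection when any replicate exceeds the LOD."""
    statuses = list(statuses)
    if not statuses:
        raise ValueError("site has no replicates")
    return any(s != "negative" for s in statuses)


def copies_per_liter(copies_per_reaction, volumes: VolumeConfig = VolumeConfig()):
    """Copies per liter of sampled water from copies per reaction.

    ``copies * (elution/template) / filtration``; x50 with the default
    2 uL / 50 uL / 0.5 L volumes. Linear in the copy number.
    """
    q = np.asarray(copies_per_reaction, dtype=float)
    if np.any(q < 0):
        raise ValueError("copies per reaction must be non-negative")
    out = q * volumes.liters_factor
    return float(out) if out.ndim == 0 else out


def log_transform(x):
    """log10(x + 1), the variance-stabilizing transform used for
    concentration comparisons; zero maps to zero."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("concentrations must be non-negative")
    out = np.log10(arr + 1.0)
    return float(out) if out.ndim == 0 else out


def fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of two mean concentrations (NaN when the denominator is zero,
    i.e. the ratio is censored)."""
    if mean_b == 0:
        return math.nan
    return mean_a / mean_b


def quantify_samples(
    unknowns: pd.DataFrame,
    curve: StandardCurve,
    sensitivity: SensitivityResult,
    inhibition: pd.DataFrame | None = None,
    volumes: VolumeConfig = VolumeConfig(),
    clip_negative_delta: bool = False,
) -> pd.DataFrame:
    """Per-reaction quantification of a plate's unknown wells for one assay.

    Adds columns ``raw_copies``, ``delta_cq``, ``normalized_copies``,
    ``status``, ``copies_per_liter``, ``log_copies``, ``excluded``.
    Non-detect wells carry zero copies. Samples whose IPC failed to amplify
    (infinite delay) have no finite correction: they are flagged
    ``excluded`` and drop out of quantitative summaries.

    ``inhibition`` is the site-level table from
    :func:`ednaquant.inhibition.inhibition_from_plate`; omit it to skip
    normalization (delay 0 everywhere).
    """
    out = unknowns.copy()
    detected = out["cq"].notna()
    raw = np.zeros(len(out))
    raw[detected.to_numpy()] = cq_to_copies(out.loc[detected, "cq"].to_numpy(float), curve)
    out["raw_copies"] = raw

    if inhibition is not None and not inhibition.empty:
        keys = [k for k in ("site", "season") if k in inhibition.columns and k in out.columns]
        delta_map = inhibition.set_index(keys)["delta_cq"]
        idx = pd.MultiIndex.from_frame(out[keys]) if len(keys) > 1 else out[keys[0]]
        delta = delta_map.reindex(idx).to_numpy(float)
    else:
        delta = np.zeros(len(out))
    delta = np.where(np.isnan(delta), 0.0, delta)
    out["delta_cq"] = delta

    excluded = np.isinf(delta) & (raw > 0)
    finite_delta = np.where(np.isinf(delta), 0.0, delta)
    out["normalized_copies"] = normalize_copies(
        raw, finite_delta, clip_negative_delta=clip_negative_delta
    )
    out.loc[excluded, "normalized_copies"] = np.nan
    out["excluded"] = excluded

    lod, loq = sensitivity.lod_copies, sensitivity.loq_copies
    status = classify_detection(out["normalized_copies"].fillna(0.0), lod, loq)
    out["status"] = status
    out.loc[excluded, "status"] = "excluded"

    cpl = copies_per_liter(out["normalized_copies"].fillna(0.0).to_numpy(), volumes)
    out["copies_per_liter"] = np.where(excluded, np.nan, cpl)
    out["log_copies"] = np.where(excluded, np.nan, log_transform(np.nan_to_num(cpl)))
    return out


def summarize_survey(
    samples: pd.DataFrame,
    group_keys: Sequence[str] = ("assay", "site", "season"),
    negative_fill: str = "zero_fill",
) -> pd.DataFrame:
    """Group-level detection and mean concentration.

    Per group: ``detected`` is true when any replicate exceeds the LOD;
    ``mean_copies_per_liter`` averages quantifiable replicates, with
    negative replicates entering as zero (``negative_fill='zero_fill'``,
    the default) or left out (``'omit'``); detections below the LOQ are
    excluded from means either way but still count as detections.
    ``n_quantifiable`` counts quantifiable replicates.
    """
    if negative_fill not in ("zero_fill", "omit"):
        raise PipelineConfigError(f"unknown negative_fill rule {negative_fill!r}")
    missing = [k for k in group_keys if k not in samples.columns]
    if missing:
        raise KeyError(f"unknown group key(s): {missing}")

    rows = []
    for key, grp in samples.groupby(list(group_keys), dropna=False, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        grp = grp[grp["status"] != "excluded"]
        quant = grp.loc[grp["status"] == "quantifiable", "copies_per_liter"]
        values = list(quant)
        if negative_fill == "zero_fill":
            values += [0.0] * int((grp["status"] == "negative").sum())
        rows.append(
            {
                **dict(zip(group_keys, key)),
                "detected": bool((grp["status"] != "negative").any()),
                "mean_copies_per_liter": float(np.mean(values)) if values else 0.0,
                "n_quantifiable": int(len(quant)),
                "n_replicates": int(len(grp)),
            }
        )
    return pd.DataFrame(rows)


def group_means(
    samples: pd.DataFrame,
    group_keys: Sequence[str],
    negative_fill: str = "zero_fill",
) -> pd.Series:
    """Mean copies/L per group under the same fill rule as
    :func:`summarize_survey`, keyed by the group tuple. The mean pools
    replicates directly (not site means)."""
    if negative_fill not in ("zero_fill", "omit"):
        raise PipelineConfigError(f"unknown negative_fill rule {negative_fill!r}")
    rows = []
    for key, grp in samples.groupby(list(group_keys), dropna=False, sort=True):
        grp = grp[grp["status"] != "excluded"]
        values = list(grp.loc[grp["status"] == "quantifiable", "copies_per_liter"])
        if negative_fill == "zero_fill":
            values += [0.0] * int((grp["status"] == "negative").sum())
        rows.append((key, float(np.mean(values)) if values else 0.0))
    idx = pd.Index([k for k, _ in rows], name=tuple(group_keys) if len(group_keys) > 1 else group_keys[0])
    return pd.Series([v for _, v in rows], index=idx, name="mean_copies_per_liter")
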