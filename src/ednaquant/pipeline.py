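"""End-to-end run: calibrate, assess sensitivity, correct inhibition,
quantify, gate, aggregate and compare.

Stage order is fixed: calibrate -> sensitivity -> inhibition ->
back-calculate -> normalize -> gate -> copies/L -> log transform ->
summarize -> compare. Gating uses inhibition-corrected copies (the
correction is applied before the LOD/LOQ comparison).
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import fit_standard_curve
from .compare import (
    pairwise_wilcoxon,
    significance_stars,
    spearman_correlation,
    two_sample_ttest,
)
from .inhibition import inhibition_from_plate, season_summary, validate_ipc_controls
from .io import PipelineConfig, read_plate_table, write_json, write_tsv
from .records import CalibrationError
from .survey import fold_change, group_means, quantify_samples, summarize_survey


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and assay."""


def _stage(name: str, assay: str | None = None):
    where = f"stage {name!r}" + (f", assay {assay!r}" if assay else "")

    def wrap(exc: Exception) -> StageError:
        return StageError(f"{where}: {exc}")

    return wrap


def run_pipeline(config: PipelineConfig, plate: pd.DataFrame | None = None) -> dict:
    """Run the full pipeline and write the report bundle to
    ``config.out_dir``.

    ``plate`` may be passed directly (e.g. a simulated table); otherwise
    ``config.input`` is read. Returns a dict with the in-memory artifacts:
    ``calibration``, ``sensitivity``, ``inhibition``, ``quantified``,
    ``site_summary``, ``comparisons``, ``group_means``.
    """
    if plate is None:
        if config.input is None:
            raise StageError("stage 'read': no input plate table configured")
        plate = read_plate_table(config.input)
    validate_ipc_controls(plate)

    assays = sorted(
        a
        for a in plate["assay"].unique()
        if a != config.ipc_assay
        and (plate.loc[plate["assay"] == a, "reaction_type"] != "ipc_control").all()
    )

    # inhibition is assay-independent (one IPC per extract)
    ipc = plate[plate["reaction_type"].isin(["ipc_control", "ipc_sample"])]
    if ipc.empty:
        inhibition = None
        inhibition_by_season = pd.DataFrame()
    else:
        try:
            inhibition = inhibition_from_plate(
                ipc, threshold=config.inhibition_threshold
            )
        except Exception as exc:
            raise _stage("inhibition")(exc)
        inhibition_by_season = season_summary(inhibition)

    calibration: dict[str, dict] = {}
    sensitivity: dict[str, dict] = {}
    quantified_parts = []
    for assay in assays:
        sub = plate[plate["assay"] == assay]
        standards = sub[sub["reaction_type"] == "standard"]
        if standards.empty:
            raise StageError(f"stage 'calibrate', assay {assay!r}: no standard wells")
        try:
            curve = fit_standard_curve(standards)
        except CalibrationError as exc:
            raise _stage("calibrate", assay)(exc)
        calibration[assay] = curve.to_dict()
        try:
            sens = _assess(standards, curve, config)
        except Exception as exc:
            raise _stage("sensitivity", assay)(exc)
        sensitivity[assay] = sens.to_dict()
        unknowns = sub[sub["reaction_type"] == "unknown"]
        if unknowns.empty:
            continue
        try:
            quantified_parts.append(
                quantify_samples(
                    unknowns,
                    curve,
                    sens,
                    inhibition=inhibition,
                    volumes=config.volumes,
                    clip_negative_delta=config.clip_negative_delta,
                )
            )
        except Exception as exc:
            raise _stage("quantify", assay)(exc)

    quantified = (
        pd.concat(quantified_parts, ignore_index=True)
        if quantified_parts
        else pd.DataFrame()
    )
    if not quantified.empty:
        site_summary = summarize_survey(
            quantified, ("assay", "site", "season"), config.negative_fill
        )
        comparisons = _comparisons(quantified, inhibition, config)
        means = _group_means_report(quantified, config)
    else:
        site_summary = pd.DataFrame()
        comparisons = pd.DataFrame()
        means = {}

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(calibration, out / "calibration.json")
    write_json(sensitivity, out / "sensitivity.json")
    if inhibition is not None:
        write_tsv(inhibition, out / "inhibition.tsv")
    if not quantified.empty:
        write_tsv(quantified, out / "quantified.tsv")
        write_tsv(site_summary, out / "site_summary.tsv")
        write_tsv(comparisons, out / "comparisons.tsv")
        write_json(means, out / "group_means.json")
    _write_log(out / "run_log.txt", config, assays, len(plate))

    return {
        "calibration": calibration,
        "sensitivity": sensitivity,
        "inhibition": inhibition,
        "inhibition_by_season": inhibition_by_season,
        "quantified": quantified,
        "site_summary": site_summary,
        "comparisons": comparisons,
        "group_means": means,
    }


def _assess(standards, curve, config: PipelineConfig):
    from .sensitivity import assess_sensitivity

    return assess_sensitivity(
        standards,
        curve,
        probability=config.lod_probability,
        cv_threshold=config.loq_cv_threshold,
    )


def _comparisons(
    quantified: pd.DataFrame,
    inhibition: pd.DataFrame | None,
    config: PipelineConfig,
) -> pd.DataFrame:
    """The survey's comparison families, one table row per test.

    Pairwise rank-sum tests run among species within each season, between
    seasons within each species, and between stream classes within each
    species; each family is adjusted separately. The seasonal inhibition
    t-test and the delay-salinity Spearman correlation are appended when
    IPC data are present.
    """
    usable = quantified[quantified["status"] != "excluded"]
    frames = []

    def family(df: pd.DataFrame, by: str, label: str):
        groups = {
            str(name): grp["log_copies"].to_numpy(float)
            for name, grp in df.groupby(by, dropna=True)
            if len(grp) > 0
        }
        if len(groups) < 2:
            return
        res = pairwise_wilcoxon(groups, adjust=config.p_adjust)
        res.insert(0, "family", label)
        frames.append(res)

    for season, grp in usable.groupby("season", dropna=True):
        family(grp, "assay", f"species|{season}")
    for assay, grp in usable.groupby("assay"):
        family(grp, "season", f"season|{assay}")
        family(grp, "stream_class", f"stream_class|{assay}")

    if inhibition is not None and not inhibition.empty:
        finite = inhibition[np.isfinite(inhibition["delta_cq"])]
        seasons = [g for _, g in finite.groupby("season")]
        if len(seasons) == 2 and all(len(g) >= 2 for g in seasons):
            res = two_sample_ttest(
                seasons[0]["delta_cq"], seasons[1]["delta_cq"]
            )
            frames.append(
                pd.DataFrame(
                    [
                        {
                            "family": "inhibition",
                            "group_a": str(seasons[0]["season"].iloc[0]),
                            "group_b": str(seasons[1]["season"].iloc[0]),
                            "method": "t_test",
                            "statistic": res.statistic,
                            "p_raw": res.p_raw,
                            "p_adjusted": res.p_adjusted,
                            "stars": res.stars,
                        }
                    ]
                )
            )
        sal = finite.dropna(subset=["salinity"])
        if len(sal) >= 3:
            res = spearman_correlation(sal["delta_cq"], sal["salinity"])
            frames.append(
                pd.DataFrame(
                    [
                        {
                            "family": "inhibition",
                            "group_a": "delta_cq",
                            "group_b": "salinity",
                            "method": "spearman",
                            "statistic": res.statistic,
                            "p_raw": res.p_raw,
                            "p_adjusted": res.p_adjusted,
                            "stars": res.stars,
                        }
                    ]
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["family", "group_a", "group_b", "method", "statistic",
                     "p_raw", "p_adjusted", "stars"]
        )
    return pd.concat(frames, ignore_index=True)


def _group_means_report(quantified: pd.DataFrame, config: PipelineConfig) -> dict:
    """Per-(assay, season) mean concentrations and their fold changes."""
    means = group_means(
        quantified[quantified["status"] != "excluded"],
        ("assay", "season"),
        config.negative_fill,
    )
    mean_dict = {f"{a}|{s}": v for (a, s), v in means.items()}
    folds = {}
    for (ka, kb) in itertools.combinations(sorted(mean_dict), 2):
        hi, lo = (ka, kb) if mean_dict[ka] >= mean_dict[kb] else (kb, ka)
        fc = fold_change(mean_dict[hi], mean_dict[lo])
        folds[f"{hi} / {lo}"] = round(fc, 2) if np.isfinite(fc) else None
    return {"mean_copies_per_liter": mean_dict, "fold_changes": folds}


def _write_log(path: Path, config: PipelineConfig, assays, n_rows: int) -> None:
    lines = [
        f"ednaquant {__version__}",
        f"config_hash: {config.digest()}",
        f"seed: {config.seed}",
        f"plate_rows: {n_rows}",
        f"assays: {', '.join(assays)}",
        "stages: calibrate > sensitivity > inhibition > back-calculate > "
        "normalize > gate > copies/L > transform > summarize > compare",
    ]
    path.write_text("\n".join(lines) + "\n")
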