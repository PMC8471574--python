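"""Synthetic qPCR plates and field surveys.

The generator reproduces the statistical structure the analysis assumes,
so every pipeline stage is testable without instrument data:

* standards and unknowns draw their template count ``k`` from a Poisson
  distribution (``k ~ Poisson(Q * per_molecule_efficiency)``); a well is a
  non-detect iff ``k = 0``, and otherwise reports
  ``Cq = intercept + slope*log10(k) + Normal(0, cq_noise_sd)``. Poisson
  sampling alone produces the falling detection probability and rising CV
  at low copies that the LOD/LOQ estimators model;
* field wells add a per-site, per-season inhibition delay to every Cq,
  and the same delay shifts the site's spiked-IPC wells, so the inhibition
  module can recover and correct it;
* per-site salinity is written so the delay-salinity correlation the
  survey statistics test for is present by construction.

The default survey emulates a six-site, two-season, three-replicate salmon
eDNA monitoring design on a river with a hatchery mainstem (sites 1-3) and
two tributaries (sites 4-6).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import PLATE_COLUMNS, SEASONS, records_to_frame

#: Copies-per-reaction -> copies-per-liter factor implied by the default
#: volumes (2 uL template, 50 uL elution, 0.5 L filtered).
LITERS_FACTOR = 50.0

DEFAULT_STANDARDS: tuple[tuple[float, int], ...] = tuple(
    (10.0**j, 10) for j in range(8)
)


@dataclass(frozen=True)
class SimulationConfig:
    """Per-assay generative parameters for qPCR wells.

    ``per_molecule_efficiency`` is the probability that one template
    molecule is captured and amplified; 1.0 gives the theoretical Poisson
    detection floor (~3 copies at 95%), smaller values raise the LOD to
    ``-ln(0.05)/efficiency``.
    """

    assay: str = "assay"
    curve_slope: float = -3.4149  # cycles per log10(copies)
    curve_intercept: float = 37.5  # cycles at 1 copy
    cq_noise_sd: float = 0.2  # cycles
    per_molecule_efficiency: float = 1.0
    seed: Optional[int] = None
    standards: tuple[tuple[float, int], ...] = DEFAULT_STANDARDS
    ipc_control_cq: float = 28.0
    lognormal_sigma_log10: float = 0.3  # replicate-level biological variation

    def __post_init__(self):
        if self.curve_slope >= 0:
            raise ValueError("curve_slope must be negative")
        if self.cq_noise_sd < 0:
            raise ValueError("cq_noise_sd must be non-negative")
        if not 0 < self.per_molecule_efficiency <= 1:
            raise ValueError("per_molecule_efficiency must be in (0, 1]")


@dataclass(frozen=True)
class Site:
    name: str
    stream_class: str  # mainstem | tributary
    salinity: float  # practical salinity units
    effect: float = 1.0  # multiplicative concentration effect


@dataclass(frozen=True)
class SurveyDesign:
    """Site/season/species structure of a simulated field survey."""

    sites: tuple[Site, ...]
    species_means: Mapping[tuple[str, str], float]  # (assay, season) -> copies/L
    seasons: tuple[str, ...] = SEASONS
    replicate_count: int = 3
    #: (site name, season) -> injected IPC Cq delay in cycles; when absent,
    #: delays derive from salinity via ``salinity_inhibition_slope``.
    inhibition_delta: Optional[Mapping[tuple[str, str], float]] = None
    salinity_inhibition_slope: float = 0.0  # cycles per salinity unit

    def __post_init__(self):
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if any(v < 0 for v in self.species_means.values()):
            raise ValueError("species means must be non-negative")

    def delta(self, site: Site, season: str) -> float:
        if self.inhibition_delta is not None:
            return float(self.inhibition_delta[(site.name, season)])
        return self.salinity_inhibition_slope * site.salinity


def _draw_well(rng, mean_copies: float, cfg: SimulationConfig, shift: float = 0.0):
    """Template count and Cq for one reaction; Cq is NaN for a non-detect."""
    k = rng.poisson(mean_copies * cfg.per_molecule_efficiency)
    if k == 0:
        return 0, np.nan
    cq = (
        cfg.curve_intercept
        + cfg.curve_slope * np.log10(k)
        + shift
        + rng.normal(0.0, cfg.cq_noise_sd)
    )
    return int(k), float(cq)


def simulate_dilution_series(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Replicated serial-dilution standards for one assay.

    Defaults emulate a 10-fold series from 1 to 1e7 copies/reaction with
    ten replicates per level.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rows = []
    for level, (q, n_rep) in enumerate(config.standards):
        for rep in range(1, n_rep + 1):
            _, cq = _draw_well(rng, float(q), config)
            rows.append(
                {
                    "sample_id": f"{config.assay}-std{level}-r{rep}",
                    "site": None,
                    "season": None,
                    "stream_class": None,
                    "replicate": rep,
                    "assay": config.assay,
                    "reaction_type": "standard",
                    "known_copies": float(q),
                    "cq": cq,
                    "salinity": np.nan,
                }
            )
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def simulate_field_survey(
    design: SurveyDesign,
    configs: Mapping[str, SimulationConfig] | SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    ipc_assay: str = "IPC",
    n_ipc_controls: int = 3,
) -> pd.DataFrame:
    """Unknown, IPC and NTC wells for a multi-site two-season survey.

    Per site/season/species/replicate, the expected copies per reaction are
    ``copies_per_liter * site effect / 50`` with lognormal replicate
    variation; the realized template count is Poisson; the well's Cq (and
    the site's spiked-IPC Cq) is shifted by the site/season inhibition
    delay. ``configs`` maps assay name to its generative parameters (or a
    single config for a one-assay survey).
    """
    if isinstance(configs, SimulationConfig):
        configs = {configs.assay: configs}
    species = list(configs)
    seeds = {cfg.seed for cfg in configs.values() if cfg.seed is not None}
    if rng is None:
        rng = np.random.default_rng(min(seeds) if seeds else None)
    base = next(iter(configs.values()))

    rows = []
    for season in design.seasons:
        # IPC run alone in clean reactions: one set per sampling event
        for rep in range(1, n_ipc_controls + 1):
            rows.append(
                {
                    "sample_id": f"{season}-ipc-control-r{rep}",
                    "site": None,
                    "season": season,
                    "stream_class": None,
                    "replicate": rep,
                    "assay": ipc_assay,
                    "reaction_type": "ipc_control",
                    "known_copies": np.nan,
                    "cq": base.ipc_control_cq + rng.normal(0.0, base.cq_noise_sd),
                    "salinity": np.nan,
                }
            )
        for site in design.sites:
            delta = design.delta(site, season)
            for rep in range(1, design.replicate_count + 1):
                sample = f"{season}-{site.name}-r{rep}"
                rows.append(
                    {
                        "sample_id": sample,
                        "site": site.name,
                        "season": season,
                        "stream_class": site.stream_class,
                        "replicate": rep,
                        "assay": ipc_assay,
                        "reaction_type": "ipc_sample",
                        "known_copies": np.nan,
                        "cq": base.ipc_control_cq
                        + delta
                        + rng.normal(0.0, base.cq_noise_sd),
                        "salinity": site.salinity,
                    }
                )
                for sp in species:
                    cfg = configs[sp]
                    mean_cpl = design.species_means.get((sp, season), 0.0) * site.effect
                    lam = (
                        mean_cpl
                        / LITERS_FACTOR
                        * 10.0 ** rng.normal(0.0, cfg.lognormal_sigma_log10)
                    )
                    _, cq = _draw_well(rng, lam, cfg, shift=delta)
                    rows.append(
                        {
                            "sample_id": sample,
                            "site": site.name,
                            "season": season,
                            "stream_class": site.stream_class,
                            "replicate": rep,
                            "assay": sp,
                            "reaction_type": "unknown",
                            "known_copies": np.nan,
                            "cq": cq,
                            "salinity": site.salinity,
                        }
                    )
        for assay in [*species, ipc_assay]:
            rows.append(
                {
                    "sample_id": f"{season}-{assay}-ntc",
                    "site": None,
                    "season": season,
                    "stream_class": None,
                    "replicate": 1,
                    "assay": assay,
                    "reaction_type": "ntc",
                    "known_copies": np.nan,
                    "cq": np.nan,
                    "salinity": np.nan,
                }
            )
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


# ---------------------------------------------------------------------------
# Default survey scenario


def _assay_config(assay, efficiency_pct, intercept, lod, seed):
    slope = -1.0 / np.log10(1.0 + efficiency_pct / 100.0)
    return SimulationConfig(
        assay=assay,
        curve_slope=float(slope),
        curve_intercept=intercept,
        per_molecule_efficiency=float(min(1.0, -np.log(0.05) / lod)),
        seed=seed,
    )


def default_assay_configs(seed: Optional[int] = None) -> dict[str, SimulationConfig]:
    """Four salmon assays with sensitivities and efficiencies typical of a
    validated species-specific TaqMan panel (LODs ~4-10 copies,
    efficiencies ~95-106%)."""
    return {
        "O_keta": _assay_config("O_keta", 96.26, 37.5, 4.11, seed),
        "O_kisutch": _assay_config("O_kisutch", 95.15, 38.0, 8.44, seed),
        "O_masou": _assay_config("O_masou", 100.67, 37.0, 4.65, seed),
        "O_mykiss": _assay_config("O_mykiss", 106.33, 36.5, 10.38, seed),
    }


def default_survey_design() -> SurveyDesign:
    """Six-site, two-season salmon survey with hatchery-river structure.

    Sites 1-3 sit on the mainstem (higher concentrations, brackish
    salinity near the mouth), 4-6 on two tributaries. The dominant chum
    salmon signal peaks in the spawning season at ~1.09e6 copies/L against
    ~1.71e4 off-season; the three minor species stay low year-round.
    Site/season inhibition delays span -0.33 to 1.33 cycles with a
    spawning-season mean of 0.44 and an off-season mean of 0.07, and rise
    with salinity.
    """
    sites = (
        Site("site1", "mainstem", salinity=2.5, effect=1.8),
        Site("site2", "mainstem", salinity=3.0, effect=1.7),
        Site("site3", "mainstem", salinity=1.0, effect=1.5),
        Site("site4", "tributary", salinity=0.10, effect=0.4),
        Site("site5", "tributary", salinity=0.20, effect=0.3),
        Site("site6", "tributary", salinity=0.15, effect=0.3),
    )
    species_means = {
        ("O_keta", "spawning"): 1.09e6,
        ("O_keta", "non_spawning"): 1.71e4,
        ("O_masou", "spawning"): 1.09e6 / 77.11,
        ("O_masou", "non_spawning"): 1.96e3,
        ("O_kisutch", "spawning"): 1.09e6 / 626.10,
        ("O_kisutch", "non_spawning"): 1.5e3,
        ("O_mykiss", "spawning"): 1.09e6 / 42.74,
        ("O_mykiss", "non_spawning"): 1.5e3,
    }
    inhibition_delta = {
        ("site1", "spawning"): 0.80,
        ("site2", "spawning"): 1.33,
        ("site3", "spawning"): 0.55,
        ("site4", "spawning"): -0.33,
        ("site5", "spawning"): 0.20,
        ("site6", "spawning"): 0.09,
        ("site1", "non_spawning"): 0.39,
        ("site2", "non_spawning"): 0.25,
        ("site3", "non_spawning"): 0.12,
        ("site4", "non_spawning"): -0.15,
        ("site5", "non_spawning"): -0.10,
        ("site6", "non_spawning"): -0.09,
    }
    return SurveyDesign(
        sites=sites,
        species_means=species_means,
        inhibition_delta=inhibition_delta,
        salinity_inhibition_slope=0.35,
    )


SCENARIOS = ("dilution", "yangyang-default")


def simulate_scenario(name: str, seed: Optional[int] = None):
    """Build a named scenario.

    Returns ``(plate, truth)``: the plate table and a JSON-serializable
    dict of the injected ground-truth parameters for recovery tests.

    * ``dilution`` — one assay's replicated serial dilution.
    * ``yangyang-default`` — four-assay dilution series plus the default
      six-site two-season field survey with IPC and NTC wells.
    """
    rng = np.random.default_rng(seed)
    if name == "dilution":
        cfg = SimulationConfig(seed=seed)
        plate = simulate_dilution_series(cfg, rng=rng)
        truth = {"config": _config_dict(cfg)}
        return plate, truth
    if name == "yangyang-default":
        configs = default_assay_configs(seed)
        design = default_survey_design()
        parts = [simulate_dilution_series(cfg, rng=rng) for cfg in configs.values()]
        parts.append(simulate_field_survey(design, configs, rng=rng))
        plate = pd.concat(parts, ignore_index=True)
        truth = {
            "configs": {k: _config_dict(v) for k, v in configs.items()},
            "species_means": {
                f"{sp}|{season}": v
                for (sp, season), v in design.species_means.items()
            },
            "inhibition_delta": {
                f"{site}|{season}": v
                for (site, season), v in design.inhibition_delta.items()
            },
            "sites": [dataclasses.asdict(s) for s in design.sites],
        }
        return plate, truth
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")


def _config_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["standards"] = [list(s) for s in cfg.standards]
    return d
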