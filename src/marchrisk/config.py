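"""Configuration dataclasses for cohort generation, the training regimen,
the stress-fracture risk model, and full pipeline runs, with YAML round-trip.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import params as P


@dataclass
class CohortConfig:
    """Conditions for the synthetic cohort.

    ``group_params`` holds the per-sex, per-load (mean, SD) for every gait
    variable; the defaults are the published group values the generator
    emulates.  ``stride_cv`` is the within-trial stride-to-stride coefficient
    of variation applied to stance duration, stride duration and peak force.
    ``within_subject_rho`` is the correlation, across load conditions, induced
    by a per-subject latent effect on each peak variable (marginals stay at
    the configured mean/SD).
    """

    n_female: int = P.N_FEMALE
    n_male: int = P.N_MALE
    seed: int = 0
    grf_sampling_rate: float = 1000.0  # Hz
    # Long enough that even the tallest subjects (longest strides) complete
    # >= 20 strides, as the recording protocol requires.
    trial_duration: float = 22.0  # s
    speed: float = P.RUNNING_SPEED  # m/s
    stride_cv: float = 0.02
    baseline_noise_sd: float = 2.0  # N, swing-phase baseline
    segmentation_threshold: float = 25.0  # N
    within_subject_rho: float = 0.5
    # GRF waveform shape: relative prominence of the early impact bump.
    impact_ratio: float = 0.4
    foot_strike_mix: bool = False
    rearfoot_impact_ratio: float = 0.55
    nonrearfoot_impact_ratio: float = 0.20
    # Whether peak GRF in BW refers to body weight alone (the convention the
    # printed values imply, since normalized peaks rise with carried load)
    # or to body weight plus carried load.
    bw_includes_load: bool = False
    group_params: dict = field(default_factory=lambda: copy.deepcopy(P.GROUP_PARAMS))
    anthropometry: dict = field(default_factory=lambda: copy.deepcopy(P.ANTHROPOMETRY))
    mass_height_rho: float = 0.7
    # Tibia element synthesis: class mixture over (intramedullary, trabecular,
    # cortical) and per-class Hounsfield-unit (mean, sd).
    n_elements: int = 2000
    class_mixture: tuple = (0.15, 0.35, 0.50)
    # Per-class HU (mean, sd); the intramedullary band sits just above the
    # calibration's zero-density point so the induced moduli stay in [0, 6) MPa.
    class_hu_params: dict = field(
        default_factory=lambda: {
            "intramedullary": (-20.0, 3.0),
            "trabecular": (500.0, 250.0),
            "cortical": (1600.0, 150.0),
        }
    )

    def __post_init__(self) -> None:
        if self.n_female < 2 or self.n_male < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.grf_sampling_rate < 200.0:
            raise ValueError("GRF sampling rate must be >= 200 Hz")
        for variable, by_sex in self.group_params.items():
            for sex, by_load in by_sex.items():
                for load, (_, sd) in by_load.items():
                    if sd < 0:
                        raise ValueError(
                            f"negative SD for {variable}/{sex}/{load}"
                        )
        if not 0.0 <= self.within_subject_rho <= 1.0:
            raise ValueError("within_subject_rho must be in [0, 1]")

    def n_for_sex(self, sex: str) -> int:
        return self.n_female if sex == P.FEMALE else self.n_male


@dataclass
class TrainingRegimen:
    """A repeating training week: consecutive training days with a fixed daily
    running distance, followed by rest days."""

    weeks: int = 10
    training_days_per_week: int = 5
    rest_days_per_week: int = 2
    daily_distance: float = 1700.0  # m per training day

    def __post_init__(self) -> None:
        if self.training_days_per_week + self.rest_days_per_week != 7:
            raise ValueError("training + rest days per week must equal 7")
        if self.daily_distance <= 0:
            raise ValueError("daily distance must be positive")
        if self.weeks < 1:
            raise ValueError("need at least one week")

    @property
    def total_days(self) -> int:
        return 7 * self.weeks

    def is_training_day(self, day: int) -> bool:
        """1-based calendar day -> whether it is a training day."""
        if day < 1:
            raise ValueError("day index is 1-based")
        return (day - 1) % 7 < self.training_days_per_week

    def distance_on(self, day: int) -> float:
        return self.daily_distance if self.is_training_day(day) else 0.0


#: Default strain-life coefficients for cortical bone: log10(Nf) =
#: intercept + slope * log10(strain in microstrain).  The slope is a typical
#: strain-life exponent for cortical bone in cyclic loading; the intercept is
#: a placeholder that pipeline-level calibration replaces (see
#: pipeline.calibrate_sn_intercept).
DEFAULT_SN_SLOPE = -9.3
DEFAULT_SN_INTERCEPT = 40.0


@dataclass
class RiskModelParams:
    """Parameters of the probabilistic fatigue damage-repair-adaptation model.

    * ``sn_intercept``/``sn_slope``: strain-life (S-N) curve on log10 scales.
    * ``sn_scatter_sd``: SD (decades of log10 fatigue life) of the lognormal
      between-replicate scatter driving the Monte-Carlo risk estimate.
    * ``repair_time_constant``: days; accumulated damage decays by a factor e
      over this time under exponential repair (the default kinetics).
    * ``apposition_rate``: periosteal bone deposition, micrometres per day,
      that grows the outer radius of the midshaft annulus and lowers strain.
    """

    sn_intercept: float = DEFAULT_SN_INTERCEPT
    sn_slope: float = DEFAULT_SN_SLOPE
    sn_scatter_sd: float = 0.8
    repair_time_constant: float = 26.0  # days
    repair_mode: str = "exponential"  # or "linear"
    apposition_rate: float = 4.0  # um/day
    initial_outer_radius: float = 0.012  # m
    initial_inner_radius: float = 0.007  # m
    adaptation_mode: str = "bending"  # or "combined"
    axial_per_bending: float = 0.0  # (F/A)/(M c/I) stress ratio for "combined"
    mc_samples: int = 1000
    seed: int = 0
    round_cycles: bool = False

    def __post_init__(self) -> None:
        if self.sn_slope >= 0:
            raise ValueError("S-N slope must be negative (life falls with strain)")
        if self.repair_time_constant <= 0:
            raise ValueError("repair time constant must be positive")
        if self.apposition_rate < 0:
            raise ValueError("apposition rate must be non-negative")
        if not 0 <= self.initial_inner_radius < self.initial_outer_radius:
            raise ValueError("need 0 <= inner radius < outer radius")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        if self.sn_scatter_sd < 0:
            raise ValueError("scatter SD must be non-negative")
        if self.repair_mode not in ("exponential", "linear"):
            raise ValueError("repair_mode must be 'exponential' or 'linear'")


@dataclass
class StatsConfig:
    alpha: float = 0.05
    adjustment: str = "bh"


@dataclass
class RunConfig:
    """One pipeline run: cohort + regimen + risk model + statistics settings.

    A single master ``seed`` deterministically derives per-stage seeds.
    ``strain_source`` selects where tibial strain comes from: ``"draws"``
    (per-subject draws from the configured strain distributions, the default)
    or ``"surrogate"`` (the beam-theory midshaft surrogate).
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    regimen: TrainingRegimen = field(default_factory=TrainingRegimen)
    risk_model: RiskModelParams = field(default_factory=RiskModelParams)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    strain_source: str = "draws"
    calibrate_sn: bool = True
    calibration_target_pct: float = 3.3  # male no-load cohort mean week-10 risk
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.strain_source not in ("draws", "surrogate"):
            raise ValueError("strain_source must be 'draws' or 'surrogate'")


# ---------------------------------------------------------------------------
# Serialization


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {_key_to_plain(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _key_to_plain(key: Any) -> Any:
    # YAML mapping keys stay strings so the file round-trips losslessly.
    return str(key) if isinstance(key, float) else key


def _restore_load_keys(group_params: dict) -> dict:
    out = {}
    for variable, by_sex in group_params.items():
        out[variable] = {}
        for sex, by_load in by_sex.items():
            out[variable][sex] = {
                float(load): tuple(ms) for load, ms in by_load.items()
            }
    return out


def config_to_dict(config: RunConfig) -> dict:
    return _to_plain(config)


def config_from_dict(data: dict) -> RunConfig:
    data = copy.deepcopy(data)
    cohort = data.get("cohort", {})
    if "group_params" in cohort:
        cohort["group_params"] = _restore_load_keys(cohort["group_params"])
    if "anthropometry" in cohort:
        cohort["anthropometry"] = {
            fieldname: {sex: tuple(v) for sex, v in by_sex.items()}
            for fieldname, by_sex in cohort["anthropometry"].items()
        }
    if "class_mixture" in cohort:
        cohort["class_mixture"] = tuple(cohort["class_mixture"])
    if "class_hu_params" in cohort:
        cohort["class_hu_params"] = {
            k: tuple(v) for k, v in cohort["class_hu_params"].items()
        }
    return RunConfig(
        cohort=CohortConfig(**cohort),
        regimen=TrainingRegimen(**data.get("regimen", {})),
        risk_model=RiskModelParams(**data.get("risk_model", {})),
        stats=StatsConfig(**data.get("stats", {})),
        **{
            k: v
            for k, v in data.items()
            if k not in ("cohort", "regimen", "risk_model", "stats")
        },
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path: str | Path) -> RunConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: RunConfig) -> str:
    """Stable short hash identifying a configuration (for provenance blocks)."""
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
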