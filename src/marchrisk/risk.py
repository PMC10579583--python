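"""Probabilistic tibial stress-fracture risk over a simulated training regimen.

The model combines four ingredients per calendar day:

* loading cycles: daily running distance divided by the subject's
  load-condition-dependent representative stride length;
* an S-N (strain-life) curve, log10(Nf) = intercept + slope*log10(strain),
  giving the fatigue life at the day's effective strain;
* Miner-rule damage accumulation with first-order repair (damage decays by a
  factor e over the repair time constant; a linear-removal variant is
  selectable);
* bone adaptation: periosteal apposition grows the outer radius of the
  midshaft annulus (default 4 um/day), and the strain adaptation ratio
  follows from beam theory, lowering the effective strain as training
  proceeds.

Stress-fracture risk by day d is the probability that cumulative damage has
reached 1, estimated by Monte-Carlo over lognormal scatter of the fatigue
life (common random numbers across conditions), with an exact closed form
available because damage is linear in the per-day increments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .config import RiskModelParams, TrainingRegimen
from .tibia import BeamCrossSection

#: Miner damage at failure, with an absolute tolerance so that exact
#: closed-form cases (e.g. N equal increments summing to 1) are not missed
#: to floating-point rounding.
FAILURE_THRESHOLD = 1.0 - 1e-9


@dataclass
class RiskTrajectory:
    """Per-calendar-day outputs of one risk simulation."""

    day: np.ndarray  # 1..7*weeks
    cumulative_risk: np.ndarray  # P(failure by day), in [0, 1], non-decreasing
    mean_damage: np.ndarray  # mean Miner damage across replicates
    adaptation_ratio: np.ndarray  # effective-strain multiplier applied that day
    failure_day: int | None = None  # deterministic (no-scatter) mode only

    @property
    def final_risk(self) -> float:
        return float(self.cumulative_risk[-1])


def loading_cycles_per_day(
    daily_distance: float, stride_length: float, round_cycles: bool = False
) -> float:
    """Loading cycles for one day: distance / stride length (0 on rest days)."""
    if stride_length <= 0:
        raise ValueError("stride length must be positive")
    cycles = daily_distance / stride_length
    return float(round(cycles)) if round_cycles else cycles


def fatigue_life(strain: float, params: RiskModelParams) -> float:
    """Cycles to failure at a strain level (microstrain) from the S-N curve;
    zero strain never fails."""
    if strain < 0:
        raise ValueError("strain must be non-negative")
    if strain == 0:
        return np.inf
    return 10.0 ** (params.sn_intercept + params.sn_slope * np.log10(strain))


def adaptation_ratio(elapsed_days: float, params: RiskModelParams) -> float:
    """Strain adaptation ratio after ``elapsed_days`` of periosteal apposition.

    The outer radius grows by the apposition rate per elapsed day (inner
    radius fixed); with bending-dominated loading the ratio is
    [c(t)/I(t)] / [c(0)/I(0)] with c the outer radius and I the annulus
    second moment.  ``adaptation_mode="combined"`` adds an axial term F/A in
    the configured proportion.  Equals 1 at t = 0 and is strictly decreasing
    for a positive apposition rate.
    """
    if elapsed_days < 0:
        raise ValueError("elapsed_days must be non-negative")
    if params.apposition_rate == 0:
        return 1.0
    r0 = params.initial_outer_radius
    ri = params.initial_inner_radius
    rt = r0 + params.apposition_rate * 1e-6 * elapsed_days

    def stress_index(r_out: float) -> float:
        section = BeamCrossSection(outer_radius=r_out, inner_radius=ri)
        bending = r_out / section.second_moment
        if params.adaptation_mode == "combined":
            # axial_per_bending is the F/A : M*c/I stress ratio at day 0.
            sec0 = BeamCrossSection(outer_radius=r0, inner_radius=ri)
            axial_scale = params.axial_per_bending * (sec0.outer_radius / sec0.second_moment) * sec0.area
            return bending + axial_scale / section.area
        return bending

    return stress_index(rt) / stress_index(r0)


def _repair_factor(params: RiskModelParams) -> float:
    return float(np.exp(-1.0 / params.repair_time_constant))


def damage_update(
    damage,
    strain_today: float,
    cycles_today: float,
    params: RiskModelParams,
    ratio: float = 1.0,
):
    """One day of Miner damage with repair.

    Exponential repair: D <- D * exp(-1/tau) + cycles/Nf(strain * ratio).
    Linear repair removes 1/tau of damage per day instead.  Rest days
    (``cycles_today`` = 0) apply repair only.  Accepts scalar or vector D
    (vector = Monte-Carlo replicates).
    """
    if cycles_today < 0:
        raise ValueError("cycles must be non-negative")
    damage = np.asarray(damage, dtype=float)
    if np.any(damage < 0):
        raise ValueError("damage must be non-negative")
    if np.isfinite(params.repair_time_constant):
        if params.repair_mode == "exponential":
            damage = damage * _repair_factor(params)
        else:
            damage = np.maximum(damage - 1.0 / params.repair_time_constant, 0.0)
    if cycles_today > 0:
        damage = damage + cycles_today / fatigue_life(strain_today * ratio, params)
    return damage if damage.ndim else float(damage)


def _daily_schedule(
    strain: float,
    stride_length: float,
    regimen: TrainingRegimen,
    params: RiskModelParams,
):
    """Per-day (cycles, effective strain, adaptation ratio) arrays."""
    days = np.arange(1, regimen.total_days + 1)
    cycles = np.array(
        [
            loading_cycles_per_day(
                regimen.distance_on(d), stride_length, params.round_cycles
            )
            for d in days
        ]
    )
    ratios = np.array([adaptation_ratio(d - 1, params) for d in days])
    return days, cycles, ratios


def _base_damage_trajectory(
    strain: float,
    stride_length: float,
    regimen: TrainingRegimen,
    params: RiskModelParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scatter-free damage trajectory (days, damage, ratios).  Because damage
    is linear in the daily increments, a replicate with log10-life offset z
    has trajectory damage * 10**(-z)."""
    days, cycles, ratios = _daily_schedule(strain, stride_length, regimen, params)
    damage = np.empty(len(days))
    d = 0.0
    for i in range(len(days)):
        d = damage_update(d, strain, cycles[i], params, ratio=ratios[i])
        damage[i] = d
    return days, damage, ratios


def risk_closed_form(
    strain: float,
    stride_length: float,
    regimen: TrainingRegimen,
    params: RiskModelParams,
) -> np.ndarray:
    """Exact cumulative risk per day under lognormal fatigue-life scatter.

    A replicate with scatter z ~ N(0, sigma) on log10 life fails by day d iff
    max_{s<=d} D0(s) * 10^(-z) >= 1, so risk(d) = Phi(log10 M(d) / sigma)
    with M the running maximum of the scatter-free damage trajectory.
    """
    _, damage, _ = _base_damage_trajectory(strain, stride_length, regimen, params)
    running_max = np.maximum.accumulate(damage)
    with np.errstate(divide="ignore"):
        log_m = np.log10(running_max)
    if params.sn_scatter_sd == 0:
        return (running_max >= FAILURE_THRESHOLD).astype(float)
    return norm.cdf(log_m / params.sn_scatter_sd)


def simulate_risk(
    strain: float,
    stride_length: float,
    regimen: TrainingRegimen,
    params: RiskModelParams,
    seed: int | None = None,
) -> RiskTrajectory:
    """Monte-Carlo risk trajectory over the regimen calendar.

    Each replicate draws one lognormal fatigue-life offset (SD
    ``sn_scatter_sd`` decades, common across days), accumulates damage with
    repair and adaptation, and fails when damage reaches 1;
    ``cumulative_risk(day)`` is the failed fraction.  With zero scatter the
    trajectory is the deterministic analytic mode and ``failure_day`` is set.
    Fixed seed implies an identical trajectory on re-run.
    """
    if params.mc_samples < 1:
        raise ValueError("mc_samples must be >= 1")
    days, base, ratios = _base_damage_trajectory(strain, stride_length, regimen, params)
    if params.sn_scatter_sd == 0:
        failed = np.maximum.accumulate(base) >= FAILURE_THRESHOLD
        failure_day = int(days[failed.argmax()]) if failed.any() else None
        return RiskTrajectory(
            day=days,
            cumulative_risk=failed.astype(float),
            mean_damage=base,
            adaptation_ratio=ratios,
            failure_day=failure_day,
        )
    rng = np.random.default_rng(params.seed if seed is None else seed)
    z = rng.normal(0.0, params.sn_scatter_sd, size=params.mc_samples)
    scale = 10.0 ** (-z)  # damage multiplier per replicate
    damage = np.outer(scale, base)  # (mc, days)
    failed_by = np.maximum.accumulate(damage >= FAILURE_THRESHOLD, axis=1)
    return RiskTrajectory(
        day=days,
        cumulative_risk=failed_by.mean(axis=0),
        mean_damage=damage.mean(axis=0),
        adaptation_ratio=ratios,
    )


def relative_risk_increase(risk_baseline: float, risk_loaded: float) -> float:
    """Relative increase 100*(loaded - baseline)/baseline, rounded to the
    integer percent the published convention uses."""
    if risk_baseline == 0:
        raise ValueError("baseline risk must be nonzero")
    return float(round(100.0 * (risk_loaded - risk_baseline) / risk_baseline))
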