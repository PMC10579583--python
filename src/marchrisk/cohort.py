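"""Seeded synthetic cohorts: subject anthropometrics, stride-structured
vertical ground-reaction-force trials, per-stride peak summaries, and tibial
element tables.

The generator reproduces the statistical structure of the emulated study —
two sexes, three carried-load conditions (0.0 / 11.3 / 22.7 kg), treadmill
running at 3.0 m/s — so that every downstream stage (stride selection, strain
surrogate, risk simulation, statistics) can be exercised without any
experimental data.  Anthropometrics are truncated normals within the
published per-sex ranges; gait peaks are plain normals at the published
per-sex, per-load means and SDs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import params as P
from . import tibia
from .config import CohortConfig


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometrics of one synthetic subject."""

    subject_id: str
    sex: str
    age: float  # years
    mass: float  # kg
    height: float  # m
    foot_length: float  # m
    body_fat: float  # percent

    @property
    def bmi(self) -> float:
        return self.mass / self.height**2

    @property
    def body_weight(self) -> float:
        """Weight force, N."""
        return self.mass * P.GRAVITY


@dataclass
class GaitTrial:
    """One subject x load GRF recording on a uniform time grid."""

    subject_id: str
    load: float  # kg carried
    time: np.ndarray  # s
    vertical_grf: np.ndarray  # N
    sampling_rate: float  # Hz
    speed: float  # m/s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "fz_n": self.vertical_grf})


def _truncnorm_ppf(u: np.ndarray, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    """Quantile transform onto a truncated normal; degenerate SD=0 gives the mean."""
    if sd == 0:
        return np.full_like(np.asarray(u, dtype=float), mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def truncated_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Mean of the truncated normal actually sampled (differs from ``mean``
    when the printed range is asymmetric about it)."""
    if sd == 0:
        return mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.mean(a, b, loc=mean, scale=sd))


def generate_subjects(config: CohortConfig, rng: np.random.Generator | None = None) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles.

    Marginals are exact truncated normals at the configured (mean, SD, range);
    mass and height are coupled through a Gaussian copula
    (``config.mass_height_rho``) so the derived BMI has a realistic spread.
    Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    subjects: list[SubjectProfile] = []
    for sex, prefix in ((P.FEMALE, "F"), (P.MALE, "M")):
        n = config.n_for_sex(sex)
        anthro = config.anthropometry
        z_mass = rng.standard_normal(n)
        z_h = config.mass_height_rho * z_mass + np.sqrt(
            1.0 - config.mass_height_rho**2
        ) * rng.standard_normal(n)
        from scipy.stats import norm

        mass = _truncnorm_ppf(norm.cdf(z_mass), *anthro["mass"][sex])
        height = _truncnorm_ppf(norm.cdf(z_h), *anthro["height"][sex])
        age = _truncnorm_ppf(rng.uniform(size=n), *anthro["age"][sex])
        foot = _truncnorm_ppf(rng.uniform(size=n), *anthro["foot_length"][sex])
        fat = _truncnorm_ppf(rng.uniform(size=n), *anthro["body_fat"][sex])
        for i in range(n):
            subjects.append(
                SubjectProfile(
                    subject_id=f"{prefix}{i + 1:02d}",
                    sex=sex,
                    age=float(age[i]),
                    mass=float(mass[i]),
                    height=float(height[i]),
                    foot_length=float(foot[i]),
                    body_fat=float(fat[i]),
                )
            )
    return subjects


def subjects_frame(subjects: list[SubjectProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "sex": [s.sex for s in subjects],
            "age_years": [s.age for s in subjects],
            "mass_kg": [s.mass for s in subjects],
            "height_m": [s.height for s in subjects],
            "foot_length_m": [s.foot_length for s in subjects],
            "body_fat_pct": [s.body_fat for s in subjects],
            "bmi_kg_m2": [s.bmi for s in subjects],
        }
    )


# ---------------------------------------------------------------------------
# GRF waveform synthesis

_SHAPE_GRID = np.linspace(0.0, 1.0, 2001)


def _stance_shape(impact_ratio: float) -> tuple[np.ndarray, float]:
    """Normalized double-bump stance shape on [0, 1]: a full-stance active
    (raised-cosine) bump plus an early impact bump of relative prominence
    ``impact_ratio``.  Returns (shape values on the internal grid, max)."""
    tau = _SHAPE_GRID
    active = 0.5 * (1.0 - np.cos(2.0 * np.pi * tau))
    center, half = 0.15, 0.15
    impact = np.where(
        np.abs(tau - center) < half,
        0.5 * (1.0 + np.cos(np.pi * (tau - center) / half)),
        0.0,
    )
    g = active + impact_ratio * impact
    return g, float(g.max())


def _subject_impact_ratio(subject: SubjectProfile, config: CohortConfig, rng: np.random.Generator) -> float:
    if not config.foot_strike_mix:
        return config.impact_ratio
    p_rear = P.REARFOOT_PROPORTION[subject.sex]
    rearfoot = rng.uniform() < p_rear
    return config.rearfoot_impact_ratio if rearfoot else config.nonrearfoot_impact_ratio


def generate_grf_trial(
    subject: SubjectProfile,
    load: float,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> GaitTrial:
    """Synthesize one vertical-GRF trial.

    Stance is a smooth double-bump whose support starts and ends exactly at
    the segmentation threshold, so the detected stance duration equals the
    generated one to within a sample period.  The per-subject stance
    duration, normalized stride length, and peak GRF (in bodyweights) are
    drawn from the configured sex x load distributions; strides within the
    trial jitter around the subject values with CV ``config.stride_cv``.
    Swing-phase samples carry baseline noise clipped strictly below the
    threshold.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    thr = config.segmentation_threshold

    def draw(variable: str) -> float:
        mean, sd = config.group_params[variable][subject.sex][load]
        return float(rng.normal(mean, sd)) if sd > 0 else mean

    stance_subj = max(draw("stance_duration"), 0.05)
    nsl_subj = max(draw("normalized_stride_length"), 0.3)
    peak_bw = max(draw("grf_peak"), 1.2)
    reference_weight = subject.body_weight
    if config.bw_includes_load:
        reference_weight = (subject.mass + load) * P.GRAVITY
    peak_n = peak_bw * reference_weight

    stride_subj = nsl_subj * subject.height / config.speed
    stance_subj = min(stance_subj, 0.9 * stride_subj)

    impact_ratio = _subject_impact_ratio(subject, config, rng)
    shape, shape_max = _stance_shape(impact_ratio)

    n_samples = int(round(config.trial_duration * config.grf_sampling_rate)) + 1
    dt = 1.0 / config.grf_sampling_rate
    time = np.arange(n_samples) * dt
    if config.baseline_noise_sd > 0:
        grf = rng.normal(0.0, config.baseline_noise_sd, size=n_samples)
        np.clip(grf, -0.8 * thr, 0.8 * thr, out=grf)
    else:
        grf = np.zeros(n_samples)

    cv = config.stride_cv
    t0 = 0.25 * stride_subj  # partial leading swing
    start = t0
    n_footstrikes = 0
    while True:
        stride_k = stride_subj * max(1.0 + cv * rng.standard_normal(), 0.5)
        stance_k = min(
            stance_subj * max(1.0 + cv * rng.standard_normal(), 0.5), 0.9 * stride_k
        )
        peak_k = max(peak_n * (1.0 + cv * rng.standard_normal()), 2.0 * thr)
        if start + stance_k > config.trial_duration:
            break
        i0 = int(np.ceil(start / dt))
        i1 = int(np.floor((start + stance_k) / dt))
        tau = (time[i0 : i1 + 1] - start) / stance_k
        g = np.interp(tau, _SHAPE_GRID, shape) / shape_max
        grf[i0 : i1 + 1] = thr + (peak_k - thr) * g
        n_footstrikes += 1
        start += stride_k

    if n_footstrikes - 1 < 20:
        raise ValueError(
            f"trial too short: only {n_footstrikes - 1} complete strides "
            "(need >= 20); increase trial_duration"
        )
    return GaitTrial(
        subject_id=subject.subject_id,
        load=load,
        time=time,
        vertical_grf=grf,
        sampling_rate=config.grf_sampling_rate,
        speed=config.speed,
    )


def write_trial_csv(trial: GaitTrial, path) -> None:
    trial.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_trial_csv(path, subject_id: str = "", load: float = 0.0, speed: float = P.RUNNING_SPEED) -> GaitTrial:
    df = pd.read_csv(path)
    time = df["time_s"].to_numpy()
    dt = np.diff(time)
    if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trial time grid is not uniform")
    return GaitTrial(
        subject_id=subject_id,
        load=load,
        time=time,
        vertical_grf=df["fz_n"].to_numpy(),
        sampling_rate=1.0 / dt[0] if len(dt) else 0.0,
        speed=speed,
    )


# ---------------------------------------------------------------------------
# Peak summaries

def draw_peak_summary(
    subject: SubjectProfile,
    load: float,
    config: CohortConfig,
    rng: np.random.Generator,
    latent: dict[str, float] | None = None,
    variables: tuple[str, ...] = P.PEAK_VARIABLES,
) -> dict[str, float]:
    """One draw per variable from the subject's sex x load distribution.

    ``latent`` (a per-subject standard-normal effect per variable) induces the
    configured within-subject correlation across load conditions while leaving
    each marginal at its configured mean and SD.
    """
    rho = config.within_subject_rho
    out: dict[str, float] = {}
    for variable in variables:
        if variable not in config.group_params:
            raise KeyError(f"unknown variable {variable!r}")
        mean, sd = config.group_params[variable][subject.sex][load]
        z = latent.get(variable, 0.0) if latent else 0.0
        if latent:
            eps = rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal()
        else:
            eps = rng.standard_normal()
        out[variable] = mean + sd * eps
    return out


def generate_peak_summaries(
    subjects: list[SubjectProfile],
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    variables: tuple[str, ...] = P.PEAK_VARIABLES,
) -> pd.DataFrame:
    """Peak-summary table: one row per subject x load, one column per variable."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for subject in subjects:
        latent = {v: float(rng.standard_normal()) for v in variables}
        for load in P.LOADS:
            row = {"subject_id": subject.subject_id, "sex": subject.sex, "load": load}
            row.update(draw_peak_summary(subject, load, config, rng, latent, variables))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tibial element synthesis

def generate_tibia_elements(
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    subject: SubjectProfile | None = None,
    calibration: tibia.HUCalibration | None = None,
    n_elements: int | None = None,
) -> pd.DataFrame:
    """Element table (element_id, hu, volume_mm3) whose induced moduli populate
    the configured tissue-class mixture.

    Per-class Hounsfield units are normal draws clipped to the HU interval
    that the calibration maps into that class, so the induced classification
    is consistent with the mixture by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if calibration is None:
        calibration = tibia.HUCalibration()
    n = n_elements if n_elements is not None else config.n_elements
    mixture = np.asarray(config.class_mixture, dtype=float)
    if mixture.sum() <= 0 or len(mixture) != 3:
        raise ValueError("class mixture must be 3 non-negative proportions")
    mixture = mixture / mixture.sum()
    classes = rng.choice(3, size=n, p=mixture)
    class_names = np.array(tibia.TISSUE_CLASSES)
    hu_lo, hu_hi = tibia.class_hu_bounds(calibration)
    hu = np.empty(n)
    for k, name in enumerate(tibia.TISSUE_CLASSES):
        mask = classes == k
        mean, sd = config.class_hu_params[name]
        draws = rng.normal(mean, sd, size=mask.sum())
        hu[mask] = np.clip(draws, hu_lo[k], hu_hi[k])
    volume = rng.gamma(shape=4.0, scale=0.5, size=n)  # mm^3, mean 2
    return pd.DataFrame(
        {
            "element_id": np.arange(n),
            "hu": hu,
            "volume_mm3": volume,
            "class_drawn": class_names[classes],
        }
    )
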