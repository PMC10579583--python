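"""Published group-level parameters used as generator defaults and worked examples.

These are the study conditions the synthetic cohort emulates: anthropometrics by
sex (mean, SD, range), and per-sex, per-load-condition means and SDs for the
spatiotemporal, kinematic, kinetic, tibial-strain, and stress-fracture-risk
variables of a 3.0 m/s loaded treadmill-running protocol (loads 0.0, 11.3 and
22.7 kg, 20 women / 21 men).
"""

from __future__ import annotations

FEMALE = "female"
MALE = "male"
SEXES = (FEMALE, MALE)

#: External load conditions, kg carried in a symmetric vest.
LOADS = (0.0, 11.3, 22.7)

#: Fixed treadmill speed, m/s.
RUNNING_SPEED = 3.0

#: Group sizes of the emulated study.
N_FEMALE = 20
N_MALE = 21

GRAVITY = 9.81  # m/s^2

#: Anthropometrics: field -> sex -> (mean, sd, low, high).
ANTHROPOMETRY = {
    "age": {FEMALE: (19.7, 1.0, 18.0, 21.0), MALE: (19.6, 1.2, 18.0, 21.0)},
    "mass": {FEMALE: (60.3, 6.4, 47.7, 71.8), MALE: (72.0, 6.3, 60.0, 83.7)},
    "height": {FEMALE: (1.65, 0.08, 1.49, 1.77), MALE: (1.77, 0.06, 1.62, 1.88)},
    "foot_length": {FEMALE: (0.24, 0.01, 0.22, 0.26), MALE: (0.27, 0.01, 0.26, 0.29)},
    "body_fat": {FEMALE: (18.3, 3.0, 14.5, 26.4), MALE: (8.7, 1.9, 6.0, 13.2)},
}

#: Proportion of rear-foot strikers by sex (used only when the foot-strike
#: mixture knob of the generator is enabled).
REARFOOT_PROPORTION = {FEMALE: 0.70, MALE: 0.57}

# Per-variable (mean, sd) keyed [variable][sex][load].  Units:
#   stance_duration s; normalized_stride_length unitless (stride length / height);
#   angles degrees; moments N*m/kg; grf_peak and JRFs in bodyweights (BW);
#   tibial_strain microstrain; sf_risk percent.
GROUP_PARAMS = {
    "stance_duration": {
        FEMALE: {0.0: (0.25, 0.02), 11.3: (0.28, 0.02), 22.7: (0.29, 0.02)},
        MALE: {0.0: (0.26, 0.02), 11.3: (0.29, 0.02), 22.7: (0.30, 0.02)},
    },
    "normalized_stride_length": {
        FEMALE: {0.0: (1.27, 0.09), 11.3: (1.25, 0.08), 22.7: (1.22, 0.07)},
        MALE: {0.0: (1.23, 0.07), 11.3: (1.23, 0.07), 22.7: (1.21, 0.07)},
    },
    "trunk_flexion": {
        FEMALE: {0.0: (16.8, 4.6), 11.3: (17.5, 4.6), 22.7: (19.0, 3.9)},
        MALE: {0.0: (20.1, 4.6), 11.3: (22.4, 4.1), 22.7: (22.5, 3.9)},
    },
    "hip_flexion": {
        FEMALE: {0.0: (42.3, 7.7), 11.3: (43.7, 7.1), 22.7: (46.1, 6.4)},
        MALE: {0.0: (37.1, 7.3), 11.3: (36.6, 6.0), 22.7: (36.4, 6.6)},
    },
    "hip_extension": {
        FEMALE: {0.0: (19.4, 9.1), 11.3: (19.1, 9.9), 22.7: (18.6, 7.9)},
        MALE: {0.0: (21.8, 7.8), 11.3: (22.3, 7.7), 22.7: (22.4, 7.7)},
    },
    "knee_flexion": {
        FEMALE: {0.0: (49.5, 5.1), 11.3: (49.2, 5.0), 22.7: (49.2, 5.5)},
        MALE: {0.0: (45.9, 5.2), 11.3: (46.4, 5.0), 22.7: (46.0, 5.5)},
    },
    "ankle_plantarflexion": {
        FEMALE: {0.0: (18.0, 7.9), 11.3: (16.5, 8.6), 22.7: (15.4, 7.1)},
        MALE: {0.0: (17.6, 8.1), 11.3: (18.5, 7.7), 22.7: (17.7, 7.6)},
    },
    "ankle_dorsiflexion": {
        FEMALE: {0.0: (42.1, 4.8), 11.3: (44.0, 4.9), 22.7: (45.2, 5.6)},
        MALE: {0.0: (36.6, 4.8), 11.3: (38.2, 5.3), 22.7: (39.0, 5.3)},
    },
    "grf_peak": {
        FEMALE: {0.0: (2.4, 0.1), 11.3: (2.6, 0.2), 22.7: (2.8, 0.2)},
        MALE: {0.0: (2.5, 0.2), 11.3: (2.6, 0.2), 22.7: (2.8, 0.3)},
    },
    "hip_flexion_moment": {
        FEMALE: {0.0: (0.9, 0.1), 11.3: (1.1, 0.2), 22.7: (1.2, 0.2)},
        MALE: {0.0: (0.9, 0.1), 11.3: (1.0, 0.1), 22.7: (1.1, 0.2)},
    },
    "hip_extension_moment": {
        FEMALE: {0.0: (1.8, 0.2), 11.3: (2.1, 0.3), 22.7: (2.4, 0.2)},
        MALE: {0.0: (2.2, 0.5), 11.3: (2.5, 0.5), 22.7: (2.7, 0.4)},
    },
    "knee_extension_moment": {
        FEMALE: {0.0: (2.4, 0.5), 11.3: (2.4, 0.5), 22.7: (2.6, 0.5)},
        MALE: {0.0: (2.2, 0.4), 11.3: (2.3, 0.5), 22.7: (2.5, 0.5)},
    },
    "ankle_pf_moment": {
        FEMALE: {0.0: (2.6, 0.3), 11.3: (2.8, 0.2), 22.7: (2.9, 0.3)},
        MALE: {0.0: (3.0, 0.5), 11.3: (3.1, 0.5), 22.7: (3.3, 0.5)},
    },
    "hip_jrf": {
        FEMALE: {0.0: (9.4, 1.5), 11.3: (10.4, 1.7), 22.7: (11.6, 1.4)},
        MALE: {0.0: (8.0, 1.5), 11.3: (8.6, 1.4), 22.7: (9.3, 1.5)},
    },
    "knee_jrf": {
        FEMALE: {0.0: (12.6, 0.8), 11.3: (13.8, 1.1), 22.7: (15.1, 1.4)},
        MALE: {0.0: (11.5, 1.2), 11.3: (12.5, 1.4), 22.7: (13.1, 1.5)},
    },
    "ankle_jrf": {
        FEMALE: {0.0: (12.7, 0.9), 11.3: (13.7, 1.4), 22.7: (14.9, 1.6)},
        MALE: {0.0: (11.7, 1.9), 11.3: (12.4, 1.8), 22.7: (13.1, 2.0)},
    },
    "tibial_strain": {
        FEMALE: {0.0: (5007.0, 867.0), 11.3: (5439.0, 1042.0), 22.7: (5908.0, 1159.0)},
        MALE: {0.0: (4540.0, 906.0), 11.3: (4835.0, 1045.0), 22.7: (5036.0, 1191.0)},
    },
    "sf_risk": {
        FEMALE: {0.0: (4.5, 5.5), 11.3: (8.9, 10.3), 22.7: (15.7, 16.9)},
        MALE: {0.0: (3.3, 6.0), 11.3: (5.6, 12.0), 22.7: (7.7, 14.4)},
    },
}

#: The 16 per-stride peak variables (everything except the two spatiotemporal
#: rows, which the stride-selection stage measures from the waveform instead).
PEAK_VARIABLES = tuple(
    v
    for v in GROUP_PARAMS
    if v not in ("stance_duration", "normalized_stride_length")
)

ALL_VARIABLES = tuple(GROUP_PARAMS)


def group_mean_sd(variable: str, sex: str, load: float) -> tuple[float, float]:
    """Look up the (mean, SD) of one variable for one sex and load condition."""
    try:
        return GROUP_PARAMS[variable][sex][load]
    except KeyError as exc:
        raise KeyError(
            f"no group parameters for variable={variable!r} sex={sex!r} load={load!r}"
        ) from exc
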