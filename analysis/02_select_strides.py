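"""Generate one vertical-GRF trial per subject and load condition, run the
six-step representative-stride selection (25 N segmentation, 100-point
resampling, pointwise median, FMD depth, argmin), and tabulate the
spatiotemporal parameters of the selected strides.

Writes results/strides/spatiotemporal.csv and a demo trial +
representative-stride CSV for one subject.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from marchrisk import cohort as co
from marchrisk import params as P
from marchrisk import strides as sd
from marchrisk.config import CohortConfig, RunConfig
from marchrisk.pipeline import measure_spatiotemporal

SEED = 11
OUT = Path("results/strides")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = RunConfig(seed=SEED)
    config.cohort = CohortConfig(seed=SEED)
    rng = np.random.default_rng(SEED)
    subjects = co.generate_subjects(config.cohort, rng)

    table = measure_spatiotemporal(subjects, config, np.random.default_rng(SEED + 1))
    table.to_csv(OUT / "spatiotemporal.csv", index=False, float_format="%.4f")

    print("stance duration (s) / normalized stride length, mean (SD):")
    for load in P.LOADS:
        line = [f"  load {load:>4} kg:"]
        for sex in P.SEXES:
            sub = table[(table["sex"] == sex) & (table["load"] == load)]
            line.append(
                f"{sex} {sub.stance_duration.mean():.3f} ({sub.stance_duration.std():.3f}) / "
                f"{sub.normalized_stride_length.mean():.2f} ({sub.normalized_stride_length.std():.2f})"
            )
        print("  ".join(line))

    # demo: write one raw trial and its representative stride
    demo = subjects[0]
    trial = co.generate_grf_trial(demo, 0.0, config.cohort, np.random.default_rng(99))
    co.write_trial_csv(trial, OUT / "trial_demo.csv")
    rep, depth, all_strides = sd.representative_stride(
        trial.time, trial.vertical_grf, trial_id=demo.subject_id
    )
    pd.DataFrame({"point": np.arange(100), "fz_n": rep.grf_resampled}).to_csv(
        OUT / "representative_stride_demo.csv", index=False, float_format="%.3f"
    )
    print(
        f"demo subject {demo.subject_id}: {len(all_strides)} strides, "
        f"representative index {depth.selected_index}, "
        f"depth {depth.depths[depth.selected_index]:.2f} N"
    )


if __name__ == "__main__":
    main()
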