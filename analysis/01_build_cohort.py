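"""Build the 10-patient virtual AF cohort.

Draws each patient's target LV end-diastolic volume from the truncated
normal N(117, 30^2) mL law, assigns sex at an exact 60% male split, and
writes the cohort manifest.  Age and BMI are carried as metadata only.

Run:  python analysis/01_build_cohort.py [--seed 1]
"""

import argparse
from pathlib import Path

from afloop.config import RunConfig
from afloop.pipeline import _cohort_seed
from afloop.virtual_cohort import cohort_manifest, generate_cohort


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    config = RunConfig(master_seed=args.seed)
    cohort = generate_cohort(
        config.n_patients, _cohort_seed(config.master_seed), config.cohort
    )
    df = cohort_manifest(cohort, config.master_seed)
    args.out.mkdir(parents=True, exist_ok=True)
    path = args.out / "cohort.csv"
    df.to_csv(path, index=False)

    n_male = (df.sex == "male").sum()
    print(f"cohort of {len(df)} virtual patients -> {path}")
    print(f"  sex: {n_male} male / {len(df) - n_male} female")
    print(
        f"  EDV targets: {df.edv_target_ml.mean():.1f} +- "
        f"{df.edv_target_ml.std(ddof=1):.1f} mL "
        f"(range {df.edv_target_ml.min():.0f}-{df.edv_target_ml.max():.0f})"
    )


if __name__ == "__main__":
    main()
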