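"""Summarise the trial: treatment contrasts versus untreated AF.

Aggregates the factorial results into a table of scenario means, percent
LVSV change and absolute LVEF change versus untreated AF, with paired t
tests Bonferroni-corrected over the four management arms (alpha = .01).
Also writes tidy per-patient points for box plots and, when matplotlib is
available, the box-plot figures themselves.

Run after 03:  python analysis/04_summarize_trial.py
"""

import argparse
from pathlib import Path

import pandas as pd

from afloop.stats import summarize_cohort


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument(
        "--results", type=Path, default=Path("results/results.csv")
    )
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    results = pd.read_csv(args.results)
    summary = summarize_cohort(results)

    args.out.mkdir(parents=True, exist_ok=True)
    summary.to_csv(args.out / "summary.csv", index=False)
    tidy = results[
        ["patient_id", "scenario_key", "clinical_label", "lvsv", "lvef"]
    ]
    tidy.to_csv(args.out / "boxplot_data.csv", index=False)

    labelled = summary[summary.clinical_label != ""]
    cols = [
        "clinical_label", "lvsv_mean_ml", "lvsv_sd_ml", "lvef_mean_pct",
        "lvef_sd_pct", "pct_sv_vs_af_mean", "delta_ef_vs_af_mean_pp",
        "p_adjusted", "significant",
    ]
    print(labelled[cols].to_string(index=False, float_format="%.2f"))

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        order = [
            "Rapidly conducted AF",
            "Pharmacologically rate-controlled AF",
            "Paced rate-controlled AF",
            "Sinus rhythm with irregularity",
            "Successfully restored sinus rhythm",
        ]
        fig, axes = plt.subplots(2, 1, figsize=(8, 7), sharex=True)
        for ax, metric, label in zip(
            axes, ("lvsv", "lvef"), ("LVSV [mL]", "LVEF [%]")
        ):
            data = [
                tidy.loc[tidy.clinical_label == lab, metric] for lab in order
            ]
            ax.boxplot(data, tick_labels=[lab.replace(" ", "\n") for lab in order])
            ax.set_ylabel(label)
        fig.tight_layout()
        fig.savefig(args.out / "figures_trial_boxplots.png", dpi=150)
        print(f"figures -> {args.out / 'figures_trial_boxplots.png'}")
    except ImportError:
        print("matplotlib unavailable; skipped figures")


if __name__ == "__main__":
    main()
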