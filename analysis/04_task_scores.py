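"""Y-maze strategy labels and town route-learning / pointing scores.

Classifies every probe trial (allocentric / egocentric / ego+ excluded),
scores rounds-to-criterion and cumulative route errors, and summarizes
pointing accuracy and speed.  Writes results/scores/task_scores.csv.

Run:  python analysis/04_task_scores.py [--seed 1]
"""

import argparse
import sys
from pathlib import Path

HERE = Path(__file__).resolve().parent
sys.path.insert(0, str(HERE))
from _shared import study_config  # noqa: E402

from navscape.pipeline import score_tables, simulate_cohort  # noqa: E402

OUT = HERE.parent / "results" / "scores"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-per-cell", type=int, default=8)
    args = ap.parse_args()

    cfg = study_config(args.seed, args.n_per_cell)
    _, _, ymazes, towns = simulate_cohort(cfg)
    scores = score_tables(ymazes, towns)

    OUT.mkdir(parents=True, exist_ok=True)
    scores.to_csv(OUT / "task_scores.csv", index=False)

    print("Y-maze strategy counts per cell:")
    print(scores.groupby("cell")["ymaze_label"].value_counts().unstack(fill_value=0))
    print("\ntown task (means):")
    print(scores.groupby("cell")[["rounds_to_criterion", "route_errors",
                                  "mean_pointing_error", "mean_pointing_rt"]]
          .mean().round(2))
    print(f"\nwrote {OUT/'task_scores.csv'}")


if __name__ == "__main__":
    main()
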