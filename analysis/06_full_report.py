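"""Run the entire pipeline in one pass and write the report bundle.

Equivalent to `navscape all`: simulation, metric tables, maps/Gi*, task
scores, model fits, and a summary.md with a provenance line for every
statistic.  Everything lands in results/full_report/.

Run:  python analysis/06_full_report.py [--seed 1]
"""

import argparse
import sys
from pathlib import Path

HERE = Path(__file__).resolve().parent
sys.path.insert(0, str(HERE))
from _shared import study_config  # noqa: E402

from navscape.pipeline import run_study  # noqa: E402

OUT = HERE.parent / "results" / "full_report"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-per-cell", type=int, default=8)
    args = ap.parse_args()

    run_study(study_config(args.seed, args.n_per_cell), OUT)
    print((OUT / "summary.md").read_text())


if __name__ == "__main__":
    main()
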