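"""Does combining head movement with gaze increase decisions?

Reads the report from analysis 03 (rerunning the pipeline if absent) and
summarises the head+gaze decision combination per validation split: how
many trials get a decision from either source, how often both agree, and
the quality of the merged decisions.  Writes results/combination.csv.
"""

import json
from pathlib import Path

import pandas as pd

from soundturn import pipeline as pl

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    report_path = ROOT / "results" / "run" / "report.json"
    if report_path.exists():
        report = json.load(open(report_path))
    else:
        report = pl.run_pipeline(pl.PipelineConfig(seed=SEED),
                                 ROOT / "results" / "run")
    rows = []
    for split, c in report["combination"].items():
        rows.append({
            "split": split,
            "n_decisions_head": c["n_decisions_head"],
            "n_decisions_gaze": c["n_decisions_gaze"],
            "n_decisions_combined": c["n_decisions_combined"],
            "n_both": c["n_both"], "n_agree": c["n_agree"],
            "n_conflict": c["n_conflict"],
            "specificity_pct": c["specificity_pct"],
        })
        print(f"{split}: head {c['n_decisions_head']} + gaze "
              f"{c['n_decisions_gaze']} -> combined "
              f"{c['n_decisions_combined']} decisions "
              f"({c['n_agree']}/{c['n_both']} agreements, "
              f"{c['n_conflict']} conflicts), "
              f"specificity {c['specificity_pct']}%")
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "combination.csv", index=False)


if __name__ == "__main__":
    main()
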