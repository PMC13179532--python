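"""Recompute the published validation statistics from the recorded tables.

The original study's prediction counts (class x speaker side per feature
set and split) are recorded in soundturn.reference_counts; this script
rederives specificity, exact one-sided binomial tests, decision accounting
and the cross-feature-set averages from those counts alone.  Writes
results/reference_statistics.csv.
"""

from pathlib import Path

import pandas as pd

from soundturn.decisions import (
    average_correct_rate,
    binomial_p_one_sided,
    specificity,
)
from soundturn.reference_counts import SPLITS, reference_tables

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = []
    for split in SPLITS:
        tables = reference_tables(split)
        for fs, t in tables.items():
            s = specificity(t)
            rows.append({
                "split": split, "feature_set": fs,
                "n_trials": t.n_trials, "n_decisions": t.n_decisions,
                "n_correct": t.n_correct,
                "specificity_pct": None if s is None else round(100 * s, 1),
                "p_one_sided": (None if t.n_decisions == 0 else
                                binomial_p_one_sided(t.n_correct, t.n_decisions)),
            })
        avg = average_correct_rate(tables.values())
        print(f"{split}: average correct-decision rate {avg}%")
    df = pd.DataFrame(rows)
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "reference_statistics.csv", index=False)
    inf = df[df["split"] == "validation_infant"]
    print(inf.to_string(index=False))


if __name__ == "__main__":
    main()
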