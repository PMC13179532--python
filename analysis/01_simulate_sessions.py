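"""Simulate the study cohort: 28 infants + 30 toddlers, 10 lateralized
sounds each.

Writes the stimulus log and a per-group trial summary to results/, and the
raw per-frame OpenFace-dialect session tables to scratch/sessions/ (they are
bulky and regenerable from the seed).
"""

from pathlib import Path

import pandas as pd

from soundturn import synth

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    schedule, frames = synth.simulate_cohort(28, 30, SEED)
    out_raw = ROOT / "scratch" / "sessions"
    paths = synth.write_session(schedule, frames, out_raw)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    log = synth.schedule_to_frame(schedule)
    log.to_csv(results / "stimulus_log.csv", index=False)

    summary = (log.groupby("group")
               .agg(participants=("participant_id", "nunique"),
                    trials=("trial_index", "size"))
               .reset_index())
    summary.to_csv(results / "cohort_summary.csv", index=False)

    n_frames = sum(len(f) for f in frames.values())
    print(f"simulated {len(log)} trials for "
          f"{log['participant_id'].nunique()} participants (seed {SEED})")
    print(summary.to_string(index=False))
    print(f"wrote {len(paths['features'])} session tables "
          f"({n_frames} frames) to {out_raw}")


if __name__ == "__main__":
    main()
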