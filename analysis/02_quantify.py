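"""Descriptive quantification of the simulated study.

Computes the per-dyad face-looking summaries and comment summaries, prints
the study-level descriptive table (the analogue of a corpus descriptives
table), and runs the paired t-test contrasting appropriate vs non-attuned
mind-related comment proportions across mothers.

Reads results/sim/, writes results/summaries.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gazemind import paired_t, read_session, summarize_comments, summarize_looking
from gazemind.gaze import summaries_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    frames = ROOT / "sim" / "frames.csv"
    comments = ROOT / "sim" / "comments.csv"
    dyads = sorted(pd.read_csv(frames)["dyad_id"].astype(str).unique())
    sessions = [read_session(frames, comments, dyad_id=d) for d in dyads]

    look = summaries_table([summarize_looking(s) for s in sessions])
    comm = pd.DataFrame(
        [vars(summarize_comments(s.comments, dyad_id=s.dyad_id)) for s in sessions]
    )
    tbl = look.merge(comm, on="dyad_id")
    tbl.to_csv(ROOT / "summaries.csv", index=False)

    print("study descriptives (mean +- SD over dyads):")
    for col, label in [
        ("n_comments", "comments per session"),
        ("prop_appropriate", "appropriate mind-related proportion"),
        ("prop_nonattuned", "non-attuned mind-related proportion"),
        ("p_pupil", "pupil-detected proportion"),
        ("p_face_present", "face-present proportion"),
        ("p_looking_total", "face-looking / all frames"),
        ("p_looking_given_face_pupil", "face-looking / face+pupil frames"),
    ]:
        print(f"  {label}: {tbl[col].mean():.4f} +- {tbl[col].std(ddof=1):.4f}")

    t, df, p = paired_t(tbl["prop_appropriate"], tbl["prop_nonattuned"])
    print(f"appropriate vs non-attuned: paired t({df}) = {t:.2f}, p = {p:.2e}")


if __name__ == "__main__":
    main()
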