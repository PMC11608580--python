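"""Between-dyad association: face-looking tendency vs verbal mind-mindedness.

Binomial GLM (logit link): successes = face-looking frame counts, trials =
frames with face present and pupils detected, covariate = proportion of
appropriate mind-related comments; likelihood-ratio test of the slope.

With the default (rho_link = 0) simulation no association is expected; the
script reports whatever the data say. Note the model is the plain binomial
GLM, which understates between-dyad overdispersion by design (it mirrors
the reported analysis), so its p-value should be read with that caveat.

Reads results/sim/, writes results/between_dyad.json.
"""

import json
from pathlib import Path

import pandas as pd

from gazemind import between_dyad_analysis, read_session, summarize_comments, summarize_looking

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    frames = ROOT / "sim" / "frames.csv"
    comments = ROOT / "sim" / "comments.csv"
    dyads = sorted(pd.read_csv(frames)["dyad_id"].astype(str).unique())
    sessions = [read_session(frames, comments, dyad_id=d) for d in dyads]
    look = [summarize_looking(s) for s in sessions]
    comm = [summarize_comments(s.comments, dyad_id=s.dyad_id) for s in sessions]

    fit, test = between_dyad_analysis(look, comm)
    print(f"GLM slope (log-odds per unit MM score): {fit.coefficients[1]:.3f} "
          f"(SE {fit.bse[1]:.3f})")
    print(f"LRT: chi2({test.df}) = {test.chi2:.2f}, p = {test.p:.3g}")
    payload = {
        "coefficients": [float(c) for c in fit.coefficients],
        "bse": [float(b) for b in fit.bse],
        "loglik": fit.loglik,
        "chi2": test.chi2, "df": test.df, "p": test.p,
    }
    with open(ROOT / "between_dyad.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
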