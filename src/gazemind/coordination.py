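"""Windowed comment-gaze coincidence coding and the two core analyses.

Between dyads: a binomial GLM asks whether mothers who produce a larger
proportion of appropriate mind-related comments also look at their infant's
face in a larger proportion of eligible frames.

Within dyads: each comment is coded for whether any face-looking frame
falls inside a time window centered on its onset (default 5 s, i.e. 2.5 s
either side), and a logistic mixed model with a random intercept per mother
asks whether that coincidence is more likely for appropriate mind-related
comments than for all other comments, with a likelihood-ratio test against
the class-free null. Robustness companions: a window-size sweep and a
first-half/second-half contrast restricted to appropriate comments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gaze import FaceLookingSummary
from .mindedness import CommentSummary
from .models import (
    GlmFit,
    GlmmFit,
    LrtResult,
    fit_binomial_glm,
    fit_binomial_glmm,
    lrt,
)
from .streams import APPROPRIATE_MR, DyadSession

APPROPRIATE = "appropriate"
OTHER_CLASS = "other"


@dataclass(frozen=True)
class CoincidenceRecord:
    """Per-comment coincidence outcome within one window size."""

    dyad_id: str
    comment_id: int
    comment_class: str  # APPROPRIATE or OTHER_CLASS
    window: float
    looked: bool
    looked_before: bool
    looked_after: bool


def _coincidence_arrays(
    look_t: np.ndarray, onsets: np.ndarray, window: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized coincidence indicators for sorted face-looking frame times.

    looked: any looking frame with |t - onset| <= window/2;
    looked_before uses t in [onset - window/2, onset] (onset frame counts as
    'before'); looked_after uses t in (onset, onset + window/2].
    """
    half = window / 2.0
    lo = np.searchsorted(look_t, onsets - half, side="left")
    mid = np.searchsorted(look_t, onsets, side="right")
    hi = np.searchsorted(look_t, onsets + half, side="right")
    looked_before = mid > lo
    looked_after = hi > mid
    return looked_before | looked_after, looked_before, looked_after


def code_coincidence(
    session: DyadSession, window: float = 5.0
) -> list[CoincidenceRecord]:
    """Code each comment for face-looking coincidence within the window.

    Comment classes pool non-attuned mind-related with other comments:
    the contrast of interest is appropriate mind-related vs everything else.
    Windows truncated by the session boundary are used as-is.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    f = session.frames
    look_t = f.loc[f["face_looking"].astype(bool), "t"].to_numpy(dtype=float)
    onsets = session.comments["onset"].to_numpy(dtype=float)
    cats = session.comments["category"].to_numpy()
    looked, before, after = _coincidence_arrays(look_t, onsets, window)
    return [
        CoincidenceRecord(
            dyad_id=session.dyad_id,
            comment_id=i,
            comment_class=APPROPRIATE if cats[i] == APPROPRIATE_MR else OTHER_CLASS,
            window=window,
            looked=bool(looked[i]),
            looked_before=bool(before[i]),
            looked_after=bool(after[i]),
        )
        for i in range(len(onsets))
    ]


def records_table(records: Sequence[CoincidenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "dyad_id": [r.dyad_id for r in records],
            "comment_id": [r.comment_id for r in records],
            "comment_class": [r.comment_class for r in records],
            "window": [r.window for r in records],
            "looked": [int(r.looked) for r in records],
            "looked_before": [int(r.looked_before) for r in records],
            "looked_after": [int(r.looked_after) for r in records],
        }
    )


# ---------------------------------------------------------------------------
# between-dyad analysis


def between_dyad_analysis(
    summaries: Sequence[FaceLookingSummary],
    comment_summaries: Sequence[CommentSummary],
) -> tuple[GlmFit, LrtResult]:
    """Binomial GLM of face-looking counts on the verbal MM score.

    Successes are face-looking frame counts; trials are frames with the face
    present and pupils detected; the covariate is the proportion of
    appropriate mind-related comments. Dyads with no eligible frames are
    excluded. Returns the slope fit and the LRT against the intercept-only
    model.
    """
    by_id = {c.dyad_id: c for c in comment_summaries}
    succ, trials, x = [], [], []
    for s in summaries:
        if s.dyad_id not in by_id:
            raise ValueError(f"no comment summary for dyad {s.dyad_id}")
        if s.n_face_pupil < 1:
            continue
        succ.append(s.n_looking)
        trials.append(s.n_face_pupil)
        x.append(by_id[s.dyad_id].prop_appropriate)
    if len(succ) < 3:
        raise ValueError("between-dyad model needs at least 3 usable dyads")
    full = fit_binomial_glm(succ, trials, x)
    null = fit_binomial_glm(succ, trials, None)
    return full, lrt(full, null)


# ---------------------------------------------------------------------------
# within-dyad coincidence analyses


def _pooled_design(
    sessions: Sequence[DyadSession], window: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[CoincidenceRecord]]:
    records: list[CoincidenceRecord] = []
    for s in sessions:
        records.extend(code_coincidence(s, window))
    y = np.array([r.looked for r in records], dtype=float)
    group = np.array([r.dyad_id for r in records])
    x = np.array(
        [1.0 if r.comment_class == APPROPRIATE else 0.0 for r in records]
    )
    return y, group, x, records


def coordination_analysis(
    sessions: Sequence[DyadSession], window: float = 5.0
) -> tuple[GlmmFit, LrtResult, list[CoincidenceRecord]]:
    """GLMM of coincidence on comment class, with LRT against the null.

    Pools coincidence records across dyads; the full model has a fixed
    comment-class effect and a random intercept per mother, the null drops
    the class effect but keeps the random intercept. A dyad without
    appropriate comments still contributes OTHER records.
    """
    y, group, x, records = _pooled_design(sessions, window)
    if x.sum() == 0:
        raise ValueError("no appropriate mind-related comments in the study")
    if x.sum() == len(x):
        raise ValueError("all comments are appropriate: class effect inestimable")
    full = fit_binomial_glmm(y, group, x)
    null = fit_binomial_glmm(y, group, None)
    return full, lrt(full, null), records


def window_sweep(
    sessions: Sequence[DyadSession], windows: Sequence[float] = (4.0, 5.0, 6.0)
) -> dict[float, tuple[GlmmFit, LrtResult]]:
    """Re-run the coincidence analysis across window sizes (robustness)."""
    out: dict[float, tuple[GlmmFit, LrtResult]] = {}
    for w in windows:
        fit, test, _ = coordination_analysis(sessions, window=w)
        out[float(w)] = (fit, test)
    return out


def halves_analysis(
    sessions: Sequence[DyadSession], window: float = 5.0
) -> tuple[GlmmFit, LrtResult]:
    """Before/after contrast within the window, appropriate comments only.

    Each appropriate comment contributes two rows: looked in the first half
    of the window ([onset - w/2, onset]) and in the second ((onset,
    onset + w/2]). The GLMM regresses the outcome on the half indicator
    (second half = 1) with a random intercept per mother; the LRT (df=1)
    asks whether coincidence differs before vs after the comment.
    """
    y, group, half = [], [], []
    for s in sessions:
        for r in code_coincidence(s, window):
            if r.comment_class != APPROPRIATE:
                continue
            y.extend([float(r.looked_before), float(r.looked_after)])
            group.extend([r.dyad_id, r.dyad_id])
            half.extend([0.0, 1.0])
    if not y:
        raise ValueError("no appropriate mind-related comments in the study")
    y = np.asarray(y)
    group = np.asarray(group)
    half = np.asarray(half)
    full = fit_binomial_glmm(y, group, half)
    null = fit_binomial_glmm(y, group, None)
    return full, lrt(full, null)
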