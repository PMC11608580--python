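"""Comment-stream measures of verbal mind-mindedness.

The verbal mind-mindedness (MM) score of a mother is the proportion of her
comments coded *appropriate mind-related* — comments attributing an internal
state that fits the infant's current behavior. Semantic categorization is a
human coding task and enters this pipeline as data; what is implemented here
is the temporal transcript segmentation (a silence of more than 1 s starts a
new comment), the summary proportions, and the agreement/contrast statistics
used on such codes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from .streams import APPROPRIATE_MR, NONATTUNED_MR, CommentEvent


@dataclass(frozen=True)
class WordToken:
    """A transcribed word with aligned start/end times in seconds."""

    start: float
    end: float
    text: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"token {self.text!r}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class CommentSummary:
    dyad_id: str
    n_comments: int
    prop_appropriate: float
    prop_nonattuned: float


def segment_transcript(
    tokens: Sequence[WordToken],
    gap_threshold: float = 1.0,
    dyad_id: str = "",
) -> list[CommentEvent]:
    """Group word tokens into comments at temporal discontinuities.

    Consecutive tokens belong to the same comment unless the silence between
    them exceeds ``gap_threshold`` seconds (strictly more than 1 s by
    default; a gap of exactly the threshold does not split). Comment onset is
    the first token's start; categories are left as ``other`` for the coder.
    """
    if not tokens:
        return []
    starts = [t.start for t in tokens]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("tokens must be sorted by start time")
    comments: list[CommentEvent] = []
    onset = tokens[0].start
    words = [tokens[0].text]
    prev_end = tokens[0].end
    for tok in tokens[1:]:
        if tok.start - prev_end > gap_threshold:
            comments.append(
                CommentEvent(dyad_id=dyad_id, onset=onset, category="other",
                             text=" ".join(w for w in words if w))
            )
            onset = tok.start
            words = [tok.text]
        else:
            words.append(tok.text)
        prev_end = max(prev_end, tok.end)
    comments.append(
        CommentEvent(dyad_id=dyad_id, onset=onset, category="other",
                     text=" ".join(w for w in words if w))
    )
    return comments


def summarize_comments(comments, dyad_id: str | None = None) -> CommentSummary:
    """MM summary: proportions of appropriate / non-attuned comments.

    Accepts a list of :class:`CommentEvent` or a comments DataFrame. The MM
    score is undefined on an empty comment stream, which raises.
    """
    if hasattr(comments, "columns"):
        cats = list(comments["category"])
        did = dyad_id or ""
    else:
        comments = list(comments)
        cats = [c.category for c in comments]
        did = dyad_id or (comments[0].dyad_id if comments else "")
    n = len(cats)
    if n == 0:
        raise ValueError("MM score undefined for an empty comment stream")
    n_app = sum(c == APPROPRIATE_MR for c in cats)
    n_na = sum(c == NONATTUNED_MR for c in cats)
    return CommentSummary(
        dyad_id=did,
        n_comments=n,
        prop_appropriate=n_app / n,
        prop_nonattuned=n_na / n,
    )


def paired_t(x, y) -> tuple[float, int, float]:
    """Classical paired t-test on d = x - y; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t needs two equal-length 1-d vectors")
    n = len(x)
    if n < 2:
        raise ValueError("paired_t needs n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, n - 1, 1.0
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    res = stats.ttest_rel(x, y)
    return float(res.statistic), n - 1, float(res.pvalue)


def cohens_kappa(a, b) -> float:
    """Unweighted Cohen's kappa, (p_o - p_e) / (1 - p_e)."""
    a = list(a)
    b = list(b)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    if len(a) == 0:
        raise ValueError("empty label vectors")
    if len(set(a)) == 1 and set(a) == set(b):
        raise ValueError("kappa undefined: both coders constant and identical")
    return float(cohen_kappa_score(a, b))
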