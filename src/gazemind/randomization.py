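"""Shuffle-null ("randomized dataset") test for the coincidence effect.

Each randomized dataset keeps every dyad's comment stream and its total
face-looking count but permutes the face-looking labels uniformly over the
shuffle domain, destroying the fine time structure between gaze and
comments while preserving both occurrence rates. Refitting the coincidence
GLMM on each randomized dataset yields a null distribution for the
comment-class effect; the observed effect is compared with its percentile
interval and an empirical p-value.

The default shuffle domain is the *eligible* frames (face present and
pupils detected), which preserves the structural impossibility of
face-looking without a visible face; ``domain='all'`` permutes over every
frame for the stricter reading of "shuffling the stream".
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coordination import coordination_analysis
from .models import fit_glmm_cells
from .streams import APPROPRIATE_MR, DyadSession

ELIGIBLE = "eligible"
ALL = "all"


@dataclass(frozen=True)
class RandomizationResult:
    observed_effect: float  # GLMM comment-class coefficient, log-odds
    observed_chi2: float  # LRT statistic of the observed fit (diagnostic)
    null_effects: np.ndarray  # converged null refits only
    ci_low: float  # 2.5th percentile of the null effects
    ci_high: float  # 97.5th percentile
    empirical_p: float
    n_failed: int
    B: int
    seed: int
    window: float
    domain: str

    @property
    def outside_ci(self) -> bool:
        return bool(
            not (self.ci_low <= self.observed_effect <= self.ci_high)
        )

    @property
    def reliable(self) -> bool:
        return self.n_failed <= 0.1 * self.B


def _dyad_stream_key(dyad_id: str) -> int:
    # stable across runs and session ordering
    return zlib.crc32(str(dyad_id).encode())


def dyad_rng(seed: int, dyad_id: str, replicate: int) -> np.random.Generator:
    """The RNG stream for one dyad in one replicate (order-invariant)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _dyad_stream_key(dyad_id), int(replicate)])
    )


def shuffle_face_looking(
    session: DyadSession, rng: np.random.Generator, domain: str = ELIGIBLE
) -> DyadSession:
    """Copy of the session with face-looking labels permuted over the domain.

    The permutation is uniform over domain frames; the multiset of labels
    (hence the per-dyad face-looking count) is preserved exactly. Comments
    and the face/pupil streams are untouched. An empty domain returns an
    unchanged copy.
    """
    if domain not in (ELIGIBLE, ALL):
        raise ValueError("domain must be 'eligible' or 'all'")
    out = session.copy()
    f = out.frames
    flags = f["face_looking"].to_numpy(bool).copy()
    if domain == ELIGIBLE:
        mask = f["face_present"].to_numpy(bool) & f["pupil_detected"].to_numpy(bool)
    else:
        mask = np.ones(len(f), dtype=bool)
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return out
    flags[idx] = flags[idx][rng.permutation(len(idx))]
    f["face_looking"] = flags
    return out


# ---------------------------------------------------------------------------
# the randomization test


class _DyadPlan:
    """Precomputed per-dyad structures for fast shuffle refits.

    Domain frame times are sorted, so the looking frames inside a comment
    window form a contiguous slice of the domain; coincidence under any
    permutation reduces to slice sums of the permuted label vector.
    """

    __slots__ = ("dyad_id", "flags", "lo", "hi", "is_app", "n_app", "n_other")

    def __init__(self, session: DyadSession, window: float, domain: str):
        f = session.frames
        if domain == ELIGIBLE:
            mask = f["face_present"].to_numpy(bool) & f["pupil_detected"].to_numpy(bool)
        else:
            mask = np.ones(len(f), dtype=bool)
        times = f.loc[mask, "t"].to_numpy(float)
        self.dyad_id = session.dyad_id
        self.flags = f.loc[mask, "face_looking"].to_numpy(bool)
        onsets = session.comments["onset"].to_numpy(float)
        half = window / 2.0
        self.lo = np.searchsorted(times, onsets - half, side="left")
        self.hi = np.searchsorted(times, onsets + half, side="right")
        self.is_app = (
            session.comments["category"].to_numpy() == APPROPRIATE_MR
        )
        self.n_app = int(self.is_app.sum())
        self.n_other = len(onsets) - self.n_app

    def coincidence_counts(self, flags: np.ndarray) -> tuple[int, int]:
        """(# appropriate comments looked, # other comments looked)."""
        cs = np.concatenate([[0], np.cumsum(flags)])
        looked = (cs[self.hi] - cs[self.lo]) > 0
        k_app = int(np.sum(looked & self.is_app))
        k_other = int(np.sum(looked) - k_app)
        return k_app, k_other


def randomization_test(
    sessions: Sequence[DyadSession],
    B: int = 1000,
    window: float = 5.0,
    seed: int = 0,
    domain: str = ELIGIBLE,
) -> RandomizationResult:
    """Compare the observed coincidence effect with the shuffle null.

    Fits the coincidence GLMM on the observed data, then on ``B``
    randomized datasets (every session shuffled independently per
    replicate), collecting the comment-class coefficient of each converged
    refit. The empirical p-value is (1 + #{|null| >= |observed|}) /
    (B_converged + 1); the null CI is the 2.5-97.5 percentile range.
    Fully reproducible given ``seed``; per-dyad streams are keyed by
    dyad_id, so the result is invariant to session ordering.
    """
    if domain not in (ELIGIBLE, ALL):
        raise ValueError("domain must be 'eligible' or 'all'")
    full, test, _ = coordination_analysis(sessions, window=window)
    observed = float(full.fixed_effects[1])

    plans = [_DyadPlan(s, window, domain) for s in sessions]
    G = len(plans)
    cell_group = np.repeat(np.arange(G), 2)
    cell_X = np.column_stack([np.ones(2 * G), np.tile([0.0, 1.0], G)])
    cell_n = np.empty(2 * G)
    for g, pl in enumerate(plans):
        cell_n[2 * g] = pl.n_other
        cell_n[2 * g + 1] = pl.n_app
    warm = np.concatenate([full.fixed_effects, [max(full.random_intercept_sd, 0.05)]])

    null_effects: list[float] = []
    n_failed = 0
    cell_k = np.empty(2 * G)
    for b in range(B):
        for g, pl in enumerate(plans):
            rng = dyad_rng(seed, pl.dyad_id, b)
            flags = pl.flags[rng.permutation(len(pl.flags))] if len(pl.flags) else pl.flags
            k_app, k_other = pl.coincidence_counts(flags)
            cell_k[2 * g] = k_other
            cell_k[2 * g + 1] = k_app
        fit = fit_glmm_cells(
            cell_group, cell_X, cell_n, cell_k, G, start=warm.copy()
        )
        if fit.converged:
            null_effects.append(float(fit.fixed_effects[1]))
        else:
            n_failed += 1

    null_arr = np.asarray(null_effects)
    b_eff = len(null_arr)
    if b_eff == 0:
        raise RuntimeError("all randomization refits failed")
    ci_low, ci_high = np.percentile(null_arr, [2.5, 97.5])
    emp_p = (1 + int(np.sum(np.abs(null_arr) >= abs(observed)))) / (b_eff + 1)
    return RandomizationResult(
        observed_effect=observed,
        observed_chi2=test.chi2,
        null_effects=null_arr,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        empirical_p=float(emp_p),
        n_failed=n_failed,
        B=B,
        seed=seed,
        window=window,
        domain=domain,
    )
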