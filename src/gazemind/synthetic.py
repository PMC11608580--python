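"""Synthetic dyad-study generator with the structure the analyses assume.

Each simulated dyad is a 20-min session at 1 Hz. Face presence in the
mother's view follows a two-state Markov chain (stationary probability
~0.294, mean in-view dwell 10 s); pupil detection is i.i.d. Bernoulli
(~0.92); comments arrive as a Poisson process whose per-dyad rate is
gamma-mixed so the count distribution matches the observed mean 343.3 and
SD 102.7; comment categories are i.i.d. given a per-dyad appropriateness
propensity. Face-looking is Bernoulli per eligible frame (face present and
pupils detected) with a per-dyad logit intercept drawn from a normal
calibrated so the face-looking proportion has mean ~0.445 and SD ~0.125 on
the proportion scale, plus an optional log-odds bump ``beta_couple`` on
frames within half a coupling window of an appropriate-comment onset — the
minimal generative mechanism for a timed gaze-comment coordination effect.

Between-dyad coupling of the two propensities (verbal mind-mindedness and
face-looking) is controlled by ``rho_link``, the correlation of their
latent normal scores. All defaults make the generator *null* with respect
to both analyses (``beta_couple=0``, ``rho_link=0``) while reproducing the
marginal descriptives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit, roots_hermite

from .streams import (
    APPROPRIATE_MR,
    NONATTUNED_MR,
    OTHER,
    CameraModel,
    DyadSession,
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-generator parameters; defaults reproduce the observed marginals."""

    n_dyads: int = 40
    duration: float = 1200.0
    face_present_stationary: float = 0.2941
    face_dwell_mean: float = 10.0
    pupil_rate: float = 0.9215
    looking_mean: float = 0.4453  # mean face-looking | face & pupil, proportion scale
    looking_sd: float = 0.1250  # between-dyad SD on the proportion scale
    comment_rate: float = 343.3 / 1200.0  # per second
    comment_count_sd: float = 102.68  # between-dyad SD of session comment counts
    p_appropriate: float = 0.0577
    appropriate_sd: float = 0.0307  # between-dyad SD of the MM score
    p_nonattuned: float = 0.0041
    beta_couple: float = 0.0  # log-odds bump near appropriate-comment onsets
    couple_window: float = 5.0
    couple_side: str = "both"  # 'both' | 'before' | 'after'
    rho_link: float = 0.0  # corr(latent MM propensity, latent looking propensity)
    seed: int = 0
    with_geometry: bool = False

    def __post_init__(self) -> None:
        for name in (
            "face_present_stationary",
            "pupil_rate",
            "looking_mean",
            "p_appropriate",
            "p_nonattuned",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_appropriate + self.p_nonattuned > 1.0:
            raise ValueError("p_appropriate + p_nonattuned > 1")
        if not -1.0 <= self.rho_link <= 1.0:
            raise ValueError("rho_link outside [-1, 1]")
        if self.couple_side not in ("both", "before", "after"):
            raise ValueError("couple_side must be 'both', 'before' or 'after'")
        if min(self.n_dyads, self.duration, self.face_dwell_mean,
               self.comment_rate, self.couple_window) <= 0:
            raise ValueError("counts, durations and rates must be positive")

    @property
    def looking_logit_params(self) -> tuple[float, float]:
        """Calibrated (mean, sd) of the per-dyad looking logit intercept."""
        return fit_logit_normal(self.looking_mean, self.looking_sd)

    @property
    def appropriate_logit_params(self) -> tuple[float, float]:
        return fit_logit_normal(self.p_appropriate, self.appropriate_sd)


# ---------------------------------------------------------------------------
# logit-normal moment calibration

_GH_NODES = roots_hermite(80)
_CAL_CACHE: dict[tuple[float, float], tuple[float, float]] = {}


def logit_normal_moments(mu: float, sd: float) -> tuple[float, float]:
    """Mean and SD of expit(Z), Z ~ N(mu, sd^2), by Gauss-Hermite quadrature."""
    z, w = _GH_NODES
    vals = expit(mu + math.sqrt(2.0) * sd * z)
    m = float(np.sum(w * vals) / math.sqrt(math.pi))
    m2 = float(np.sum(w * vals * vals) / math.sqrt(math.pi))
    return m, math.sqrt(max(m2 - m * m, 0.0))


def fit_logit_normal(mean: float, sd: float) -> tuple[float, float]:
    """Find (mu, sigma) of a logit-normal with given proportion-scale moments.

    Degenerate request sd=0 returns (logit(mean), 0). Raises if the target
    SD is unattainable for the given mean.
    """
    key = (round(mean, 12), round(sd, 12))
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must be strictly inside (0, 1)")
    if sd == 0.0:
        out = (float(logit(mean)), 0.0)
        _CAL_CACHE[key] = out
        return out

    def resid(params):
        mu, log_s = params
        m, s = logit_normal_moments(mu, math.exp(log_s))
        return [m - mean, s - sd]

    s0 = sd / max(mean * (1.0 - mean), 1e-6)
    sol = optimize.root(resid, [float(logit(mean)), math.log(s0)], tol=1e-12)
    mu, sigma = float(sol.x[0]), float(math.exp(sol.x[1]))
    m, s = logit_normal_moments(mu, sigma)
    if not sol.success or abs(m - mean) > 1e-8 or abs(s - sd) > 1e-8:
        raise ValueError(
            f"cannot calibrate logit-normal to mean={mean}, sd={sd} "
            f"(achieved {m:.6g}, {s:.6g})"
        )
    _CAL_CACHE[key] = (mu, sigma)
    return mu, sigma


# ---------------------------------------------------------------------------
# generation


def _markov_chain(rng, T: int, stationary: float, dwell_mean: float) -> np.ndarray:
    """Two-state chain on {0,1}: stationary P(1), mean dwell in state 1."""
    p10 = min(1.0 / dwell_mean, 1.0)
    p01 = stationary * p10 / (1.0 - stationary)
    if p01 > 1.0:
        raise ValueError("incompatible stationary probability and dwell mean")
    u = rng.random(T)
    state = np.empty(T, dtype=bool)
    s = u[0] < stationary
    state[0] = s
    for t in range(1, T):
        s = (u[t] >= p10) if s else (u[t] < p01)
        state[t] = s
    return state


def _coupled_frames(
    t: np.ndarray, app_onsets: np.ndarray, half: float, side: str
) -> np.ndarray:
    """Frames within the coupling half-window of any appropriate onset."""
    if len(app_onsets) == 0:
        return np.zeros(len(t), dtype=bool)
    o = np.sort(app_onsets)
    if side == "both":
        lo, hi = t - half, t + half
        # onset in [t-half, t+half]
        return np.searchsorted(o, hi, "right") > np.searchsorted(o, lo, "left")
    if side == "before":
        # frame precedes the onset: onset in [t, t+half]
        return np.searchsorted(o, t + half, "right") > np.searchsorted(o, t, "left")
    # 'after': frame follows the onset: onset in [t-half, t)
    return np.searchsorted(o, t, "left") > np.searchsorted(o, t - half, "left")


def generate_dyad(
    config: GeneratorConfig, dyad_index: int, rng: np.random.Generator
) -> DyadSession:
    """Simulate one dyad session; see the module docstring for the model."""
    T = int(config.duration)
    dyad_id = f"d{dyad_index:03d}"

    # latent bivariate-normal propensities: z_mm -> comment appropriateness,
    # z_look -> looking intercept, correlated rho_link
    z_mm = rng.standard_normal()
    z_look = config.rho_link * z_mm + math.sqrt(
        1.0 - config.rho_link**2
    ) * rng.standard_normal()
    mu_app, sd_app = config.appropriate_logit_params
    mu_look, sd_look = config.looking_logit_params
    p_app_m = float(expit(mu_app + sd_app * z_mm))
    alpha_m = mu_look + sd_look * z_look

    # comments: gamma-mixed Poisson count, uniform onsets, i.i.d. categories
    mean_count = config.comment_rate * config.duration
    var_count = config.comment_count_sd**2
    if var_count > mean_count:
        shape = mean_count**2 / (var_count - mean_count)
        lam = rng.gamma(shape, mean_count / shape)
    else:
        lam = mean_count
    n_comments = rng.poisson(lam)
    onsets = np.sort(rng.random(n_comments)) * config.duration
    u = rng.random(n_comments)
    categories = np.where(
        u < p_app_m,
        APPROPRIATE_MR,
        np.where(u < p_app_m + config.p_nonattuned, NONATTUNED_MR, OTHER),
    )

    # frame streams
    t = np.arange(T)
    face = _markov_chain(rng, T, config.face_present_stationary, config.face_dwell_mean)
    pupil = rng.random(T) < config.pupil_rate
    eligible = face & pupil
    app_onsets = onsets[categories == APPROPRIATE_MR]
    bump = _coupled_frames(
        t.astype(float), app_onsets, config.couple_window / 2.0, config.couple_side
    )
    p_look = expit(alpha_m + config.beta_couple * bump)
    looking = eligible & (rng.random(T) < p_look)

    frames = pd.DataFrame(
        {
            "t": t,
            "face_present": face,
            "pupil_detected": pupil,
            "gaze_x": np.full(T, np.nan),
            "gaze_y": np.full(T, np.nan),
            "face_poly": [None] * T,
            "face_looking": looking,
        }
    )
    comments = pd.DataFrame(
        {
            "onset": onsets,
            "category": categories,
            "text": [None] * n_comments,
        }
    )
    session = DyadSession(
        dyad_id=dyad_id, duration=config.duration, frames=frames, comments=comments
    )
    if config.with_geometry:
        _attach_geometry(session, rng)
    return session


def _attach_geometry(
    session: DyadSession, rng: np.random.Generator, camera: CameraModel | None = None
) -> None:
    """Synthesize gaze points and face boxes consistent with the flags.

    Purely illustrative geometry (a 300x240 px face box; gaze inside the box
    when looking, far outside the 4-degree AOI reach when not), so the
    geometric classifier reproduces the simulated flags exactly.
    """
    camera = camera or CameraModel()
    f = session.frames
    T = len(f)
    px_per_deg_x = camera.width / camera.h_fov
    clearance = 6.0 * px_per_deg_x  # > 4 deg AOI radius with margin, both axes
    w, h = 300.0, 240.0
    gx = np.full(T, np.nan)
    gy = np.full(T, np.nan)
    polys: list[str | None] = [None] * T
    face = f["face_present"].to_numpy(bool)
    pupil = f["pupil_detected"].to_numpy(bool)
    looking = f["face_looking"].to_numpy(bool)
    for i in range(T):
        if face[i]:
            cx = rng.uniform(w / 2 + clearance + 10, camera.width - w / 2 - 10)
            cy = rng.uniform(h / 2 + 10, camera.height - h / 2 - 10)
            polys[i] = (
                f"{cx - w / 2:.1f},{cy - h / 2:.1f};{cx + w / 2:.1f},{cy - h / 2:.1f};"
                f"{cx + w / 2:.1f},{cy + h / 2:.1f};{cx - w / 2:.1f},{cy + h / 2:.1f}"
            )
            if pupil[i]:
                if looking[i]:
                    gx[i] = rng.uniform(cx - w / 2, cx + w / 2)
                    gy[i] = rng.uniform(cy - h / 2, cy + h / 2)
                else:
                    gx[i] = rng.uniform(5.0, cx - w / 2 - clearance)
                    gy[i] = rng.uniform(5.0, camera.height - 5.0)
        elif pupil[i]:
            gx[i] = rng.uniform(0, camera.width)
            gy[i] = rng.uniform(0, camera.height)
    f["gaze_x"] = gx
    f["gaze_y"] = gy
    f["face_poly"] = polys


def generate_study(config: GeneratorConfig) -> list[DyadSession]:
    """Simulate ``config.n_dyads`` independent sessions, reproducibly.

    Each dyad gets an independent RNG stream spawned from the master seed,
    so per-dyad output is invariant to generation order.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_dyads)
    return [
        generate_dyad(config, i, np.random.default_rng(children[i]))
        for i in range(config.n_dyads)
    ]
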