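import numpy as np
import pandas as pd
import pytest

from gazemind import DyadSession, GeneratorConfig, generate_study


def make_session(
    dyad_id="d0",
    duration=60.0,
    looking_t=(),
    eligible_t=None,
    comments=(),
):
    """Hand-built session: eligible frames everywhere unless specified.

    ``comments`` is a sequence of (onset, category) pairs; ``looking_t``
    the frame times flagged face-looking (must be eligible).
    """
    T = int(duration)
    t = np.arange(T)
    eligible = (
        np.isin(t, list(eligible_t)) if eligible_t is not None else np.ones(T, bool)
    )
    looking = np.isin(t, list(looking_t))
    frames = pd.DataFrame(
        {
            "t": t,
            "face_present": eligible,
            "pupil_detected": eligible,
            "gaze_x": np.full(T, np.nan),
            "gaze_y": np.full(T, np.nan),
            "face_poly": [None] * T,
            "face_looking": looking & eligible,
        }
    )
    cdf = pd.DataFrame(
        {
            "onset": [o for o, _ in comments],
            "category": [c for _, c in comments],
            "text": [None] * len(comments),
        }
    )
    return DyadSession(dyad_id=dyad_id, duration=duration, frames=frames, comments=cdf)


@pytest.fixture(scope="session")
def small_study():
    """Ten short dyads with strong, clearly detectable real-time coupling.

    High face availability and a low looking baseline keep the window-level
    coincidence contrast far from its saturation ceiling, so sign and
    significance checks are stable at this small scale.
    """
    cfg = GeneratorConfig(
        n_dyads=10,
        duration=600,
        face_present_stationary=0.9,
        looking_mean=0.15,
        looking_sd=0.05,
        beta_couple=1.5,
        seed=424,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """One default-scale 40-dyad null study."""
    return generate_study(GeneratorConfig(seed=7))
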