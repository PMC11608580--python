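"""Face-looking classification by gaze-AOI / face-region overlap.

The point of gaze is surrounded by a circular area of interest (AOI) of
fixed radius in degrees of visual angle (default 4°). A frame counts as
*face-looking* when the AOI overlaps the infant's face region at all, i.e.
when the gaze point lies within the AOI radius of the region (distance zero
inside it). Distances are measured in degree space after a per-axis linear
pixel-to-angle mapping, so the 4° circle corresponds to an ellipse in pixel
space (about 80.8 px by 68.6 px semi-axes at the default camera).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .streams import CameraModel, DyadSession, ValidationError, parse_polygon


@dataclass(frozen=True)
class AOISpec:
    """Gaze area of interest: a disc of ``radius`` degrees of visual angle."""

    radius: float = 4.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("AOI radius must be positive")


@dataclass(frozen=True)
class FaceLookingSummary:
    """Per-dyad face-looking descriptives (one row of the study summary table)."""

    dyad_id: str
    n_frames: int
    p_face_present: float
    p_pupil: float
    p_looking_total: float
    p_looking_given_face_pupil: float | None
    n_face_pupil: int
    n_looking: int


def px_to_deg(point, camera: CameraModel) -> tuple[float, float]:
    """Map a pixel coordinate to degrees of visual angle, image-center origin.

    Linear small-angle mapping: x_deg = (x - width/2) * h_fov / width, and
    likewise vertically. Off-frame points map linearly beyond ±fov/2.
    """
    x, y = float(point[0]), float(point[1])
    return (
        (x - camera.width / 2.0) * camera.h_fov / camera.width,
        (y - camera.height / 2.0) * camera.v_fov / camera.height,
    )


def _poly_to_deg(poly: np.ndarray, camera: CameraModel) -> np.ndarray:
    pts = np.asarray(poly, dtype=float)
    out = np.empty_like(pts)
    out[:, 0] = (pts[:, 0] - camera.width / 2.0) * camera.h_fov / camera.width
    out[:, 1] = (pts[:, 1] - camera.height / 2.0) * camera.v_fov / camera.height
    return out


def aoi_overlap(
    gaze,
    face_region: np.ndarray | None,
    camera: CameraModel | None = None,
    aoi: AOISpec | None = None,
) -> bool:
    """True iff the gaze AOI disc overlaps the face region.

    Equivalent to: the Euclidean distance in degree space from the gaze
    point to the face polygon (zero inside it) is at most the AOI radius.
    An absent face region can never overlap.
    """
    if face_region is None:
        return False
    camera = camera or CameraModel()
    aoi = aoi or AOISpec()
    region = np.asarray(face_region, dtype=float)
    if region.ndim != 2 or region.shape[0] < 3:
        raise ValidationError("face region must have at least 3 vertices")
    poly = Polygon(_poly_to_deg(region, camera))
    gaze_deg = Point(px_to_deg(gaze, camera))
    return poly.distance(gaze_deg) <= aoi.radius


def classify_frames(
    session: DyadSession,
    camera: CameraModel | None = None,
    aoi: AOISpec | None = None,
    passthrough: bool = False,
) -> DyadSession:
    """Return a copy of the session with ``face_looking`` set per frame.

    A frame is never face-looking unless the face is present and the pupils
    were detected; among those frames, face-looking is decided by
    :func:`aoi_overlap` of the gaze point with the face region. With
    ``passthrough=True`` the coder-supplied flags are kept as-is (after the
    structural gate), for inputs whose looking state was coded manually.
    """
    out = session.copy()
    f = out.frames
    eligible = f["face_present"].to_numpy(bool) & f["pupil_detected"].to_numpy(bool)
    if passthrough:
        f["face_looking"] = f["face_looking"].to_numpy(bool) & eligible
        return out

    camera = camera or CameraModel()
    aoi = aoi or AOISpec()
    looking = np.zeros(len(f), dtype=bool)
    missing: list[int] = []
    rows = zip(
        f["t"].to_numpy(),
        eligible,
        f["gaze_x"].to_numpy(float),
        f["gaze_y"].to_numpy(float),
        f["face_poly"].tolist(),
    )
    for i, (t, ok, gx, gy, poly_spec) in enumerate(rows):
        if not ok:
            continue
        poly = poly_spec if isinstance(poly_spec, np.ndarray) else parse_polygon(poly_spec)
        if poly is None:
            missing.append(int(t))
            continue
        if not (np.isfinite(gx) and np.isfinite(gy)):
            missing.append(int(t))
            continue
        looking[i] = aoi_overlap((gx, gy), poly, camera, aoi)
    if missing:
        raise ValidationError(
            f"frames with face+pupil but no gaze/face_region at t={missing}"
        )
    f["face_looking"] = looking
    return out


def summarize_looking(session: DyadSession) -> FaceLookingSummary:
    """Per-dyad face-looking proportions with the study's denominators.

    ``p_looking_given_face_pupil`` divides by frames with the face present
    *and* pupils detected (the denominator later reused as binomial trials in
    the between-dyad model); ``p_looking_total`` divides by all frames. With
    no eligible frames the conditional proportion is None and the dyad is
    excluded from the between-dyad model by the caller.
    """
    f = session.frames
    n = len(f)
    if n == 0:
        raise ValidationError(f"session {session.dyad_id} has no frames")
    face = f["face_present"].to_numpy(bool)
    pupil = f["pupil_detected"].to_numpy(bool)
    looking = f["face_looking"].to_numpy(bool)
    eligible = face & pupil
    n_fp = int(eligible.sum())
    n_look = int(looking.sum())
    return FaceLookingSummary(
        dyad_id=session.dyad_id,
        n_frames=n,
        p_face_present=float(face.mean()),
        p_pupil=float(pupil.mean()),
        p_looking_total=n_look / n,
        p_looking_given_face_pupil=(n_look / n_fp) if n_fp else None,
        n_face_pupil=n_fp,
        n_looking=n_look,
    )


def summaries_table(summaries) -> pd.DataFrame:
    """Stack per-dyad summaries into one DataFrame (one row per dyad)."""
    return pd.DataFrame(
        {
            "dyad_id": [s.dyad_id for s in summaries],
            "n_frames": [s.n_frames for s in summaries],
            "p_face_present": [s.p_face_present for s in summaries],
            "p_pupil": [s.p_pupil for s in summaries],
            "p_looking_total": [s.p_looking_total for s in summaries],
            "p_looking_given_face_pupil": [
                s.p_looking_given_face_pupil for s in summaries
            ],
            "n_face_pupil": [s.n_face_pupil for s in summaries],
            "n_looking": [s.n_looking for s in summaries],
        }
    )
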