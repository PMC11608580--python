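"""Core data model for dyadic behavioral streams.

A *dyad session* is one mother-infant free-play session recorded through a
head-mounted eye tracker worn by the mother: a 1 Hz stream of frame-level
annotations (is the infant's face in view, were the mother's pupils detected,
where was she looking) plus a stream of timestamped maternal comments, each
categorized as appropriate mind-related, non-attuned mind-related, or other.

Frames live on an integer-second grid anchored at session start; comment
onsets are real-valued seconds. Face regions are stored as pixel polygons
serialized as ``"x1,y1;x2,y2;..."`` in the CSV dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

APPROPRIATE_MR = "appropriate_mr"
NONATTUNED_MR = "nonattuned_mr"
OTHER = "other"
CATEGORIES = (APPROPRIATE_MR, NONATTUNED_MR, OTHER)

FRAME_COLUMNS = [
    "t",
    "face_present",
    "pupil_detected",
    "gaze_x",
    "gaze_y",
    "face_poly",
    "face_looking",
]
COMMENT_COLUMNS = ["onset", "category", "text"]


class SchemaError(ValueError):
    """A delimited input file does not carry the documented columns."""


class ValidationError(ValueError):
    """Stream content violates a session invariant; message names the rows."""


@dataclass(frozen=True)
class CameraModel:
    """Scene-camera geometry of the head-mounted eye tracker.

    Defaults describe a 95° x 63° field of view recorded at 1920 x 1080
    pixels (25 fps scene video, 50 Hz eye tracking).
    """

    h_fov: float = 95.0
    v_fov: float = 63.0
    width: int = 1920
    height: int = 1080
    scene_fps: float = 25.0
    eye_hz: float = 50.0

    def __post_init__(self) -> None:
        for name in ("h_fov", "v_fov", "width", "height", "scene_fps", "eye_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CameraModel.{name} must be strictly positive")
        if self.h_fov >= 180 or self.v_fov >= 180:
            raise ValueError("field of view must be < 180 degrees per axis")


@dataclass(frozen=True)
class FrameRecord:
    """One 1 Hz frame of the mother's first-person view."""

    dyad_id: str
    t: int
    face_present: bool
    pupil_detected: bool
    gaze: tuple[float, float] | None = None
    face_region: np.ndarray | None = None
    face_looking: bool = False


@dataclass(frozen=True)
class CommentEvent:
    """A maternal comment with onset time and coder-assigned category."""

    dyad_id: str
    onset: float
    category: str
    text: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"comment at onset {self.onset}: category {self.category!r} "
                f"not in {CATEGORIES}"
            )


@dataclass(frozen=True)
class GazeSample:
    """A raw eye-tracker gaze sample (nominally 50 Hz)."""

    t: float
    x: float
    y: float
    pupil_valid: bool = True


@dataclass
class DyadSession:
    """One dyad's session: frame stream + comment stream.

    ``frames`` and ``comments`` are pandas DataFrames with the column layout
    of :data:`FRAME_COLUMNS` / :data:`COMMENT_COLUMNS`; the tabular layout
    keeps whole-study simulation and coincidence coding vectorizable.
    """

    dyad_id: str
    duration: float = 1200.0
    frames: pd.DataFrame = field(default_factory=lambda: _empty_frames())
    comments: pd.DataFrame = field(default_factory=lambda: _empty_comments())

    def copy(self) -> "DyadSession":
        return DyadSession(
            dyad_id=self.dyad_id,
            duration=self.duration,
            frames=self.frames.copy(),
            comments=self.comments.copy(),
        )

    # -- record-level views ------------------------------------------------
    def frame_records(self) -> Iterable[FrameRecord]:
        for row in self.frames.itertuples(index=False):
            gaze = None
            if np.isfinite(row.gaze_x) and np.isfinite(row.gaze_y):
                gaze = (float(row.gaze_x), float(row.gaze_y))
            yield FrameRecord(
                dyad_id=self.dyad_id,
                t=int(row.t),
                face_present=bool(row.face_present),
                pupil_detected=bool(row.pupil_detected),
                gaze=gaze,
                face_region=parse_polygon(row.face_poly),
                face_looking=bool(row.face_looking),
            )

    def comment_events(self) -> Iterable[CommentEvent]:
        for row in self.comments.itertuples(index=False):
            yield CommentEvent(
                dyad_id=self.dyad_id,
                onset=float(row.onset),
                category=str(row.category),
                text=None if row.text is None or row.text != row.text else str(row.text),
            )


def _empty_frames() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t": pd.Series(dtype=int),
            "face_present": pd.Series(dtype=bool),
            "pupil_detected": pd.Series(dtype=bool),
            "gaze_x": pd.Series(dtype=float),
            "gaze_y": pd.Series(dtype=float),
            "face_poly": pd.Series(dtype=object),
            "face_looking": pd.Series(dtype=bool),
        }
    )


def _empty_comments() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "onset": pd.Series(dtype=float),
            "category": pd.Series(dtype=object),
            "text": pd.Series(dtype=object),
        }
    )


# ---------------------------------------------------------------------------
# polygon (de)serialization


def parse_polygon(spec: object) -> np.ndarray | None:
    """Parse ``"x1,y1;x2,y2;..."`` into an (n, 2) float array, or None."""
    if spec is None or (isinstance(spec, float) and np.isnan(spec)):
        return None
    text = str(spec).strip()
    if not text:
        return None
    try:
        pts = np.array(
            [[float(v) for v in vertex.split(",")] for vertex in text.split(";")],
            dtype=float,
        )
    except ValueError as exc:
        raise ValidationError(f"malformed face polygon {text!r}") from exc
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"malformed face polygon {text!r}")
    return pts


def format_polygon(poly: np.ndarray | None) -> str:
    if poly is None:
        return ""
    return ";".join(f"{x:g},{y:g}" for x, y in np.asarray(poly, dtype=float))


# ---------------------------------------------------------------------------
# validation


def validate_session(session: DyadSession) -> None:
    """Raise :class:`ValidationError` naming the offending rows.

    Enforced invariants: unique sorted integer frame times; face_looking only
    where face_present and pupil_detected; gaze present iff pupil_detected
    (when gaze columns are used); comment categories in the enum; onsets in
    [0, duration]; sorted comments.
    """
    f = session.frames
    c = session.comments
    missing = [col for col in FRAME_COLUMNS if col not in f.columns]
    if missing:
        raise SchemaError(f"frames table missing columns {missing}")
    missing = [col for col in COMMENT_COLUMNS if col not in c.columns]
    if missing:
        raise SchemaError(f"comments table missing columns {missing}")

    t = f["t"].to_numpy()
    if len(t):
        if np.any(t != np.round(t)) or np.any(t < 0):
            bad = f.loc[(t != np.round(t)) | (t < 0), "t"].tolist()
            raise ValidationError(f"frame times must be non-negative integers: {bad}")
        dup = f.loc[f["t"].duplicated(), "t"].tolist()
        if dup:
            raise ValidationError(f"duplicate frame times: {dup}")
        if np.any(np.diff(t) < 0):
            raise ValidationError("frames not sorted by t")
        if len(f) > int(session.duration) + 1:
            raise ValidationError(
                f"{len(f)} frames exceeds duration {session.duration}+1"
            )

    looking = f["face_looking"].to_numpy(dtype=bool)
    eligible = f["face_present"].to_numpy(dtype=bool) & f["pupil_detected"].to_numpy(
        dtype=bool
    )
    bad_rows = f.loc[looking & ~eligible, "t"].tolist()
    if bad_rows:
        raise ValidationError(
            "face_looking without face_present and pupil_detected at t=" f"{bad_rows}"
        )

    if len(c):
        onsets = c["onset"].to_numpy(dtype=float)
        bad = c.loc[(onsets < 0) | (onsets > session.duration), "onset"].tolist()
        if bad:
            raise ValidationError(f"comment onsets outside [0, duration]: {bad}")
        if np.any(np.diff(onsets) < 0):
            raise ValidationError("comments not sorted by onset")
        bad_cat = sorted(set(c["category"]) - set(CATEGORIES))
        if bad_cat:
            rows = c.loc[c["category"].isin(bad_cat)].index.tolist()
            raise ValidationError(
                f"unknown comment categories {bad_cat} at rows {rows}"
            )


# ---------------------------------------------------------------------------
# file I/O


def read_session(
    frames_path,
    comments_path,
    camera: CameraModel | None = None,
    dyad_id: str | None = None,
    duration: float = 1200.0,
) -> DyadSession:
    """Read one session from the frames/comments CSV dialect and validate it.

    ``frames.csv`` columns: dyad_id, t, face_present, pupil_detected, gaze_x,
    gaze_y, face_poly, face_looking (face_looking optional, default 0).
    ``comments.csv`` columns: dyad_id, onset, category, text (text optional).
    """
    camera = camera or CameraModel()
    raw_f = pd.read_csv(frames_path, dtype={"face_poly": str})
    raw_c = pd.read_csv(comments_path)

    required_f = {"dyad_id", "t", "face_present", "pupil_detected"}
    if not required_f.issubset(raw_f.columns):
        raise SchemaError(
            f"frames file missing columns {sorted(required_f - set(raw_f.columns))}"
        )
    required_c = {"dyad_id", "onset", "category"}
    if not required_c.issubset(raw_c.columns):
        raise SchemaError(
            f"comments file missing columns {sorted(required_c - set(raw_c.columns))}"
        )

    if dyad_id is None:
        ids = set(raw_f["dyad_id"].astype(str)) | set(raw_c["dyad_id"].astype(str))
        if len(ids) != 1:
            raise ValidationError(f"expected a single dyad_id, found {sorted(ids)}")
        dyad_id = ids.pop()
    else:
        raw_f = raw_f[raw_f["dyad_id"].astype(str) == dyad_id]
        raw_c = raw_c[raw_c["dyad_id"].astype(str) == dyad_id]

    frames = pd.DataFrame(
        {
            "t": raw_f["t"].astype(int).to_numpy(),
            "face_present": raw_f["face_present"].astype(bool).to_numpy(),
            "pupil_detected": raw_f["pupil_detected"].astype(bool).to_numpy(),
            "gaze_x": pd.to_numeric(raw_f.get("gaze_x", np.nan), errors="coerce"),
            "gaze_y": pd.to_numeric(raw_f.get("gaze_y", np.nan), errors="coerce"),
            "face_poly": raw_f.get("face_poly", pd.Series(dtype=str)).where(
                raw_f.get("face_poly", pd.Series(dtype=str)).notna(), None
            )
            if "face_poly" in raw_f.columns
            else None,
            "face_looking": raw_f.get("face_looking", 0),
        }
    )
    frames["face_looking"] = (
        pd.to_numeric(frames["face_looking"], errors="coerce").fillna(0).astype(bool)
    )
    if "face_poly" not in raw_f.columns:
        frames["face_poly"] = None

    comments = pd.DataFrame(
        {
            "onset": raw_c["onset"].astype(float).to_numpy(),
            "category": raw_c["category"].astype(str).to_numpy(),
            "text": raw_c["text"] if "text" in raw_c.columns else None,
        }
    )

    # off-frame gaze points are legal but flagged by zeroing nothing: keep as-is
    session = DyadSession(
        dyad_id=str(dyad_id), duration=duration, frames=frames, comments=comments
    )
    validate_session(session)
    return session


def write_session(session: DyadSession, frames_path, comments_path) -> None:
    """Write a session back to the CSV dialect (inverse of read_session)."""
    f = session.frames.copy()
    f.insert(0, "dyad_id", session.dyad_id)
    f["face_present"] = f["face_present"].astype(int)
    f["pupil_detected"] = f["pupil_detected"].astype(int)
    f["face_looking"] = f["face_looking"].astype(int)
    f["face_poly"] = [
        p if isinstance(p, str) else format_polygon(p) for p in f["face_poly"]
    ]
    f.to_csv(frames_path, index=False)

    c = session.comments.copy()
    c.insert(0, "dyad_id", session.dyad_id)
    c.to_csv(comments_path, index=False)


# ---------------------------------------------------------------------------
# 50 Hz -> 1 Hz downsampling


def downsample_gaze(
    samples: Sequence[GazeSample] | pd.DataFrame,
    duration: float,
    max_gap: float = 0.5,
) -> pd.DataFrame:
    """Reduce a raw gaze stream to one entry per integer second.

    Each output second carries the sample whose timestamp is nearest to it
    (ties broken toward the earlier sample). ``pupil_detected`` is False when
    the nearest sample has an invalid pupil or lies more than ``max_gap``
    seconds away. Output length is exactly ``int(duration)``.
    """
    n_out = int(duration)
    grid = np.arange(n_out, dtype=float)
    out = pd.DataFrame(
        {
            "t": grid.astype(int),
            "gaze_x": np.full(n_out, np.nan),
            "gaze_y": np.full(n_out, np.nan),
            "pupil_detected": np.zeros(n_out, dtype=bool),
        }
    )
    if isinstance(samples, pd.DataFrame):
        st = samples["t"].to_numpy(dtype=float)
        sx = samples["x"].to_numpy(dtype=float)
        sy = samples["y"].to_numpy(dtype=float)
        sv = samples["pupil_valid"].to_numpy(dtype=bool)
    else:
        st = np.array([s.t for s in samples], dtype=float)
        sx = np.array([s.x for s in samples], dtype=float)
        sy = np.array([s.y for s in samples], dtype=float)
        sv = np.array([s.pupil_valid for s in samples], dtype=bool)
    if len(st) == 0:
        return out
    if np.any(np.diff(st) < 0):
        raise ValidationError("gaze samples must be sorted by t")

    # nearest sorted sample; tie (equal distance) -> earlier sample
    right = np.searchsorted(st, grid, side="left")
    left = np.clip(right - 1, 0, len(st) - 1)
    right = np.clip(right, 0, len(st) - 1)
    d_left = np.abs(grid - st[left])
    d_right = np.abs(st[right] - grid)
    pick = np.where(d_right < d_left, right, left)
    dist = np.minimum(d_left, d_right)

    ok = (dist <= max_gap) & sv[pick]
    out.loc[ok, "gaze_x"] = sx[pick[ok]]
    out.loc[ok, "gaze_y"] = sy[pick[ok]]
    out["pupil_detected"] = ok
    return out


# ---------------------------------------------------------------------------
# study-level validation report


@dataclass(frozen=True)
class SessionFlag:
    dyad_id: str
    reason: str
    value: float | None = None


@dataclass(frozen=True)
class StudyReport:
    n_sessions: int
    flags: tuple[SessionFlag, ...]

    @property
    def excludable(self) -> list[str]:
        return [fl.dyad_id for fl in self.flags if fl.reason == "low_pupil_detection"]


def validate_study(
    sessions: Sequence[DyadSession], pupil_threshold: float = 0.70
) -> StudyReport:
    """Flag sessions excludable for data loss; never mutates the input.

    A session whose pupil-detected proportion falls below ``pupil_threshold``
    (default 0.70, i.e. more than 30% data loss) is flagged excludable;
    sessions with no comments are flagged separately. The decision to drop
    flagged sessions is left to the caller.
    """
    flags: list[SessionFlag] = []
    for s in sessions:
        n = len(s.frames)
        if n == 0:
            flags.append(SessionFlag(s.dyad_id, "empty_frame_stream"))
            continue
        p_pupil = float(s.frames["pupil_detected"].mean())
        if p_pupil < pupil_threshold:
            flags.append(SessionFlag(s.dyad_id, "low_pupil_detection", p_pupil))
        if len(s.comments) == 0:
            flags.append(SessionFlag(s.dyad_id, "empty_comment_stream"))
    return StudyReport(n_sessions=len(sessions), flags=tuple(flags))
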