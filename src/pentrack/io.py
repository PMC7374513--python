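"""Data model and file formats for detection sequences, tracks and annotations.

On-disk formats
---------------
Detections are stored as JSON-lines, one frame per line::

    {"t": 1,
     "instances": [{"shoulder": [x, y], "tail": [x, y],
                    "shoulder_score": 0.9, "tail_score": 0.8,
                    "est_shoulder_from_tail": [x, y],
                    "est_tail_from_shoulder": [x, y],
                    "est_left_ear": [x, y] | null,
                    "est_right_ear": [x, y] | null}, ...],
     "ears": [{"side": "left", "location": [x, y],
               "est_shoulder": [x, y], "tag_probs": [p1, ..., pN]}, ...]}

An optional first line ``{"meta": {...}}`` may declare sequence metadata such
as ``resolution`` (pixel width/height of the coordinate frame) and ``n``
(number of housed animals).  All distances downstream are in the units of the
input coordinates.

Tracks and ground-truth annotations share one CSV layout with columns
``frame, identity, slot, shoulder_x, shoulder_y, tail_x, tail_y,
interpolated_flag`` and exactly N rows per frame.  Frames are 1-based in
files; identities and slots are 1-based in files and 0-based in memory.

Coordinates are real-valued pixels, origin top-left, x = column, y = row;
sub-pixel values are expected (the upstream detector localizes keypoints with
sub-pixel interpolation).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

#: Keypoint scores below this value are not emitted by the detector; the
#: instance-cost normalization relies on this floor.
SCORE_MIN = 0.25

TRACK_COLUMNS = [
    "frame", "identity", "slot",
    "shoulder_x", "shoulder_y", "tail_x", "tail_y",
    "interpolated_flag",
]


class ValidationError(ValueError):
    """An object violates a data-model invariant."""


class ParseError(ValueError):
    """A file could not be parsed into the data model."""


def as_point(value, name: str = "point") -> np.ndarray:
    """Coerce to a finite 2-vector (pixel column, pixel row).

    Always copies, so domain objects never alias caller-owned buffers.
    """
    arr = np.array(value, dtype=float)
    if arr.shape != (2,):
        raise ValidationError(f"{name} must be a 2-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} must be finite, got {arr}")
    return arr


@dataclass
class InstanceDetection:
    """One detected animal: paired shoulder/tail keypoints plus the detector's
    association estimates (each part's prediction of where its partner is).

    Missing association estimates fall back to the true partner coordinate,
    which zeroes the corresponding back-and-forth error term.
    """

    shoulder: np.ndarray
    tail: np.ndarray
    shoulder_score: float = 1.0
    tail_score: float = 1.0
    est_shoulder_from_tail: Optional[np.ndarray] = None
    est_tail_from_shoulder: Optional[np.ndarray] = None
    est_left_ear: Optional[np.ndarray] = None
    est_right_ear: Optional[np.ndarray] = None

    def __post_init__(self):
        self.shoulder = as_point(self.shoulder, "shoulder")
        self.tail = as_point(self.tail, "tail")
        if np.array_equal(self.shoulder, self.tail):
            raise ValidationError("shoulder and tail must be distinct points")
        for attr in ("shoulder_score", "tail_score"):
            s = float(getattr(self, attr))
            if not (SCORE_MIN <= s <= 1.0):
                raise ValidationError(
                    f"{attr}={s} outside [{SCORE_MIN}, 1]: parts below the "
                    f"floor are not detected and cannot contribute")
            setattr(self, attr, s)
        if self.est_shoulder_from_tail is None:
            self.est_shoulder_from_tail = self.shoulder.copy()
        else:
            self.est_shoulder_from_tail = as_point(
                self.est_shoulder_from_tail, "est_shoulder_from_tail")
        if self.est_tail_from_shoulder is None:
            self.est_tail_from_shoulder = self.tail.copy()
        else:
            self.est_tail_from_shoulder = as_point(
                self.est_tail_from_shoulder, "est_tail_from_shoulder")
        for attr in ("est_left_ear", "est_right_ear"):
            v = getattr(self, attr)
            if v is not None:
                setattr(self, attr, as_point(v, attr))

    @property
    def length(self) -> float:
        """Shoulder-to-tail distance in input units."""
        return float(np.linalg.norm(self.shoulder - self.tail))


@dataclass
class EarObservation:
    """A located ear tag with its classifier output.

    ``tag_probs`` is a probability vector over the N housed identities; an
    unreadable ("unknown") tag arrives as the uniform vector, produced
    upstream by the classifier.
    """

    side: str
    location: np.ndarray
    est_shoulder: Optional[np.ndarray] = None
    tag_probs: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValidationError(f"ear side must be 'left' or 'right', got {self.side!r}")
        self.location = as_point(self.location, "ear location")
        if self.est_shoulder is not None:
            self.est_shoulder = as_point(self.est_shoulder, "est_shoulder")
        if self.tag_probs is None:
            raise ValidationError("ear observation requires tag_probs")
        p = np.asarray(self.tag_probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValidationError("tag_probs must be a non-empty vector")
        if np.any(p < 0):
            raise ValidationError("tag_probs entries must be >= 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"tag_probs must sum to 1 within 1e-9, got {p.sum()!r}")
        self.tag_probs = p


@dataclass
class FrameDetections:
    """All raw detector output for one frame (variable cardinality)."""

    t: int
    instances: list = field(default_factory=list)
    ears: list = field(default_factory=list)

    def __post_init__(self):
        self.t = int(self.t)
        if self.t < 1:
            raise ValidationError(f"frame index must be >= 1, got {self.t}")


class DetectionSequence(list):
    """A contiguous list of FrameDetections (t = 1..T) plus file metadata."""

    def __init__(self, frames: Iterable[FrameDetections] = (), meta: Optional[dict] = None):
        super().__init__(frames)
        self.meta = dict(meta or {})


@dataclass
class GroundTruthFrame:
    """Annotated poses for every housed animal in one frame.

    ``identities`` are 0-based in memory and must be a permutation of 0..N-1.
    """

    t: int
    identities: np.ndarray
    shoulders: np.ndarray
    tails: np.ndarray

    def __post_init__(self):
        self.identities = np.asarray(self.identities, dtype=int)
        self.shoulders = np.asarray(self.shoulders, dtype=float)
        self.tails = np.asarray(self.tails, dtype=float)
        n = self.identities.size
        if sorted(self.identities.tolist()) != list(range(n)):
            raise ValidationError(
                f"frame {self.t}: identities must be a permutation of 0..{n - 1}, "
                f"got {sorted(self.identities.tolist())}")
        if self.shoulders.shape != (n, 2) or self.tails.shape != (n, 2):
            raise ValidationError(f"frame {self.t}: pose arrays must have shape ({n}, 2)")

    @property
    def n(self) -> int:
        return self.identities.size

    def by_identity(self) -> tuple[np.ndarray, np.ndarray]:
        """(shoulders, tails) reordered so row n is identity n."""
        order = np.argsort(self.identities)
        return self.shoulders[order], self.tails[order]


@dataclass
class IdentityAssignment:
    """Per-frame bijection from track slots to identities (0-based).

    ``slot_to_identity[t, i]`` is the identity occupying slot i in frame t+1.
    """

    slot_to_identity: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.slot_to_identity, dtype=int)
        if a.ndim != 2:
            raise ValidationError("slot_to_identity must be a (T, N) array")
        n = a.shape[1]
        for t in range(a.shape[0]):
            if sorted(a[t].tolist()) != list(range(n)):
                raise ValidationError(f"frame {t + 1}: slot->identity map is not a bijection")
        self.slot_to_identity = a

    @property
    def n_frames(self) -> int:
        return self.slot_to_identity.shape[0]

    @property
    def n(self) -> int:
        return self.slot_to_identity.shape[1]


# ---------------------------------------------------------------------------
# JSON-lines detections
# ---------------------------------------------------------------------------

def _instance_from_json(obj: dict) -> InstanceDetection:
    return InstanceDetection(
        shoulder=obj["shoulder"],
        tail=obj["tail"],
        shoulder_score=obj.get("shoulder_score", 1.0),
        tail_score=obj.get("tail_score", 1.0),
        est_shoulder_from_tail=obj.get("est_shoulder_from_tail"),
        est_tail_from_shoulder=obj.get("est_tail_from_shoulder"),
        est_left_ear=obj.get("est_left_ear"),
        est_right_ear=obj.get("est_right_ear"),
    )


def _ear_from_json(obj: dict) -> EarObservation:
    return EarObservation(
        side=obj["side"],
        location=obj["location"],
        est_shoulder=obj.get("est_shoulder"),
        tag_probs=obj["tag_probs"],
    )


def _point_json(p: Optional[np.ndarray]):
    return None if p is None else [float(p[0]), float(p[1])]


def _frame_to_json(frame: FrameDetections) -> dict:
    return {
        "t": frame.t,
        "instances": [
            {
                "shoulder": _point_json(d.shoulder),
                "tail": _point_json(d.tail),
                "shoulder_score": d.shoulder_score,
                "tail_score": d.tail_score,
                "est_shoulder_from_tail": _point_json(d.est_shoulder_from_tail),
                "est_tail_from_shoulder": _point_json(d.est_tail_from_shoulder),
                "est_left_ear": _point_json(d.est_left_ear),
                "est_right_ear": _point_json(d.est_right_ear),
            }
            for d in frame.instances
        ],
        "ears": [
            {
                "side": e.side,
                "location": _point_json(e.location),
                "est_shoulder": _point_json(e.est_shoulder),
                "tag_probs": [float(p) for p in e.tag_probs],
            }
            for e in frame.ears
        ],
    }


def read_detection_sequence(path) -> DetectionSequence:
    """Read a JSON-lines detection file into a validated, contiguous sequence.

    Frames are sorted by ``t``; gaps in 1..T are filled with empty frames.
    Raises :class:`ParseError` (naming the line) on malformed JSON and
    :class:`ValidationError` on invariant violations (duplicate ``t``, scores
    outside [0.25, 1], tag vectors that do not sum to one, ...).
    """
    frames: dict[int, FrameDetections] = {}
    meta: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: malformed JSON on line {lineno}: {exc}") from None
            if "meta" in obj and "t" not in obj:
                meta.update(obj["meta"])
                continue
            try:
                frame = FrameDetections(
                    t=obj["t"],
                    instances=[_instance_from_json(d) for d in obj.get("instances", [])],
                    ears=[_ear_from_json(e) for e in obj.get("ears", [])],
                )
            except KeyError as exc:
                raise ParseError(f"{path}: line {lineno} missing field {exc}") from None
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
            if frame.t in frames:
                raise ValidationError(f"{path}: duplicate frame index t={frame.t} on line {lineno}")
            frames[frame.t] = frame
    if not frames:
        return DetectionSequence([], meta)
    t_max = max(frames)
    ordered = [frames.get(t, FrameDetections(t=t)) for t in range(1, t_max + 1)]
    return DetectionSequence(ordered, meta)


def write_detection_sequence(frames: Sequence[FrameDetections], path, meta: Optional[dict] = None) -> None:
    """Write frames as JSON-lines (optional leading metadata line)."""
    with open(path, "w") as fh:
        if meta:
            fh.write(json.dumps({"meta": meta}) + "\n")
        for frame in frames:
            fh.write(json.dumps(_frame_to_json(frame)) + "\n")


# ---------------------------------------------------------------------------
# Track / ground-truth CSV
# ---------------------------------------------------------------------------

def write_tracks(tracks, ids: Optional[IdentityAssignment], path) -> None:
    """Write a track set (and optional identity assignment) as CSV.

    Exactly N rows per frame; ``identity`` falls back to the slot index when
    no assignment is given (location-only output).  Coordinates round-trip
    losslessly well beyond 6 decimal places.
    """
    if ids is not None and ids.n_frames != tracks.n_frames:
        raise ValidationError(
            f"tracks cover {tracks.n_frames} frames but identity assignment "
            f"covers {ids.n_frames}")
    rows = []
    for t in range(tracks.n_frames):
        for i in range(tracks.n_targets):
            identity = i if ids is None else int(ids.slot_to_identity[t, i])
            rows.append((
                t + 1, identity + 1, i + 1,
                tracks.shoulders[t, i, 0], tracks.shoulders[t, i, 1],
                tracks.tails[t, i, 0], tracks.tails[t, i, 1],
                int(tracks.origin[t, i] != 0),
            ))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False)


def read_ground_truth(path) -> list[GroundTruthFrame]:
    """Read a CSV in the :func:`write_tracks` layout as per-frame annotations.

    N is inferred from the first frame; every frame must contain each
    identity exactly once (fixed cardinality).
    """
    df = pd.read_csv(path)
    missing = {"frame", "identity", "shoulder_x", "shoulder_y", "tail_x", "tail_y"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return []
    frames: list[GroundTruthFrame] = []
    n_ref = None
    for t, grp in df.groupby("frame", sort=True):
        idents = grp["identity"].to_numpy(dtype=int) - 1
        if n_ref is None:
            n_ref = idents.size
        if idents.size != n_ref:
            raise ValidationError(
                f"{path}: frame {t} has {idents.size} rows, expected {n_ref} "
                f"(fixed cardinality)")
        if sorted(idents.tolist()) != list(range(n_ref)):
            raise ValidationError(
                f"{path}: frame {t} does not contain each identity 1..{n_ref} exactly once")
        frames.append(GroundTruthFrame(
            t=int(t),
            identities=idents,
            shoulders=grp[["shoulder_x", "shoulder_y"]].to_numpy(dtype=float),
            tails=grp[["tail_x", "tail_y"]].to_numpy(dtype=float),
        ))
    return frames


def write_ground_truth(frames: Sequence[GroundTruthFrame], path) -> None:
    """Write annotations in the shared CSV layout (slot column mirrors identity)."""
    rows = []
    for f in frames:
        for k in range(f.n):
            rows.append((
                f.t, int(f.identities[k]) + 1, int(f.identities[k]) + 1,
                f.shoulders[k, 0], f.shoulders[k, 1],
                f.tails[k, 0], f.tails[k, 1], 0,
            ))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)
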