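"""Precision/recall scoring against per-frame pose annotations.

Because cardinality is fixed — the tracker always reports exactly N poses
and the annotations always contain exactly N animals — every unmatched
prediction is simultaneously a false positive and a false negative, so
precision and recall coincide.

A prediction matches under two criteria:

- **location**: prediction and some ground-truth pose are mutually nearest
  (by the pose error Delta = shoulder distance + tail distance) and the
  error is below that ground truth's shoulder-to-tail body length; labels
  are ignored.  Suited to pen-level metrics (distance traveled, space use).
- **location_id**: the mutual-nearest partner must additionally carry the
  same identity.  Suited to individual-level monitoring.

The body-length gate is heuristic but adapts to animals of any size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GroundTruthFrame, IdentityAssignment, ValidationError
from .tracks import TrackSet

MATCH_MODES = ("location", "location_id")


@dataclass
class ScenarioResult:
    """Pooled matching counts for one scenario/mode over a frame sequence."""

    mode: str
    scenario: str
    true_positives: int
    false_positives: int
    false_negatives: int
    n_frames: int
    n_targets: int

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 0.0

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "scenario": self.scenario,
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "n_frames": self.n_frames,
            "n_targets": self.n_targets,
            "precision": self.precision,
            "recall": self.recall,
        }


def pose_error(gt_pose, pred_pose) -> float:
    """Delta: shoulder-to-shoulder plus tail-to-tail Euclidean distance."""
    gs, gt_ = gt_pose
    ps, pt = pred_pose
    return float(np.linalg.norm(np.asarray(gs, float) - np.asarray(ps, float))
                 + np.linalg.norm(np.asarray(gt_, float) - np.asarray(pt, float)))


def gt_length(gt_pose) -> float:
    """Shoulder-to-tail body length of an annotated pose."""
    s, t = gt_pose
    ell = float(np.linalg.norm(np.asarray(s, float) - np.asarray(t, float)))
    if ell == 0.0:
        raise ValidationError("ground-truth body length is zero")
    return ell


def match_frame(gt_shoulders, gt_tails, pred_shoulders, pred_tails, mode: str) -> np.ndarray:
    """Per-identity match booleans for one frame.

    Rows of the ground-truth and prediction arrays are ordered by identity
    (row n = identity n).  ``mode="location_id"`` requires prediction n and
    ground truth n to be mutually nearest and within the body-length gate;
    ``mode="location"`` only requires *some* mutual-nearest partner within
    its body length.  Exact argmin ties resolve toward the lower index.
    """
    if mode not in MATCH_MODES:
        raise ValidationError(f"mode must be one of {MATCH_MODES}, got {mode!r}")
    gt_s = np.asarray(gt_shoulders, float)
    gt_t = np.asarray(gt_tails, float)
    pr_s = np.asarray(pred_shoulders, float)
    pr_t = np.asarray(pred_tails, float)
    n = gt_s.shape[0]
    if pr_s.shape[0] != n:
        raise ValidationError(f"cardinality mismatch: {n} annotations vs {pr_s.shape[0]} predictions")
    # delta[j, i] = pose error between ground truth j and prediction i
    delta = (np.linalg.norm(gt_s[:, None, :] - pr_s[None, :, :], axis=2)
             + np.linalg.norm(gt_t[:, None, :] - pr_t[None, :, :], axis=2))
    lengths = np.linalg.norm(gt_s - gt_t, axis=1)
    nearest_gt = np.argmin(delta, axis=0)     # per prediction i
    nearest_pred = np.argmin(delta, axis=1)   # per ground truth j
    matched = np.zeros(n, dtype=bool)
    for i in range(n):
        if mode == "location_id":
            matched[i] = (nearest_gt[i] == i and nearest_pred[i] == i
                          and delta[i, i] < lengths[i])
        else:
            k = nearest_gt[i]
            matched[i] = (nearest_pred[k] == i and delta[k, i] < lengths[k])
    return matched


def predictions_by_identity(tracks: TrackSet, ids: IdentityAssignment):
    """Reorder tracker output so row n of each frame is identity n;
    returns (shoulders, tails) of shape (T, N, 2)."""
    if ids.n_frames != tracks.n_frames or ids.n != tracks.n_targets:
        raise ValidationError("tracks and identity assignment are not aligned")
    n_frames, n = tracks.n_frames, tracks.n_targets
    shoulders = np.empty_like(tracks.shoulders)
    tails = np.empty_like(tracks.tails)
    for t in range(n_frames):
        shoulders[t, ids.slot_to_identity[t]] = tracks.shoulders[t]
        tails[t, ids.slot_to_identity[t]] = tracks.tails[t]
    return shoulders, tails


def precision_recall(gt_frames, pred, mode: str, scenario: str = "") -> ScenarioResult:
    """Pooled precision/recall over a sequence.

    ``pred`` is either a ``(TrackSet, IdentityAssignment)`` pair or a list of
    :class:`GroundTruthFrame`-like objects (e.g. read back from a tracks
    CSV).  Frames must align one-to-one with the annotations.
    """
    if isinstance(pred, tuple):
        tracks, ids = pred
        pr_s, pr_t = predictions_by_identity(tracks, ids)
        pred_frames = [(pr_s[t], pr_t[t]) for t in range(tracks.n_frames)]
        pred_ts = list(range(1, tracks.n_frames + 1))
    else:
        pred_frames = [f.by_identity() for f in pred]
        pred_ts = [f.t for f in pred]
    gt_ts = [f.t for f in gt_frames]
    if gt_ts != pred_ts:
        raise ValidationError(
            f"misaligned frames: annotations cover {gt_ts[:3]}...{gt_ts[-1:]} "
            f"but predictions cover {pred_ts[:3]}...{pred_ts[-1:]}")
    if not gt_frames:
        raise ValidationError("empty sequence")
    n = gt_frames[0].n
    tp = 0
    for gt, (ps, pt) in zip(gt_frames, pred_frames):
        gs, gtl = gt.by_identity()
        tp += int(match_frame(gs, gtl, ps, pt, mode).sum())
    total = n * len(gt_frames)
    return ScenarioResult(
        mode=mode, scenario=scenario,
        true_positives=tp, false_positives=total - tp, false_negatives=total - tp,
        n_frames=len(gt_frames), n_targets=n,
    )
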