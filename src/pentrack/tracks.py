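"""Fixed-cardinality track interpolation.

Raw per-frame detections have variable cardinality: occlusions cause misses
and the detector produces occasional false positives.  Because the number of
housed animals N is fixed and known, the detections can be forced into
exactly N continuous tracks:

1. **Prune** frames with more than N instances, dropping the highest-cost
   detections.  Cost combines the detector's back-and-forth association
   error (each part's estimate of its partner, measured against the actual
   partner), normalized by body length, with the part scores.
2. **Duplicate** (forward pass 1..T, then backward pass T..1): whenever a
   frame-to-frame Hungarian assignment leaves an entry unmatched, copy it
   into the neighboring frame as a placeholder.  After both passes every
   frame holds the same number of entries, linked into disjoint chains.
3. **Interpolate** each placeholder's position linearly in time between the
   nearest genuinely detected entries on its chain; placeholders beyond the
   first/last detection hold the nearest detected position.

The inter-frame assignment cost is the stay-put pose displacement delta
(shoulder and tail distances in quadrature); no gating threshold is applied,
since fixed cardinality requires every entry to be carried forward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import FrameDetections, InstanceDetection, ValidationError
from .motion import slot_distance

ORIGIN_DETECTED = 0
ORIGIN_DUPLICATE = 1
ORIGIN_INTERPOLATED = 2

ORIGIN_NAMES = {
    ORIGIN_DETECTED: "detected",
    ORIGIN_DUPLICATE: "duplicate_raw",
    ORIGIN_INTERPOLATED: "interpolated",
}


@dataclass
class TrackSet:
    """Exactly N track slots per frame over T frames.

    ``shoulders``/``tails`` have shape (T, N, 2); slot i forms one continuous
    chain across frames.  ``origin[t, i]`` records whether the entry is a
    genuine detection, a raw duplicate, or an interpolated placeholder, and
    ``source[t, i]`` is the index of the originating detection in the (pruned)
    input frame, or -1 for fabricated entries.
    """

    shoulders: np.ndarray
    tails: np.ndarray
    origin: np.ndarray
    source: np.ndarray

    def __post_init__(self):
        self.shoulders = np.asarray(self.shoulders, dtype=float)
        self.tails = np.asarray(self.tails, dtype=float)
        self.origin = np.asarray(self.origin, dtype=np.int8)
        self.source = np.asarray(self.source, dtype=int)
        if self.shoulders.shape != self.tails.shape or self.shoulders.ndim != 3:
            raise ValidationError("shoulders/tails must both be (T, N, 2)")
        if self.origin.shape != self.shoulders.shape[:2] or self.source.shape != self.origin.shape:
            raise ValidationError("origin/source must be (T, N)")

    @property
    def n_frames(self) -> int:
        return self.shoulders.shape[0]

    @property
    def n_targets(self) -> int:
        return self.shoulders.shape[1]

    def pose(self, t: int, i: int) -> tuple[np.ndarray, np.ndarray]:
        return self.shoulders[t, i], self.tails[t, i]


def instance_cost(d: InstanceDetection, score_mode: str = "divide") -> float:
    """Confidence cost of a detection: association error over body length,
    scaled by the part scores.

    Zero iff both association estimates are exact.  With ``score_mode=
    "divide"`` (default) scores at the 0.25 floor double the cost and scores
    of 1 halve it; ``"multiply"`` applies the scores as a product instead.
    """
    sep = d.length
    if sep == 0.0:
        raise ValidationError("instance cost undefined for coincident shoulder and tail")
    err = (np.linalg.norm(d.est_shoulder_from_tail - d.shoulder)
           + np.linalg.norm(d.est_tail_from_shoulder - d.tail))
    base = err / (2.0 * sep)
    score_sum = d.shoulder_score + d.tail_score
    if score_mode == "divide":
        return float(base / score_sum)
    if score_mode == "multiply":
        return float(base * score_sum)
    raise ValueError(f"unknown score_mode {score_mode!r}")


def prune_frame(frame: FrameDetections, n_targets: int, score_mode: str = "divide") -> FrameDetections:
    """Keep at most N instances per frame, dropping the highest-cost ones.

    Ears are untouched.  Ties break toward the earlier-listed instance
    (stable sort), and frames already at or below N pass through unchanged.
    """
    if n_targets < 1:
        raise ValidationError("n_targets must be >= 1")
    if len(frame.instances) <= n_targets:
        return frame
    costs = np.array([instance_cost(d, score_mode) for d in frame.instances])
    keep = np.sort(np.argsort(costs, kind="stable")[:n_targets])
    return FrameDetections(
        t=frame.t,
        instances=[frame.instances[k] for k in keep],
        ears=frame.ears,
    )


def _tie_broken_assignment(cost: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian assignment with ties broken toward lower original indices.

    A lexicographic perturbation far below meaningful cost differences makes
    the optimum unique; totals should always be evaluated on the original
    matrix.
    """
    if cost.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    finite = cost[np.isfinite(cost)]
    scale = 1.0 + (np.abs(finite).max() if finite.size else 0.0)
    n_rows, n_cols = cost.shape
    rows = np.arange(n_rows)[:, None]
    cols = np.arange(n_cols)[None, :]
    # earlier rows dominate the tie-break, then earlier columns
    perturb = (np.power(0.5, rows, dtype=float) * (cols + 1.0) / (n_cols + 1.0))
    return linear_sum_assignment(cost + 1e-9 * scale * perturb)


def associate_adjacent(prev_poses, next_poses):
    """Minimum-cost bipartite matching between two frames' poses.

    Poses are (shoulder, tail) pairs; cost is the stay-put displacement
    delta.  Returns ``(pairs, unmatched_prev)`` where ``pairs`` is a list of
    (prev_index, next_index) of size min(len(prev), len(next)).
    """
    if not prev_poses or not next_poses:
        return [], list(range(len(prev_poses)))
    cost = np.array([[slot_distance(a, b) for b in next_poses] for a in prev_poses])
    rows, cols = _tie_broken_assignment(cost)
    pairs = sorted(zip(rows.tolist(), cols.tolist()))
    matched = {i for i, _ in pairs}
    unmatched = [i for i in range(len(prev_poses)) if i not in matched]
    return pairs, unmatched


class _Entry:
    __slots__ = ("shoulder", "tail", "source", "origin", "prev", "next")

    def __init__(self, shoulder, tail, source, origin):
        self.shoulder = np.asarray(shoulder, dtype=float)
        self.tail = np.asarray(tail, dtype=float)
        self.source = source
        self.origin = origin
        self.prev = None
        self.next = None

    @property
    def pose(self):
        return self.shoulder, self.tail


def build_tracks(frames, n_targets: int) -> TrackSet:
    """Run the two duplication passes and interpolation over pruned frames.

    Pass 1 (t = 1..T): entries of frame t-1 left unmatched by the Hungarian
    assignment against frame t are copied into frame t as duplicates.  Pass 2
    (t = T..1) mirrors this backward: frame t+1 entries without a backward
    link are copied into frame t.  All assignment links are kept, yielding
    disjoint chains; duplicates are then replaced by time-weighted linear
    interpolation between the nearest flanking detections on their chain
    (or hold the nearest detection at the sequence boundaries).

    If no frame ever reaches N detections the resulting chains are fewer
    than N; missing chains are padded by cloning existing ones (flagged
    duplicate throughout) so the fixed-cardinality contract always holds.
    A sequence with no detections at all is an error.
    """
    n_frames = len(frames)
    if n_frames == 0:
        raise ValidationError("empty sequence: nothing to track")
    if all(len(f.instances) == 0 for f in frames):
        raise ValidationError("no detections in any frame: nothing to track")

    entries: list[list[_Entry]] = [
        [_Entry(d.shoulder, d.tail, k, ORIGIN_DETECTED) for k, d in enumerate(f.instances)]
        for f in frames
    ]
    for f in frames:
        if len(f.instances) > n_targets:
            raise ValidationError(
                f"frame {f.t} has {len(f.instances)} instances > N={n_targets}; prune first")

    # pass 1: forward duplication
    for t in range(1, n_frames):
        prev, cur = entries[t - 1], entries[t]
        if prev and cur:
            cost = np.array([[slot_distance(a.pose, b.pose) for b in cur] for a in prev])
            rows, cols = _tie_broken_assignment(cost)
            for i, j in zip(rows, cols):
                prev[i].next = cur[j]
                cur[j].prev = prev[i]
        for a in prev:
            if a.next is None:
                dup = _Entry(a.shoulder.copy(), a.tail.copy(), -1, ORIGIN_DUPLICATE)
                a.next = dup
                dup.prev = a
                cur.append(dup)

    # pass 2: backward duplication (duplicates copy the frame t+1 entry)
    for t in range(n_frames - 2, -1, -1):
        cur, nxt = entries[t], entries[t + 1]
        for b in nxt:
            if b.prev is None:
                dup = _Entry(b.shoulder.copy(), b.tail.copy(), -1, ORIGIN_DUPLICATE)
                dup.next = b
                b.prev = dup
                cur.append(dup)

    n_chains = len(entries[0])
    assert all(len(row) == n_chains for row in entries)

    shoulders = np.empty((n_frames, n_targets, 2))
    tails = np.empty((n_frames, n_targets, 2))
    origin = np.full((n_frames, n_targets), ORIGIN_DUPLICATE, dtype=np.int8)
    source = np.full((n_frames, n_targets), -1, dtype=int)

    for slot, head in enumerate(entries[0]):
        e = head
        for t in range(n_frames):
            shoulders[t, slot] = e.shoulder
            tails[t, slot] = e.tail
            origin[t, slot] = e.origin
            source[t, slot] = e.source
            e = e.next
        assert e is None

    # pad missing chains by cloning existing ones round-robin
    for slot in range(n_chains, n_targets):
        src = slot % n_chains
        shoulders[:, slot] = shoulders[:, src]
        tails[:, slot] = tails[:, src]
        origin[:, slot] = ORIGIN_DUPLICATE
        source[:, slot] = -1

    _interpolate_duplicates(shoulders, tails, origin)
    return TrackSet(shoulders, tails, origin, source)


def _interpolate_duplicates(shoulders, tails, origin) -> None:
    """Replace duplicate positions chain-by-chain with time-weighted
    interpolation between flanking detections; hold at the boundaries."""
    n_frames, n_slots = origin.shape
    ts = np.arange(n_frames)
    for i in range(n_slots):
        det = ts[origin[:, i] == ORIGIN_DETECTED]
        if det.size == 0:
            continue  # cloned chain: positions already copied, stays duplicate_raw
        for t in ts[origin[:, i] != ORIGIN_DETECTED]:
            right = np.searchsorted(det, t)
            if right == 0:
                t1 = t2 = det[0]
            elif right == det.size:
                t1 = t2 = det[-1]
            else:
                t1, t2 = det[right - 1], det[right]
            if t1 == t2:
                shoulders[t, i] = shoulders[t1, i]
                tails[t, i] = tails[t1, i]
            else:
                w = (t2 - t) / (t2 - t1)
                shoulders[t, i] = w * shoulders[t1, i] + (1 - w) * shoulders[t2, i]
                tails[t, i] = w * tails[t1, i] + (1 - w) * tails[t2, i]
            origin[t, i] = ORIGIN_INTERPOLATED
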