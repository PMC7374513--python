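"""Fuse intermittent ear-tag sightings into per-slot identity likelihoods.

Ear-tag classifications arrive as probability vectors attached to detected
ear locations, while tracks are built from shoulder/tail instances.  Rather
than hard-assigning ears to instances, each ear is *softly* linked to each
instance through the detector's association vectors: the average
back-and-forth shoulder<->ear distance, normalized by the shoulder-ear
separation, is mapped through a decaying exponential to a link probability.
An instance's identity likelihood is then the product over all ears in the
frame of a link-weighted blend of the ear's tag vector with the uniform
vector, normalized over identities.  Unlinked ears contribute a constant
factor that washes out under normalization, so the two limiting behaviors
hold exactly: no linked ears -> uniform; one perfectly linked, confidently
classified ear -> that ear's tag vector.

Interpolated track entries are fabricated geometry with no detector output,
so they receive uniform emissions: manufactured positions must not
manufacture identity evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import EarObservation, FrameDetections, GroundTruthFrame, InstanceDetection, ValidationError
from .tracks import ORIGIN_DETECTED, TrackSet, _tie_broken_assignment

#: Floor on link and emission probabilities, guarding against classifier
#: over-confidence destabilizing long products.
PROB_FLOOR = 1e-6

#: Decay rate of the link probability in the normalized ear-shoulder distance.
LINK_DECAY = 10.0


@dataclass
class EmissionTensor:
    """log p(observation | slot i holds identity n), shape (T, N, N).

    Rows over n are normalized probability vectors in linear space.
    """

    log_e: np.ndarray

    def __post_init__(self):
        self.log_e = np.asarray(self.log_e, dtype=float)
        if self.log_e.ndim != 3:
            raise ValidationError("log_e must have shape (T, N_slots, N_ids)")

    @property
    def n_frames(self) -> int:
        return self.log_e.shape[0]

    @property
    def n_slots(self) -> int:
        return self.log_e.shape[1]

    @property
    def n_identities(self) -> int:
        return self.log_e.shape[2]


def ear_shoulder_distance(shoulder, est_ear, ear, est_shoulder) -> float:
    """Average back-and-forth error between an instance's shoulder and an ear,
    normalized by their separation.

    ``est_ear`` is the instance's prediction of the ear location; and
    ``est_shoulder`` the ear's prediction of the shoulder.  Zero iff both
    predictions are exact.
    """
    shoulder = np.asarray(shoulder, float)
    ear = np.asarray(ear, float)
    sep = float(np.linalg.norm(shoulder - ear))
    if sep == 0.0:
        raise ValidationError("ear-shoulder distance undefined for coincident points")
    err = (np.linalg.norm(np.asarray(est_shoulder, float) - shoulder)
           + np.linalg.norm(np.asarray(est_ear, float) - ear))
    return float(err / (2.0 * sep))


def link_probability(d: float) -> float:
    """Probability that an ear belongs to an instance at normalized distance d,
    exp(-10 d) floored at 1e-6."""
    if d < 0:
        raise ValidationError("distance must be nonnegative")
    return max(PROB_FLOOR, math.exp(-LINK_DECAY * d))


def _ear_link(instance: InstanceDetection, ear: EarObservation) -> float:
    """Link probability between one instance and one ear, with the missing
    association-estimate fallbacks (absent estimate -> zero error term)."""
    est_ear = instance.est_left_ear if ear.side == "left" else instance.est_right_ear
    if est_ear is None:
        est_ear = ear.location
    est_shoulder = ear.est_shoulder if ear.est_shoulder is not None else instance.shoulder
    d = ear_shoulder_distance(instance.shoulder, est_ear, ear.location, est_shoulder)
    return link_probability(d)


def instance_id_likelihood(instance: InstanceDetection, ears, n_identities: int) -> np.ndarray:
    """Identity probability vector for one instance given the frame's ears.

    Product over ears of ``p_link * tag + (1 - p_link) / N``, normalized
    over identities (in log space, so many near-zero factors cannot
    underflow).
    """
    if n_identities < 1:
        raise ValidationError("n_identities must be >= 1")
    log_p = np.full(n_identities, -math.log(n_identities))
    for ear in ears:
        if ear.tag_probs.size != n_identities:
            raise ValidationError(
                f"ear tag_probs has length {ear.tag_probs.size}, expected {n_identities}")
        p_link = _ear_link(instance, ear)
        factor = p_link * ear.tag_probs + (1.0 - p_link) / n_identities
        log_p += np.log(np.maximum(factor, 1e-300))
    log_p -= np.logaddexp.reduce(log_p)
    return np.exp(log_p)


def build_emissions(
    tracks: TrackSet,
    frames,
    n_identities: int,
    init: GroundTruthFrame | None = None,
    floor: float = PROB_FLOOR,
) -> EmissionTensor:
    """Assemble the per-frame emission tensor for inference.

    Detected slots get :func:`instance_id_likelihood`; interpolated or
    duplicated slots get the uniform vector.  With ``init`` (initialized
    scenario), first-frame annotations are matched to slots by the Hungarian
    algorithm on the pose error and the matched rows are overwritten with a
    near-one-hot vector (1 - (N-1)*eps at the annotated identity, eps =
    1e-6 elsewhere).  All rows are floored at ``floor`` and renormalized
    before the log transform.
    """
    if len(frames) != tracks.n_frames:
        raise ValidationError(
            f"tracks cover {tracks.n_frames} frames but {len(frames)} detection frames given")
    n_frames, n_slots = tracks.n_frames, tracks.n_targets
    probs = np.full((n_frames, n_slots, n_identities), 1.0 / n_identities)
    for t in range(n_frames):
        ears = frames[t].ears
        if not ears:
            continue
        for i in range(n_slots):
            if tracks.origin[t, i] != ORIGIN_DETECTED:
                continue
            inst = frames[t].instances[tracks.source[t, i]]
            probs[t, i] = instance_id_likelihood(inst, ears, n_identities)

    if init is not None:
        if init.n != n_identities:
            raise ValidationError(
                f"first-frame annotation has N={init.n}, expected {n_identities}")
        # pose error Delta between annotations and frame-1 slots
        cost = np.empty((n_slots, init.n))
        for i in range(n_slots):
            for k in range(init.n):
                cost[i, k] = (np.linalg.norm(tracks.shoulders[0, i] - init.shoulders[k])
                              + np.linalg.norm(tracks.tails[0, i] - init.tails[k]))
        rows, cols = _tie_broken_assignment(cost)
        eps = 1e-6
        for i, k in zip(rows, cols):
            row = np.full(n_identities, eps)
            row[init.identities[k]] = 1.0 - (n_identities - 1) * eps
            probs[0, i] = row

    probs = np.maximum(probs, floor)
    probs /= probs.sum(axis=2, keepdims=True)
    return EmissionTensor(np.log(probs))
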