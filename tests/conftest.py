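import numpy as np
import pytest

from pentrack import (EarObservation, FrameDetections, InstanceDetection, TrackSet)
from pentrack.tracks import ORIGIN_DETECTED


def make_instance(shoulder, tail, shoulder_score=1.0, tail_score=1.0,
                  est_shoulder=None, est_tail=None, est_left_ear=None,
                  est_right_ear=None) -> InstanceDetection:
    """Instance with exact association estimates unless overridden."""
    return InstanceDetection(
        shoulder=shoulder, tail=tail,
        shoulder_score=shoulder_score, tail_score=tail_score,
        est_shoulder_from_tail=shoulder if est_shoulder is None else est_shoulder,
        est_tail_from_shoulder=tail if est_tail is None else est_tail,
        est_left_ear=est_left_ear, est_right_ear=est_right_ear,
    )


def make_ear(location, tag_probs, side="left", est_shoulder=None) -> EarObservation:
    return EarObservation(side=side, location=location,
                          est_shoulder=est_shoulder, tag_probs=tag_probs)


def static_trackset(positions, n_frames: int) -> TrackSet:
    """Track set where slot i sits at positions[i] (shoulder; tail 10 px right)
    in every frame, flagged detected."""
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    shoulders = np.tile(pos, (n_frames, 1, 1))
    tails = shoulders + np.array([10.0, 0.0])
    origin = np.full((n_frames, n), ORIGIN_DETECTED, dtype=np.int8)
    source = np.tile(np.arange(n), (n_frames, 1))
    return TrackSet(shoulders, tails, origin, source)


def random_trackset(rng: np.random.Generator, n_frames: int, n_slots: int,
                    scale: float = 30.0) -> TrackSet:
    shoulders = rng.uniform(0, scale, size=(n_frames, n_slots, 2))
    tails = shoulders + rng.uniform(5, 15, size=(n_frames, n_slots, 2))
    origin = np.full((n_frames, n_slots), ORIGIN_DETECTED, dtype=np.int8)
    source = np.tile(np.arange(n_slots), (n_frames, 1))
    return TrackSet(shoulders, tails, origin, source)


def random_emissions(rng: np.random.Generator, n_frames: int, n_slots: int,
                     n_ids: int) -> np.ndarray:
    """Random normalized log emission rows."""
    p = rng.dirichlet(np.ones(n_ids), size=(n_frames, n_slots))
    return np.log(p)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
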