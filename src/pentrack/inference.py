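"""Identity assignment by forward-backward smoothing over track slots.

For each identity n, the occupied track slot over time is a hidden Markov
chain: the state space is the N slots of each frame, transitions follow the
stay-put exponential-mixture density of the pose displacement between slot
positions in adjacent frames, and emissions are the marker-fusion identity
likelihoods.  The forward-backward algorithm yields per-frame posterior
marginals p(slot i holds identity n | all observations); everything runs in
log space with the max-shifted log-sum-exp so that chains of tens of
thousands of frames with emissions near the 1e-6 floor never underflow
(the textbook linear-domain recursion reaches exact zero within a few
hundred such frames).

Transition densities are used as raw mixture values without per-step
normalization over destination slots; the constants cancel in the per-frame
comparisons (``normalize_transitions=True`` enables row normalization).
Identities are finalized per frame by a Hungarian assignment minimizing the
summed negative log posteriors over slot<->identity bijections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp as _scipy_logsumexp

from .io import FrameDetections, GroundTruthFrame, IdentityAssignment, ValidationError
from .markers import EmissionTensor, build_emissions
from .motion import MotionModel, slot_distance, transition_density
from .tracks import TrackSet, _tie_broken_assignment, build_tracks, prune_frame

SCENARIOS = ("location", "initialized", "uninitialized")


@dataclass
class PosteriorTensor:
    """Log posterior marginals (up to per-identity additive constants) with
    the forward/backward tensors that produced them; all shaped (T, N, N)."""

    log_post: np.ndarray
    log_alpha: np.ndarray
    log_beta: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.log_post.shape[0]


def log_sum_exp(values) -> float:
    """Max-shifted log(sum(exp(values))); errors on an empty input."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("log_sum_exp of an empty collection is undefined")
    return float(_scipy_logsumexp(v))


def _log_transitions(tracks: TrackSet, model: MotionModel, normalize: bool = False) -> np.ndarray:
    """log transition densities, shape (T-1, N, N):
    entry [t, i, j] = log p(slot i at frame t+1 | slot j at frame t)."""
    n_frames, n_slots = tracks.n_frames, tracks.n_targets
    # pose displacement between every slot pair of adjacent frames
    cur_s = tracks.shoulders[1:, :, None, :]
    cur_t = tracks.tails[1:, :, None, :]
    prev_s = tracks.shoulders[:-1, None, :, :]
    prev_t = tracks.tails[:-1, None, :, :]
    delta = np.sqrt(((cur_s - prev_s) ** 2).sum(-1) + ((cur_t - prev_t) ** 2).sum(-1))
    log_t = model.log_density(delta.ravel()).reshape(n_frames - 1, n_slots, n_slots)
    if normalize:
        log_t = log_t - _scipy_logsumexp(log_t, axis=1, keepdims=True)
    return log_t


def _forward_all(log_e: np.ndarray, log_trans: np.ndarray) -> np.ndarray:
    """Forward recursion for all identities at once; shapes (T, N, Nid)."""
    n_frames = log_e.shape[0]
    log_alpha = np.empty_like(log_e)
    log_alpha[0] = log_e[0]
    for t in range(1, n_frames):
        # sum over previous slot j: alpha[t-1, j, n] + trans[t-1, i, j]
        log_alpha[t] = log_e[t] + _scipy_logsumexp(
            log_trans[t - 1][:, :, None] + log_alpha[t - 1][None, :, :], axis=1)
    return log_alpha


def _backward_all(log_e: np.ndarray, log_trans: np.ndarray) -> np.ndarray:
    """Backward recursion for all identities at once; beta_T = 1."""
    n_frames = log_e.shape[0]
    log_beta = np.zeros_like(log_e)
    for t in range(n_frames - 2, -1, -1):
        # sum over next slot j: beta[t+1, j, n] + e[t+1, j, n] + trans[t, j, i]
        inner = log_beta[t + 1] + log_e[t + 1]           # (N, Nid)
        trans_to_next = log_trans[t].T                   # [i_prev, j_next]
        log_beta[t] = _scipy_logsumexp(
            trans_to_next[:, :, None] + inner[None, :, :], axis=1)
    return log_beta


def forward_pass(emissions: EmissionTensor, tracks: TrackSet, model: MotionModel, identity: int,
                 normalize_transitions: bool = False) -> np.ndarray:
    """log alpha[t, i] for one identity (stabilized log-sum-exp recursion)."""
    log_trans = _log_transitions(tracks, model, normalize_transitions)
    return _forward_all(emissions.log_e[:, :, [identity]], log_trans)[:, :, 0]


def backward_pass(emissions: EmissionTensor, tracks: TrackSet, model: MotionModel, identity: int,
                  normalize_transitions: bool = False) -> np.ndarray:
    """log beta[t, i] for one identity; boundary beta_T(i) = 1."""
    log_trans = _log_transitions(tracks, model, normalize_transitions)
    return _backward_all(emissions.log_e[:, :, [identity]], log_trans)[:, :, 0]


def forward_pass_expspace(emissions: EmissionTensor, tracks: TrackSet, model: MotionModel,
                          identity: int) -> np.ndarray:
    """Textbook linear-domain forward recursion, kept as the reference that
    motivates the log-space implementation: on long sequences its values
    underflow to exact zero."""
    log_trans = _log_transitions(tracks, model)
    e = np.exp(emissions.log_e[:, :, identity])
    alpha = np.empty_like(e)
    alpha[0] = e[0]
    for t in range(1, e.shape[0]):
        alpha[t] = e[t] * (np.exp(log_trans[t - 1]) @ alpha[t - 1])
    return alpha


def posterior_marginals(emissions: EmissionTensor, tracks: TrackSet, model: MotionModel | None = None,
                        normalize_transitions: bool = False) -> PosteriorTensor:
    """Forward-backward posterior marginals for every identity.

    ``log_post[t, i, n] = log alpha_t(i) + log beta_t(i)`` per identity n,
    defined up to an additive constant over slots for each (t, n).
    """
    model = model or MotionModel.default()
    if emissions.n_frames != tracks.n_frames or emissions.n_slots != tracks.n_targets:
        raise ValidationError("emissions and tracks are not aligned")
    if tracks.n_frames == 1:
        la = emissions.log_e.copy()
        lb = np.zeros_like(la)
        return PosteriorTensor(la + lb, la, lb)
    log_trans = _log_transitions(tracks, model, normalize_transitions)
    log_alpha = _forward_all(emissions.log_e, log_trans)
    log_beta = _backward_all(emissions.log_e, log_trans)
    return PosteriorTensor(log_alpha + log_beta, log_alpha, log_beta)


def assign_identities(post: PosteriorTensor) -> IdentityAssignment:
    """Per-frame Hungarian assignment minimizing summed -log posteriors over
    slot<->identity bijections; ties break toward the lower slot index."""
    n_frames, n_slots, n_ids = post.log_post.shape
    if n_slots != n_ids:
        raise ValidationError("posterior must be square in slots x identities")
    out = np.empty((n_frames, n_slots), dtype=int)
    for t in range(n_frames):
        cost = -post.log_post[t]
        rows, cols = _tie_broken_assignment(cost)
        out[t, rows] = cols
    return IdentityAssignment(out)


def track_identities(
    frames,
    n_targets: int,
    scenario: str = "uninitialized",
    model: MotionModel | None = None,
    init: GroundTruthFrame | None = None,
    score_mode: str = "divide",
    emission_floor: float = 1e-6,
    normalize_transitions: bool = False,
) -> tuple[TrackSet, IdentityAssignment]:
    """Full pipeline: prune -> build tracks -> emissions -> smoothing -> assignment.

    ``scenario``:

    - ``"location"``: identities are the slot indices (no marker inference);
    - ``"initialized"``: first-frame annotations (``init``) pin identities;
    - ``"uninitialized"``: identities come from ear-tag sightings alone.
    """
    if scenario not in SCENARIOS:
        raise ValidationError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    if scenario == "initialized" and init is None:
        raise ValidationError("initialized scenario requires first-frame annotations")
    model = model or MotionModel.default()
    pruned = [prune_frame(f, n_targets, score_mode) for f in frames]
    tracks = build_tracks(pruned, n_targets)
    if scenario == "location":
        ids = IdentityAssignment(
            np.tile(np.arange(n_targets), (tracks.n_frames, 1)))
        return tracks, ids
    emissions = build_emissions(
        tracks, pruned, n_targets,
        init=init if scenario == "initialized" else None,
        floor=emission_floor)
    post = posterior_marginals(emissions, tracks, model, normalize_transitions)
    return tracks, assign_identities(post)
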