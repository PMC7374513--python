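# Methods

This note records the model assumptions, parameter choices, numerical
details and known limitations behind `pentrack`.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Problem setting and assumptions

A static overhead camera views the entire living space of a pen housing a
fixed, known number N of animals.  A per-frame detector supplies, for each
detected instance, paired shoulder/tail keypoints with scores in [0.25, 1]
(parts below 0.25 are not emitted) and *association estimates* — each part's
prediction of its partner's location, and of the left/right ear locations.
Ear tags, when visible, are classified into a probability vector over the N
housed identities; unreadable tags arrive as the uniform vector.  All
distances are in the pixel units of the input coordinates (the format's
optional `resolution` metadata documents the frame size; nothing rescales
internally).

Assumptions inherited from this setting: no births/removals mid-sequence
(fixed cardinality), frame rates high enough (≥ ~4 fps) that animals move
little between frames (stay-put motion), and identity information that is
sparse in time but individually unambiguous (unique tags).

## Fixed-cardinality track interpolation

When a frame holds more than N instances, the highest-cost ones are dropped.
The cost divides the normalized back-and-forth association error by the sum
of the part scores: scores at the 0.25 floor double the cost, scores of one
halve it.  (The alternative reading in which the score sum multiplies the
error is available as `score_mode="multiply"`; division is the default
because it makes low-confidence parts *more* expendable, which is the
behavior the pruning step needs.)

Two sweeps then force exactly N entries per frame.  Forward, each frame is
matched to the next by a Hungarian assignment on the pose displacement δ;
unmatched entries from the earlier frame are copied forward as duplicates.
The backward sweep mirrors this.  No gating distance is applied: with fixed
cardinality every chain must continue, so far matches are preferred over
dropped ones.  Assignment ties break toward lower original indices via a
lexicographic perturbation ≤ 1e−9 relative to the largest cost; reported
totals always use unperturbed costs.

Duplicates are replaced by time-weighted linear interpolation between the
nearest flanking genuine detections on their chain, or hold the nearest
detection at sequence boundaries.  One degenerate case is not covered by the
sweeps: if *no* frame ever reaches N detections, the sweeps produce
max_t(N_t) < N chains.  The builder then pads by cloning existing chains
(flagged duplicate throughout, never treated as evidence) so the
fixed-cardinality contract holds for any dropout pattern; a sequence with no
detections at all is an error.

## Marker fusion

An ear j and instance i are linked with probability
`max(1e−6, exp(−10 d))`, where d is the average of the two association
errors (ear's shoulder estimate vs the shoulder; instance's side-appropriate
ear estimate vs the ear) over twice their separation.  The floor keeps a
single over-confident mislink from zeroing a likelihood; a missing
association estimate falls back to the true partner coordinate, zeroing that
error term.

The identity likelihood of an instance multiplies, over *all* ears in the
frame, the link-weighted blend `p_link·tag + (1 − p_link)/N`, then
normalizes over identities.  Normalization makes the two limiting behaviors
exact — no linked ears → uniform, one perfectly linked confident ear → that
ear's tag vector — and renders the unlinked ears' near-constant factors
irrelevant, so no per-instance ear gating is needed.  Interpolated or
duplicated track entries receive uniform likelihoods: fabricated geometry
must not fabricate identity evidence.  All emission rows are floored at
1e−6 and renormalized before the log transform.

In the initialized scenario, first-frame annotations are matched to slots by
a Hungarian assignment on the pose error Δ and the matched rows are
overwritten with `1 − (N−1)ε` at the annotated identity (ε = 1e−6).

## Smoothing and assignment

For each identity independently, the occupied slot is a hidden Markov chain
over the N slots with transition weight p(δ) between slot positions in
adjacent frames, where p is the exponential mixture

| component | weight | rate λ | mean 1/λ (px) |
|-----------|--------|--------|---------------|
| stay-put  | 0.6    | 9/10   | 1.11          |
| walking   | 0.3    | 1/6    | 6             |
| running   | 0.1    | 1/30   | 30            |

(mean displacement 5.47 px/frame).  These defaults describe overhead pen
video at a few fps and a ~1000-px frame width; `fit_motion_model` re-estimates
them from observed displacements by EM (quantile-initialized, multi-restart,
seed-controlled) for other geometries.

Forward and backward recursions run in log space with max-shifted
log-sum-exp; transition log-densities are computed per mixture component as
`logsumexp_k(log w_k λ_k − λ_k δ)` so arbitrarily large δ stays finite.  The
backward boundary condition is β_T ≡ 1 (the recursion runs from t+1 to t, so
the terminal frame, not the first, is unconstrained).  Posterior marginals
α_t(i)·β_t(i) are defined up to a per-(frame, identity) constant; the
per-frame Hungarian assignment on −log posteriors is invariant to those
constants.  Transition densities are applied **raw**, without per-step
normalization over destination slots; constants shared across identities
cancel in the assignment.  `normalize_transitions=True` switches to a
row-stochastic kernel (see Limitations).

## Evaluation

A prediction matches when it and a ground-truth pose are mutually nearest by
Δ and Δ is strictly below that ground truth's shoulder-to-tail length — a
gate that adapts to animal size.  `location_id` additionally requires the
indices to coincide.  The gate is evaluated against the mutually-nearest
ground truth's own body length; argmin ties break toward lower index, and
mutual nearestness prevents double matches.  With exactly N predictions and
N annotations per frame, unmatched counts are simultaneously false positives
and false negatives, so precision = recall by construction.

## Synthetic scenes

The generator emulates the statistical structure the tracker assumes, not
images.  Defaults describe a 1024×576-px view of 16 animals of body length
60 ± 6 px.

* **Motion.**  Headings persist with wrapped-Gaussian turn noise
  (`turn_sd = (1 − persistence)·π`, persistence 0.97).  Each frame draws a
  pose displacement δ from the motion model and solves the centroid step
  exactly (δ² = m² + |m·u + w|², with w the tail shift induced by the body
  rotation), so the empirical δ marginal matches the mixture; turns whose
  tail swing alone would exceed the drawn δ are capped at
  2·arcsin(δ/2L) — a sharp turn takes several frames.  Blocked steps steer
  toward the pen center; only the rare clip of a huge step distorts δ.  An
  optional `pile` attractor draws animals together to reproduce prolonged
  proximity.
* **Detector corruption.**  Per-animal dropout, Poisson false positives
  (low scores, inflated association noise — exactly what the pruning cost
  penalizes), occasional shoulder/tail reversal (association estimates stay
  consistent with the reversed pose, as a confused detector's would),
  Gaussian noise on association estimates, part scores decreasing in the
  applied noise.
* **Tag classifier.**  Visible ears report the confusion-matrix row of the
  true identity — near-one-hot when readable (day accuracy 0.95) — or the
  uniform vector with `unknown_tag_prob`, mirroring a classifier trained
  toward one-hot/uniform targets.  Ear visibility is a rare per-frame event
  (presets: 0.008–0.012 day, 0.0025–0.003 night per ear), making identity
  evidence sparse and intermittent; night presets are also more confused
  (accuracy 0.8) and more often unreadable (unknown 0.6), with higher
  detector dropout.

What the generator does **not** emulate: persistent activity states (steps
are drawn i.i.d. per frame, so animals alternate resting/walking faster
than real ones), occlusion structure (dropout is independent, not
proximity-driven unless `pile` is set), image appearance, and camera
distortion.  Passing tests therefore demonstrate the estimation machinery
under the assumed statistics, not detector performance on real video.

## Numerical and design choices

* Seeded `numpy.random.Generator` everywhere; identical config + seed gives
  byte-identical outputs.
* Hungarian tie-breaks: lexicographic perturbation toward lower indices,
  magnitude ≤ 1e−9 of the largest cost entry.
* Pruning ties keep the earlier-listed instance (stable sort).
* EM refit: K = 3 components by default, quantile-based rate initialization
  with 5 jittered restarts, keeping the highest log-likelihood; components
  reported sorted by decreasing rate.
* Degenerate inputs: coincident shoulder/tail (undefined cost
  normalization), coincident ear/shoulder, zero-length annotations, empty
  sequences and non-bijective assignments all raise validation errors.

## Limitations

* **Independent per-identity chains.**  The smoothing treats each identity's
  slot chain independently; mutual exclusion is only restored by the final
  per-frame Hungarian step.  Slots in dense neighborhoods absorb posterior
  mass from several identities; the shared part cancels in the assignment,
  but identity-specific transients (e.g. a first-frame pin) can leak across
  chains at close encounters.
* **Raw transition densities.**  With unnormalized densities, a chain's
  per-step self-weight depends on how far it moved (p(0) ≈ 0.593 at rest vs
  ~0.03 at a 6-px step), so identity evidence decays off fast-moving chains
  between sightings.  Under sparse tag glimpses this lowers identity scores
  noticeably; `normalize_transitions=True` removes the effect and raises
  identity precision substantially in the sparse-sighting presets, at the
  cost of departing from the raw-density formulation that is the default
  here.  The acceptance script and tests run the default.
* **Per-frame assignment.**  Nothing smooths the final assignment itself, so
  physically discontinuous identity flips between adjacent frames are
  possible when marginals are near-uniform.
* **Scaled-down analogues.**  Scenario scores in the tests and acceptance
  script use N = 8, T = 300 (and N = 16, T = 3000 for the noiseless check) —
  sizes chosen so the whole suite runs comfortably on one CPU; they mirror
  the qualitative scenario ordering (location ≥ initialized ≥ uninitialized;
  night ≤ day), not any particular absolute score from full-length video.
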