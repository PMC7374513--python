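# pentrack

Long-term tracking of a **fixed, known number of animals** (group-housed
livestock under an overhead camera) from imperfect per-frame keypoint
detections, with individual identification from intermittent ear-tag
sightings.

Animals in a pen never enter or leave, so exactly N targets exist in every
frame even when a detector misses some and hallucinates others.  `pentrack`
exploits that constraint to build N continuous tracks, then recovers *which
animal is which* by probabilistic smoothing over the whole video — useful for
animal-science and precision-livestock work where months-long individual
activity records matter and the animals themselves are visually
indistinguishable apart from their ear tags.

## Method

Input per frame t: detected instances `x_i^t = {s_i^t, t_i^t}` (shoulder and
tail pixel coordinates with part scores and association estimates), plus ear
observations with a classifier probability vector `p(e_j^t -> {1..N} | I_t)`
over the N housed identities.

1. **Fixed-cardinality track interpolation.** Frames with more than N
   instances are pruned by the confidence cost

       C(x) = (|(t->s) − s| + |(s->t) − t|) / (2 |s − t| (score_s + score_t)),

   zero when the detector's back-and-forth association estimates are exact.
   A forward and a backward sweep link frames with minimum-cost bipartite
   (Hungarian) assignment on the pose displacement
   `δ(a,b) = sqrt(|s_a − s_b|² + |t_a − t_b|²)`, duplicating any entry left
   unmatched into the neighboring frame; duplicates are then replaced by
   time-weighted linear interpolation between their flanking detections.
   The result is exactly N linked chains spanning all T frames.

2. **Marker fusion.** Each ear is softly linked to each instance through the
   normalized back-and-forth shoulder↔ear distance d, with link probability
   `max(1e−6, exp(−10 d))`; an instance's identity likelihood is the product
   over ears of `p_link · tag + (1 − p_link)/N`, normalized over identities.
   Interpolated entries carry uniform likelihoods.

3. **MAP identity estimation.** For each identity, the occupied slot over
   time is smoothed by the forward–backward algorithm under a "stay-put"
   motion model — a three-component exponential mixture over δ,
   `p(δ) = 0.6·(9/10)e^{−9δ/10} + 0.3·(1/6)e^{−δ/6} + 0.1·(1/30)e^{−δ/30}` —
   computed entirely in log space (max-shifted log-sum-exp), so chains of
   tens of thousands of frames never underflow.  A per-frame Hungarian
   assignment on the negative log posterior marginals yields one identity
   per track slot per frame.

4. **Evaluation.** Predictions match annotations when mutually nearest by
   the pose error `Δ = |s̄ − ŝ| + |t̄ − t̂|` within the annotated
   shoulder-to-tail body length — with (`location_id`) or without
   (`location`) requiring the labels to agree.  With fixed cardinality,
   false positives equal false negatives, so precision = recall.

Three scenarios mirror common deployments: `location` (poses only),
`initialized` (first-frame identities annotated), `uninitialized`
(identities from tag glimpses alone).  A seeded synthetic scene generator
(`pentrack.synthetic`) emulates the detector and tag classifier —
exponential-mixture step lengths, dropout, false positives, shoulder/tail
reversal, association noise, intermittent near-one-hot tag sightings — so
the whole pipeline is testable without video.

## Worked example

```bash
pentrack simulate --preset day_medium --n 8 --frames 300 --seed 7 --out demo
pentrack track --detections demo/detections.jsonl --n 8 \
         --scenario uninitialized --out demo
pentrack evaluate demo/gt.csv demo/tracks.csv --mode location
pentrack evaluate demo/gt.csv demo/tracks.csv --mode location_id
```

prints

```
wrote demo/detections.jsonl and demo/gt.csv (N=8, T=300)
wrote demo/tracks.csv (300 frames x 8 tracks, 7.2% interpolated)
mode=location  frames=300  targets=8
TP=2332  FP=68  FN=68
precision=0.9717  recall=0.9717
mode=location_id  frames=300  targets=8
TP=1043  FP=1357  FN=1357
precision=0.4346  recall=0.4346
```

Reading: of the 2400 animal-frames (8 animals × 300 frames), 97.2% of poses
are tracked within a body length (`location`); 43.5% additionally carry the
correct individual identity (`location_id`) — the `day_medium` preset gives
each animal only a handful of readable tag glimpses in a 300-frame clip, so
many identities remain uncertain, and supplying first-frame annotations
(`--scenario initialized --init demo/gt.csv`) or processing longer sequences
raises the identity score.  The same pipeline is available from Python via
`pentrack.simulate`, `pentrack.track_identities` and
`pentrack.precision_recall`.

## Layout

- `src/pentrack/io.py` — data model, JSON-lines detections, CSV tracks/annotations
- `src/pentrack/tracks.py` — pruning, duplication passes, interpolation
- `src/pentrack/markers.py` — ear→instance linking, emission tensor
- `src/pentrack/motion.py` — exponential-mixture motion model and EM refit
- `src/pentrack/inference.py` — forward–backward smoothing, identity assignment
- `src/pentrack/evaluation.py` — mutual-nearest matching, precision/recall
- `src/pentrack/synthetic.py` — seeded scene generator and scenario presets
- `src/pentrack/cli.py` — `pentrack simulate | track | evaluate | fit-motion-model`
- `docs/methods.md` — modeling assumptions, parameters, numerical choices
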