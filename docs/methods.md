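# Methods

This note documents the models, parameter choices, and numerical
conventions behind `calcistream`, and what the synthetic benchmarks do and
do not establish about real recordings.

## Processing model and assumptions

The pipeline assumes 8-bit grayscale frames on a 512×512 working
subwindow (geometry configurable), rigid integer-pixel image motion, and
calcium traces that are *sums* of pixel intensities over fixed ROIs — no
source demixing, because demixing is acausal and a real-time path cannot
use it. Causality is structural: `FrameProcessor.push` consumes one frame
at a time and is bit-identical to batch processing (tested), and the
displacement estimate for a frame uses only that frame and a template
frozen at the end of the reference epoch.

### Stage 1 — stabilization

* Contrast kernel: the size (17×17) is fixed but the kernel shape was an
  open choice; we use a difference-of-Gaussians approximation to a
  Laplacian-of-Gaussian with σ = size/8 and the conventional 1.6 ratio,
  renormalized to sum exactly to zero so constant regions respond with 0.
* Correlation is zero-padded (linear, not circular); the argmax is taken
  over a ±16-pixel search radius (default; real shifts of interest are
  ~10 px). Ties break toward the smallest |Δx|+|Δy|, then smallest Δy,
  then Δx — determinism matters more than which tie wins.
* Displacements are integer-pixel only. Subpixel interpolation would
  complicate exact ground-truth checking and the downstream thresholds
  (e.g. the 4-pixel rule in the artifact score) are integer-valued anyway.
* Frames inside the reference epoch receive displacement (0, 0) flagged
  low-confidence: no template exists yet, and the protocol assumes the
  subject is quiescent during this period.
* Correction translates by (−Δx, −Δy) with zero fill; the vacated border
  is why border tiles are excluded from trace extraction.

### Stage 2 — enhancement

Smoothing (3×3 mean) precedes background estimation (opening with a flat
19×19 square) precedes subtraction; the order is fixed. The structuring
element shape was unspecified by size alone; a flat square is the
hardware-natural choice and makes the opening separable. Both filters
replicate edges — zero padding would create dark rims that leak into
border ROIs. The result is clipped to [0, 255] to match sensor depth
(the drop filter's G = 255 presumes it).

Invariants relied on downstream and tested: enhanced ≥ 0, enhanced ≤
smoothed (anti-extensivity), and idempotence of the background operator.

### Stage 3 — traces

* Tile geometry: 512/16 = 32 per side; the 124 perimeter tiles are
  excluded (4·32 − 4), leaving 900 ROIs in raster order.
* Contour masks are ingested (from an external segmentation or from
  synthetic ground truth); pixels outside the 25×25 bounding square
  centered on the mask centroid are discarded with a warning.
* Drop filter: δ = G·C·q read literally as a product (G = 255, q = 0.9,
  applied only when C < 50). Note the magnitude: for C = 10, δ = 2295,
  which only arrests near-total single-frame drops. The recursion is
  initialized F(0) = T(0) (no prior frame exists).
* Spike inference uses a strict `>` at the threshold (determinism at the
  boundary) and suppresses events for traces whose training SD is zero.
  The default output is a binary event per frame; a count mode
  floor(max(0, ΔT)/Φ) is available but decoding uses raw traces by
  default — raw amplitudes carry more information than thresholded
  events, and they are cheaper.

### Stage 4 — decoding

* Gray code: row m is +1 for bins b with ((b − m) mod K) < K/2. This is
  the natural M = K/2 cyclic code; the single-bit adjacency property is
  validated exhaustively for all even K ≤ 64.
* Base learner: L2-regularized linear SVM (squared hinge, primal
  coordinate solver — deterministic), inputs standardized per unit,
  C = 1.0. The choice of base learner was open; any regularized linear
  unit with a real-valued margin works, and the codeword match uses the
  margins (not hard signs) so "closest codeword" degrades gracefully.
* Ties in the codeword match go to the lowest bin index; all-zero outputs
  therefore decode to bin 1.
* Behavior tree, most-frequent-category-first: intertrial vs rest, then
  pre-trial, then reward retrieval, then correct vs incorrect choice
  (topology configurable). A node whose training subset contains one
  class becomes a constant node with a warning.
* Label smoothing: causal mode over the trailing 5 frames, shortened at
  the series start; ties go to the most recent raw label among the tied.
* No speed filtering is applied anywhere in the position path.
* Splits: first half / second half of frames for position; for behavior,
  a frame split at 2/3 of the session stands in for the
  train-on-100/test-on-50-trials protocol at desk scale.
* Circular-shift control: traces rolled against position by
  500…2500 frames before training, tested on aligned pairs, accuracies
  averaged over the five shifts.

### Metrics

* λ uses circular distance between bin centers on the 2L = 500-cm
  circularized loop. The alternative (folding back to physical track
  distance) would make errors between opposite running directions at the
  same place count as zero; the decoder's target space is the
  circularized loop, so distances live there too.
* ρ counts λ ≤ 30 cm; with 20.8-cm bins that admits the true bin and one
  neighbor each side (3 of 24 bins ⇒ ~12.5% chance).
* S and Ω share the transform −log₁₀(P)·sign(R) with Pearson P from the
  t-distribution with n−2 df; P is clamped at 1e−300 to keep scores
  finite. Ω restricts frames to position bins whose maximum displacement
  exceeds 4 pixels — elsewhere artifact could not have acted and the
  frames only dilute the correlation.
* Event metrics: an event counts as predicted if ≥ 1 frame in its window
  carries the event label; precision is the fraction of predicted event
  windows overlapping a true window; F = 2PS/(P+S), defined 0 when S = 0.
  Frame-level sensitivity/precision are reported alongside. The null
  permutes window labels among windows (window boundaries fixed), seeded.
* The displacement-parity probe compares median displacement between
  correctly and incorrectly classified *frames* within event windows
  (one-sided rank-sum); when either side is empty the gap is defined as 0
  — no motion-selective prediction is demonstrable.

### Latency model

τ_L = I/2 (boxcar light integration — verified by simulation: the
cross-correlation between a band-limited signal and its frame-binned
version peaks at I/2 within one sample); τ_T = P·C with
P = W(B−1)+R under 1-based row/column indexing (the convention under
which the 608×608 worked example is self-consistent: B = R = 560,
P = 340,432); τ_I = 0.888 ms + 47.3 µs per output unit. The intercept
and slope are configuration defaults from a measured hardware fit, not
quantities this software measures. Exposure is I − 1 ms (A/D overhead).
The worst-case budget replaces mean τ_I with its 2.5-ms distribution
bound; at 20 Hz this gives 25 + 20.5 + 2.5 ≈ 48 ms, conventionally
quoted as 47.5 ms with the transmission delay at its nominal 20 ms.
Values are rounded to 0.1 ms only at presentation.

## Synthetic sessions: what they emulate, and what they don't

The generator produces the statistical structure each stage assumes:

* **Trajectory**: alternating constant-speed runs (50 cm/s default,
  capped at 150 cm/s) with end-of-track dwell and optional multiplicative
  speed jitter; 24 circularized bins, 12 per direction.
* **Cells**: truncated-Gaussian footprints (radius 6 px, σ = radius/2),
  Gaussian place tuning (σ = 12 cm) with direction preference, amplitude
  60 intensity units; calcium follows drive instantly upward and decays
  at 0.5^(1/(0.7 s · fps)) per frame.
* **Background**: low-order 2D polynomial plus *static smooth texture*
  (Gaussian-filtered noise, SD 15 units at 2.5-px correlation length).
  The texture stands in for vessels and neuropil; without static
  anatomical structure a contrast filter sees only the time-varying
  cells and template registration is ill-posed.
* **Motion**: integer-pixel rigid translation only — persistent shift
  events and transient jitter events that return to baseline. Integer
  shifts make recovery exactly checkable.
* **Noise**: additive i.i.d. Gaussian (σ = 2), clipped with the frame to
  0..255; a saturation fraction above 1% logs a warning.
* **Behavior mode**: five mutually exclusive categories; pre-trial is a
  1-s window before the center touch, choices span touch-to-touch,
  reward retrieval is a 2-s window from magazine entry, and a uniform
  0.5–3-s magazine travel delay separates choice from reward (so reward
  onset is not a fixed latency after choice). The intertrial interval
  (6 s) is deliberately longer than all event categories combined, as in
  the task emulated, so "no event" is the majority state. Reward-locked
  jitter (2–5 px, 60% of rewards, spanning the retrieval window) models
  brain motion while the animal works the magazine. Cells are
  category-tuned with additive drive noise; options add representational
  drift (linear per-cell gain ramp) or restrict which categories are
  encoded.

Not modeled: optical PSF, photobleaching, non-rigid deformation, spiking
biophysics, and quantitative in-vivo noise statistics (none are
published for this preparation; defaults were chosen for testability).
Passing tests therefore establish *algorithmic* correctness — exact
displacement recovery, decoder recovery of generative structure, correct
statistics — not in-vivo performance figures. In particular, decoding
accuracies on synthetic sessions (often perfect) exceed what real
sessions yield.

## The benchmark experiments (`calcistream.experiments`)

* `position_decoding_experiment` — 8000 frames (a ~7-minute session at
  20 Hz), 50 cells, trace-level (ground-truth traces + σ = 3 noise stand
  in for extracted traces, isolating the decoder from rendering error).
  Expected: median λ under one bin width; circular-shift control near
  the ~12.5% chance hit rate.
* `shift_recovery_experiment` — 260 rendered 512×512 frames with ~15
  random jitter events (±8 px) and one persistent shift; expected 100%
  exact recovery after the 50-frame reference epoch.
* `motion_artifact_experiment` — the ersatz-decoding demonstration, in
  an isolation design: cells encode pre-trial and choice but *not*
  reward, and the magazine delay (2.5–6 s) outlasts the indicator decay
  so no calcium signal marks the reward window. The motion-only (Mot)
  predictor then decodes reward events above its label-shuffle null
  (25-trial unrendered session; event statistics need that many events),
  and on a 15-trial rendered session the trace decoder trained without
  motion correction predicts exactly the high-displacement reward frames
  (positive gap, rank-sum p < 0.05) while correction abolishes the
  motion-selective predictions and restores parity. The isolation is
  deliberate: with category-tuned reward cells the calcium signal
  saturates event prediction and leaves no room to observe the artifact
  pathway.

## Numerical conventions and degenerate inputs

Displacement sign: (Δx, Δy) is the motion of image content relative to
the template (columns, rows); correction translates by the negation.
Textureless stabilization windows return (0, 0) flagged low-confidence.
Constant traces yield Φ = 0 with events suppressed and degenerate tuning
curves flagged; zero-variance curves make S missing (NaN) rather than 0.
Bins with no qualifying displacement make Ω missing. Empty contour labels
are skipped with warnings. All generators and fits take explicit seeds;
the SVM solver is deterministic.

## Known limitations

* Rigid integer translation cannot represent rotation, scaling, or
  non-rigid tissue deformation; residual subpixel motion is invisible.
* Trace sums are not demixed, so overlapping sources mix — by design for
  the contour-free path, a caveat for single-cell interpretation.
* The drop filter's literal δ = G·C·q is enormous for mid-sized masks
  and effectively inert except against near-total drops.
* The latency model's processing-time coefficients are fixed constants
  from an external hardware characterization; the package does not
  benchmark wall-clock latency.
* The behavior-session generator's timing is scaled down (shorter
  intertrial intervals, fewer trials) relative to a 45-minute in-vivo
  session; event statistics at this scale have few events per test
  epoch, which is why the Mot probe uses a longer session.
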