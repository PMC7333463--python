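# Methods

califlow is a dataflow-structured pipeline for real-time neuron detection
and calcium-signal extraction from miniature two-photon imaging video,
together with a ground-truthed simulator and an evaluation harness. This
note documents the models, the numerical choices, and what the synthetic
data does and does not establish.

## Dataflow runtime

The processing chain is expressed as a dataflow graph: actors (Motion
Correction, Preprocessing, Neuron Detection, Signal Extraction, plus
ImgSrc, Fork and SetParams) connected by FIFO edges whose tokens carry
*references* to frames and matrices, never pixel copies. An actor fires
only when every input edge holds at least its declared consumption count;
an edge may carry initial tokens ("delays"). The scheduler is
single-threaded and demand-driven: each graph iteration fires the sources
once, then repeatedly fires the most downstream enabled actor until the
graph is quiescent. Any admissible schedule would do; this one is simple
and deterministic. Token conservation (enqueued − dequeued + delay =
occupancy) is asserted after every firing.

Parameter adaptation uses a two-graph arrangement: a *subinit* graph
computes parameter values and a *body* graph does the per-frame work. Each
captured subinit output port is bound at construction time to one or more
(actor, parameter) targets in the body graph; one subinit iteration runs,
the bound values are pushed, then the body iterates once per frame. In
real-time operation the body iteration count equals the number of analysis
frames, so the subinit is effectively disabled for the run. Bindings are
the only channel through which calibration results reach the detector;
this is asserted in an integration test by inspecting the run log.

Actor state (the motion-correction reference frame, the persistent
detection matrix, baseline windows) is held inside the actor objects, the
standard equivalent of modeling state as self-loop edges.

## Simulator

The generator emulates two-photon calcium imaging of a small cortical
population:

- **Spiking.** 100 leaky integrate-and-fire neurons, Euler-stepped once
  per frame: `V += (V_rest − V)/λ + θ·λ·(−0.5)·ε`, with ε standard normal
  (the noise term's fixed sign is immaterial because ε is symmetric). A
  neuron fires when V exceeds threshold, resets to rest, and is refractory
  for 5 frames. Group A (40% of neurons) receives external stimulus events
  (Bernoulli, p = 0.02/frame, each adding the synaptic weight w = 0.2);
  each group B neuron has one or two group A parents whose spikes add w
  per parent one frame later. Constants not fixed by the source design:
  V_rest = 0, V_threshold = 1, λ = 10 frames, θ = 0.065 — θ was calibrated
  once so that the group A baseline rate is ≈2% per frame; all are
  configurable.
- **Rendering.** Each neuron has a connected, roughly elliptical binary
  mask (mean bounding size ≈ 6.84 × 6.76 px on a 400×400 grid, matching
  the mask statistics of the reference data). Mask pixels jump to
  intensity 128 at spike frames and decay by 2^(−1/8) per frame (half-life
  8 frames, a fast GCaMP indicator at ~30 Hz). Overlapping masks combine
  by per-pixel max, which preserves the "set to 128" semantics. Mask
  centers keep ≥12 px spacing so that two true neurons can never fall
  within the detector's 10 px cross-threshold merge distance — the
  regime in which the reference mask set achieved full detection.
- **Burn-in.** The network and the fluorescence decay run for 100 unused
  pre-roll frames so frame 0 is statistically stationary, as in a
  recording that starts mid-activity. Without this, frame 0 is empty and
  the motion-correction reference has no content to anchor to.
- **Motion.** Per-frame rigid motion: translation uniform in ±10 px per
  axis (±3 for the "small" drift regime, ±[7,10] for "large", and a 1
  px/frame rectangular-perimeter path for "constant" drift), plus, with
  probability P_rot %, a rotation uniform in ±α_rot about the image
  center (bilinear, zero fill). Frame 0 is left unmoved: the correction
  reference initializes from the first frame, so estimates are only
  comparable to ground truth when the initial reference sits at the true
  pose. The ground-truth track is recorded per frame.
- **Noise.** Two additive zero-mean fields: white "shot" noise
  (σ = s × 1.0, i.i.d. per pixel and frame) and temporally autocorrelated
  "colored" noise (per-pixel AR(1), coefficient 0.8, innovations scaled so
  the marginal σ = c × 0.4). Labels `sNNcMM` encode tenths of the base
  sigmas (s03c05 → s = 0.3, c = 0.5). Output is clamped to [0,255] and
  quantized to 8 bits.
- **Silent-neuron control.** `n_silent = k` forces exactly k neurons
  silent (they can never fire) and guarantees every other neuron spikes at
  least once in the recorded window (a neuron that happened not to fire
  receives one spike at a random frame), reproducing the k-inactive
  configuration deterministically for a fixed seed.

Everything is driven by a single seed through split `SeedSequence`
streams; a bundle is bit-exactly reproducible from (config, seed).

What the simulator does *not* emulate: neuropil contamination, one-photon
background haze, photobleaching, non-rigid deformation, realistic PSF
blur, or correlated network states beyond the two-group feed-forward
drive. Passing tests on this data show the pipeline's mechanics are
correct under the stated conditions; they do not certify accuracy on real
recordings.

## Motion correction

Rigid, translation-first, with selective rotation:

1. **Estimation.** Frames are downsampled by a factor of 2 per axis (the
   quarter-pixel-count operating point; the description of the original
   implementation gives an internally inconsistent 1.67, which is also
   available by configuration). A windowed FFT cross-correlation
   (|shift| ≤ 30 px by default) proposes candidate translations — the top
   three surface peaks are disambiguated by actual frame correlation,
   because sparse blob fields can produce a spurious strongest peak — and
   an enhanced-correlation-coefficient (ECC) iteration refines the warp to
   sub-pixel accuracy (≤50 iterations, stop when the coefficient changes
   by <1e-4). For the Euclidean model a coarse sweep over rotation angles
   (±8° in 1.5° steps, each with its own translation estimate) seeds the
   ECC refinement of (tx, ty, θ). Estimation never modifies frames;
   corrections are applied at full resolution with bilinear interpolation
   and zero border fill.
2. **Gating.** The translation-only correction is accepted when its
   full-resolution Pearson correlation with the reference frame reaches
   τ₁; otherwise the Euclidean estimate is attempted and gated by τ₂.
   Each τ = mean − p·σ over the 100 most recent accepted correlations
   (p₁ = 2, p₂ = 10), clamped from below by per-gate floors (0.6 / 0.55)
   that also serve during warm-up. The clamp matters: with p = 10 the raw
   threshold goes negative as soon as the history has variance, and a
   gate below ~0.5 accepts wrong warps that permanently poison the
   reference pose. Estimates outside the admissible bounds (|t| > 30 px,
   |θ| > 9°) are rejected regardless of correlation.
3. **Reference update and failure.** Every accepted corrected frame
   replaces the reference; a frame failing both gates is replaced by the
   reference and logged ("motion correction failed at frame k"). Failed
   frames push nothing into the correlation history and are excluded from
   error averages.

Because the reference is replaced on every acceptance, per-step estimation
error accumulates as a slow random walk of the reference pose; with
sub-0.1 px per-step accuracy this stays within a fraction of a pixel over
1,800-frame runs, which is what the ≤1 px mean displacement error
criterion measures. On low-content frames (few visible neurons) the gates
deliberately fail frames rather than risk mis-correction.

## Preprocessing

For detection only (signal extraction always reads the unpreprocessed
corrected frame): 3×3 Gaussian smooth → 3×3 median filter → subtraction of
a wide Gaussian low-pass background estimate (kernel 31; removes the
diffuse glow of deep, out-of-focus neurons), clamped at 0 → min-max
normalization `(I − I_min)·255/(I_max − I_min)`, evaluated ratio-first so
the output range is exactly [0, 255]; a constant frame maps to zeros. The
stage order is a package choice (the source description lists the
components without an order); histogram equalization is deliberately not
used — the printed normalization formula is the specified "equalization".

## Neuron detection

Multi-threshold blob detection. The frame is binarized at every level from
0 to 255 in `threshold_step` increments using ≥-threshold semantics (so
the level-0 binarization is the whole frame — one giant component removed
by the area filter — rather than a speckle field of exact-zero background
pixels). Connected components (8-connectivity) at each level are filtered
by area [A_min, A_max] and by shape: circularity 4πA/P² ≥ 0.5 with a
city-block perimeter scaled by π/4, inertia ratio (minor/major second
moment) ≥ 0.3, and convexity (area / pixel-corrected convex-hull area)
≥ 0.5, the hull test running only for components below 0.8 circularity.
Components surviving at different levels whose running-mean centers lie
within `min_dist = 10` px merge into one blob (center = mean of member
centers, radius = furthest-pixel distance of the largest member); blobs
seen at fewer than 2 levels are discarded as single-level noise. For
speed, levels above the second are evaluated only inside masked windows
around each second-level component — exact, because higher-level
components nest inside lower-level ones.

Training mode accumulates the persistent detection matrix δ_p: a per-frame
detection within d = 2 px (per axis) of a known row is a repeat; anything
else is appended as a newly discovered neuron. Real-time mode emits the
frozen training matrix (the neuron set and its ordering are fixed);
per-frame detection still runs for diagnostics, and a flag can re-enable
accumulation.

## Parameter calibration (SetParams)

Pre-initialization from a rough neuron radius r̂: A_min = π(r̂/2)²,
A_max = π(2r̂)², threshold step 10. Calibration then runs detection over
the training frames and, while the cumulative distinct-neuron count is
below the target T_n = 5, loosens one step at a time (A_min ×0.8,
A_max ×1.25, step ×0.8 with floor 1; ≤20 iterations). Loosening rather
than tightening is the right direction: starting loose admits early false
positives into the persistent matrix, which the accumulation rule can
never remove.

## Signal extraction

Per neuron i, the ROI is the circle from δ_p row i. The signal is
β[i] = (F_i − F0_i)/F0_i with F_i the mean over pixels whose centers fall
in the circle. F0 is a rolling baseline: the mean of the W = 50 preceding
ROI means, excluding window frames whose ROI mean exceeded 3× the window
median (so calcium transients do not inflate the baseline); below a floor
of 1 intensity unit β is defined as 0 — both a divide-by-zero guard and
the natural value on the simulator's dark background. A neuron
contributes 0 before its first discovery. The anchoring of F0 to a fixed
experimental event in the cited baseline method has no analogue in
continuous operation; the rolling window is the substitute.

## Evaluation

- **Motion:** per-frame |Δtx|, |Δty|, |Δθ| against the injected track over
  non-failed frames; failure rate as a percentage of all frames.
- **Detection:** greedy one-to-one matching of detected circles to truth
  masks (candidate when the center lies inside the mask, consumed
  nearest-centroid-first); pixel-level precision (matched pixels / circle
  pixels, pooled over all detections) and recall (matched pixels / mask
  pixels, pooled over all masks), F1 = 2uv/(u+v); detection rate =
  matched active neurons / active neurons. Per-neuron averaging is
  available by flag.
- **SNR:** R_s = mean Pearson correlation between each detected neuron's
  β trace and its ground-truth spike train. The null redraws, per neuron
  and per repetition, a random circle of that neuron's radius that
  overlaps no truth mask at all (spike trains are correlated across the
  simulated network, so a region carrying even a sliver of another
  neuron's mask is not a genuine null; a ≤20% overlap allowance is
  available by argument); its β (plain rolling-mean baseline —
  null regions contain no transients, and the vectorized form makes 97,000
  draws affordable) is correlated with the neuron's spike train;
  R_n is the grand mean over 1,000 repetitions, computed efficiently by
  convolving each frame with the ROI disk once so any center's trace is a
  single gather. SNR = 10·log₁₀(R_s/R_n). R_n is a near-zero null: its
  sampling fluctuation (≈1/√T /√(1000·ν)) dominates the variance of the
  dB value, which is why the SNR check carries a wide tolerance while the
  hard property is the ≥3-orders-of-magnitude separation.

## Problem sizes used in the checks

The acceptance harness regenerates everything from scratch: the
nine-noise-configuration detection sweep runs a 400-frame version of each
1,800-frame setting (the detection-rate numerator counts only neurons that
actually fired, and every firing leaves ~50 frames of visible
fluorescence, so the frame count does not bias the rate); the test suite
uses 300 frames per configuration. The silent-neuron/SNR dataset keeps
its full geometry, with 1,800 frames in the harness and 1,200 in the test
suite — trace length is the one axis that materially tightens the null.
Grid size, neuron count, motion, and noise settings are never reduced:
detection-gate stability depends on frame content density, so shrinking
the field of view changes the problem, while shortening it does not.

## Known limitations

- Rigid correction only; no affine/homography or piecewise models.
- The reference-replacement policy makes long-run accuracy a slow random
  walk; an anchored or exponentially averaged template would remove the
  drift but departs from the specified actor design.
- Overlapping neurons are not demixed; the detector reports circles, not
  segmentation masks.
- The correlation gates presuppose content-rich frames; on very sparse
  fields (few visible neurons in a large field of view) frames fail — by
  design — rather than risk reference poisoning.
- No neuropil correction or spike deconvolution.
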