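# Methods

## Morphological model

All operators are grayscale morphology with *flat 1D* structuring elements
(SEs).  Erosion/dilation of a row f by a line SE of length L are the
sliding-window minimum/maximum over the SE domain intersected with the row:
positions outside the image contribute nothing — no padded values are
invented.  The line SE anchor is centred; even L anchors at index L//2.
Dilation uses the same (unreflected) window as erosion, so the duality
dilate(f) = −erode(−f) holds identically; the opening reflects the
dilation anchor internally so it is a true opening (anti-extensive and
idempotent) for even L too.  The implementation is the two-pass block
prefix/suffix (van Herk / Gil–Werman) scheme, O(1) comparisons per pixel;
its correctness is defined by — and tested against — a brute-force window
scan and scipy's nearest-padded 1D rank filters, which coincide with
clipped windows because every window contains its own edge pixel.

Width selectivity follows directly: a flat plateau of width K vanishes
under line erosion iff L > K (tested exhaustively for K, L ≤ 12), so an
opening with K < L < K_l estimates a background containing every structure
wider than L and none narrower.  Pair SEs span two adjacent pixels along
one axis, anchored at the first pixel; erosion clears a pixel whose
partner is outside the image (zero padding), so single-pixel noise is
removed at borders too, and the conditional recovery restores genuine
target pixels clipped this way.

## Detection chain

Stages 1–10 are described in the README.  Design points that were
genuinely open:

* **Threshold (step 4).**  Two policies: absolute T, and per-row adaptive
  T = µ + k·σ of the enhanced row (default k = 5).  Adaptive is per-row —
  not per-image — so batch and streaming remain exactly equivalent.  An
  all-zero row segments to an empty mask under either policy.
* **Recovery (steps 7–9)** is two pair-SE dilations (reverse order of the
  erosions) intersected with the step-4 mask.  Algebraically the composite
  of the two erosions and two conditioned dilations equals a binary
  opening by a 2×2 block: components that are unions of 2×2 blocks pass
  through unchanged (property-tested); shapes thinner than 2 pixels
  anywhere lose those protrusions (a 5-pixel "plus" dies entirely, a
  thresholded-Gaussian diamond loses its four tips, symmetrically).  The
  conditioning guards against any recovery variant re-admitting erased
  noise or bridging neighbours; for these exact SEs it is a provable
  no-op, and it is kept for faithfulness to the staged hardware design.
* **Labeling (step 10).**  A pixel (i, j) joins any labeled pixel in
  (i−1, j−m..j+n) ∪ (i, j−p..j+q); defaults m = n = 1, p = 1, q = 0 give
  8-connectivity with one row of memory.  The minimum candidate label wins
  and equivalences are merged by union-find, so the in-row term acts
  symmetrically with reach max(p, q).  A component finalizes as soon as a
  full row passes without extending it — with m, n ≤ 1 that is the row
  after its last active row — and at end of image all open components
  flush.  The streaming engine additionally emits early when the upcoming
  step-4 mask is provably empty over a component's reachable column
  window; the emitted records (labels, pixels, centroids, finalize rows)
  are identical to batch processing, which a 1000-scene fuzz corpus
  asserts.
* **Centroiding.**  Sub-pixel position is the weighted mean of member
  pixel coordinates with weights = enhanced value **minus the applied row
  threshold** (the thresholded centre of gravity of star centroiding).
  With raw enhanced weights, near-threshold pixels flicker in and out of
  the mask between frames and each carries its full weight, which
  dominated the scatter (~0.03 px, erratic in T, for the static test);
  margin weights give a stable 0.012–0.018 px across thresholds.  Records
  still carry enhanced intensities, and `weighted_centroid` implements the
  plain enhanced-intensity mean.

## Hardware state and latency model

The streaming state is the sum of: two gray FIFOs of depth L (erosion,
dilation), a gray synchronization delay line of 2·(L//2) pixels aligning
the original row with the opening output, three binary row buffers of W
bits (cross-row pair erosion, its recovery dilation, the delayed step-4
mask), two single-bit pair registers, a sparse store for the enhanced
values of masked pixels awaiting the one-row recovery lag (64 entries ×
(bitdepth + column-address bits); targets occupy well under 1 % of a row),
and a register table for 16 concurrently open components (label, column
interval, centroid accumulators) — open components are registers, not a
labeled row.  With defaults (L = 15, W = 1024, 8-bit) this totals 6242
bits = 780 pixel-equivalents = 0.074 % of the frame, under one row, and is
independent of image height.  Per-stage emission delays (line look-ahead
L//2 + 1 each, one or two clocks per pair/threshold/label stage, a
20-cycle sequential divider for the centroid) total 50 pixel clocks = 2 µs
at 25 MHz; the per-stage constants are a reconstruction constrained by the
block structure and are asserted, as a table, in the tests.  The
improvement factor compares a configurable frame-based processing time
(default 10 ms) with this latency; the time advance for a target in row i
adds the readout still pending, interpolating from T_proc (last row) to
T_read + T_proc (first row).

## Rolling-shutter timing

Row i exposes at t0 + i·dt (dt configurable; dt = 0 degenerates to a
global shutter); timestamps default to the exposure midpoint (+T_exp/2),
start-referenced on request — the choice is a convention and both are
exact for the finite-difference velocity estimator.  Seamless readout
means H·dt = 1/f_P, making row H of one frame coincide with row 0 of the
next.  Hyper-frame resolution: n exposure-distinct targets evenly spread
over a frame update the scene every 1/(n·f_P); with one target per row the
limit is dt itself.  Velocity is (pos − pos_ref)/(T − T_ref), exact for
noiseless linear motion; a coincident epoch flags the track as undefined
rather than failing.  Detections are timestamped at their last row (the
moment the component completed); for velocimetry the fractional centroid
row gives a finer timestamp and is used in the examples.

## Synthetic scenes

`synthgen` renders the study conditions: Gaussian spots sampled at pixel
centres (adequate for σ ≥ 0.5 px; the sampled sum reproduces I0 to better
than 0.1 % for σ ≥ 0.7 — sampling, not pixel-area integration, is a
documented choice), over flat, clipped-linear-gradient ("stray light",
>210 gray with optional saturation), low-pass-filtered random "cloud"
fields (default correlation length 24 px ≫ L, rescaled to gray 30–60), and
saturated-core disk ("moon") backgrounds whose rim decays smoothly to
~50 gray.  Defects: Bernoulli hot pixels, 3×3 dark (dead-pixel)
depressions, additive Gaussian read noise; Poisson shot noise is a config
hook only, not modeled.  Frames are quantized and clamped to bit depth;
identical (spec, seed) gives byte-identical frames.  Rolling-shutter
sequences render each constant-velocity spot at the closed-form fixed
point of "position at the exposure time of its own row".

What the generator does **not** emulate: optical aberrations and defocus
shape, pixel-response non-uniformity, correlated (row/column-pattern)
readout noise, and photon statistics.  Passing tests therefore demonstrate
the morphology, streaming and timing logic under calibrated Gaussian
conditions, not end-to-end performance on a specific sensor.

## Experiment analogues and their conditions

* **Static precision**: 500 seeded 64×64 frames, one spot σ = 0.7 px,
  peak ≈ 200 gray on a flat 20 floor, read noise 2 gray; pipeline L = 15,
  absolute T = 10.  Per-axis 1σ centroid scatter ≈ 0.015 px (bound
  0.03 px).
* **Robustness**: moon disk (radius 80 px on 256², saturated core, rim to
  ~50), saturating stray ramp, clouds — each with one embedded weak spot.
  The interferer yields no detection; the weak spot is always found.
* **Sky accuracy**: 200 seeded 120×160 frames, five spots σ = 1.5 px with
  peaks 16–19.5 gray above a 120→240 ramp, read noise 2, slow linear
  drift (≤ 2 px over the series); cubic per-target drift fits are the
  benchmark, residuals pooled per axis, identification = matched-frame
  fraction.  Identification is 100 %; the residual lands at ≈ 0.13 px
  (column axis) and ≈ 0.20 px (row axis).  Note the information-theoretic
  floor: at peak 16 over noise 2 the single-frame centroid CRLB is
  2σ_n/(peak·√(π/2)) ≈ 0.10 px per axis, and substituting the *true*
  background for the estimate still leaves ≈ 0.095 px — the row-axis
  excess is the noise of the per-row 1D background estimate, an intrinsic
  cost of row-local processing at this SNR.
* **Recovery ablation**: 500 seeded 32×32 scenes, spot σ = 0.7 at uniform
  sub-pixel offsets, peak 100, read noise 2, processed with recovery on
  vs off (centroid from post-erosion pixels).  Erosion survivors are the
  upper-left corners of set 2×2 blocks, a systematically shifted set, so
  the off-mode RMS error vs truth is ≈ 12× the on-mode (bound ≥ 3×); an
  on-pixel-centre symmetric spot shows comparable frame-to-frame scatter
  in both modes (constant bias, not noise).

Problem sizes (64–256 px frames, 200–500 frame series) were chosen so
every experiment is a desk-scale computation while keeping the per-frame
statistics of the conditions they emulate.

## Known limitations

* The clipped-window opening under-runs a monotone rising ramp in the last
  L//2 columns of a row, which can segment spurious edge pixels; real
  stray-light scenes saturate there (flat ⇒ no artifact).  Detections
  whose component hugs the final columns of a steep unsaturated ramp
  should be treated with suspicion.
* On a rising ramp a narrow spot's flank partially leaks into the
  background estimate, slightly deflating its enhanced peak.
* The pair-SE suppression requires a 2×2-block core: targets whose mask
  is one pixel thin everywhere (σ well below ~0.5 px at low SNR) are
  removed as noise by design.
* The hardware model is an accounting model, not a cycle-accurate
  emulation; fixed-point effects are out of scope.
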