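# Methods

`microflow` automates the functional analysis of intravital video
microscopy (IVM): given a ~60 s brightfield video of transilluminated
tissue, it answers, for every place where a microvessel crosses a fixed
reference grid, the question *is blood actually flowing here?* The design
is a two-step pipeline — structural segmentation first, functional
classification second — mirroring how a trained human analyzer works.

## The physical signal

Red blood cells absorb the transillumination light, so vessels appear as
dark tubes on a bright field. In a perfused vessel the RBC column moves,
and every pixel over it flickers; in a stagnant vessel or an optical
artifact nothing changes over time. Summing the absolute intensity
difference between consecutive frames (the SAD image)

    SAD[r, c] = sum_i |frame_i[r, c] - frame_{i-1}[r, c]|

therefore produces an image that is bright precisely over perfused
vessels. All structural analysis happens on this image, not on any single
frame.

## Preprocessing

**Motion gate.** Tissue motion corrupts the SAD image (every edge
flickers). A block-matching estimator compares each frame to frame 0:
blocks (default 32 px, tiled with 50% overlap, capped at 36 blocks for
tractability on large frames) are matched by exhaustive integer search
(±8 px) minimizing mean absolute difference, and the frame's global
displacement is the per-axis median over blocks — the median is essential
because in-vessel RBC motion must not register as tissue motion. "Motion
velocity" is operationalized as the frame-to-frame displacement change
times the frame rate (px/s); frames above the threshold (default
0.3 px/s) are dropped, frame 0 is always kept, and the SAD difference
across a splice is taken between the two surviving neighbours. At 32.5
frames/s a 0.3 px/s threshold corresponds to ~0.009 px between frames,
below integer matching resolution, so in practice the gate drops exactly
the frames where the integer displacement estimate changes; the threshold
is a config value, and sub-pixel registration is deliberately out of
scope — the gate rejects frames, it does not warp them.

**CLAHE.** The SAD image is rescaled to [0, 1] and contrast-limited
adaptive histogram equalization (clip limit 0.01, 8×8 tiles) is applied.
Besides visibility, this step gives the image a fixed dynamic range,
which the segmentation thresholds rely on (below).

## Step 1 — curvilinear segmentation

A Steger-style unbiased ridge detector runs on the enhanced SAD image:
Gaussian-derivative filtering at scale σ gives the gradient and Hessian
per pixel; the ridge normal is the Hessian eigenvector of the
largest-magnitude eigenvalue; a pixel emits a sub-pixel ridge point when
the first directional derivative along the normal vanishes within the
pixel (|offset| ≤ 0.5 px on both axes) and the principal eigenvalue is
negative (bright line). The scale default derives from the expected
vessel width w (default 4 px) as σ = w/(2√3), the classical width–scale
relation for bar profiles.

Hysteresis thresholds are *absolute* second-derivative magnitudes on the
CLAHE-normalized image (low 0.03, high 0.06). We measured crest strengths
of 0.07–0.25 for phantom vessels against a noise floor below 0.025 at
twice the default sensor noise, so these values transfer across videos
precisely because CLAHE fixes the range; data-derived quantile thresholds
are still available (`low_quantile`/`high_quantile`) but are not the
default, because on clean images the candidate population is dominated by
true ridge pixels and a high quantile of it discards most of the vessel.

Ridge points are rasterized into a binary map (no explicit sub-pixel
polyline linking — downstream stages only consume the binary map), closed
morphologically (radius-1 close uses the 3×3 square, i.e. the Chebyshev
disk, which is the smallest footprint that closes a 1-px gap in a
collinear run), and every 8-connected component smaller than 4 pixels is
removed; a component of exactly 4 pixels is kept. "Shorter than 4 pixels"
is read as component pixel count, exposed as `min_segment_px`.

## Sampling

Three equidistant horizontal and three vertical reference lines are
placed at round(k·extent/4), k = 1..3 — equidistant from each other and
the borders. Each maximal contiguous run of mask pixels along a line is
one *crossing*, the unit that receives a flow decision; its center is the
lower median of the run. Around every cross-section pixel a 16×16×200
block (rows × cols × frames, taken from the first 200 surviving frames)
is cut from the stabilized video. The even window has no center pixel;
the target sits at offset (8, 8), spanning [p−8, p+7]. Pixels closer than
8 px to the border are skipped and counted, never padded — padding would
fabricate temporal signal for the classifier.

## Step 2 — the spatio-temporal 3D-CNN

Each block is linearly rescaled to [0, 1] (a constant block maps to
zeros). The network is:

    conv 8 × (7×7×7), valid, stride 1, ReLU
    conv 8 × (5×5×5), valid, stride 1, dense channel mixing, ReLU
    max-pool 2×2×2, stride 2 (floor)
    flatten  → 6840 for a 16×16×200 block
    dense 128, ReLU
    dense 2, soft-max

Valid convolutions with stride 1 and non-overlapping pooling are the only
padding/stride combination that flattens 16×16×200 to exactly 6840 —
this arithmetic is pinned in the test suite as the architecture's anchor.
The soft-max has two units and the flow-class probability is reported;
a single sigmoid unit would yield identical probabilities. A pixel is
flowing when its probability is ≥ 0.5, and a crossing is flowing when
strictly more than 50% of its cross-section pixels are flowing — an
exactly-half split is non-flowing, so a 3-of-4 cross-section is flowing
and a 2-of-4 one is not.

Training minimizes categorical cross-entropy with Adadelta (ρ = 0.95,
ε = 1e−6, no learning rate to tune) in batches of 30 for up to 100
epochs, stopping early when the epoch-to-epoch training-loss change stays
below 1e−4 for 3 consecutive epochs. All randomness (He weight
initialization, batch shuffling) derives from one config seed. The
network centers the unit-normalized block at zero internally
(x − 0.5): with non-negative inputs the first convolution's output is
dominated by its mean response and Adadelta's adaptive steps take far
longer to escape the symmetric plateau; centering removes that without
touching the normalization contract. Ten-fold cross-validation of pixel
accuracy is available (`cross_validate_cnn`, CLI `--cv 10`) but not run
by default.

The engine is pure numpy: convolutions (forward, weight gradients, and
the transposed-convolution input gradient) are evaluated in the frequency
domain — real FFTs of activations and kernels, channel mixing as a
complex einsum, one inverse transform per output channel. On
valid-correlation index ranges the circular transform has no wrap-around,
so this is exact linear correlation up to float rounding; the test suite
checks backprop against central finite differences. The same seed gives
bit-identical training runs on one platform.

**Baseline.** A logistic regression on the flattened block (51,200
features for the canonical geometry, L2-regularized, scikit-learn) serves
as the comparator; it shares the prediction and majority-rule interface.

## Evaluation

Confusion counts use flowing = positive. The five derived metrics are
accuracy (TP+TN)/n, positive precision TP/(TP+FP), sensitivity
TP/(TP+FN), F1 2TP/(2TP+FP+FN) and negative precision TN/(TN+FN); a
metric whose denominator is zero is reported as undefined (None), never
coerced to 0 or 1. Presentation rounding is 2 decimals; full precision is
kept internally.

The end-to-end protocol scores a full pipeline run against phantom ground
truth: a flowing call matches the nearest true crossing within 3 px
(configurable); the detection rate is the fraction of truly flowing
crossings marked flowing, and the error rate is the fraction of flowing
calls that are false (non-flowing or unmatched).

## The phantom generator

Synthetic videos stand in for animal recordings, which cannot be
redistributed. The generator renders the contrast mechanism the method
exploits and nothing more: smooth random spline centerlines (3–5 jittered
waypoints), a Gaussian absorption profile across each tube (hard support
cutoff at width/2, so ground-truth masks are exact), dark elongated
blobs (Gaussian profile along the axis, 2–6 px long, exponential gaps
scaled by an RBC density parameter) advected along flowing centerlines as
a wrapped continuous stream, static dark tubes for stagnant vessels, a
static low-frequency illumination texture, additive Gaussian read noise
plus an intensity-proportional shot-noise term, and optional sub-pixel
global drift. Per-crossing ground-truth labels are computed against the
default reference grid from the exact tube masks.

Default study conditions: 256×256 px frames (desk scale; the instrument's
1000×1000 px is available by config), 6–10 vessels of width 3–6 px, 70%
flowing, RBC speeds 0.5–2.5 px/frame (the slow-flow regime at the reduced
scale), contrast 0.4–0.8, read and shot noise 1% of full scale each,
frame rate 32.5 Hz and 0.4 µm/px kept at the instrument's nominal values.

What the phantoms do *not* model: hemodynamics (RBC deformation,
bifurcation dynamics, plasma gaps), leukocytes, focal-plane blur of deep
vessels, illumination flicker, or vessel crowding at realistic tissue
density. Passing the synthetic benchmark therefore demonstrates that the
implementation recovers the labels its own generative model encodes — a
correctness check of the machinery, not a claim about accuracy on animal
data, which depends on the original videos and labels.

## Synthetic benchmark sizes

The parameter-recovery benchmark (`microflow.benchmark`) renders 15
phantom videos of 220 frames (200 consumed per block), yielding roughly
300 labeled crossings; a seed-derived 70/30 split is made at the crossing
level so no crossing contributes pixels to both sides. Training uses at
most 2 pixel-blocks per training crossing (about 400 blocks) for 10
epochs — within the convergence behaviour we observe for Adadelta at
this data size — and evaluation uses every cross-section pixel of the
held-out crossings, aggregated by the majority rule. The end-to-end check
runs the full pipeline on one additional phantom never seen in training.

## Numerical and degenerate-input conventions

- SAD is computed in float64; unsigned integer frames cannot wrap.
- CLAHE of a constant image returns it unchanged (zeros after rescale).
- A constant block normalizes to all-zeros rather than dividing by zero.
- Run centers of even-length cross-sections take the lower median.
- Grid-line rounding collisions on tiny images are nudged upward to keep
  lines strictly increasing (and must stay inside the image).
- Decisions with an empty probability list, single-class training sets,
  sub-2-frame stacks and non-finite inputs raise errors rather than
  guessing.

## Known limitations

- Integer-only motion search: drift slower than ~1 px over the recording
  is invisible to the gate and is treated as noise.
- The detector's dark-line mode is not exposed; the SAD image always
  presents perfusion as bright ridges.
- No vessel diameter, flow velocity or direction estimation; crossings
  are scored independently (no tracking of a vessel between grid lines).
- Closely adjacent or crossing vessels can merge into one run on a grid
  line, which blurs the per-vessel attribution of the decision.
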