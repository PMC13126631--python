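# Methods

This note records the models and procedures implemented in `afmstate`,
the assumptions behind them, the parameters that matter, and the design
choices made where more than one reasonable convention exists.  It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coarse-grained molecular representation

A conformer is a set of spheres ("beads") in nanometres: one bead per
amino-acid residue centred on its Calpha, and one bead per lipid
phosphorus with kind `PO4`; acyl chains are omitted.  The per-residue
effective radius is supplied by a user table; absent an entry the
default is 0.38 nm, a common Calpha-bead convention, and the PO4 default
is 0.235 nm (half of a 0.47 nm coarse-grained phosphate bead).  These
defaults are declared package conventions, not values transcribed from
any particular force-field table, and all tests pass radii explicitly so
no result depends on them.  An ensemble requires identical bead counts
and kinds across conformers so that bead *i* always names the same
residue; this is asserted on load.

## Pseudo-AFM image formation

The probe is a cone of half-apex angle Θ capped by a sphere of radius
R.  For a pixel whose axis passes at lateral distance d from a bead of
radius r centred at height z_b, the tip-apex height at first contact is

    z = z_b + sqrt((R+r)^2 − d^2) − R           if d ≤ (R+r) cos Θ
    z = z_b + (R + r − d cos Θ)/sin Θ − R       otherwise,

the two branches agreeing exactly at the crossover.  A pixel records the
maximum over beads, floored at 0 (bare stage).  The cone is treated as
infinitely tall; molecules are far shorter than real tips, so shaft
truncation never matters at this scale.

Conventions fixed for bit-reproducibility:

* **Rotations** are applied sequentially about the fixed z-, x- and
  y-axes (ψ, φ, θ; extrinsic), about the geometric centroid of the bead
  centres.  Whether the sequential scheme is meant intrinsically is
  ambiguous in the underlying description; extrinsic was chosen and the
  composition `Ry·Rx·Rz` is asserted against hand-built matrices in the
  tests.
* **Stage reference**: after rotation, the model is shifted so that the
  lowest bead *surface* (`min(center_z − radius)`) sits at z = 0.  Taking
  the literal minimum of centres would bury half of the lowest bead
  below the stage; the centre-based mode is still available
  (`stage_mode="center"`) for fidelity comparisons.
* **Pixel grid**: pixel (i, j) has its centre at
  `origin + ((j+0.5), (i+0.5))·pixel_size`, row index increasing with
  +y.  The default grid is 36 × 36 px at 0.8 nm/px, centred on the
  origin.

The batch renderer (`render_many`) used by rigid-body fitting computes
in float32 (≈1e-6 nm per-pixel error) for throughput; the single-image
renderer is float64 and bit-identical to a per-pixel scalar loop, which
the acceptance suite asserts.

## Line-scan lag and white noise

An HS-AFM frame is acquired line by line; molecular diffusion between
lines distorts the assembled image.  Each scan line therefore receives
an independent perturbation of the pose *relative to t = 0* — not a
cumulative random walk — drawn as `N(0, s·σ_i²)` per component and
truncated by rejection to `Δr = sqrt(Δx²+Δy²) ≤ w·Δr_max` (jointly for
the lateral pair) and `|Δangle| ≤ w·Δmax` per angle.  Rejection rather
than clipping preserves the normal shape inside the window and yields
the expected near-uniform limit at large `s`, which the tests check via
the CDF of the ψ-perturbation at `s = 10`.  Reference parameter set:
σ_x² = σ_y² = 0.81 nm², σ_φ² = σ_θ² = 6.25 deg², σ_ψ² = 25 deg²,
Δr_max = 1.2 nm, Δφ_max = Δθ_max = 5°, Δψ_max = 10°, s = w = 1.

Scan order is bottom row to top, each line rendered from a full fresh
transform at the perturbed pose (so any line can be replayed exactly
from the perturbation log).  The conformation itself is held fixed
during the scan.  `s = 0` or `w = 0` short-circuits to the static
render, bit-exactly.  White noise is plain i.i.d. `N(0, σ_N²)` per pixel
with no clamping, applied at data-loading time only, with σ_N drawn
from the grid 0–0.3 nm in 0.01 nm steps.

## Conformational states

Conformers are rigid-body superposed (Kabsch) onto the first frame —
removing rigid-body motion from the state definition — flattened, and
reduced by PCA to six components by default.  A full-covariance Gaussian
mixture is fitted for each candidate K (default range 2–30, five
restarts, seeded); K minimises the BIC among candidates whose smallest
cluster keeps a minimum occupancy (default 1 % of frames).  States are
relabelled 1..K by increasing mean PC1 so the label axis tracks the
conformational transition, and each state is represented by the member
nearest (Euclidean, in the retained PC space) to its cluster's empirical
mean.  Reported RMSDs are always after optimal superposition; whether
the original description refits before measuring is unstated, so this
is declared, not reproduced.  Within-state mean pairwise RMSD uses all
pairs up to 200 members, then a seeded subsample.

## Paired training data

Each sample pair is (ground-truth render, scan-lag-distorted render) of
a uniformly drawn frame at a shared probe/pose, plus the frame's state
label.  Probe and pose are drawn from discrete grids — R ∈ {1.0..3.0} nm
step 0.1, Θ ∈ {5..30}° step 1, φ, θ ∈ {−20..20}° step 1,
ψ ∈ {−180..180}° step 1 — reflecting a disc-shaped scaffold lying flat
on the stage, which physically caps the tilts.  Pairs are streamed to
POSIX tar shards (`<key>.gt.tiff`, `<key>.noisy.tiff`, `<key>.json`);
each shard is deterministic given (seed, shard index), so shards can be
produced in parallel.  White noise and the ±3 px joint shift
augmentation are applied at load time, so one stored dataset serves many
noise levels; the scan-lag distortion is baked in at build time.

**Normalisation convention.**  Both members of a pair are min–max scaled
by the *noisy input's* extrema.  At inference only the input's extrema
are available to map the denoised output back to nanometres, so training
against targets in that same frame keeps train and test consistent.
(The alternative — normalising the target by its own extrema — would ask
the network to also predict an unobservable scale.)  A constant image
maps to zeros with vmin = vmax recorded.

## Multitask transformer autoencoder

The network embeds 6 × 6-pixel patches (36 tokens on a 36 px image),
prepends a class token, adds learned positional embeddings, and runs a
pre-norm transformer encoder (GELU MLPs, MLP ratio 4, 8 heads).  Two
branches share the encoding: a classifier (2 further transformer blocks,
then a linear map from the class token to K logits) and a decoder (a
linear projection of the patch tokens to a narrower width, more blocks,
and a per-token linear back to pixels).  The encoder is deliberately
deeper and wider than the decoder (reference configuration 12
layers/512 dims vs 8 layers/256 dims) so that representational capacity
sits in front of the bottleneck.  Patch size, head count and classifier
depth are declared defaults — the underlying description does not pin
them — and all are configurable.

The loss is `L = α·MSE(gt01, denoised01) + β·CE(y, ŷ)` with α = 100,
β = 1 balancing the scales of the two terms.  Optimisation is AdamW
(weight decay 1e-4) with linear warmup to the peak learning rate and
cosine decay to zero; optional global-norm gradient clipping
(`TrainConfig.grad_clip`, off by default) is available for
high-learning-rate regimes.

The implementation is a self-contained numpy transformer with a small
reverse-mode autodiff engine (`afmstate.nn.autodiff`), gradient-checked
against central finite differences in the test suite.  GELU uses the
tanh approximation.  All computation is float32 by default and fully
seeded; there is no dropout, no mixed precision and no multi-device
path, so checkpoints reproduce bit-for-bit.

**Desk-scale configuration.**  The tested configuration is a 4-layer /
128-dim encoder with a 2-layer / 64-dim decoder, trained for 10 epochs
on 5 000 pairs from the hinge fixture.  At this data scale the reference
recipe (batch 192, peak LR 2e-3, 5 warmup epochs) takes too few
optimisation steps for the classifier head to converge, so the
desk-scale recipe uses batch 24, peak LR 5e-4 and one warmup epoch —
about 2 000 steps — while keeping the loss weights, optimiser and
schedule shape unchanged.  The reference-scale 12/512–8/256 model is
constructible and smoke-tested for a forward/backward pass only.

**Attention rollout.**  Per layer, head-averaged attention is blended
with the identity, `A' = 0.5(A + I)`, row-renormalised, and multiplied
across layers in forward order; the class-token row (restricted to patch
tokens) is reshaped to the patch grid, upsampled, and min–max scaled to
[0, 1].  Rollout spans the encoder *and* classifier blocks by default —
the attribution of self-attention to "the classifier" is ambiguous —
and either span can be disabled.

**Transfer.**  `transfer_init` copies every weight whose name and shape
match a source checkpoint, reinitialises the classifier output layer
when K changes, and can freeze the encoder.

## Rigid-body fitting

Every candidate structure (the K cluster centres) is rendered over an
exhaustive grid of orientations — default ψ ∈ [−180°, 180°] step 5
(73 values), φ, θ ∈ [−30°, 30°] step 5 (13 values each) — and probe
parameters when enabled (R and Θ are fixed at 1 nm / 10° for simulated
tests and gridded over {1, 2, 3} nm × {10°, 20°, 30°} for experimental
data, where the probe is unknown).  Each rendered image is additionally
translated by integer pixels within ±3 px, implemented as a zero-fill
shift of the rendered image rather than a re-render (identical values
for interior content, ~49× cheaper).  The score is the Pearson
correlation coefficient over all pixels; the winner is the global
argmax with ties broken lexicographically in (state, ψ, φ, θ, R, Θ,
shift) order, so results are bit-reproducible.  `fit_after_denoise`
first runs the autoencoder, then fits only the predicted state's centre,
searching pose alone.

## Synthetic hinge fixture

The fixture molecule is two rigid rods of overlapping beads (12 per
6 nm arm, radius 0.8 nm) joined at a pivot, opening in the stage plane.
State k of K sets the hinge angle to the k-th of K evenly spaced values
in 40–120°; each frame adds i.i.d. Gaussian jitter (0.15 nm) to every
bead; 250 frames per state, K = 4 by default.  These defaults are sized
so a 36 × 36 image at 0.8 nm/px resolves the motion and the desk-scale
network trains in minutes: the ~27° hinge step between adjacent states
moves arm tips by several pixels, well above the jitter.  A
nanodisc-like variant (`make_reference_scene`) adds a flat PO4 ring
under the molecule so the ±20° tilt limits are physically meaningful,
and `linear_morph` provides Cartesian interpolation between endpoint
conformers as a stand-in for a geometric morphing trajectory.

What the fixture does *not* emulate: real structural detail (a protein
is not two rods), within-state anharmonicity, correlated domain motion,
tip contamination, double-tip artifacts or sample deformation.  Passing
tests therefore demonstrate that the pipeline's machinery is correct and
self-consistent at desk scale, not that any accuracy number transfers to
real molecules.

## Experimental-image preprocessing

The stage level of a lattice-supported image is the mean height outside
both the lattice holes and the molecule; holes are filled with that
value, the image mean is subtracted, the molecule's intensity-weighted
centroid is moved to the central pixel by an integer shift, and the
frame is symmetrically cropped or zero-padded to 36 × 36.  Masks may be
supplied; otherwise they are derived from a median ± 3·MAD threshold so
the pipeline stays deterministic and auditable.  The pipeline is
idempotent on an already-standardised frame; when cropping changes the
image mean, a second pass re-levels by that (small) difference — an
unavoidable consequence of subtracting the mean before cropping, which
follows the published order of operations.

## Numerical choices and degenerate inputs

* Min–max scaling of a constant image returns zeros, recording
  vmin = vmax; rescaling inverts exactly.
* The correlation coefficient is undefined when both images are
  constant (raises); an all-constant *candidate* render scores −inf
  inside the fit search and can never win.
* Truncated sampling short-circuits to exact zeros at `s = 0` or
  `w = 0`, avoiding 0/0 rejection loops.
* Rank-deficient ensembles yield fewer PCA components with a warning;
  superposition requires ≥3 non-collinear beads.
* All randomness flows from one seed through labelled substreams
  (`afmstate.config.substream`), so adding a consumer never reshuffles
  another module's draws.

## Problem sizes used by the test suite and acceptance script

Clustering and fitting checks run on the default K = 4 hinge fixture
(1 000 frames).  The learning check trains the desk-scale model on
5 000 pairs for 10 epochs and evaluates 400 held-out noise-free images,
200 distortion-denoising pairs and a 3-point white-noise ladder.
Rigid-body comparisons use a reduced search grid (ψ step 30–45°, φ, θ
step 10–20°, shifts ±1 px) over 40–100 images per condition; the default
5°/±3 px grid is exercised on single images.  These sizes are the
package's own desk-scale choices, documented so the printed numbers can
be regenerated exactly.

## Known limitations

* The mapping from per-line variances to a physical diffusion
  coefficient is not implemented; the noise model is phenomenological.
* No rotational diffusion on SO(3); per-line angular perturbations are
  independent Euler displacements relative to t = 0.
* No flexible fitting or gradient-based pose refinement; the fit is a
  local Euler-grid search by design.
* The numpy training loop is single-process and CPU-bound; it is meant
  for desk-scale experiments, not production-scale training.
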