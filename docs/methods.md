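# Methods

This note documents the models, parameter choices, and numerical
decisions behind `swarmsense`, and what the synthetic data does and does
not establish about real tank footage.

## Synthetic swarm generator

No quantitative motion model of the original fish is available (the
system being emulated was only observed qualitatively), so the
generator's update rules are this package's own, boids-style presets chosen to reproduce the
*defining statistic* of each pattern:

| pattern | rule | statistic enforced |
|---|---|---|
| FOLLOWING (1) | leader wanders (heading random walk, σ = 0.08 rad/step); each fish steers at its predecessor, speeding up when lagging | mean chain gap ≤ 3×speed |
| PARALLEL (2) | one shared heading with per-fish jitter (σ = 0.05 rad) | per-step circular variance < 0.1 |
| SHOAL (3) | independent persistent random walks (σ = 0.5 rad/step), weak cohesion for stragglers | pooled heading circular variance > 0.5 |
| TORNADO (4) | orbit about the arena center at radius 0.25·min(arena), radius relaxed at gain 0.1/step, fixed rotation sense | radius CoV < 0.2; angular velocity single-signed ≥ 90% of steps |

Defaults emulate the study tank scaled to pixels: 10 fish, 320×240 px
arena, 200 steps of 0.5 s, speed 3 px/step, positional jitter
0.3 px/step. Boundaries are rigid walls: velocities reflect. The
PARALLEL school reflects *synchronously* (the shared heading flips when
any member would exit); per-fish asynchronous reflection would
transiently depolarize the school, which is an artifact of the walls,
not of the pattern.

### Rendering

Fish are filled 2:1 ellipses oriented along the heading (semi-major =
2×`fish_radius`), with elliptical shading (edge 120, center up to ~245
on the 8-bit scale) plus a sinusoidal band texture along the body axis
(amplitude 55, wavelength 7 px, per-fish phase). The texture is not
cosmetic: a *flat* silhouette sliding along its own major axis changes
almost no interior pixel, so frame differencing sees only the thin
leading/trailing crescents, which the erosion stage then removes. Real
fish carry scale and fin markings that decorrelate under motion; the
bands reproduce that property and restore the contrast the detector
needs. Keeping full band amplitude out to the silhouette, and keeping
the band zero-crossings narrower than the 2×2 closing kernel can
bridge, makes the fused motion mask a solid body-shaped blob whose
centroid is essentially unbiased (measured error ≈ 1.3 px at speed 3
px/step).

Nuisance signals are applied after the fish, emulating the reported
false-positive sources: bubbles (Poisson-spawned bright discs, radius
≈ 5 px, rising 4 px/frame), a drifting vortex (local tangential
sinusoidal displacement, amplitude 2 px within a 40 px disc, applied by
bilinear resampling), and illumination drift (additive ramp, 0.2
intensity units/frame). Motion and noise draw from independent seeded
sub-streams so either component is reproducible in isolation.

What the synthetic data does **not** model: water refraction and
caustics, fish occlusion in depth, shadows, camera vibration, fish
responding to the robot or to food. Detector scores on this data bound
what the algorithm can do under controlled contrast; they do not
predict accuracy on any particular real tank.

## Detector

Both motion cues threshold at `Th = 25` (8-bit scale) — the common
motion-difference default; the background learning rate defaults to
`α = 0.05`. The morphology chain is executed literally in the prescribed
order and counts (closing ×15 with 2×2, opening ×15 with 1×1, erosion
×2, closing ×10 with 2×2). Two of its stages deserve comment:

* a 1×1 opening is mathematically the identity; it is executed anyway
  for fidelity to the recipe and logged once, and the kernel is
  configurable;
* the recipe leaves the erosion kernel open; 1×1 would be the identity
  and 2×2 is anisotropic about its anchor, so the default is 3×3.

`min_blob_area = 20 px` suppresses residual speckle smaller than a fish
at the synthetic scale. Headings use greedy nearest-neighbour
association to the previous frame gated at 15 px (≈ 5× the default
speed); this is deliberately minimal — it orients canvas markers, it is
not an identity tracker. Coordinates follow the image convention
(origin top-left, x = column, y = row, 0-based); the background model
initializes to frame 0 and output starts at frame 1.

## Trajectory canvas

A canvas summarizes one window (default 60 s) of detections on a
224×224×3 image, the classifier's input size. Markers are 9 px line
segments centered at the scaled position, angle = heading, colored by
heading octant (8 fixed colors); detections without a heading become
single-pixel dots in a reserved color, so no direction information is
invented. Arena-to-canvas scaling preserves aspect ratio with
letterboxing. All frames of the window contribute markers;
`frame_stride` exposes subsampling. Windows are half-open
`[k·w, (k+1)·w)` — a timestamp exactly on a boundary belongs to the
later window.

## Pattern classifier

The layer stack is conv 32@3×3 → ReLU → maxpool 2×2 → conv 64@3×3 →
ReLU → maxpool 2×2 → flatten → dense 1024 → ReLU → dense 4 → softmax,
trained with Adam on categorical cross-entropy for 25 epochs by
default. Convolutions are valid (no padding), stride 1 — the smallest
assumption consistent with the stated sizes. A ReLU + 2×2 pool follows
the *second* convolution as well, mirroring the first set — the
reference architecture spells out pooling only for the first set, so
this is an interpretation (it also keeps the flattened dimension
tractable). Adam's learning rate (1e−3) and the batch size (32) are
conventional defaults; the reference protocol names the optimizer but
no hyperparameters.
Inputs are scaled to [0, 1]. Ties in the argmax resolve to the lowest
class index.

The network is implemented in NumPy (`swarmsense/_nn.py`): im2col +
BLAS matmul convolutions, float32 parameters, standard bias-corrected
Adam. Gradients at max-pool ties are split equally.

**Reduced-scale protocol.** `CNNConfig.downsample` block-averages the
canvas before the conv stack (default 1 = full 224×224×3). The
package's repeated-training protocol — 400 generated images, stratified
70/30 split, 10 epochs, ten seeds — runs at `downsample = 8` (28×28×3),
which keeps one full protocol under two minutes on a single CPU; the
architecture is unchanged. Measured test accuracy on the synthetic
corpus is ≈ 0.97–1.0 per seed, far above the 0.25 chance level. This
establishes that the pipeline — generator → canvas → CNN — carries and
recovers class signal; it does not reproduce any accuracy figure
measured on real video, for which no recordings or trained weights are
available.

**Augmentation** keeps the originals and appends randomly transformed
copies (rotation ±15°, translation ±10 px, horizontal flip, random 90%
crop resized back; nearest-neighbour interpolation so marker colors
stay exact) until `round(n × multiplier)` images exist; the default
multiplier 1.35 takes a 1200-image corpus to exactly 1620.

## Evaluation measures

Binary measures follow the standard definitions: ACC = (TP+TN)/(P+N),
TPR = TP/(TP+FN), SPC = TN/(FP+TN), PPV = TP/(TP+FP). Ratios with zero
denominators are *undefined* (`None`), distinguishing "no positives
existed" from "the detector found none". Values are exact rationals
internally; percentage formatting (2 d.p., round-half-even) is display
only. For a K-class matrix the only accuracy derivable from the matrix
itself is trace/total; when a published matrix and a separately
published accuracy disagree, the package reports the derivable value
and flags the discrepancy rather than resolving it.

Detector scoring matches detections to ground truth per frame by
minimum-cost assignment on centroid distance with a 10 px gate; recall
= matched/truth, precision = matched/detected.

## Robot dynamics

State: body-frame surge/sway/yaw velocities (u, v, r) and world pose
(X, Y, α). The momentum balance is the planar Kirchhoff reduction with
added-mass derivatives; note the sway equation carries a minus sign,
`(m_b − Y_v̇) v̇ = −(m_b − X_u̇) u r + F_y`, as required by
Ṗ = P × ω (with ω = r ẑ, Ṗ_y = −P_x r): without it the unforced system
gains energy and the xz-plane mirror symmetry of the body is broken.

The tail is a rigid plate of length L hinged at the peduncle, deflected
by θ from the negative body x-axis (unit vectors m̂ along the tail, n̂
perpendicular). The forcing follows Lighthill's large-amplitude elongated-body theory
in its standard reactive closure at the tail tip: with V the tip velocity
relative to still water and w = V·n̂,

    F = m_v w (V·m̂) n̂ − ½ m_v w² m̂,      M_z = x_tip F_y − y_tip F_x

where m_v is the tail's virtual (added) mass per unit length. The −m̂
component is thrust (positive surge for pure flapping); the force
vanishes at rest; the expression is equivariant under the body's
y-mirror, which the simulation verifies to 1e−8 relative.

Parameters are sized for the 20 cm × 15 cm rigid body and are package
defaults, not published values: m_b = 1.2 kg, J_bz = 6e−3 kg·m²,
X_u̇ = −0.3 kg, Y_v̇ = −0.6 kg, N_ṙ = −4e−3 kg·m², L = 0.08 m, hinge
0.10 m behind the center of mass, m_v = ρπd²/4 ≈ 2.8 kg/m for a ~6 cm
deep fin. Optional quadratic drag (5, 10, 0.05 in surge/sway/yaw) is on
by default — without dissipation the equations never settle — and gives
terminal speeds ≈ 0.2 m/s, typical of desk-scale robotic fish; set it
to zero for the pure-equation tests. Pectoral fins contribute only
their mass (they are included in m_b); they exert no modeled force.

Integration is classical fixed-step RK4 (reproducibility over adaptive
stepping); the tail program is evaluated at the substage times, which
preserves 4th-order convergence under a moving tail (measured endpoint
error ratio ≈ 16 per halving of dt). The heading α is integrated
unwrapped — wrapping inside the integrator would destroy smoothness —
and wrapped only for display. Maneuver presets: straight = zero-bias
flapping (amplitude π/6, 2 Hz); C-turn = sustained bias π/5 with
amplitude π/12; S-turn = the same with the bias sign reversed at the
midpoint. Tail deflection is mechanically limited to |θ| ≤ π/3 and
programs are validated against it. Within a stroke the yaw rate
oscillates, so turn direction is assessed stroboscopically (net heading
change per whole flap period).

## Feeding policy

Mapped mode draws uniformly (seeded) from the observed pattern's
response set — FOLLOWING → all four drop patterns, PARALLEL →
{C-shape, straight}, SHOAL → {O-shape}, TORNADO → {O-shape, C-shape};
random mode draws uniformly over all four, as in the original data
collection. The dosing cap (5 drops/day) is enforced over a *rolling*
24 h window: a per-day cap with an undefined day boundary is read
conservatively. Human presence is a
boolean input; the sensing hardware is out of scope. Interest windows:
straight 22 s, S-shape 28 s, C-shape 32 s, O-shape 19 s; interest has
lapsed when elapsed time strictly exceeds the window.

The published response table prints row percentages only; the row
totals (30, 9, 22, 17) recovered by exhaustive denominator search are
inferences consistent with the printed rounding, not published counts,
and are treated as such in the tests.

## Degenerate inputs and tie-breaks

* `n_fish = 0` is a valid swarm: empty trajectory, constant background.
* An empty binary mask passes through the morphology chain unchanged.
* Detections with no previous-frame match keep `heading = None` and are
  drawn as reserved-color dots.
* A single-class training set warns rather than fails.
* An all-zero confusion matrix is an error; a zero row in the response
  table yields NaN percentages plus a warning.
* Argmax ties resolve to the lowest class index; max-pool gradient ties
  split equally.

## Known limitations

* The generator's realism is statistical, not visual; detector scores
  transfer to real footage only qualitatively.
* The heading tracker is single-frame association; crossing fish can
  swap headings (identity tracking is out of scope).
* The dynamic model is planar: no heave, roll, pitch, or depth control,
  and the tail is rigid (no fin compliance).
* Classifier results on the synthetic corpus say nothing about the
  accuracy achievable on real trajectory images.
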