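# Methods

`massgrader` models the computational core of a machine-vision cucumber
grader: a CNN that regresses fruit mass from a single top-view RGB image, a
mass-to-grade rule, and a discrete-event simulation of the fixed-tray
grading line that routes each fruit to its grade track. Because no public
image dataset exists for this task, the package ships a procedural generator
whose outputs carry exact ground-truth masses, making every downstream stage
testable end to end.

## Synthetic cucumber model

Each cucumber is a solid of revolution. A smooth centerline of arclength
`L` (mm) bows laterally by a sinusoidal amplitude `A` (mm), and a radius
profile

    r(s) = r_max * sin(pi * s)^q,   s in [0, 1]

tapers the cross-section to zero at both tips (`q = 0` degenerates to a
cylinder, which the volume tests exploit). The noise-free mass is

    m = rho * L * \int_0^1 pi r(s)^2 ds,

evaluated by trapezoidal quadrature on 4001 points (relative error against
cylinder/cone/ellipsoid closed forms is < 0.5%). Defaults: density
`rho = 0.00095 g/mm^3` (water-like produce), weighing noise sd 1 g
(bench-scale resolution), lengths 200–300 mm, bow 0–22 mm, taper exponent
0.12–0.38.

Sampling is mass-first: a target mass is drawn from a truncated normal
(center 170 g, sd 38 g, support 97–246 g) and `r_max` is solved from the
sampled length and taper, so induced masses span the 95–248 g grading
interval by construction; draws whose solved radius leaves the feasible
band 10–26 mm are rejected and redrawn. Grade-bucket filling for dataset
generation draws the target mass uniformly inside each grade's mass window
and rejects the rare draws whose noisy mass crosses a boundary.

The renderer draws the tube on a uniform tray background (base RGB
(182, 186, 191), Gaussian pixel noise sd 1.5 levels) using a signed
distance field to the densely sampled centerline. Radial shading
`sqrt(1 - (d/r)^2)` encodes local thickness, so images carry volume
information beyond the silhouette; bright speckles (0.8–3.5 per cm²)
stand in for spines and a yellow tip blob for the retained flower. The
rendering scale is 1.6 mm/px at 224×224 (3.73 mm/px at the 96×96 desk
profile), chosen so a realistic 300 mm fruit fits the frame with margin.

What the generator does *not* emulate: perspective and lens distortion,
specular highlights, shadows, occlusion, multi-fruit trays, and the
photometric variability of real produce. Tests passing on this data
demonstrate that the architecture, training recipe and control law work as
specified — not that the trained network transfers to real cucumbers.

## MassNet

MassNet alternates stride-2 convolutions with cross-stage-partial
bottleneck blocks. Every convolution is followed by batch normalization and
SiLU. The CSPC block splits its channels in half, passes one half through
residual bottlenecks (1×1 reduce, 3×3 expand, identity skip), concatenates
with the untouched half and fuses with a 1×1 convolution. Adaptive average
pooling collapses the final map to a fixed-length vector for any input
resolution, and a fully connected head emits one scalar.

Default plan: stem 3→32→64 (two stride-2 convs), stages 128/256/512 with
1/2/2 bottleneck repeats, head 512→128→1 — 2.82 M parameters, about a
quarter of ResNet-18's 11.18 M. The desk profile (stem 16/32, stages
48/96/128, head 128→64→1) trains in ~90 s for 30 epochs on one CPU at
96×96. Strided convolution (rather than pooling) performs the stem's
spatial reduction; depth and widths are otherwise free design choices at a
size trainable on CPU.

The network stack itself is a compact numpy autograd engine
(`massgrader.nn`): reverse-mode differentiation over conv2d (im2col with
grouped/depthwise paths), batch norm, SiLU/ReLU, max/global-average
pooling, channel split/concat, linear layers and MSE, plus Adam. Gradients
are validated against central finite differences in the test suite.
Baselines (AlexNet, VGG-11, ResNet-18, MobileNet-v1 trunks with a
global-pool + linear regression head, trained from scratch) are built on
the same engine.

## Training and evaluation

Training uses MSE loss, Adam (β₁ = 0.9, β₂ = 0.999), batch size 4, a
seeded random 8:2 train/validation split, and best-validation
checkpointing: the returned weights are those of the epoch with minimal
validation MSE. No augmentation, learning-rate schedule or early stopping.

Normalization contract: pixels are scaled to [0, 1] and standardized by
per-channel training-split statistics; target masses are z-scored by the
training-split mean/sd and mapped back to grams at prediction. The default
initial learning rate is 1e-4. Because targets are standardized, the desk
profile (`TrainConfig.desk()`: 30 epochs) raises the rate to 3e-3 —
at 1e-4 a 30-epoch budget leaves the regression badly underfit, since that
rate is calibrated to gram-scale outputs several hundred times larger.

Metrics: RMSE (g), MAPE (%), and R²; all three are cross-checked against
brute-force loop implementations at 1e-9. A constant predictor at the
training-mean mass serves as the floor baseline; its RMSE equals the test
masses' population standard deviation, a closed-form identity the tests
assert.

## Grading rules

DB37/T564-2005 mass bands, read literally from the printed inequality
symbols: grade 1 on [150, 170] g (both boundaries included), grade 2 on
(170, 250], grade 3 elsewhere. The three intervals partition (0, ∞);
boundary membership is pinned by an exhaustive sweep test. Thresholds are
configurable for other grading documents. Overall grading efficiency is
η₀ = (T_N − T_M)/T_N × 100 with misses attributed to the true grade's row.

## Grading-line simulation

The line is simulated in tray-interval ticks (pitch / chain speed seconds).
Each arriving tray triggers the entry sensor: its grade is latched in D0,
copied into slot 0 of the 14-slot shift register D10, and all slots shift
one position toward the turnouts, so a tray's grade slot index equals its
physical position in pitches downstream. Turnout 1 reads slot X (default
X = 8) and diverts grade-2 trays; turnout 2 reads slot X+4 and diverts
grade-3 trays; grade-1 trays run to the end of the line. After the last
loaded tray, empty trays (grade 0) keep the register shifting until
everything in transit has been routed.

The register is modeled as 14 ordered slots each holding a full grade
symbol {0, 1, 2, 3} — the one-shift-per-tray semantics are what matters,
not the bit-level encoding — and its contents are verified against an
independent bounded-queue oracle after every trigger.

Sensor faults: a *missed* read fails to shift the register (it falls one
position behind the physical trays), a *double* read shifts twice
(inserting a spurious slot). Either way, subsequent grades land on wrong
slots and misroutes follow mechanistically from the control law; nothing
is misrouted by fiat. The default fault model
`p_miss(v) = p_double(v) = max(0, 0.5 (v − 0.3))` is an invented,
fully-exposed stand-in for vibration-induced sensor faults at higher chain
speeds: zero through 0.3 m/s, rising linearly above.

Capacity is W_F / T in t/hr, with W_F the mass of *correctly graded*
fruit and T the feeding time `n_trays × pitch / speed` (register flush is
drain time and excluded, so error-free capacity matches the closed-form
throughput `v / pitch × mean mass × 3600/10⁶` to within sampling error).
Reading W_F as correctly-graded mass is what makes the capacity curve
plateau above the fault onset while staying exactly linear below it; the
simulation also reports the total routed mass separately. Tray pitch
defaults to 0.5 m and the mass sampler to a truncated normal on
[95, 248] g, so absolute capacities are properties of this configuration,
checked against the closed form rather than against any particular
machine. The actuation window (default 50 ms, hard cap 100 ms) is compared
against the tray interval and logged as a warning when it does not fit.

## Problem sizes

The repository's standing evaluation uses the desk profile: 400 training
images (100/160/140 per grade) at 96×96, a 320/80 split, 30 epochs, and an
independent 100-image test set (34/15/51 per grade); simulations use 500
trays. The full profile (224×224, 100 epochs, lr 1e-4, dataset 409 =
103/159/147) is the configured default for library users.

## Known limitations

- The renderer is schematic; nothing here estimates real-cucumber accuracy.
- The fault model's linear form and slope are interpretive, not measured.
- Where grade information enters the register relative to the tray edge is
  an interpretation (capture at the trailing-edge trigger), as is reading
  turnout 2 four slots downstream of turnout 1.
- float32 training on CPU: results are bit-reproducible for a fixed seed on
  fixed hardware, but not across BLAS implementations.
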