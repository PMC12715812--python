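# Methods

## Problem and model

Nucleus segmentation in cervical liquid-based cytology (and similar
micrographs) fails most often where nuclei overlap: mask-only losses happily
merge touching nuclei into one blob, and the merged contour betrays itself
only through geometry — it acquires high-curvature cusps at the points where
two smooth boundaries intersect. This package implements a dual-task
convolutional network plus a discrete-curvature *bending loss* that targets
exactly that signature, together with the instance metrics (AJI, Dice, PQ)
needed to measure whether touching nuclei were actually separated.

### Discrete bending energy

A traced nucleus boundary is an ordered closed polygon A_0..A_{m-1}. With
edge vectors v_prev = A_i − A_{i−1} and v_next = A_{i+1} − A_i, the unsigned
turning curvature at vertex i is

    k(i) = 2 |v_prev × v_next| / (|v_prev||v_next| + v_prev·v_next)
         = 2 tan(θ_i / 2),

θ_i the turning angle, and the per-vertex bending energy is

    BE(i) = k(i)² / (|v_prev| + |v_next|),

a discretisation of ∫κ²ds (Σ θ²/Δs up to the 2tan(θ/2) parametrisation; on
regular m-gons inscribed in a radius-R circle, total BE·R → π as m → ∞,
twice... half of the continuous circle energy 2π/R — the factor is intrinsic
to this discretisation and is asserted as such in the tests, not "fixed").
The bending loss of a predicted boundary map is the mean BE over all
vertices of all contours traced from the map binarized at 0.5 (contours
shorter than 8 vertices are ignored as noise).

### Network

A shared encoder of four stages — each two residual sub-blocks
(conv–BN–ReLU–conv–BN–SE-attention, with a conv–BN side path, fused by
addition) followed by 2×2 max-pooling — feeds two parallel decoders. Each
decoder stage upsamples by a 2×2 transposed convolution, concatenates the
matching encoder skip (the first three encoder stages skip into the last
three decoder stages), and applies a searchable block: dilated conv →
depthwise-separable conv → tail (SE-attention or 3×3 stride-1 max-pool).
After every stage the boundary feature is reduced by a 1×1 convolution and a
sigmoid to a single-channel gate that multiplies the mask feature
element-wise. The "fusion by matrix multiplication" of the source
architecture is realised as this Hadamard gate: a literal matrix product is
shape-inconsistent across the multi-channel stages, and the 1×1-conv+sigmoid
placed before fusion makes a multiplicative gate the coherent reading.
1×1-conv+sigmoid heads emit mask and boundary probabilities.

Decoder architecture search is train-and-compare over the Cartesian grid
(dilated kernel {3,5}) × (dilation {1,2,3}) × (depthwise kernel {3,5}) ×
(tail {SE, max-pool}) = 24 candidates, one shared spec for all four stages
of the searched branch while the partner branch keeps its default; the
winner is the maximum validation Dice, ties broken by fewer parameters,
then enumeration order. The default specs are the reported outcomes of that
search: dilated 3×3 (d=2), depthwise-separable 3×3, SE tail for the mask
decoder and max-pool 3×3 (s=1) tail for the boundary decoder.

### Objective

    L = α·BCE(mask) + β·Dice(mask) + γ·L_Bend(boundary),   α, β, γ = 0.4, 0.3, 0.3

is the printed composite ("literal" mode). Read literally the boundary
branch receives no pixel supervision and collapses to empty predictions, so
the default "supervised" mode adds α·BCE + β·Dice against the boundary
ground truth on the boundary branch. During architecture search the mask
branch instead uses 0.3·BCE + 0.7·Dice. Dice uses the squared-sum
denominator with a shared smoothing ε = 1e−6 in numerator and denominator
(so an exactly-empty prediction of an empty ground truth costs 0); BCE
clamps predictions to [1e−7, 1−1e−7].

Contour tracing is not differentiable. The default gradient path multiplies
each vertex's BE by the predicted probability at that pixel, so the loss
pushes boundary probability down precisely at high-curvature vertices; the
plain scalar (no gradient) is also available.

## Numerical choices

* **Reversal cap.** A turning angle of π zeroes the curvature denominator;
  k is capped at K_MAX = 1e3 with a warning. Inside the *differentiable*
  loss path the cap is 2·tan(67.5°) ≈ 4.83 instead: the sharpest turning
  angle an 8-connected grid contour can legitimately make is 135°, so
  anything above that level is a one-pixel spur artifact, and letting such
  vertices carry BE ≈ 5·10⁵ poisons Adam's second moments and freezes the
  boundary branch.
* **Contour tracing** is Moore-neighbour border following with Jacob's
  stopping criterion, 8-connected foreground, outer borders only (nuclei are
  simply connected); 0-based (row, col) coordinates.
* **AJI order.** The matching order the AJI formula leaves open is: ground
  truth in ascending label order, ties on the best Jaccard index toward the
  lower prediction label; a best match with zero intersection consumes no
  prediction.
* **Empty-map conventions.** Identical empty maps score AJI = Dice = PQ = 1;
  one-sided-empty maps score 0.
* **Instance recovery** is seed-and-grow: seeds are 8-connected components
  of (mask ≥ 0.5) ∧ (boundary < 0.5), debris under 10 px dropped, then
  marker-based watershed on the negated mask probability constrained to the
  mask, so boundary-band pixels are not lost from instance areas (AJI and PQ
  are area-sensitive). Defaults t_mask = t_boundary = 0.5.
* **Curriculum** is realised as per-epoch tier ordering: every epoch
  presents simple-tier batches first, then normal, then difficult (shuffled
  within tier). Curriculum on/off therefore consumes identical sample sets
  and differs only in order.

## Synthetic scenes

The generator emulates cluster crops from cytology slides: 3–6 elliptical
nuclei (major semi-axis 5–11 px at 64×64, axis ratio 0.6–1.0) over a darker
background with a dim cytoplasm halo (intensity levels 0.75 / 0.35 / 0.12,
Gaussian noise σ = 0.03), with exact instance, mask and 2-px boundary ground
truth (1-px boundaries vanish under the 4-stage encoder's downsampling).
Three tiers mirror the simple/normal/difficult cluster taxonomy of the
corpus the method was built for (proportions 200:1500:95 when a dataset is
scaled): *simple* scenes are pairwise disjoint, *normal* allows ellipse IoU
≤ 0.15, *difficult* clusters centers and allows IoU ≤ 0.40. Overlap is
resolved by draw order — instance labels are visible regions, so instances
partition the foreground and touching nuclei share a boundary but never a
pixel (a later nucleus may not hide more than 65 % of an earlier one).
Over difficult-tier scenes ≥ 90 % contain at least one touching pair, the
regime the bending loss targets.

What the generator does **not** model: staining variation and chromatin
texture, out-of-focus blur, cytoplasm boundaries, debris and inflammatory
cells, and non-elliptical nucleus shapes. Passing tests on these scenes
demonstrates the correctness of the losses, metrics and pipeline mechanics
and the feasibility of desk-scale training; they say nothing quantitative
about performance on clinical micrographs.

## Desk-scale study conditions

Everything runs on one CPU. The network is built on a small reverse-mode
automatic-differentiation engine over numpy arrays (`blossddnet.nn`),
written for this package; convolutions are im2col + BLAS matmul. Training
follows the published recipe where stated — batch size 8 and Adam with
learning rate 1e−4 are the `TrainConfig` defaults, and 448×448 inputs
remain available through configuration — but the *study conditions* used by
the tests and the acceptance script are desk-scale choices: 64×64 scenes,
base width 8–16 channels (the `ModelConfig` default stays at the U-Net
convention of 64), SE reduction 4 at narrow widths (reduction 16 would
leave 1-unit bottlenecks), learning rate 3e−3 for runs of ~60–200 Adam
steps, and 8–10 epochs on 24–50 scenes. The capacity check overfits one
scene with the literal (printed) objective; under the supervised objective
even a perfect fit retains an irreducible γ·L_Bend ≈ 0.07–0.09 floor from
the rasterization kinks of a 64×64 ground-truth ring, which measures
rasterization, not capacity.

## Known limitations

* The prob-weighted bending gradient can only *remove* boundary pixels.
  Contour vertices are ~30× sparser than image pixels, so per-vertex
  gradients outweigh the per-pixel BCE/Dice restoring force, and the term
  tends to erode the supervised boundary band toward an attractor just
  below the 0.5 binarization threshold; a warm-up does not remove the
  effect. In the paired ablation at the desk conditions the bending arm
  wins the AJI direction in 2 of 3 seeds, but the regime is noisy (one
  no-bend seed collapses outright) and a larger 48-scene pilot showed the
  reverse ordering. The desk-scale ablation demonstrates the machinery —
  shared data, paired seeds, identical initialisation — not a robust
  replication of the full-scale effect size.
* The bending loss is scale-sensitive through the vertex/pixel ratio, so
  its effective strength at 64×64 differs from 448×448 at equal γ.
* AJI/PQ at desk scale are dominated by whether the boundary branch crosses
  the 0.5 post-processing threshold at contact lines; small models at short
  training budgets sit close to that edge, which makes the instance metrics
  high-variance across seeds. For unlucky seeds a short run can collapse
  into the all-background optimum of the pixel losses outright.
* Checkpoints store the full weight set and configuration; optimizer state
  is not checkpointed, so a resumed run continues the epoch counter but
  restarts Adam's moments.
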