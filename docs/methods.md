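# Methods

## Problem and model

`gaitgcn` classifies walking sequences recorded as 25-joint Kinect-V2
skeleton trajectories into one normal and five pathological gait classes
(antalgic, lurch, steppage, stiff-legged, Trendelenburg).  The classifier
is a multiple-input-branch spatiotemporal graph convolutional network
(MIB ST-GCN) with spatiotemporal joint attention, and its decisions are
explained with class-activation maps projected onto the skeleton.

### Skeleton graph and adjacency

The skeleton is an undirected tree over V = 25 joints rooted at SpineMid.
From the binary adjacency A the network uses the symmetrically normalized
self-loop adjacency

    A_norm = D̃^(-1/2) (A + I) D̃^(-1/2),

whose largest eigenvalue is 1, so repeated graph convolutions neither
amplify nor collapse the signal.  For the spatial convolution the support
of Ã = A + I is split into K partitions that receive separate weights:

* `uni-label` (K = 1): all connections share one weight;
* `distance` (K = 2): self-loops vs. first-order neighbors;
* `spatial-configuration` (K = 3, default): self, centripetal (source
  joint not farther from the body center than the target, by BFS hop
  distance; ties break centripetal) and centrifugal (source farther).

Each partition matrix is Ã masked to its members and normalized by its
own column degrees; entries whose partition degree is zero stay zero.
Every nonzero of Ã belongs to exactly one partition (a tested
invariant).  An optional learnable edge-importance mask on the
adjacency support is available but off by default.

### Input feature streams

From a T×V×3 trajectory three 6-channel streams are computed:

* **joint** — absolute coordinates and coordinates relative to the
  center joint, r_i = x_i − x_c;
* **velocity** — one-frame and two-frame displacements
  v1(t) = x(t+1) − x(t), v2(t) = x(t+2) − x(t), zero-padded at the tail
  so every stream shares the same T;
* **bone** — the vector from each joint to its tree parent,
  b_i = x_i − x_parent(i), plus the componentwise direction angles
  arccos(b_i/‖b_i‖), clamped to [−1, 1] before the arccos.  The root
  joint gets a zero bone and the neutral angle π/2, avoiding NaNs.

Both velocity orders are kept, concatenated, which makes every stream
6-channel and the three branches architecturally symmetric.

### Network

Each selected branch is encoded by: input batch normalization over the
flattened joint·channel axis → an initial ST-GCN block (6 → W channels,
no attention) → three attention-equipped blocks (W → W/2 → W/2 → W, a
bottleneck that keeps the parameter count down).  Branch outputs are
fused by channel concatenation and passed through a two-block mainstream
(first temporal layer of each block strided by 2, so T shrinks 4×),
then global average pooling over frames and joints and a fully
connected classifier.

An ST-GCN block is: partitioned spatial graph convolution
(out = Σ_k A_k X W_k + b, frame-wise) → batchnorm/ReLU →
`block_depth` = 2 temporal convolutions (kernel 9 × 1 along the frame
axis, symmetric zero padding) each with batchnorm → spatiotemporal
joint attention (where enabled) → residual addition from the block
input (1×1-projected when channels or stride differ) → ReLU.

Temporal convolutions are depthwise-separable by default: a per-channel
k-tap filter followed by a 1×1 channel mix, reducing the weight count
from k·C_in·C_out to k·C_in + C_in·C_out (4672 vs 36864 at C = 64,
k = 9); a standard-convolution switch exists for comparison.

**Attention.**  The feature map (C×T×V) is mean-pooled over joints
(C×T) and over frames (C×V); the two pooled maps are concatenated along
the pooled axis, compacted to C/r channels (r = 4) by a shared linear
map with ReLU, then expanded back to C by two independent linear maps.
Sigmoid squashing yields per-channel frame scores and joint scores whose
channel-wise outer product gates the input.  The sigmoid/ReLU choice is
this package's; forcing both score sets to 1 reproduces the
attention-free network exactly (a tested ablation hook).  Attention sits
in the branch blocks only; a flag can enable it in the mainstream.

### Implementation note

The network, its gradients and the optimizers (Adam, momentum SGD) are
implemented directly on numpy arrays in `gaitgcn.nn`, with feature maps
held in (batch, frames, joints, channels) layout so that channel mixing,
joint aggregation and temporal windowing are contiguous BLAS operations.
Backward passes are hand-derived and verified against central-difference
gradients in double precision (tolerance 1e−7).  Temporal-convolution
input gradients are computed as a correlation of the (stride-upsampled)
output gradient with the flipped kernel.

## Synthetic gait simulator

No public pathological-gait recordings ship with the package; the
simulator provides a fully specified substitute.  The body is a chain of
rigid segments (so bone lengths are constant to machine precision at
zero noise, a tested invariant) driven by sinusoidal joint-angle
oscillators: hip flexion A_hip·sin ψ, knee flexion
A_knee·max(0, sin ψ)², ankle pitch, counter-phase arm swing, small
baseline trunk pitch/roll and pelvis bob/sway, on top of a constant
forward progression.  Left and right legs run half a cycle apart.  Phase
is parameterized through an explicit duty-factor map so the stance
portion of a leg's cycle can be compressed.

Class signatures, all scaled linearly by `severity` ∈ [0, 1]:

| class | injected deviation |
|---|---|
| antalgic | affected-side stance duty −55 %·s, hip amplitude −35 %·s |
| lurch | backward trunk pitch 0.40·s rad during affected stance |
| steppage | affected knee amplitude +140 %·s, foot drop 0.55·s rad in swing |
| stiff_legged | affected knee amplitude −85 %·s, lateral circumduction arc 0.40·s rad |
| trendelenburg | trunk roll 0.35·s rad and pelvic obliquity 0.35·s rad toward the affected side during its stance |

The head–neck chain and the hanging arms compensate 75 % of the trunk
inclination (vestibular head righting; arms hang under gravity), so
trunk pitch and roll read out at the shoulder girdle and pelvis rather
than being amplified down the longest levers — which is where
clinicians localize these compensations.  Amplitudes are clinically
plausible magnitudes of the corresponding deviations.  At severity 0 every class reduces exactly to
the normal gait for the same seed and anthropometry — the negative
control.  Per-subject anthropometry draws limb scale (σ = 6 %), cadence
(σ = 0.08 Hz around 0.9 Hz) and the affected side; per-trial randomness
is the cycle phase and isotropic Gaussian position noise (default
5 mm, Kinect-like jitter), added last.

What the simulator does **not** emulate: ground-contact constraints
(feet can pass through the floor plane), soft-tissue and tracking
artifacts with temporal correlation, multi-camera viewpoint geometry,
within-trial severity fluctuation, and the kinematic richness of real
pathology.  Passing the benchmark therefore shows that the pipeline
recovers class-defining spatiotemporal signatures under subject-wise
generalization — not that it reaches any particular accuracy on real
clinical data.

## Evaluation protocol

Evaluation is leave-one-subject-out (LOSO): one fold per subject,
testing on every trial of the held-out subject.  Reported accuracy is
the pooled sample accuracy (trace of the summed confusion matrix); the
per-fold accuracies and their unweighted mean are reported alongside,
since the two conventions differ when folds are unbalanced.

### The synthetic benchmark

The canonical experiment (in `gaitgcn.benchmark`, used by the test
suite and `scripts/acceptance.py`) simulates 8 subjects × 6 classes ×
10 trials at 64 frames, severity 0.7, 5 mm noise.  The benchmark model
is deliberately small — branch width 8 (bottleneck 4), mainstream
16 → 32, ~11 k parameters for three branches — trained with Adam
(lr 5·10⁻³, batch 16) for 10 epochs on random 32-frame temporal crops
(a cheap augmentation that also halves per-update cost); evaluation
uses the full 64 frames.  These sizes are the package's own choice for
a single-CPU numpy training loop; the wider default architecture
(branch width 64, mainstream 128 → 256) is available through
`ModelConfig` for larger studies.

With four branch combinations (three singles and the fused triple),
three seeds and a negative control, training every LOSO fold would mean
~100 fold-trainings per run of the suite.  The benchmark instead
estimates the LOSO mean from a fold subsample: each seed trains 2
deterministically chosen folds (`folds_per_seed`), giving 6
fold-accuracies per combination across 3 seeds, with the dataset
regenerated per seed so the spread reflects cohort and training
variation.  The full-LOSO path (`cross_validate`) remains the default
for the CLI `evaluate` and `ablate` verbs.

The severity-0 negative control trains the same model on a cohort whose
class labels are independent of the kinematics; its accuracy is
compared against the 1/6 chance level within a band of several binomial
standard errors (predictions across a fold are correlated, so the band
is deliberately generous).

## Class-activation maps

CAM is computed at the mainstream's final pre-pool feature map F
(post-attention — the features the classifier actually consumes):
M(t, v) = Σ_c w_c·F_c(t, v) with w the classifier column of the queried
class, rectified at zero and normalized to total mass 1.  Negative
evidence is discarded because the maps are read as positive saliency.
A map that is entirely non-positive degenerates to the uniform map with
a warning.  T' = T/4 at the final map; visualization maps frame indices
back by nearest-neighbor upsampling.  CAM is invariant to positive
rescaling of the classifier weights and to bias shifts (tested).

Two qualitative checks mirror clinical reading, both computed on
correctly classified held-out trials.  Where a class's evidence is
focal, CAM localizes sharply: steppage and stiff-legged maps place most
of their mass (≈ 0.7–0.95) on the eight leg joints, versus ≈ 0.3 for
normal gait.  Where the evidence is spatially global the statistic is
weaker: the Trendelenburg map's top joints are the upper trunk
(SpineShoulder, both shoulders, neck), but its *share* of mass on the
pelvis + shoulder girdle set does not reliably exceed the normal
class's — the simulated lateral lean translates every upper-body joint
by a similar amount, diluting the set's share toward the uniform
baseline, while the normal class's own evidence (verifying the trunk
is *not* leaning and the pelvis *not* dropping) sits exactly on the
trunk and pelvis.  The corresponding acceptance test asserts the
Trendelenburg-above-normal contrast and is expected to fail under the
synthetic conditions; it is kept as an honest record of where the
stylized simulator parts ways with qualitative observations on real
recordings.

## Numerical and design choices

* float32 forward/backward; statistics and losses accumulated in
  float64 where cheap.  Batch-norm eps 1e−5, momentum 0.1.
* Arccos arguments clamped to [−1, 1]; zero-length bones get angle π/2.
* Prediction ties break to the lowest class index (argmax convention).
* Undefined trailing velocity frames are zero-padded, not truncated.
* Model initialization is fully determined by `ModelConfig.seed`; each
  layer slot draws from its own spawned seed stream, so toggling
  attention does not reshuffle the other layers' initial weights (this
  is what makes the attention-identity ablation bit-exact).
* Optimizer default is Adam with a constant learning rate; momentum SGD
  with step decay is available.  Adam was chosen because the benchmark
  budget allows only ~10 epochs.
* Multi-body NTU frames keep the body with the highest summed tracking
  state; body-less frames repeat the last observed frame with a logged
  warning.

## Known limitations

* The numpy training loop is single-threaded BLAS-bound; wall-clock cost
  grows quickly with widths, so the wide default architecture is not
  practical to train in the bundled benchmark harness.
* The simulator's stylized oscillators produce classes that are easier
  to separate than real pathological gait at matched severity; absolute
  benchmark accuracies should not be read as clinical performance.
* Only the first tracked body of an NTU file is used; the parser is not
  a general multi-body reader.
* Fold subsampling trades LOSO-estimate variance for runtime; for a
  publication-grade number on a real dataset, run `cross_validate`
  over all folds.
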