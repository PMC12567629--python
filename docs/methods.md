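# Methods

`irkd` studies whether image representations (IRs) of wearable-sensor time
series — Gramian angular fields (GAFs) and persistence images (PIs) — carry
knowledge that a compact 1-D convolutional student can absorb through
knowledge distillation (KD), even though the deployed student only ever
sees raw series. This note records the models, the choices behind them,
and what the synthetic benchmark does and does not establish.

## Image representations

**Gramian angular field.** A window channel is min–max rescaled to
[-1, 1], each value mapped to a polar angle φ_t = arccos(x_t), and the
image formed as GASF[i,j] = cos(φ_i + φ_j) (symmetric; diagonal
cos 2φ_i = 2x_i² − 1, so per-step magnitude survives on the diagonal) or
GADF[i,j] = sin(φ_i − φ_j) (anti-symmetric, zero diagonal). The identity
cos(φ_i + φ_j) = x_i x_j − √(1−x_i²)√(1−x_j²) is enforced to 1e−12 in the
tests and is the correctness oracle for the construction. GASF is the
default variant. The series is linearly resampled to the target
resolution *before* forming the matrix (cheaper than rasterizing an
n × n matrix and resizing; an image-resize mode exists behind
`gaf_resize="image"`), and the min–max rescale is applied *after*
resampling so the resampled series attains ±1 exactly — rescaling first
would leave interpolated values strictly inside the interval. Rescaling is per window and per channel, which
makes the encoding invariant to per-window amplitude offsets; a constant
channel maps to the zero series (φ = π/2 everywhere), deterministically.

**Persistence image.** Each channel is delay-embedded
(point p = (x_p, x_{p+d}, …, x_{p+(m−1)d}); defaults m = 3, d = 2 — the
literature rarely states these, so they are explicit configuration), the
cloud reduced to at most `max_points = 64` points by greedy farthest-point
subsampling, and Vietoris–Rips persistence computed by the built-in
backend: H0 from the minimum spanning tree, H1 by GF(2) boundary-matrix
reduction of triangle columns represented as big-integer bitmasks,
truncated at the enclosing radius (beyond which the complex is a cone, so
no H1 information is lost). The backend is validated against an
exhaustive dense reduction of the full simplex stream on small clouds and
against the analytic circle (birth = adjacent chord, death = √3 r).
Finite (birth, death) pairs move to (birth, persistence) coordinates;
essential classes carry no finite persistence coordinate and are dropped.
The raster is a persistence-weighted Gaussian sum (w = pers/max pers,
`weight="constant"` available) evaluated at cell centers of a square
grid over `grid_range`², normalized by its maximum (an empty diagram stays
zero). H1 is the default homology dimension — loops are the signature of
quasi-periodicity; H0 is available. Default bandwidths follow the two
regimes the pipeline is tuned for: σ = 0.25 with grid [−10, 10] for
high-amplitude wrist-accelerometer-like data, σ = 0.015 with [−1, 1] for
normalized multi-sensor data. One diagram per channel (a joint
multichannel embedding is a plausible alternative; per-channel keeps the
image layout aligned with the GAF path).

## Networks

Both teachers and the student are pre-activation WideResNets: a width-16
stem convolution, three groups of (depth − 4)/6 residual blocks at widths
16k/32k/64k, stride 2 entering groups 2 and 3, a size-1 projection
shortcut applied to the pre-activated input where shapes change,
BN → ReLU → global average pooling → one biased linear classifier.
Convolutions are bias-free with kernel size 3 (3×3 in 2-D); no dropout.
Time-series models are 1-D, image models 2-D, otherwise identical — which
is what makes "WRN16-1 teacher vs WRN16-1 student" a pure modality
comparison. This reconstruction is validated by exact parameter counts:
at 3 input channels and 14 classes the 1-D family is 0.06/0.54/0.13/1.12 M
(16-1/16-3/28-1/28-3) and the 2-D family 0.18/1.55/0.37/3.29 M, giving
student/teacher-pair compression ratios of 25.93, 2.94, 12.36 and 1.39 %.
Because of global average pooling, input length never changes the count.
A multiply–accumulate report is provided for orientation but printed FLOP
conventions vary, so it is informational only.

The engine underneath is a compact NumPy implementation (im2col + GEMM
convolutions in channels-last layout, fused batch normalization, SGD with
momentum 0.9 and coupled weight decay 1e−4, single precision). Backward
passes are verified by exact directional finite differences for the
linear layers and against a float64 transcription of the batch-norm
gradient.

## Distillation

The objective is (1−λ)·CE + λ·[(1−α)·KD_T1 + α·KD_T2] with
KD = τ² KL(softmax(l_T/τ) ‖ softmax(l_S/τ)); mean reduction throughout so
values are batch-size invariant. The teacher is the KL reference
distribution (the classic formulation; the reverse direction is a
defensible alternative but is not implemented). Teacher logits are
computed once per dataset in evaluation mode with no gradient flow —
teachers are frozen, and the tests assert their parameters and buffers
are bit-identical after a KD run. α = 0.5 gives the equal-weight (AVER)
configuration; α = 0 reduces exactly to single-teacher KD. Defaults
τ = 4, λ = 0.7 (λ = 0.99 suits the normalized multi-sensor regime);
α is always explicit in experiment configs because the preferred value is
regime-dependent (0.3 vs 0.7), and the sweep utility exists to measure it.

The learning rate starts at 0.05, is cut by 0.2 at epoch 10, and by 0.1
at every third of the epoch budget (`late_every = epochs // 3`,
configurable). Annealing initialization trains the student architecture
from scratch (CE only, same schedule and budget — the pretraining length
is not separately tuned) and starts the KD run from those weights; with
annealing disabled the student starts from the seeded He-normal
initializer. "Best" checkpoints take the highest evaluation accuracy,
earliest epoch on ties.

## Evaluation

Corruption applies one contiguous zero-filled segment of round(p·T) steps
at a seeded uniform start (zero is the neutral value of the normalized
signal; the corruption levels are treated as dimensionless, in the units
of the stored signal) plus i.i.d. Gaussian noise of SD s everywhere, test
time only: Level 1 = (0.15, 0.06), Level 2 = (0.22, 0.09),
Level 3 = (0.30, 0.12). The corruption seed is fixed per comparison so
every method sees the identical corrupted test set.

Weight-space (mode-connectivity) curves evaluate ψ((1−η)x_a + ηx_b) over
η ∈ [−1, 2]. Interpolated batch-norm running statistics are meaningless,
so by default they are re-estimated with one pass over the training
inputs (plain average of per-batch statistics); a no-re-estimation mode
restores endpoint statistics exactly and is what the endpoint-equality
tests use.

The V-score pathway is t-SNE (2-D, seeded) → k-means (k = number of
classes, seeded) → V-measure against the true labels. The clustering step
is one concrete reading of "V-score of the feature space"; any pipeline
that produces hard clusters would slot in.

Macro-averaged F1 is reported (rather than weighted) because class
imbalance is the reason to look past accuracy in the first place.

## Synthetic benchmark

Real wrist-accelerometer corpora are private or external, so the
benchmark generates class-structured quasi-periodic signals: per class a
fundamental frequency and harmonic weight profile, per subject a
multiplicative frequency/amplitude jitter (drawn once per subject),
per window random channel phases and Gaussian noise. The desk-scale
study conditions are 5 classes at 0.8/1.3/2.0/2.9/4.0 Hz with distinct
harmonic profiles, 3 channels, 500-sample windows at 33 Hz, noise SD 0.3,
subject jitter 0.1, 16 training subjects × 200 windows/class and 4 fresh
held-out subjects × 50 windows/class — held-out subjects are new draws,
as a subject-wise split of real data would give. Teachers and students
are WRN16-1, trained 30 epochs at batch 64 over three seeds; the 2-D
teacher consumes GASF images at 32 × 32 resolution (the problem sizes of
this benchmark, including the image resolution and epoch budget, are the
package's scaled-down study conditions).

What passing shows: the pipeline trains end to end; multi-teacher KD with
annealing does not fall below scratch training; the annealed student
remains linearly connected (in the mode-connectivity sense) to its
initializer while independent scratch solutions are separated by a
barrier; accuracy degrades monotonically with corruption level. What it
does not show: real-data effect sizes. The synthetic classes are far more
separable than 14 real activities — students saturate near 100 % on clean
data — so accuracy *gaps* between KD variants here carry no information
about real corpora; the generator also omits gravity components,
orientation drift and non-stationary cadence.

## Numerical notes and limitations

- Determinism: every stochastic step (generator, initialization, batch
  order, corruption, t-SNE/k-means) flows from explicit integer seeds;
  runs are bit-reproducible on a fixed BLAS build.
- The GF(2) reduction is exact; ties in edge lengths are resolved by the
  lexicographic filtration order, so zero-persistence H1 artifacts are
  possible and are dropped from diagrams.
- Degenerate inputs: constant series → zero GAF input series; empty
  diagrams → zero PIs; p·T rounding to zero → no missing segment.
- The PI path is the CPU bottleneck (Rips on one 64-point cloud ≈ 0.1 s);
  batch conversion caches by window content, and the farthest-point
  budget is the knob that trades topological fidelity for speed.
- Cross-architecture distillation (different student families) and
  feature-space distillation terms are out of scope.
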