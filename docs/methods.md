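# Methods

## Scope and model

`brixnet` implements a complete hyperspectral regression pipeline for fruit
soluble-solids content (SSC): reflectance calibration, band-ratio ROI
masking, five-image rotation/mirror augmentation, [0, 1] normalisation,
pixel-centred patch-pair extraction, dual-branch convolutional networks with
cross-layer channel/spatial attention, Gaussian-process Bayesian
hyperparameter optimisation (BOA), and chemometric evaluation (R², RMSE,
RPD).  Because no public dataset accompanies the method, a synthetic scene
generator is a first-class module: it produces raw/white/black count cubes
with a known SSC signal so that every stage, including the networks, can be
tested against ground truth.

## Attention operators

Channel attention (spectral branch): the layer-`l` feature map `F^l`
(H×W×C) is pooled to two C-vectors (global average, global max), each pushed
through one shared perceptron `MLP = W₂·ReLU(W₁·)` with bottleneck `C/r`
(`r = 8`, one hidden unit minimum).  The previous layer's attention vector
`M^{l−1}` enters through a dense projection `W₀` (previous channel count →
current), batch normalisation and ReLU, then the same shared MLP.  The three
terms are combined with learnable scalars λ₁, λ₂, λ₃ (initialised 1.0) and
squashed by a sigmoid; the result both rescales `F^l` channel-wise and is
handed to layer `l+1`.  Spatial attention (spatial branch) pools over the
channel axis instead, concatenates [avg, max, `W_l`(previous map)] and fuses
them with a single 7×7 convolution to one sigmoid channel; when pooling has
changed the resolution between layers, the previous map is adaptively
max-pooled to the current size before `W_l` (a 3×3, 1→1 convolution).

Decisions taken where the design was open:

- **First layer**: no previous attention exists, so the λ₃/`W₀` (resp.
  `W_l`) pathway is absent there rather than fed a dummy all-ones state;
  layer 1 is parameter-free on that path.
- **Shared vs separate MLP**: the projection of the previous weights reuses
  the same shared MLP as the two pooled branches.
- **Global max pooling** is used in the channel module (not a regional
  variant); λ scalars are per-layer, not shared across layers.
- **Frozen attention**: every attention block can be frozen at exactly 1, in
  which case the network's forward pass is bitwise identical to a plain CNN
  with the same convolution parameters (initialisation streams are keyed by
  (seed, branch, layer, component), so conv weights do not depend on whether
  attention blocks exist).

## Network assembly and training

The spectral branch consumes 3×3×B patches: three stride-1 kernel-3
convolutions, each followed by batch norm, activation, channel attention and
2/2 max pooling (pooling passes through once the map is smaller than the
window — after the first pool the spectral map is 1×1).  The spatial branch
consumes 31×31×B patches with kernels 3/5/7 and 3×3-stride-2 max pooling,
spatial attention per block.  Both branches end in global average pooling;
the concatenated vector feeds two FC layers and a linear output neuron.
Training minimises MSE on labels min-max scaled by the calibration set;
per-fruit predictions are the mean of per-patch predictions mapped back to
°Brix.  The published tuned configurations (filters 32/64/128 and FC 83/51
for the spectral network; 64/128/56 and 125/93 for the spatial network;
FC 86/86 for the fused network; AdaBound/RMSProp optimizers) are available
as the `paper` budget profile.

Two numerical points matter in practice:

- **Batch-norm statistics**: the running means/variances kept during
  optimisation reflect only the last few minibatches; using them directly
  shifted held-out predictions by a roughly constant ~0.5–0.8 °Brix.  After
  the final epoch the statistics are therefore re-estimated by averaging
  batch moments over one full pass of the training set.  The EMA is also
  seeded with the first batch's moments rather than (0, 1).
- **Precision**: layers accept a dtype; float64 is the default (used by all
  small-tensor oracle tests), float32 is used for the end-to-end experiment
  drivers, roughly halving time and memory.

## Synthetic scenes

Each scene is a centred disk (radius 0.35·min(rows, cols)) of fruit on a dark
background.  Fruit reflectance = an apple-like sigmoidal baseline (pigment
absorption below ~640 nm, bright NIR plateau) + three broad Gaussian bumps
(centres 500/700/900 nm, s.d. tied to `baseline_smoothness`, amplitudes
~N(0, 0.02²) clipped at ±0.05, redrawn per fruit) − Gaussian absorption dips
(FWHM 30 nm) at the informative bands (defaults 840 and 960 nm, near the
sugar/water NIR features) whose depth is `absorption_slope × (SSC − SSC_min)`
with slope 0.02 reflectance/°Brix.  SSC is drawn from Normal(11.76, 1.92²)
°Brix, rejection-clipped to [7.2, 18.1], matching the reference statistics of
a 570-apple survey.  Counts are produced through a smooth lamp-gain spectrum,
a smooth multiplicative illumination field (CV 5 %), a dark-current offset,
and additive sensor noise (s.d. 0.01 reflectance equivalent); the white
reference sees the nominal (flat) field so that illumination variation
survives calibration, as it does with a separately acquired panel.  The
background's 715/525 nm ratio is ≈1.1 and the fruit's ≈2.7, so the 1.6
threshold separates them with margin even at the clipped extremes of the
baseline randomness; with noise disabled the ratio mask equals the true disk
exactly.

What the generator does *not* emulate: radiative-transfer effects
(curvature/limb darkening, specular highlights), instrument striping or
smile, variety-specific spectral libraries, and any spatial heterogeneity of
SSC within a fruit.  Passing the recovery test therefore shows that the
pipeline's machinery — masking, patching, attention networks, training,
aggregation, metrics — correctly extracts a linear absorption signal under
multiplicative illumination and additive noise; it does not certify accuracy
on real fruit.

## Experiment scales

The desk-scale recovery experiment uses 200 cubes of 64×64 px × 32 bands,
8 patch pairs per fruit for training (32 per fruit at prediction, since
patch-noise averaging at inference is free), a small MA-CNN
(filters 8/16/32 spectral, 8/16/16 spatial, FC 32/16), Adam at 3·10⁻³,
batch 32, 12 epochs, and a random 5:1 fruit-level split.  These sizes were
chosen so a complete 3-network × 5-seed ablation runs in minutes on one CPU
core while leaving the learning problem non-trivial (held-out R² ≈ 0.95–0.98,
residual ≈ 0.3 °Brix against a population s.d. of 1.9).  The ablation shares
one generated dataset across seeds; each seed redraws split, patch sampling,
initialisation and batch order.

## Bayesian optimisation

Configurations are encoded into the unit hypercube: integer ranges min-max
scaled, learning rates in log₁₀, categoricals one-hot (treated as continuous
inside the GP, decoded by argmax).  The surrogate is a Matérn-5/2 GP
(jitter 10⁻⁶, maximum-likelihood length scale); acquisition is probability
of improvement with ξ = 0.01 over a 512-point random candidate pool, with
candidates snapped onto the valid grid before scoring so PI is evaluated at
points that decode to themselves.  The first 5 points are scrambled-Sobol.
A failing objective records −∞ and the loop continues.  Among iterations
tied at the best objective, the one with the lowest cross-validation fold
variance wins (stability as spread), earliest on remaining ties.  The
five-fold objective always partitions *fruit* ids, never patches, and
augmentation is applied to training folds only.

## Metric conventions

Standard deviations are sample (n−1) throughout, including the SD inside
RPD, computed on the same set as the RMSE.  R² is scale-invariant, so one
value serves both the °Brix and min-max-scaled axes; RMSE is reported on
both axes because absolute errors on the two scales differ by the
calibration range.  With the sample-SD convention the least-squares identity
is `RPD = √(n/(n−1)) / √(1−R²)` (the familiar `1/√(1−R²)` only
asymptotically).  The 5:1 split takes `round(n·5/6)` calibration fruit
(570 → 475/95).  The band-ratio threshold comparison is inclusive (≥ 1.6,
"minimum threshold"), ratio bands are found by nearest-wavelength lookup,
and stray above-threshold pixels are removed by keeping the largest
8-connected component.

## Degenerate inputs and tie-breaks

Calibration pixels where white = black are set to 0 and counted in a
warning; a constant cube normalises to all zeros with a warning; an empty
ratio mask raises a dedicated "no ROI found" error; rotation fills exposed
corners with the per-band median (the background level); patches at the
image border are reflect-padded; cropping pads the mask with False (padding
never invents fruit pixels).  Non-finite training loss raises an error
naming the learning rate.  Max-pool argmax ties resolve to the first index.

## Verification approach and known limitations

Every layer's reverse-mode gradient is checked against central finite
differences.  Two artefacts of non-smoothness are handled explicitly rather
than hidden: (i) finite differences straddle ReLU kinks, and at zero-bias
initialisation a cross-layer pathway can sit exactly at a kink (a
batch-constant attention vector is mapped to exactly 0 by batch norm), so
gradient checks nudge biases off zero first; (ii) permuting pixels or
channels reorders floating-point summation inside mean pooling, so
permutation invariance is asserted at 10⁻¹², not bitwise (the max path is
exact).  The sigmoid saturates to exactly 0/1 in floating point beyond
|x| ≈ 37, so the open-interval range property is asserted for moderate
activations and the closed interval for extreme ones.  Training is
deterministic given a seed on a fixed BLAS configuration; across different
BLAS builds the last digits may differ.
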