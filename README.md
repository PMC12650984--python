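# brixnet

Nondestructive estimation of fruit soluble-solids content (SSC, °Brix) from
visible/near-infrared hyperspectral image cubes, using dual-branch
convolutional networks with **channel** and **spatial attention** whose
attention states propagate across layers, plus Gaussian-process Bayesian
hyperparameter optimisation and chemometric evaluation.  The package targets
researchers in food-quality spectroscopy who want a fully scripted, seedable
version of this pipeline that runs end to end on a laptop — including a
synthetic scene generator, so no instrument data is required to exercise or
test any stage.

## The method

An acquisition consists of a raw count cube `I_raw` (rows × cols × bands), a
white reference `I_white` (≈99.9 % reflectance panel) and a black reference
`I_black` (closed shutter).  Processing proceeds as:

1. **Reflectance calibration** — `I_cal = (I_raw − I_black) / (I_white − I_black)`.
2. **ROI extraction** — the fruit mask is the set of pixels whose two-band
   reflectance ratio at 715.16 nm / 525.54 nm is at least 1.6 (largest
   connected component kept).
3. **Augmentation** — each image becomes five: the original, three random
   rotations drawn from [0°, 30°], [150°, 180°] and [180°, 210°], and a
   left-right mirror.  Augmentation is applied inside training folds only.
4. **Normalisation and patching** — cubes are min-max scaled to [0, 1] and,
   at each sampled ROI pixel, a 3×3×B *spectral* patch and a 31×31×B
   *spatial* patch are cut around the same centre.
5. **Networks** — the spectral branch (CA-CNN) applies channel attention
   after each of three convolution blocks:

   `M_c^l = σ(λ₁·MLP(AvgPool(F^l)) + λ₂·MLP(MaxPool(F^l)) + λ₃·MLP(W₀(M_c^{l−1})))`

   with a shared two-layer perceptron and learnable fusion scalars λ₁..λ₃
   (initialised at 1).  The spatial branch (SA-CNN) applies spatial
   attention per block:

   `M_s^l = σ(W_s[AvgPool_c(F^l), MaxPool_c(F^l), W_l(M_s^{l−1})])`

   The MA-CNN concatenates both branch feature vectors and regresses SSC
   through two fully connected layers with a linear output.
6. **Hyperparameter search** — a Gaussian-process surrogate (Matérn 5/2)
   with the probability-of-improvement acquisition proposes configurations
   (filter counts, FC widths, learning rate, batch size, activation,
   optimizer); the objective is mean validation R² of a fruit-level
   five-fold cross-validation.
7. **Evaluation** — `R² = 1 − SSres/SStot`, `RMSE = √(SSres/n)`,
   `RPD = SD/RMSE` on a random 5:1 calibration/prediction split
   (570 fruit → 475/95).

The networks (convolutions, batch norm, pooling, backprop, SGD / Adam /
RMSProp / AdaBound) are implemented in NumPy inside `brixnet.nn`; gradient
correctness is verified against finite differences in the test suite.

## Worked example

```python
from brixnet.experiments import run_recovery

out = run_recovery(kind="ma-cnn", n_cubes=200, seed=1)
r = out["report"]
print(f"R2={r.r2:.4f}  RMSE={r.rmse_brix:.3f} °Brix  RPD={r.rpd:.2f}  n={r.n}")
```

This simulates 200 labelled fruit cubes (64×64 px, 32 bands, SSC drawn from
a Normal(11.76, 1.92²) °Brix population clipped to [7.2, 18.1]), preprocesses
them, trains a small MA-CNN on the 5/6 calibration split and evaluates the
held-out fruit.  On one CPU core it prints

```
R2=0.9731  RMSE=0.270 °Brix  RPD=6.19  n=33
```

i.e. the network recovers 97 % of the held-out SSC variance with a residual
error of about 0.3 °Brix — an RPD well above the ≈2.5 conventionally required
of a usable quantitative calibration.

The same pipeline is scriptable from the shell:

```bash
brixnet all --config run.yaml --seed 1     # simulate → ... → evaluate
brixnet tune --iters 10 --folds 3          # BOA over the MA-CNN search space
brixnet ablate --seeds 1,2,3               # MA vs CA vs SA comparison
```

Each run directory carries a `manifest.json` (config hash, seeds, versions);
re-running the same desk-scale config reproduces every report byte for byte.

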