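# scintidenoise

Denoising of low-dose planar bone-scintigraphy images with a
channel-attention convolutional autoencoder, together with a Poisson-count
phantom simulator and a quantitative evaluation stack.

## The problem

Bone scintigraphy images a gamma-emitting bone tracer (e.g. 99mTc-HDP);
pixel values are photon counts, so reducing the administered activity — or
equivalently the acquisition time — reduces counts and floods the image
with Poisson noise. Because the expected count in every pixel scales
linearly with acquisition time, shortening the acquisition to a fraction
*f* of the standard duration is a faithful physical proxy for an *f*-fold
dose reduction. This package targets exactly that setting: given paired
images of the same patient, region and session acquired at 30–90% and at
100% of the standard time, learn a mapping from the noisy low-dose image
to the full-dose reference.

Clinical paired data of this kind are not freely available, so the package
ships a first-class simulator: procedural pelvis/thorax activity maps
(expected counts per pixel at full acquisition), Poisson acquisition, and
binomial thinning — keeping each recorded photon with probability *f* —
which is the exact count-level realization of a shortened acquisition and
yields low-dose images that share anatomy and correlated noise with their
full-dose parent.

## The model and objective

The denoiser is a convolutional autoencoder. Each encoder stage applies a
multi-scale feature block (parallel 3×3 and 5×5 convolutions, fused 1×1,
Group Normalization, ReLU), squeeze-style channel attention
(GAP → FC → ReLU → FC → sigmoid gates), and a stride-2 convolution. A 1×1
bottleneck halves the channels; each decoder stage is a transposed
convolution (kernel 4, stride 2) followed by an efficient residual block
(depthwise 3×3 + pointwise 1×1 inside an identity skip); a final 3×3
convolution and sigmoid produce the denoised image. Training minimizes

    L_total = λ·L_MSE + (1−λ)·(1 − SSIM(X_output, X_target)),   λ = 0.7

with Adam (lr 10⁻³, batch 16, ≤2000 iterations by default) and early
stopping on the validation loss (patience 50 evaluations). Evaluation
reports PSNR = 10·log₁₀(I²_max/MSE) (I_max = 255) and Gaussian-window SSIM
(11×11, σ = 1.5) per dose level, with paired t-tests and TOST equivalence
testing (±δ bounds, default ±1).

Everything — including the convolution/attention/normalization layers and
their gradients — runs on a small numpy reverse-mode autodiff core
(`scintidenoise.nn`), so the package has no deep-learning framework
dependency and trains on a single CPU.

## Worked example

```python
from scintidenoise.pipeline import run_scaled_study

study = run_scaled_study(seed=1, work_dir="scratch/demo")
print(study["summary_frame"].to_string(index=False))
```

This simulates 40 subjects (two regions, two views, seven low-dose
fractions; 1120 pairs at 64×64), trains for 500 iterations, and evaluates
the held-out test subjects. Output from that exact invocation:

```
 dose_percent  ssim_original  ssim_denoised  ssim_p_value  psnr_original  psnr_denoised  psnr_p_value  n
           30       0.664270       0.736468  3.076128e-15      18.881748      22.169983  1.291514e-11 16
           40       0.741810       0.789282  5.283980e-13      20.328179      23.311335  2.034037e-09 16
           50       0.811954       0.836378  2.377351e-11      22.374088      24.622625  3.168273e-09 16
           60       0.862687       0.869869  9.697320e-04      24.346033      25.562256  5.150136e-05 16
           70       0.905730       0.897766  6.203800e-04      26.402751      26.595997  4.021661e-01 16
           80       0.941580       0.920397  9.980672e-10      28.759993      27.610593  1.062291e-04 16
           90       0.972472       0.939565  1.668050e-11      32.052259      28.661569  4.000514e-10 16
```

Read it like a per-dose-level results table: at 30% dose the denoiser
lifts mean SSIM against the full-dose reference from 0.664 to 0.736 and
PSNR from 18.9 dB to 22.2 dB (paired p < 10⁻¹⁰); gains shrink as the dose
rises and vanish (then invert) near 90%, where the input is already almost
as good as the reference — the characteristic signature of a denoiser that
helps exactly where noise dominates.

The same pipeline is scriptable from the shell:

```bash
scintidenoise simulate --config run.yaml
scintidenoise train    --config run.yaml
scintidenoise evaluate --config run.yaml
scintidenoise stats scores.csv denoised full --delta 1.0
```

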