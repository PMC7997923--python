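# liftfrap

**3D anisotropic diffusion-tensor estimation from volumetric FRAP time
series, via spatial Fourier analysis.**

Extracellular diffusion in organized tissues (cornea, tendon, disc,
fibrous scaffolds) is direction dependent: a single diffusivity value
misdescribes it, and the right summary is the symmetric 3×3 diffusion
tensor **D** (µm² s⁻¹).  Conventional fluorescence recovery after
photobleaching (FRAP) images one plane and can only see the in-plane
2×2 tensor — and cutting a sample into sections to measure three planes
changes the very structure being measured.  Volumetric FRAP on a fast
light-sheet microscope records the full 3D recovery of a photobleached
volume, from which the complete tensor follows from a single experiment.

`liftfrap` implements the computational half of that measurement for
simulation and analysis studies:

* a **virtual FRAP microscope** (`frap_sim`) that generates volumetric
  recovery movies with a known ground-truth tensor, a smoothed-box
  photobleach with diffusion during bleaching, and a Poisson + Gaussian
  camera noise model;
* the **tensor estimator** (`frap3d_analysis`);
* an independent **finite-difference anisotropic-diffusion solver**
  (zero-flux or periodic) used as a numerical oracle and for
  source-driven concentration-field studies;
* the **2D FRAP analysis** and the 2D→3D anisotropy proxy, so the bias
  of single-plane measurements can be quantified against 3D ground truth;
* auxiliary metrics: Stokes–Einstein predictions, structure-tensor fiber
  coherency, gravimetric water content.

## Method

After photobleaching, the normalized concentration perturbation relaxes
by free anisotropic diffusion, so each spatial-frequency mode
**q** = (u, v, w) (cycles µm⁻¹) of the image volume decays independently:

```
C̃(q, t) / C̃(q, 0) = exp(−4π² qᵀ D q t)
```

The pipeline divides each postbleach volume by the averaged prebleach
volume, takes a 3D DFT, fits a per-mode exponential decay rate k(q), and
solves the linear system

```
k(q) = 4π² (Dxx u² + Dyy v² + Dzz w² + 2Dxy uv + 2Dxz uw + 2Dyz vw)
```

by weighted least squares over ~10–80 low-frequency modes.  The tensor is
then eigendecomposed into principal diffusivities λ₁ ≥ λ₂ ≥ λ₃ with the
diffusion fractional anisotropy

```
FA = sqrt((λ₁−λ₂)² + (λ₁−λ₃)² + (λ₂−λ₃)²) / sqrt(2(λ₁² + λ₂² + λ₃²))
```

(0 = isotropic, 1 = purely unidirectional) and can be rotated into a
sample coordinate frame with `rotate_tensor`.

## Worked example

```python
import liftfrap as lf

truth = lf.DiffusionTensor3D(dxx=20.0, dyy=10.0, dzz=5.0, dxy=2.0)
cfg = lf.SimulationConfig.test_default(truth, seed=11)   # camera noise on
fit = lf.analyze(lf.simulate_liftfrap(cfg))
print(fit.tensor)
print(fit.eigensystem.eigenvalues, fit.fa)
```

prints (from `python examples/simulate_and_recover.py`):

```
recovered (with camera noise):
[[ 1.9804e+01  1.7120e+00 -3.0000e-03]
 [ 1.7120e+00  9.4730e+00  5.6000e-02]
 [-3.0000e-03  5.6000e-02  5.0640e+00]]
principal diffusivities [20.08   9.197  5.063] um^2/s, FA = 0.5930
```

i.e. the estimator recovers the input tensor to a few percent per
component under shot + read noise (and to numerical precision with noise
off), with the fractional anisotropy essentially exact.  The
`examples/` directory holds one short script per capability
(simulation + recovery, concentration fields, 2D-vs-3D bias, isotropy
validation, fiber/composition metrics); each prints the numbers it
computes and what they mean.

A thin CLI mirrors the library:

```bash
liftfrap simulate --config sim.yaml --out stack.ome.tif --seed 1
liftfrap analyze --stack stack.ome.tif --out result.json
liftfrap analyze2d --stack plane.tif --pixel-size 2.0 \
    --frame-interval 0.355 --n-prebleach 5 --out result2d.json
liftfrap benchmark-recovery --diffusivities 2,10,51 --out sweep.csv
liftfrap metrics stokes-einstein --viscosity 1e-3 --radius 1e-9
```

## Documentation

`docs/methods.md` describes the model and its assumptions, the simulator
noise model and default acquisition conditions, the numerical schemes and
their stability/accuracy characteristics, and known limitations.
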