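"""Simulate a volumetric FRAP experiment and recover the diffusion tensor.

A virtual light-sheet FRAP acquisition (76 um cubic field of view, 8
volumes/s, 10 um bleach cube bleached for 1 s) is simulated for a known
anisotropic tensor, first noiselessly and then with the camera noise
model, and the spatial-Fourier estimator is run on both.
"""

import numpy as np

import liftfrap as lf

truth = lf.DiffusionTensor3D(dxx=20.0, dyy=10.0, dzz=5.0, dxy=2.0)
print("ground truth (um^2/s):")
print(np.round(truth.as_matrix(), 3))

for label, noise, seed in [("noiseless", lf.NoiseSpec.off(), None),
                           ("with camera noise", lf.NoiseSpec(), 11)]:
    cfg = lf.SimulationConfig.test_default(truth, noise=noise, seed=seed)
    series = lf.simulate_liftfrap(cfg)
    fit = lf.analyze(series)
    print(f"\nrecovered ({label}):")
    print(np.round(fit.tensor.as_matrix(), 3))
    lams = np.round(fit.eigensystem.eigenvalues, 3)
    print(f"principal diffusivities {lams} um^2/s, "
          f"FA = {fit.fa:.4f}, mean diffusivity = {fit.mean_diffusivity:.3f}")

print("\nThe noiseless run reproduces the input tensor to numerical "
      "precision; with shot + read noise the components move by a few "
      "percent while FA stays close to its true value "
      f"({lf.fractional_anisotropy(*lf.eigendecompose(truth).eigenvalues):.4f}).")
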