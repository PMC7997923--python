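"""Why single-plane FRAP misrepresents 3D anisotropic diffusion.

A 3D recovery with fast out-of-plane diffusion (Dzz >> Dxx = Dyy) is
simulated; the full volumetric estimator and a conventional 2D analysis
of one extracted plane are compared against the ground truth.
"""

import liftfrap as lf

truth = lf.DiffusionTensor3D(dxx=8.0, dyy=8.0, dzz=40.0)
cfg = lf.SimulationConfig.test_default(truth, noise=lf.NoiseSpec.off())
series = lf.simulate_liftfrap(cfg)

fit3d = lf.analyze(series)
res2d = lf.analyze_2d(lf.extract_plane(series))

print(f"ground truth:      Dxx = {truth.dxx:5.2f}, Dyy = {truth.dyy:5.2f}, "
      f"Dzz = {truth.dzz:5.2f} um^2/s")
print(f"3D pipeline:       Dxx = {fit3d.tensor.dxx:5.2f}, "
      f"Dyy = {fit3d.tensor.dyy:5.2f}, Dzz = {fit3d.tensor.dzz:5.2f}")
print(f"2D on one plane:   Dxx = {res2d.tensor.dxx:5.2f}, "
      f"Dyy = {res2d.tensor.dyy:5.2f}   (no access to Dzz)")

bias = 100 * (res2d.tensor.dxx / truth.dxx - 1)
print(f"\nIn-plane bias of the 2D measurement: +{bias:.0f}%.")
print("The plane refills from above and below as well as laterally, so "
      "the single-plane analysis overstates the in-plane diffusivities, "
      "and its anisotropy proxy "
      f"(FA = {res2d.fa_proxy:.3f}) cannot reflect the true anisotropy "
      f"(FA = {fit3d.fa:.3f}). The volumetric estimator recovers the "
      "tensor without bias.")
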