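"""Concentration fields around a constant source under anisotropic diffusion.

Finite-difference simulation of molecules diffusing out of a held source
voxel in a closed (zero-flux) domain — the kind of computation used to
show how a 3D anisotropic tensor reshapes concentration profiles compared
with isotropic diffusion at the same mean diffusivity.
"""

import numpy as np

import liftfrap as lf

n = 24
mask = np.zeros((n, n, n), dtype=bool)
mask[n // 2, n // 2, n // 2] = True

cases = {
    "isotropic D = diag(10, 10, 10)": lf.DiffusionTensor3D(10.0, 10.0, 10.0),
    "anisotropic D = diag(19, 5.5, 5.5)": lf.DiffusionTensor3D(19.0, 5.5, 5.5),
}
for label, tensor in cases.items():
    spec = lf.PDEDomainSpec(grid=(n, n, n), spacing_um=(1.0, 1.0, 1.0),
                            tensor=tensor, source_mask=mask)
    dt = 0.5 * lf.max_stable_dt(spec)
    field = lf.fd_diffuse(spec, duration_s=400 * dt, dt_s=dt)
    profs = lf.concentration_profiles(field, (1.0, 1.0, 1.0),
                                      (n // 2, n // 2, n // 2))
    print(f"\n{label} (mean diffusivity "
          f"{lf.mean_diffusivity(tensor):.2f} um^2/s)")
    print("  r (um):", "  ".join(f"{r:5.0f}" for r in profs["x"][0][1:8]))
    for axis in "xyz":
        vals = profs[axis][1][1:8]
        print(f"  C/C0 along {axis}:", "  ".join(f"{v:.3f}" for v in vals))

print("\nProfiles are normalized to the source-center value. Under "
      "isotropic diffusion the three axis profiles coincide; under the "
      "anisotropic tensor the fast (x) axis carries visibly higher "
      "concentration at every radius, even though the mean diffusivity "
      "is identical.")
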