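"""Phase diffusion of the Poisson-spiking two-module system.

Intrinsic spiking noise makes the module phases diffuse.  The diffusion
tensor is computed from the linearized dynamics (left null eigenvectors of
the Jacobian weighted by the steady firing rates).  Uncoupled, diffusion
is isotropic; coupled, it is strongly anisotropic with the major axis
along coordinated drift -- relative drift between modules, the source of
catastrophic readout errors, is suppressed.
"""

import numpy as np

from gridlock import CoupledSystem, ModuleSpec, phase_diffusion_tensor

spec = ModuleSpec(dims=1, N=200)  # desk scale; N=1000 reproduces the headline number

coupled = CoupledSystem.build(2, spec=spec).relax()
uncoupled = CoupledSystem.build(2, spec=spec, uncoupled=True)
uncoupled.modules, uncoupled.coupling.a = coupled.modules, coupled.coupling.a
uncoupled.states = [s.copy() for s in coupled.states]

for label, system in (("uncoupled", uncoupled), ("coupled", coupled)):
    t = phase_diffusion_tensor(system)
    print(f"{label}: D =\n{np.round(t.D, 5)}")
    print(f"  eigenvalues D+ = {t.eigenvalues[0]:.5f}, D- = {t.eigenvalues[-1]:.6f} phase^2/s; "
          f"anisotropy D+/D- = {t.anisotropy:.1f}; major axis at {t.principal_angle_deg:.1f} deg")
print("the coupled major axis aligns with the joint-motion direction (1, sqrt(2)) ~ 54.7 deg")
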