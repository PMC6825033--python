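"""Evaluate the anisotropic wall model at a single material point.

A medial strip with two collagen-fiber families at +/-44.7 degrees to the
circumferential direction is subjected to simple shear in the fiber plane.
The script prints the stored energies, the Kirchhoff stress, and how both
degrade as the crack phase field d grows.
"""

import numpy as np

from fibrocrack import FiberFrame, MaterialParams, constitutive as co

mat = MaterialParams(mu=83.51, k1=101.65, k2=4.17, alpha=44.71, kappa=250.0)
frame = FiberFrame.from_angle(mat.alpha)

gamma = 0.3  # amount of shear in the circumferential-axial plane
F = np.eye(3)
F[0, 1] = gamma
state = co.compute_kinematics(F, frame)

print(f"simple shear gamma = {gamma} in the fiber plane")
print(f"  I1 = {state.I1:.4f}, I4 = {state.I4:.4f}, I6 = {state.I6:.4f}, J = {state.J:.4f}")
print(f"  ground-matrix energy  Psi0_iso = {co.psi0_iso(state, mat):8.4f} kPa")
print(f"  fiber energy          Psi0_ani = {co.psi0_ani(state, mat):8.4f} kPa")
# one family is stretched (I4 > 1) and stores exponential energy, the other
# is shortened (I6 < 1) and is switched off (tension-only fibers)

for d in (0.0, 0.5, 1.0):
    tau = co.kirchhoff_stress(state, d, mat)
    print(f"  d = {d:3.1f}: tau_12 = {tau[0, 1]:8.3f} kPa, "
          f"Psi = {co.degraded_energy(state, d, mat):8.4f} kPa")
# d = 0 is the intact response; d = 1 is fully ruptured (zero stress);
# quadratic degradation scales energy by (1-d)^2 in between.
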