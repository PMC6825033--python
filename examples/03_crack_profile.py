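"""The regularized crack: 1-D profile and the homogeneous damage law.

A bar clamped to d = 1 at its left end (a fully formed crack face) relaxes
into the exponential optimal profile exp(-x/l) whose crack-surface integral
equals one unit of sharp crack area.  A uniformly driven bar instead follows
the homogeneous solution d = H/(1+H): damage stays at zero until the driving
energy exceeds the failure surface, then saturates towards 1.
"""

import numpy as np

from fibrocrack import CoupledModel, MaterialParams, Mesh, PhaseFieldParams, SolverSettings
from fibrocrack.phasefield import homogeneous_d

l, L, n = 0.5, 6.0, 120
xs = np.linspace(0, L, n + 1)
nodes = np.array([[x, y] for y in (0.0, L / n) for x in xs])
elems = np.array([[i, i + 1, n + 2 + i, n + 1 + i] for i in range(n)])
mesh = Mesh(nodes=nodes, elements=elems, cell_type="quad")

pf = PhaseFieldParams(l=l, gc_iso_over_l=1.0, gc_ani_over_l=1.0)
model = CoupledModel(mesh, {0: (MaterialParams(mu=1.0), pf)},
                     settings=SolverSettings(check_mesh_rule=False))

d = model.solve_phasefield(np.zeros((model.ne, model.nqp)), np.zeros(model.nn),
                           dt=1.0, d_dirichlet=[(np.array([0, n + 1]), 1.0)],
                           grad_factor=1.0)
x = mesh.nodes[: n + 1, 0]
print("clamped-crack profile vs exp(-x/l):")
for i in (0, 10, 20, 40):
    print(f"  x = {x[i]:5.2f} mm: d = {d[i]:.5f}, exact {np.exp(-x[i] / l):.5f}")

print("\nhomogeneous damage law d = H/(1+H):")
for H in (0.0, 0.5, 1.0, 4.0):
    dh = model.solve_phasefield(np.full((model.ne, model.nqp), H),
                                np.zeros(model.nn), dt=1.0)
    print(f"  H = {H:3.1f}: solver d = {dh.max():.6f}, analytic {homogeneous_d(H):.6f}")
# H is the history of <Hbar - 1>: zero while the effective energy stays
# below the critical fracture energy per length scale, hence d = 0 exactly
# until the failure surface is crossed.
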