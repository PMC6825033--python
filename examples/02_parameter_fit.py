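"""Identify the elastic constants from the four homogeneous test modes.

Synthetic uniaxial (circumferential, axial) and in-plane shear curves are
generated from known medial constants with a little measurement noise, and
the nonlinear least-squares identification is run from a deliberately poor
starting point.  The printed table mirrors how such fits are reported:
parameters, per-mode correlation coefficients, and the normalized RMSE.
"""

from fibrocrack import MaterialParams
from fibrocrack.fitting import fit_parameters, generate_synthetic_dataset

truth = MaterialParams(mu=83.509, k1=101.651, k2=4.173, alpha=44.705)
data = generate_synthetic_dataset(truth, noise_sd=0.5, seed=42)

init = MaterialParams(mu=40.0, k1=50.0, k2=2.0, alpha=30.0)
result = fit_parameters(data, init=init)

print("generating values: mu=83.509 kPa, k1=101.651 kPa, k2=4.173, alpha=44.705 deg")
print(result.summary())
# With 0.5 kPa noise the recovered mu/alpha agree with the generating values
# to a fraction of a percent; k2 trades off against k1 and is identified
# more loosely (see docs/methods.md on identifiability).
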