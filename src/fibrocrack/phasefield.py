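"""Regularized crack geometry and phase-field evolution physics.

A sharp crack is smeared over a length scale ``l`` by the crack surface
density

    gamma(d, grad d; L) = (1 / 2l) (d^2 + grad d . L grad d),

with the anisotropic structure tensor

    L = l^2 (I + omega_M M (x) M + omega_Mp M' (x) M'),

which biases the gradient energy so cracks align with fibers as the
anisotropy (penalty) parameters omega grow.  Failure is driven by the
effective (undegraded) energies normalized by the critical fracture
energies per length scale,

    Hbar = Psi0_iso / (gc_iso/l) + Psi0_ani / (gc_ani/l),

gated by the failure surface Hbar = 1 through the irreversible history
field H = max_s <Hbar(s) - 1>.  The rate-independent homogeneous solution
of the superposed evolution law (1 - d) H = d - (1/2) Div(L grad d) is
d = H / (1 + H), used as a solver oracle throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseFieldParams",
    "structure_tensor",
    "crack_density",
    "crack_sources",
    "update_history",
    "homogeneous_d",
    "evolution_residual",
]

_I3 = np.eye(3)


@dataclass(frozen=True)
class PhaseFieldParams:
    """Fracture constants of one wall layer.

    Parameters
    ----------
    l : float
        Regularization length scale (mm), > 0.  Resolution rule l > 2h.
    gc_iso_over_l, gc_ani_over_l : float
        Critical fracture energy per length scale for the ground matrix and
        the fibrous content (kPa), > 0.
    omega_M, omega_Mp : float
        Anisotropy parameters, each in the open range (-1, inf) set by the
        ellipticity of the regularized crack surface.
    eta : float
        Artificial viscosity (kPa * s), >= 0; eta = 0 recovers the
        rate-independent evolution law.
    a_iso, a_ani : float
        Degradation exponents (> 1); default quadratic.
    """

    l: float
    gc_iso_over_l: float
    gc_ani_over_l: float
    omega_M: float = 0.0
    omega_Mp: float = 0.0
    eta: float = 0.0
    a_iso: float = 2.0
    a_ani: float = 2.0

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError(f"length scale l must be > 0, got {self.l}")
        if self.gc_iso_over_l <= 0 or self.gc_ani_over_l <= 0:
            raise ValueError("critical fracture energies gc/l must be > 0")
        for name, w in (("omega_M", self.omega_M), ("omega_Mp", self.omega_Mp)):
            if w <= -1.0:
                raise ValueError(
                    f"{name} = {w} violates ellipticity; admissible range is (-1, inf)"
                )
        if self.eta < 0:
            raise ValueError("viscosity eta must be >= 0")
        if self.a_iso <= 1.0 or self.a_ani <= 1.0:
            raise ValueError("degradation exponents must exceed 1")


def structure_tensor(pf: PhaseFieldParams, frame) -> np.ndarray:
    """Anisotropic structure tensor L = l^2 (I + w_M M(x)M + w_Mp M'(x)M') (mm^2).

    Positive definite for admissible omega.  Accepts per-element frames
    (batched M of shape (..., 3)).
    """
    return structure_tensor_iso(pf) + structure_tensor_ani(pf, frame)


def structure_tensor_iso(pf: PhaseFieldParams) -> np.ndarray:
    """Isotropic part L_iso = l^2 I."""
    return pf.l**2 * _I3


def structure_tensor_ani(pf: PhaseFieldParams, frame) -> np.ndarray:
    """Anisotropic part L_ani = l^2 (w_M M(x)M + w_Mp M'(x)M')."""
    L = pf.omega_M * frame.A_M
    if frame.Mp is not None:
        L = L + pf.omega_Mp * frame.A_Mp
    else:
        L = np.broadcast_to(L, frame.A_M.shape).copy()
    return pf.l**2 * L


def crack_density(d, grad_d, L, l: float):
    """Crack surface density gamma = (1/2l)(d^2 + grad d . L grad d) (1/mm)."""
    d = np.asarray(d, dtype=float)
    grad_d = np.asarray(grad_d, dtype=float)
    quad = np.einsum("...i,...ij,...j->...", grad_d, L, grad_d)
    return (d**2 + quad) / (2.0 * l)


def crack_sources(psi_iso, psi_ani, pf: PhaseFieldParams):
    """Dimensionless crack driving sources (Hbar_iso, Hbar_ani, Hbar).

    Hbar_iso = Psi0_iso / (gc_iso/l), Hbar_ani = Psi0_ani / (gc_ani/l),
    and their sum.  Effective (undegraded) energies enter here.
    """
    h_iso = np.asarray(psi_iso, dtype=float) / pf.gc_iso_over_l
    h_ani = np.asarray(psi_ani, dtype=float) / pf.gc_ani_over_l
    return h_iso, h_ani, h_iso + h_ani


def update_history(H_prev, Hbar):
    """Irreversible history update H = max(H_prev, <Hbar - 1>).

    The Macaulay bracket keeps the solid intact until the failure surface
    Hbar = 1 is crossed; the running maximum makes H non-decreasing.
    """
    gate = np.maximum(np.asarray(Hbar, dtype=float) - 1.0, 0.0)
    return np.maximum(np.asarray(H_prev, dtype=float), gate)


def homogeneous_d(H):
    """Rate-independent homogeneous phase field d = H / (1 + H)."""
    H = np.asarray(H, dtype=float)
    return H / (1.0 + H)


def evolution_residual(d, d_n, lap_term, H, pf: PhaseFieldParams, dt: float):
    """Strong-form residual of the phase-field evolution law at a point,

        r = eta (d - d_n)/dt - (1 - d) H + d - (1/2) Div(L grad d),

    where ``lap_term`` supplies Div(L grad d).  With eta = 0 and vanishing
    divergence the root is the homogeneous solution d = H/(1+H).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    d = np.asarray(d, dtype=float)
    return (
        pf.eta * (d - np.asarray(d_n, dtype=float)) / dt
        - (1.0 - d) * np.asarray(H, dtype=float)
        + d
        - 0.5 * np.asarray(lap_term, dtype=float)
    )
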