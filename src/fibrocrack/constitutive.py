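"""Anisotropic hyperelasticity of the arterial wall with damage degradation.

The stored energy splits into an isotropic ground-matrix part and an
anisotropic part carried by two families of collagen fibers (HGO model):

    Psi0_iso = (mu/2) (I1 - 3 - 2 ln J) + (kappa/4) (J^2 - 1 - 2 ln J)
    Psi0_ani = (k1 / 2 k2) sum_{i in {4,6}} [exp(k2 <Ii - 1>^2) - 1]

where I1 = tr(b), b = F F^T, J = det F, and I4, I6 are the squared stretches
along the two mean fiber directions M and M'.  Fibers only store energy in
tension (Ii > 1) by default.  Progressive damage enters through degradation
functions g_i(d) = (1 - d)^{a_i}:

    Psi = g_iso(d) Psi0_iso + g_ani(d) Psi0_ani

All stress/tangent routines are batched: any leading shape is accepted for
the deformation gradient (e.g. ``(n_elem, n_qp, 3, 3)``) and broadcast
against the scalar damage field.

Units: stresses and energy densities in kPa, lengths in mm, angles in
degrees at the user surface (radians internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialParams",
    "FiberFrame",
    "KinematicState",
    "InvalidDeformationError",
    "compute_kinematics",
    "psi0_iso",
    "psi0_ani",
    "degradation",
    "degraded_energy",
    "kirchhoff_stress",
    "energetic_force",
    "first_piola_stress",
    "first_piola_tangent",
    "material_tangent",
]

_I3 = np.eye(3)


class InvalidDeformationError(ValueError):
    """Raised when a deformation gradient has non-positive determinant."""


@dataclass(frozen=True)
class MaterialParams:
    """Hyperelastic constants of one wall layer.

    Parameters
    ----------
    mu : float
        Shear modulus of the ground matrix (kPa), > 0.
    k1 : float
        Fiber stiffness-like parameter (kPa), >= 0.
    k2 : float
        Dimensionless fiber exponent, > 0.
    alpha : float
        Mean fiber angle measured from the circumferential direction
        (degrees), in [0, 90).
    kappa : float
        Bulk modulus (kPa), > 0.  Only stated for the notched-plate study
        in the source data (3.0 kPa); configurable elsewhere.
    fibers_tension_only : bool
        If True (default) fibers under compression (Ii <= 1) store no
        energy and carry no stress.
    """

    mu: float
    k1: float = 0.0
    k2: float = 1.0
    alpha: float = 0.0
    kappa: float = 3.0
    fibers_tension_only: bool = True

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be > 0, got {self.mu}")
        if self.k1 < 0:
            raise ValueError(f"k1 must be >= 0, got {self.k1}")
        if self.k2 <= 0:
            raise ValueError(f"k2 must be > 0, got {self.k2}")
        if not (0.0 <= self.alpha < 90.0):
            raise ValueError(f"alpha must lie in [0, 90) degrees, got {self.alpha}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")

    def scaled(self, factor: float) -> "MaterialParams":
        """Return a copy with mu, k1, k2 scaled by ``factor`` (alpha kept)."""
        return MaterialParams(
            mu=self.mu * factor,
            k1=self.k1 * factor,
            k2=self.k2 * factor,
            alpha=self.alpha,
            kappa=self.kappa,
            fibers_tension_only=self.fibers_tension_only,
        )


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("fiber direction must be a nonzero vector")
    return v / n


@dataclass(frozen=True)
class FiberFrame:
    """Reference mean fiber directions M and (optionally) M'.

    ``M`` and ``Mp`` are unit vectors; ``Mp=None`` models a single fiber
    family (as in the notched-plate benchmark).  Arrays of shape
    ``(..., 3)`` are accepted for per-element frames.
    """

    M: np.ndarray
    Mp: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "M", _unit(self.M))
        if self.Mp is not None:
            object.__setattr__(self, "Mp", _unit(self.Mp))

    @property
    def A_M(self) -> np.ndarray:
        """Structure tensor M (x) M."""
        return np.einsum("...i,...j->...ij", self.M, self.M)

    @property
    def A_Mp(self) -> np.ndarray | None:
        if self.Mp is None:
            return None
        return np.einsum("...i,...j->...ij", self.Mp, self.Mp)

    @classmethod
    def from_angle(cls, alpha_deg: float, two_families: bool = True) -> "FiberFrame":
        """Symmetric families at +/- alpha to the first (circumferential) axis,
        lying in the 1-2 plane."""
        a = np.deg2rad(alpha_deg)
        M = np.array([np.cos(a), np.sin(a), 0.0])
        Mp = np.array([np.cos(a), -np.sin(a), 0.0]) if two_families else None
        return cls(M=M, Mp=Mp)


@dataclass
class KinematicState:
    """Per-point kinematics derived from the deformation gradient.

    All arrays share the leading (batch) shape of ``F``.
    """

    F: np.ndarray
    J: np.ndarray
    b: np.ndarray
    I1: np.ndarray
    I4: np.ndarray
    I6: np.ndarray | None
    m: np.ndarray
    mp: np.ndarray | None
    frame: FiberFrame = field(repr=False)


def compute_kinematics(F: np.ndarray, frame: FiberFrame) -> KinematicState:
    """Kinematic quantities J, b, I1, I4, I6 and spatial fiber vectors.

    Raises
    ------
    InvalidDeformationError
        If det F <= 0 anywhere in the batch.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0.0):
        bad = float(np.min(J))
        raise InvalidDeformationError(
            f"non-positive determinant det F = {bad:.6g}: deformation is not admissible"
        )
    b = F @ np.swapaxes(F, -1, -2)
    I1 = np.trace(b, axis1=-2, axis2=-1)
    m = np.einsum("...ij,...j->...i", F, frame.M)
    I4 = np.einsum("...i,...i->...", m, m)
    if frame.Mp is not None:
        mp = np.einsum("...ij,...j->...i", F, frame.Mp)
        I6 = np.einsum("...i,...i->...", mp, mp)
    else:
        mp, I6 = None, None
    return KinematicState(F=F, J=J, b=b, I1=I1, I4=I4, I6=I6, m=m, mp=mp, frame=frame)


_EXP_ARG_MAX = 500.0  # exp overflow guard for the fiber term


def _fiber_excess(I: np.ndarray, tension_only: bool) -> np.ndarray:
    """<Ii - 1> with the optional tension-only switch."""
    e = np.asarray(I, dtype=float) - 1.0
    if tension_only:
        e = np.maximum(e, 0.0)
    return e


def psi0_iso(state: KinematicState, p: MaterialParams) -> np.ndarray:
    """Effective (undamaged) isotropic energy density, kPa.

    Compressible neo-Hookean plus a convex volumetric term; zero and
    stress-free at F = I.
    """
    J, I1 = state.J, state.I1
    lnJ = np.log(J)
    return 0.5 * p.mu * (I1 - 3.0 - 2.0 * lnJ) + 0.25 * p.kappa * (J**2 - 1.0 - 2.0 * lnJ)


def psi0_ani(state: KinematicState, p: MaterialParams) -> np.ndarray:
    """Effective (undamaged) fiber energy density, kPa.

    Exponential HGO term summed over the active fiber families.
    """
    if p.k1 == 0.0:
        return np.zeros(np.shape(state.I4))
    total = np.zeros(np.shape(state.I4))
    for I in (state.I4, state.I6):
        if I is None:
            continue
        e = _fiber_excess(I, p.fibers_tension_only)
        arg = p.k2 * e**2
        if np.any(arg > _EXP_ARG_MAX):
            raise OverflowError(
                f"fiber energy overflow: k2*<I-1>^2 = {float(np.max(arg)):.3g} "
                f"(invariant up to {float(np.max(I)):.6g})"
            )
        total = total + (np.exp(arg) - 1.0)
    return (p.k1 / (2.0 * p.k2)) * total


def degradation(d: np.ndarray, a: float) -> np.ndarray:
    """Degradation function g(d) = (1 - d)^a for d in [0, 1], a > 1."""
    d = np.asarray(d, dtype=float)
    if np.any((d < 0.0) | (d > 1.0)):
        raise ValueError("phase-field d must lie in [0, 1]")
    if a <= 1.0:
        raise ValueError(f"degradation exponent must exceed 1, got {a}")
    return (1.0 - d) ** a


def degraded_energy(state, d, p: MaterialParams, a_iso: float = 2.0, a_ani: float = 2.0):
    """Psi = g_iso(d) Psi0_iso + g_ani(d) Psi0_ani (kPa)."""
    return degradation(d, a_iso) * psi0_iso(state, p) + degradation(d, a_ani) * psi0_ani(state, p)


def energetic_force(state, d, p: MaterialParams, a_iso: float = 2.0, a_ani: float = 2.0):
    """Scalar energetic force f = -dPsi/dd, work conjugate to the phase field."""
    d = np.asarray(d, dtype=float)
    if np.any((d < 0.0) | (d > 1.0)):
        raise ValueError("phase-field d must lie in [0, 1]")
    return (
        a_iso * (1.0 - d) ** (a_iso - 1.0) * psi0_iso(state, p)
        + a_ani * (1.0 - d) ** (a_ani - 1.0) * psi0_ani(state, p)
    )


def _fiber_psi4(I: np.ndarray, p: MaterialParams):
    """First and second derivatives of the per-family fiber energy wrt its
    invariant: psi4 = k1 e exp(k2 e^2), psi44 = k1 (1 + 2 k2 e^2) exp(k2 e^2),
    with e = <I - 1>.  Both vanish identically for inactive (compressed)
    fibers when the tension-only switch is on."""
    e = _fiber_excess(I, p.fibers_tension_only)
    ex = np.exp(p.k2 * e**2)
    psi4 = p.k1 * e * ex
    psi44 = p.k1 * (1.0 + 2.0 * p.k2 * e**2) * ex
    if p.fibers_tension_only:
        active = np.asarray(I) > 1.0
        psi4 = np.where(active, psi4, 0.0)
        psi44 = np.where(active, psi44, 0.0)
    return psi4, psi44


def _g_vol(g_iso, J, degrade_compressed_volume):
    """Degradation applied to the volumetric (kappa) term.

    With ``degrade_compressed_volume=False`` the volumetric response stays
    undegraded where J < 1: ruptured material still resists interpenetration
    (a contact-like penalty for closing crack faces); the driving energy is
    unaffected by this choice.
    """
    if degrade_compressed_volume:
        return g_iso
    return np.where(np.asarray(J) < 1.0, 1.0, g_iso)


def kirchhoff_stress(state: KinematicState, d, p: MaterialParams,
                     a_iso: float = 2.0, a_ani: float = 2.0,
                     degrade_compressed_volume: bool = True) -> np.ndarray:
    """Kirchhoff stress tau = 2 dPsi/dg (kPa), symmetric, zero at F = I.

    tau = g_iso mu (b - I) + g_vol (kappa/2)(J^2 - 1) I
        + g_ani * 2 sum_i psi4(Ii) m_i (x) m_i
    """
    g_iso = degradation(d, a_iso)
    g_ani = degradation(d, a_ani)
    J, b = state.J, state.b
    g_vol = _g_vol(g_iso, J, degrade_compressed_volume)
    tau = (
        g_iso[..., None, None] * p.mu * (b - _I3)
        + (g_vol * 0.5 * p.kappa * (J**2 - 1.0))[..., None, None] * _I3
    )
    for I, m in ((state.I4, state.m), (state.I6, state.mp)):
        if I is None:
            continue
        psi4, _ = _fiber_psi4(I, p)
        tau = tau + (g_ani * 2.0 * psi4)[..., None, None] * np.einsum(
            "...i,...j->...ij", m, m
        )
    return tau


def first_piola_stress(state: KinematicState, d, p: MaterialParams,
                       a_iso: float = 2.0, a_ani: float = 2.0,
                       degrade_compressed_volume: bool = True) -> np.ndarray:
    """First Piola-Kirchhoff stress P = dPsi/dF (kPa); tau = P F^T."""
    g_iso = degradation(d, a_iso)
    g_ani = degradation(d, a_ani)
    F, J = state.F, state.J
    FinvT = np.swapaxes(np.linalg.inv(F), -1, -2)
    g_vol = _g_vol(g_iso, J, degrade_compressed_volume)
    P = (
        g_iso[..., None, None] * p.mu * (F - FinvT)
        + (g_vol * 0.5 * p.kappa * (J**2 - 1.0))[..., None, None] * FinvT
    )
    for I, m, M in ((state.I4, state.m, state.frame.M), (state.I6, state.mp, state.frame.Mp)):
        if I is None:
            continue
        psi4, _ = _fiber_psi4(I, p)
        P = P + (g_ani * 2.0 * psi4)[..., None, None] * np.einsum(
            "...i,...j->...ij", m, np.broadcast_to(M, m.shape)
        )
    return P


def first_piola_tangent(state: KinematicState, d, p: MaterialParams,
                        a_iso: float = 2.0, a_ani: float = 2.0,
                        degrade_compressed_volume: bool = True) -> np.ndarray:
    """Material tangent A_iJkL = d P_iJ / d F_kL (kPa).

    Major symmetry A_iJkL = A_kLiJ holds (second derivative of an energy);
    this is the operator assembled into the Newton stiffness.
    """
    g_iso = degradation(d, a_iso)
    g_ani = degradation(d, a_ani)
    F, J = state.F, state.J
    Finv = np.linalg.inv(F)
    FinvT = np.swapaxes(Finv, -1, -2)
    batch = F.shape[:-2]
    g_vol = _g_vol(g_iso, J, degrade_compressed_volume)

    I_ik_JL = np.einsum("ik,jl->ijkl", _I3, _I3)  # delta_ik delta_JL
    A = np.zeros(batch + (3, 3, 3, 3))
    # dF^-T_{iJ} / dF_{kL} = -F^-1_{Jk} F^-1_{Li}
    dFinvT = -np.einsum("...jk,...li->...ijkl", Finv, Finv)
    coef_vol = g_vol * 0.5 * p.kappa * (J**2 - 1.0)
    A += (g_iso * p.mu)[..., None, None, None, None] * (I_ik_JL - dFinvT)
    A += (
        (g_vol * p.kappa * J**2)[..., None, None, None, None]
        * np.einsum("...ij,...kl->...ijkl", FinvT, FinvT)
        + coef_vol[..., None, None, None, None] * dFinvT
    )
    for I, m, M in ((state.I4, state.m, state.frame.M), (state.I6, state.mp, state.frame.Mp)):
        if I is None:
            continue
        psi4, psi44 = _fiber_psi4(I, p)
        Mb = np.broadcast_to(M, m.shape)
        A += (g_ani * 4.0 * psi44)[..., None, None, None, None] * np.einsum(
            "...i,...j,...k,...l->...ijkl", m, Mb, m, Mb
        )
        A += (g_ani * 2.0 * psi4)[..., None, None, None, None] * np.einsum(
            "ik,...j,...l->...ijkl", _I3, Mb, Mb
        )
    return A


def material_tangent(state: KinematicState, d, p: MaterialParams,
                     a_iso: float = 2.0, a_ani: float = 2.0) -> np.ndarray:
    """Spatial elasticity tensor c_ijkl (kPa) with minor and major symmetries.

    Push-forward of the first-Piola tangent minus the geometric stress term:
    c_ijkl = F_jJ F_lL A_iJkL - delta_ik tau_jl.  At F = I, d = 0, k1 = 0 it
    reduces to the isotropic small-strain tensor with shear modulus mu.
    """
    A = first_piola_tangent(state, d, p, a_iso, a_ani)
    tau = kirchhoff_stress(state, d, p, a_iso, a_ani)
    F = state.F
    c = np.einsum("...jJ,...lL,...iJkL->...ijkl", F, F, A)
    c = c - np.einsum("ik,...jl->...ijkl", _I3, tau)
    return c
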