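"""Anisotropic hyperelastic constitutive model for corneal stroma.

The strain-energy density is split isochorically into three parts,

    W = W_vol(J) + W_aniso(I4_i, I6_i, I3) + W_matrix(I1, I3),

with

* ``W_vol(J) = (J - 1)^2 / D`` — a volumetric penalty enforcing
  near-incompressibility (D small, default 1e-5 in reciprocal stress
  units);
* ``W_matrix = C10 (I3^(-1/3) I1 - 3)`` — a Neo-Hookean ground-substance
  matrix acting on the isochoric first invariant;
* ``W_aniso = (1/N) sum_i K_i [ W_fib(I4_i; mu1, gamma1) + W_fib(I6_i; mu2, gamma2) ]``
  — a density-weighted mean over N = 16 discretised fibril orientations
  of two fibril families: in-plane lamellar fibrils (direction a0_i in
  the local tangent plane) and out-of-plane interweaving fibrils
  inclined 15 degrees to the tangent plane.  Interweaving lamellae
  cross the plane both upwards and downwards with no preferred sense,
  so the out-of-plane term is the balanced mean of the two mirrored
  sub-families at +/- the elevation angle (a single-sided family would
  give the sheet an unphysical through-thickness shear polarisation).

Each fibril family follows the exponential-logarithmic form

    W_fib(I) = (mu / gamma) ((I3^(-1/3) I)^(gamma/2) - 1) - mu ln (I3^(-1/3) I)^(1/2),

which is zero with zero slope at the stress-free state.  A fibril term
is active only when its squared-stretch invariant (I4_i or I6_i)
exceeds 1, i.e. fibrils carry load in tension only; the gate is applied
per orientation and per family.

All public functions broadcast over leading batch axes: ``F`` may have
shape ``(..., 3, 3)`` and ``K`` shape ``(..., 16)``.  Stresses are
returned in the units of the stiffness parameters (mm-MPa convention
throughout the package).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orientations import N_ORIENTATIONS, in_plane_directions, out_of_plane_directions


class InvertedElementError(ValueError):
    """Raised when a deformation gradient has non-positive determinant."""


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive constants.

    The defaults for ``C10``, ``mu1``, ``gamma1``, ``mu2`` and ``gamma2``
    are illustrative placeholders of plausible corneal magnitude and are
    NOT fitted to experimental data; supply calibrated values for any
    quantitative stress prediction.  All simulations in this package are
    displacement-controlled, so the reorientation results do not depend
    on them.
    """

    D: float = 1e-5            # incompressibility penalty, 1/MPa
    C10: float = 0.03          # ground-substance stiffness, MPa
    mu1: float = 0.02          # in-plane fibril stiffness, MPa
    gamma1: float = 40.0       # in-plane fibril nonlinearity, dimensionless
    mu2: float = 0.008         # out-of-plane fibril stiffness, MPa
    gamma2: float = 30.0       # out-of-plane fibril nonlinearity, dimensionless
    out_of_plane_angle_deg: float = 15.0  # elevation of b0 above the tangent plane

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("incompressibility penalty D must be positive")
        if self.C10 <= 0:
            raise ValueError("ground-substance stiffness C10 must be positive")
        if self.mu1 < 0 or self.mu2 < 0:
            raise ValueError("fibril stiffnesses mu1, mu2 must be non-negative")
        if self.gamma1 <= 0 or self.gamma2 <= 0:
            raise ValueError("fibril nonlinearity exponents gamma1, gamma2 must be positive")

    @property
    def n_orientations(self) -> int:
        return N_ORIENTATIONS


@dataclass(frozen=True)
class FibrilFrame:
    """Reference fibril directions of the 16 orientations.

    ``a0`` are unit in-plane vectors at angles theta_i in the tangent
    plane; ``b0`` share the azimuths but are elevated
    ``out_of_plane_angle_deg`` above the plane.
    """

    a0: np.ndarray  # (16, 3)
    b0: np.ndarray  # (16, 3)
    out_of_plane_angle_deg: float = 15.0

    @property
    def b0_mirror(self) -> np.ndarray:
        """Mirrored out-of-plane directions (elevation below the plane).

        Interweaving lamellae cross the tangent plane both upwards and
        downwards with no preferred sense; the out-of-plane energy
        averages the two mirrored sub-families so the material carries
        no spurious through-thickness shear polarisation.
        """
        return self.b0 * np.array([1.0, 1.0, -1.0])

    @classmethod
    def standard(cls, out_of_plane_angle_deg: float = 15.0) -> "FibrilFrame":
        return cls(
            a0=in_plane_directions(),
            b0=out_of_plane_directions(out_of_plane_angle_deg),
            out_of_plane_angle_deg=out_of_plane_angle_deg,
        )

    @classmethod
    def from_params(cls, params: MaterialParams) -> "FibrilFrame":
        return cls.standard(params.out_of_plane_angle_deg)


@dataclass(frozen=True)
class DeformationState:
    """Kinematic quantities derived from a deformation gradient.

    All entries broadcast over leading batch axes.  ``I4`` and ``I6``
    hold the per-orientation squared stretches a0_i . C a0_i and
    b0_i . C b0_i (shape ``(..., 16)``).
    """

    F: np.ndarray
    C: np.ndarray
    J: np.ndarray
    I1: np.ndarray
    I3: np.ndarray
    I4: np.ndarray
    I6: np.ndarray
    I6m: np.ndarray  # squared stretch of the mirrored (-elevation) sub-family


def kinematics(F: np.ndarray, frame: FibrilFrame) -> DeformationState:
    """Populate the deformation state for deformation gradient(s) ``F``."""
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] != (3, 3):
        raise ValueError("F must have shape (..., 3, 3)")
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvertedElementError("deformation gradient has non-positive determinant")
    C = np.einsum("...ki,...kj->...ij", F, F)
    I1 = np.einsum("...ii->...", C)
    I3 = np.linalg.det(C)
    I4 = np.einsum("...ij,ai,aj->...a", C, frame.a0, frame.a0)
    I6 = np.einsum("...ij,ai,aj->...a", C, frame.b0, frame.b0)
    I6m = np.einsum("...ij,ai,aj->...a", C, frame.b0_mirror, frame.b0_mirror)
    return DeformationState(F=F, C=C, J=J, I1=I1, I3=I3, I4=I4, I6=I6, I6m=I6m)


def _fibril_families(state: DeformationState, params: MaterialParams, frame: FibrilFrame):
    """(invariant, directions, mu, gamma) for each discretised fibril family.

    The out-of-plane contribution is the balanced mean of the two
    mirrored sub-families at +/- the elevation angle, each carrying
    half of mu2 and gated on its own invariant.
    """
    return (
        (state.I4, frame.a0, params.mu1, params.gamma1),
        (state.I6, frame.b0, 0.5 * params.mu2, params.gamma2),
        (state.I6m, frame.b0_mirror, 0.5 * params.mu2, params.gamma2),
    )


# ----------------------------------------------------------------------
# energy components
# ----------------------------------------------------------------------
def energy_vol(J, D: float):
    """Volumetric penalty (J - 1)^2 / D; zero iff J = 1."""
    if D <= 0:
        raise ValueError("D must be positive")
    J = np.asarray(J, dtype=float)
    return (J - 1.0) ** 2 / D


def energy_matrix(I1, I3, C10: float):
    """Neo-Hookean ground substance C10 (I3^(-1/3) I1 - 3)."""
    I1 = np.asarray(I1, dtype=float)
    I3 = np.asarray(I3, dtype=float)
    if np.any(I3 <= 0):
        raise ValueError("I3 must be positive")
    return C10 * (I3 ** (-1.0 / 3.0) * I1 - 3.0)


def energy_fibril(I, I3, mu: float, gamma: float):
    """One fibril family's energy as a function of its squared stretch.

    With ``x = I3^(-1/3) I`` the energy is
    ``(mu/gamma)(x^(gamma/2) - 1) - mu ln x^(1/2)``; it vanishes with
    zero slope at x = 1.  Applied identically to the in-plane (I4, mu1,
    gamma1) and out-of-plane (I6, mu2, gamma2) families.
    """
    I = np.asarray(I, dtype=float)
    I3 = np.asarray(I3, dtype=float)
    if np.any(I <= 0) or np.any(I3 <= 0):
        raise ValueError("fibril invariants must be positive")
    x = I3 ** (-1.0 / 3.0) * I
    return (mu / gamma) * (x ** (gamma / 2.0) - 1.0) - 0.5 * mu * np.log(x)


def energy_aniso(state: DeformationState, K: np.ndarray, params: MaterialParams):
    """Density-weighted fibril energy, mean over the 16 orientations.

    Each family's term enters only when its own invariant exceeds 1
    (tension gate, applied per orientation and per family).
    """
    K = np.asarray(K, dtype=float)
    if K.shape[-1] != N_ORIENTATIONS:
        raise ValueError(f"K must have {N_ORIENTATIONS} entries on its last axis")
    I3 = state.I3[..., None]
    total = np.zeros(np.broadcast_shapes(K.shape, state.I4.shape))
    for invariant, mu, gamma in (
        (state.I4, params.mu1, params.gamma1),
        (state.I6, 0.5 * params.mu2, params.gamma2),
        (state.I6m, 0.5 * params.mu2, params.gamma2),
    ):
        total = total + np.where(
            invariant > 1.0, energy_fibril(invariant, I3, mu, gamma), 0.0
        )
    return np.mean(K * total, axis=-1)


def energy_total(state: DeformationState, K: np.ndarray, params: MaterialParams):
    """Total strain-energy density W_vol + W_aniso + W_matrix."""
    return (
        energy_vol(state.J, params.D)
        + energy_aniso(state, K, params)
        + energy_matrix(state.I1, state.I3, params.C10)
    )


# ----------------------------------------------------------------------
# stress
# ----------------------------------------------------------------------
def _dW_dC(
    state: DeformationState,
    K: np.ndarray,
    params: MaterialParams,
    frame: FibrilFrame,
    include_volumetric: bool = True,
) -> np.ndarray:
    """Derivative of the strain energy with respect to C, shape (..., 3, 3).

    At the tension-gate boundary (I4 = 1 or I6 = 1) the derivative is
    evaluated one-sidedly: the fibril term contributes only on the
    tension side of the gate.
    """
    K = np.asarray(K, dtype=float)
    C = state.C
    Cinv = np.linalg.inv(C)
    J = state.J
    I3m13 = state.I3 ** (-1.0 / 3.0)
    eye = np.broadcast_to(np.eye(3), C.shape)

    # ground substance: C10 I3^(-1/3) (I - (I1/3) C^-1)
    out = params.C10 * I3m13[..., None, None] * (eye - (state.I1 / 3.0)[..., None, None] * Cinv)

    if include_volumetric:
        out = out + (J * (J - 1.0) / params.D)[..., None, None] * Cinv

    # fibril families: sum_i (K_i / N) W'(x_i) dx_i/dC, gated in tension
    for invariant, dirs, mu, gamma in _fibril_families(state, params, frame):
        if mu == 0.0:
            continue
        x = I3m13[..., None] * invariant  # (..., 16)
        dWdx = 0.5 * mu * (x ** (gamma / 2.0 - 1.0) - 1.0 / x)
        w = np.where(invariant > 1.0, K / N_ORIENTATIONS * dWdx, 0.0)
        outer = np.einsum("ai,aj->aij", dirs, dirs)
        struct = np.einsum("...a,aij->...ij", w, outer, optimize=True)
        trace_part = np.einsum("...a,...a->...", w, invariant) / 3.0
        out = out + I3m13[..., None, None] * (struct - trace_part[..., None, None] * Cinv)
    return out


def second_piola(
    F: np.ndarray,
    K: np.ndarray,
    params: MaterialParams,
    frame: FibrilFrame,
    include_volumetric: bool = True,
) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dW/dC."""
    state = kinematics(F, frame)
    return 2.0 * _dW_dC(state, K, params, frame, include_volumetric)


def first_piola(
    F: np.ndarray,
    K: np.ndarray,
    params: MaterialParams,
    frame: FibrilFrame,
    include_volumetric: bool = True,
) -> np.ndarray:
    """First Piola-Kirchhoff stress P = F S."""
    S = second_piola(F, K, params, frame, include_volumetric)
    return np.einsum("...ik,...kj->...ij", np.asarray(F, dtype=float), S)


def _C4_deviatoric(
    state: DeformationState, K: np.ndarray, params: MaterialParams, frame: FibrilFrame
) -> np.ndarray:
    """4 d2W_dev/dC dC for the isochoric terms, shape (..., 3, 3, 3, 3)."""
    K = np.asarray(K, dtype=float)
    Cinv = np.linalg.inv(state.C)
    beta = state.I3 ** (-1.0 / 3.0)
    eye = np.eye(3)
    CiCi = np.einsum("...ij,...kl->...ijkl", Cinv, Cinv)
    CiCi_sym = 0.5 * (
        np.einsum("...ik,...jl->...ijkl", Cinv, Cinv)
        + np.einsum("...il,...jk->...ijkl", Cinv, Cinv)
    )
    b = beta[..., None, None, None, None]

    # ground substance
    eye_ci = np.einsum("ij,...kl->...ijkl", eye, Cinv) + np.einsum(
        "...ij,kl->...ijkl", Cinv, eye
    )
    I1e = state.I1[..., None, None, None, None]
    C4 = 4.0 * params.C10 * b * (-eye_ci / 3.0 + I1e / 9.0 * CiCi + I1e / 3.0 * CiCi_sym)

    # fibril families
    for invariant, dirs, mu, gamma in _fibril_families(state, params, frame):
        if mu == 0.0:
            continue
        x = beta[..., None] * invariant
        f1 = 0.5 * mu * (x ** (gamma / 2.0 - 1.0) - 1.0 / x)
        f2 = 0.5 * mu * ((gamma / 2.0 - 1.0) * x ** (gamma / 2.0 - 2.0) + 1.0 / x**2)
        gate = invariant > 1.0
        w1 = np.where(gate, K / N_ORIENTATIONS * f1, 0.0)  # (..., 16)
        w2 = np.where(gate, K / N_ORIENTATIONS * f2, 0.0)
        A = np.einsum("ai,aj->aij", dirs, dirs)
        G = A - invariant[..., None, None] / 3.0 * Cinv[..., None, :, :]
        C4 = C4 + 4.0 * (beta**2)[..., None, None, None, None] * np.einsum(
            "...a,...aij,...akl->...ijkl", w2, G, G, optimize=True
        )
        a_ci = np.einsum("...a,aij,...kl->...ijkl", w1, A, Cinv, optimize=True) + np.einsum(
            "...a,...ij,akl->...ijkl", w1, Cinv, A, optimize=True
        )
        wI = np.einsum("...a,...a->...", w1, invariant)[..., None, None, None, None]
        C4 = C4 + 4.0 * b * (-a_ci / 3.0 + wI / 9.0 * CiCi + wI / 3.0 * CiCi_sym)
    return C4


def first_elasticity(
    F: np.ndarray,
    K: np.ndarray,
    params: MaterialParams,
    frame: FibrilFrame,
    include_volumetric: bool = False,
) -> np.ndarray:
    """Consistent tangent dP/dF of the (deviatoric) first Piola stress.

    Shape ``(..., 3, 3, 3, 3)`` with ``A[i, j, k, l] = dP_ij / dF_kl``.
    Used by the finite-element kernel, whose mean-dilatation volumetric
    treatment adds its own element-level terms, so the volumetric part
    is excluded by default.
    """
    F = np.asarray(F, dtype=float)
    state = kinematics(F, frame)
    S = 2.0 * _dW_dC(state, K, params, frame, include_volumetric=False)
    C4 = _C4_deviatoric(state, K, params, frame)
    if include_volumetric:
        Cinv = np.linalg.inv(state.C)
        J = state.J[..., None, None, None, None]
        Jc = state.J
        CiCi = np.einsum("...ij,...kl->...ijkl", Cinv, Cinv)
        CiCi_sym = 0.5 * (
            np.einsum("...ik,...jl->...ijkl", Cinv, Cinv)
            + np.einsum("...il,...jk->...ijkl", Cinv, Cinv)
        )
        S = S + 2.0 * (Jc * (Jc - 1.0) / params.D)[..., None, None] * Cinv
        # 4 d2Wvol/dC2 with Wvol = (J-1)^2/D and dJ/dC = (J/2) C^-1
        C4 = C4 + (2.0 / params.D) * (
            (2.0 * J**2 - J) * CiCi - (J**2 - J) * 2.0 * CiCi_sym
        )
    A = np.einsum("ik,...jl->...ijkl", np.eye(3), S) + np.einsum(
        "...im,...kn,...mjnl->...ijkl", F, F, C4, optimize=True
    )
    return A


def cauchy_stress(
    F: np.ndarray, K: np.ndarray, params: MaterialParams, frame: FibrilFrame
) -> np.ndarray:
    """Cauchy stress sigma = (2/J) F (dW/dC) F^T, symmetric, shape (..., 3, 3)."""
    F = np.asarray(F, dtype=float)
    state = kinematics(F, frame)
    dWdC = _dW_dC(state, K, params, frame)
    sigma = (2.0 / state.J)[..., None, None] * np.einsum(
        "...ik,...kl,...jl->...ij", F, dWdC, F
    )
    return 0.5 * (sigma + np.swapaxes(sigma, -1, -2))
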