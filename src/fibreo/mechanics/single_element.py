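"""Single-element displacement cases (10 mm cube, homogeneous deformation).

The three bundled cases prescribe face displacements on a 10 mm cube:

* case 1 — 0.8 mm in both X and Y (equibiaxial, up to 8 % strain);
* case 2 — 0.8 mm in X and 0.4 mm in Y;
* case 3 — 0.8 mm in X only (uniaxial, Y free).

A single cube under affine face displacements deforms homogeneously, so
no finite-element solve is needed: the deformation gradient is diagonal
in the loading frame, with the unprescribed stretches (thickness, plus
the free lateral stretch in case 3) determined by a 1-or-2 variable
zero-traction root find.  The fibril distribution at the integration
point starts from the strip model's central (group B) distribution and
is updated from the strain state at every increment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from ..constitutive import FibrilFrame, MaterialParams, cauchy_stress, kinematics
from ..microstructure import FibrilDistribution
from ..orientations import LOADING_AXIS_BINS, N_ORIENTATIONS, TRANSVERSE_BINS
from ..reorientation import ReorientationState, update
from ..trend import ReorientationTrend

#: edge length of the cube, mm
CUBE_SIZE_MM = 10.0

#: prescribed full-load face displacements (U1, U2) in mm per case;
#: None marks a traction-free lateral face
CASE_DISPLACEMENTS = {1: (0.8, 0.8), 2: (0.8, 0.4), 3: (0.8, None)}

#: default X-strain schedule; includes every measurement checkpoint
DEFAULT_SCHEDULE = (0.005, 0.01, 0.014, 0.02, 0.028, 0.036, 0.043, 0.05, 0.06, 0.07, 0.08)


class TractionSolveError(RuntimeError):
    """Raised when the zero-traction root find fails to converge."""


def traction_free_F(
    eps_x: float,
    eps_y: float | None,
    K: np.ndarray,
    params: MaterialParams,
    frame: FibrilFrame,
    guess: np.ndarray | None = None,
    _depth: int = 0,
) -> np.ndarray:
    """Deformation gradient with prescribed X (and optionally Y) strain.

    Solves sigma_zz = 0 for the thickness stretch (plus sigma_yy = 0
    for the lateral stretch when ``eps_y`` is None).  The material is
    orthotropic in the loading frame (balanced out-of-plane families),
    so F remains diagonal.
    """
    lam_x = 1.0 + eps_x
    free_y = eps_y is None

    def unpack(v):
        if free_y:
            lam_y, lam_z = v
        else:
            lam_y = 1.0 + eps_y
            (lam_z,) = v
        return lam_y, lam_z

    def residual(v):
        lam_y, lam_z = unpack(v)
        if lam_y <= 0.05 or lam_z <= 0.05:
            return np.full(len(v), 1e6)
        sigma = cauchy_stress(np.diag([lam_x, lam_y, lam_z]), K, params, frame)
        # scale the stiff volumetric equations to O(1)
        res = [sigma[2, 2] * params.D]
        if free_y:
            res.insert(0, sigma[1, 1] * params.D)
        return np.array(res)

    if guess is None:
        lam_t = lam_x ** -0.5 if free_y else (lam_x * (1.0 + eps_y)) ** -1
        guess = np.array([lam_t, lam_t]) if free_y else np.array([lam_t])
    sol = optimize.root(residual, guess, method="hybr", tol=1e-14)
    lam_y, lam_z = unpack(sol.x)
    F = np.diag([lam_x, lam_y, lam_z])
    sigma = cauchy_stress(F, K, params, frame)
    sref = max(abs(sigma[0, 0]), params.C10, 1e-9)
    checks = [abs(sigma[2, 2])] + ([abs(sigma[1, 1])] if free_y else [])
    if max(checks) > 1e-6 * sref:
        if _depth < 4:
            # cold start too far from the root: continuation from half
            # the strain supplies a good predictor
            F_half = traction_free_F(
                0.5 * eps_x,
                None if free_y else 0.5 * eps_y,
                K,
                params,
                frame,
                _depth=_depth + 1,
            )
            half_guess = (
                np.array([F_half[1, 1], F_half[2, 2]])
                if free_y
                else np.array([F_half[2, 2]])
            )
            return traction_free_F(
                eps_x, eps_y, K, params, frame, half_guess, _depth=_depth + 1
            )
        raise TractionSolveError(
            f"zero-traction solve did not converge at eps_x={eps_x:.4f} "
            f"(residual stresses {checks}, reference {sref:.3e})"
        )
    return F


@dataclass
class SingleElementHistory:
    """Per-increment record of the homogeneous single-element run."""

    case: int
    strains: np.ndarray                # X engineering strains visited
    F: list[np.ndarray]                # deformation gradient per increment
    states: list[ReorientationState]   # reorientation state per increment

    def at_strain(self, eps_x: float, atol: float = 1e-9) -> ReorientationState:
        idx = int(np.argmin(np.abs(self.strains - eps_x)))
        if abs(self.strains[idx] - eps_x) > atol:
            raise KeyError(f"strain {eps_x} is not an increment checkpoint")
        return self.states[idx]

    def loading_axis_gain_pct(self, eps_x: float) -> float:
        """Mean percent density change in the two bins nearest the X axis."""
        st = self.at_strain(eps_x)
        return float(np.mean(st.percent_change[list(LOADING_AXIS_BINS)]))

    def transverse_loss_pct(self, eps_x: float) -> float:
        """Mean percent density change in the two bins nearest the Y axis."""
        st = self.at_strain(eps_x)
        return float(np.mean(st.percent_change[list(TRANSVERSE_BINS)]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for eps, st in zip(self.strains, self.states):
            for i in range(N_ORIENTATIONS):
                rows.append(
                    {
                        "case": self.case,
                        "strain_x": eps,
                        "orientation": i + 1,
                        "K_ref": st.K_ref.K[i],
                        "K": st.K_cur.K[i],
                        "percent_change": st.percent_change[i],
                    }
                )
        return pd.DataFrame(rows)


def single_element_case(
    case: int,
    trend: ReorientationTrend,
    K_ref: FibrilDistribution,
    params: MaterialParams | None = None,
    frame: FibrilFrame | None = None,
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE,
) -> SingleElementHistory:
    """Run one displacement case and return the density history vs strain.

    The prescribed Y displacement ramps proportionally to X (both reach
    full value together), so in case 1 the in-plane stretches are equal
    at every increment.  The distribution is updated from the converged
    strain state of each increment (state function of strain).
    """
    if case not in CASE_DISPLACEMENTS:
        raise ValueError(f"case must be one of {sorted(CASE_DISPLACEMENTS)}")
    params = params or MaterialParams()
    frame = frame or FibrilFrame.from_params(params)
    u1, u2 = CASE_DISPLACEMENTS[case]
    eps_x_max = u1 / CUBE_SIZE_MM

    Fs, states = [], []
    guess = None
    K_state = K_ref
    for eps_x in schedule:
        ramp = eps_x / eps_x_max
        eps_y = None if u2 is None else ramp * u2 / CUBE_SIZE_MM
        # staggered coupling iterated to a fixed point per increment
        for _ in range(3):
            F = traction_free_F(eps_x, eps_y, K_state.K, params, frame, guess)
            guess = np.array([F[1, 1], F[2, 2]]) if u2 is None else np.array([F[2, 2]])
            st = update(K_ref, kinematics(F, frame), trend)
            if np.abs(st.K_cur.K - K_state.K).max() < 1e-12:
                K_state = st.K_cur
                break
            K_state = st.K_cur
        Fs.append(F)
        states.append(st)
    return SingleElementHistory(case, np.asarray(schedule, dtype=float), Fs, states)
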