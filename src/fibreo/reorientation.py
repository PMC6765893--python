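"""Strain-driven update of the 16-orientation fibril distribution.

The algorithm treats the experimentally fitted uniaxial trend dK(eps)
as a directional kernel and superposes it over all 16 orientations:

1. the engineering strain along each in-plane orientation is read from
   the I4 invariants, ``eps_i = sqrt(I4_i) - 1``;
2. for every direction j whose strain exceeds the 1 % threshold, the
   16-entry trend (defined relative to the uniaxial loading axis, gain
   lobe at the pair (8, 9)) is rotated so its gain lobe is centred on
   direction j, and evaluated at eps_j;
3. the 16 rotated contributions are summed;
4. a conservation correction scales the summed change by the mean local
   density C1 (converting the trend's mean-one units to the local
   normalisation) and removes its mean, so the total fibril content is
   exactly unchanged — reorientation transfers density, it never
   creates or destroys it.

The updated distribution is a state function of the current strain: it
is recomputed from the reference (unloaded) distribution at every call,
with no history variable, so unloading retraces loading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constitutive import DeformationState
from .microstructure import FibrilDistribution
from .orientations import N_ORIENTATIONS
from .trend import ReorientationTrend


class ClampingWarning(UserWarning):
    """Issued when non-negativity clamping removes a large share of the transfer."""


@dataclass
class ReorientationState:
    """Reference and current distributions plus the driving strains."""

    K_ref: FibrilDistribution
    K_cur: FibrilDistribution
    eps: np.ndarray  # (16,) per-orientation engineering strains

    @property
    def dK(self) -> np.ndarray:
        return self.K_cur.K - self.K_ref.K

    @property
    def percent_change(self) -> np.ndarray:
        """100 (K_cur - K_ref) / K_ref per orientation."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.K_ref.K > 0, 100.0 * self.dK / self.K_ref.K, 0.0
            )


def directional_strains(state: DeformationState) -> np.ndarray:
    """Engineering strain along each in-plane orientation: sqrt(I4_i) - 1."""
    return np.sqrt(state.I4) - 1.0


def trend_contribution(trend: ReorientationTrend, eps_j: float, j: int) -> np.ndarray:
    """Change components contributed by the strain along direction ``j``.

    ``j`` is the 0-based orientation index.  The trend table, whose gain
    lobe sits at the pair (8, 9) around the uniaxial loading axis, is
    rotated so the gain pair lands on bins (j, j+1): entry k receives
    the trend value at offset ``(k - j + 7) mod 16`` (0-based).  For
    j = 7 (bin 8) the rotation is the identity.  Returns all zeros when
    the strain is at or below the threshold (compression included).
    """
    if eps_j <= trend.eps_threshold:
        return np.zeros(N_ORIENTATIONS)
    table = trend.evaluate(max(float(eps_j), 0.0))
    offsets = (np.arange(N_ORIENTATIONS) - j + 7) % N_ORIENTATIONS
    return table[offsets]


def superpose(trend: ReorientationTrend, eps: np.ndarray) -> np.ndarray:
    """Sum the rotated trend contributions of all 16 directional strains."""
    eps = np.asarray(eps, dtype=float)
    if eps.shape != (N_ORIENTATIONS,):
        raise ValueError(f"expected {N_ORIENTATIONS} directional strains")
    out = np.zeros(N_ORIENTATIONS)
    for j in range(N_ORIENTATIONS):
        out += trend_contribution(trend, eps[j], j)
    return out


def conserve(dK: np.ndarray, K: FibrilDistribution | np.ndarray) -> np.ndarray:
    """Apply the density-scaling conservation correction.

    The raw summed change is scaled per orientation by
    ``C1 = mean(K)`` — which converts the trend's mean-one units to the
    units of the local distribution — and its mean is removed so that
    the corrected change sums to exactly zero.  A change that already
    sums to zero is only C1-scaled.
    """
    Kv = K.K if isinstance(K, FibrilDistribution) else np.asarray(K, dtype=float)
    dK = np.asarray(dK, dtype=float)
    C1 = Kv.mean()
    return C1 * (dK - dK.mean())


def update(
    K_ref: FibrilDistribution,
    defo: DeformationState,
    trend: ReorientationTrend,
    clamp_warn_fraction: float = 0.5,
) -> ReorientationState:
    """Recompute the current distribution from the reference and a strain state.

    ``K_cur = clamp_nonneg(K_ref + conserve(superpose(trend, eps), K_ref))``,
    rebalanced proportionally after any clamping so the total content
    equals that of the reference exactly.  Emits a
    :class:`ClampingWarning` when clamping removes more than
    ``clamp_warn_fraction`` of the transferred content (the trend
    magnitudes are then too large for this distribution).
    """
    eps = directional_strains(defo)
    dK = conserve(superpose(trend, eps), K_ref)
    K_new = K_ref.K + dK
    if np.any(K_new < 0.0):
        clamped = -K_new[K_new < 0.0].sum()
        transferred = 0.5 * np.abs(dK).sum()
        if transferred > 0.0 and clamped > clamp_warn_fraction * transferred:
            warnings.warn(
                f"non-negativity clamping removed {100 * clamped / transferred:.1f}% of the "
                "transferred fibril content; trend magnitudes are too large for this "
                "distribution",
                ClampingWarning,
                stacklevel=2,
            )
        K_new = np.clip(K_new, 0.0, None)
        total = K_new.sum()
        if total > 0.0:
            K_new = K_new * (K_ref.K.sum() / total)
    return ReorientationState(
        K_ref=K_ref,
        K_cur=FibrilDistribution(K_new, K_ref.normalization),
        eps=eps,
    )
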