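"""Material-point biaxial strain-ratio sweep.

Characterises how the reorientation response grows with loading
anisotropy, mirroring the situation near a surgical tissue-removal
boundary where the circumferential strain exceeds the radial strain: a
material point is subjected to in-plane biaxial stretch with the
circumferential strain fixed and the radial strain reduced by the
requested circumferential/radial ratio.  At ratio 1 (equibiaxial, the
intact situation) the update is exactly neutral; the density gain in
the two bins nearest the circumferential axis increases monotonically
with the ratio.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..constitutive import FibrilFrame, MaterialParams, kinematics
from ..microstructure import FibrilDistribution
from ..orientations import LOADING_AXIS_BINS
from ..reorientation import update
from ..trend import ReorientationTrend
from .single_element import traction_free_F


def biaxial_sweep(
    strain_ratios,
    trend: ReorientationTrend,
    K_ref: FibrilDistribution,
    max_strain: float = 0.05,
    params: MaterialParams | None = None,
    frame: FibrilFrame | None = None,
) -> pd.DataFrame:
    """Density change in the near-axis bins versus strain ratio.

    The circumferential direction is the local X axis (between
    orientation bins 8 and 9); for each ratio the point sees
    circumferential strain ``max_strain`` and radial strain
    ``max_strain / ratio``, with the thickness response traction free.
    Returns a DataFrame with columns ``ratio``, ``eps_circ``,
    ``eps_rad`` and ``near_axis_gain_pct``.
    """
    params = params or MaterialParams()
    frame = frame or FibrilFrame.from_params(params)
    rows = []
    for ratio in strain_ratios:
        if ratio < 1.0:
            raise ValueError("strain ratio is circumferential/radial and must be >= 1")
        eps_c = float(max_strain)
        eps_r = eps_c / float(ratio)
        F = traction_free_F(eps_c, eps_r, K_ref.K, params, frame)
        st = update(K_ref, kinematics(F, frame), trend)
        gain = float(np.mean(st.percent_change[list(LOADING_AXIS_BINS)]))
        rows.append(
            {
                "ratio": float(ratio),
                "eps_circ": eps_c,
                "eps_rad": eps_r,
                "near_axis_gain_pct": gain,
            }
        )
    return pd.DataFrame(rows)
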