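"""Angular conventions shared across the package.

Collagen-fibril orientations are *axial*: an angle theta and theta + 180
degrees describe the same fibril axis.  X-ray scans report 256 azimuthal
readings over the full circle (uniform spacing of 360/256 = 1.40625
degrees, stored exactly; "1.4 degrees" in common usage is a rounding);
point symmetry therefore leaves 128 unique axes, which the numerical
model further reduces to 16 orientation bins with centres

    theta_i = pi/32 + (i - 1) * pi/16,   i = 1, ..., 16.

Reading j (0-based) is taken to sit at azimuth (j + 0.5) * 360/256
degrees, so that the eight fine axes aggregated into orientation bin i
are centred exactly on theta_i, and the specimen loading axis (local
angle 90 degrees) falls on the boundary between bins 8 and 9 while the
transverse axis falls between bins 16 and 1.

In the local tangent plane the unit direction of bin i is
(sin theta_i, cos theta_i, 0): the loading axis maps onto the global X
axis and the transverse axis onto Y.  Orientations symmetric about the
loading axis pair up as (1, 16), (2, 15), ..., (8, 9).
"""

from __future__ import annotations

import numpy as np

#: number of discretised fibril orientations used by the model
N_ORIENTATIONS = 16

#: number of azimuthal intensity readings in one scan
N_READINGS = 256

#: number of unique fibril axes after point-symmetric folding
N_AXES = N_READINGS // 2

#: azimuthal spacing of the raw readings, degrees (exact value)
READING_SPACING_DEG = 360.0 / N_READINGS

#: orientation-bin centres theta_i, radians, shape (16,)
ORIENTATION_ANGLES = np.pi / 32 + np.pi / 16 * np.arange(N_ORIENTATIONS)

#: 0-based index pairs symmetric about the loading axis: (0,15), (1,14), ...
SYMMETRIC_PAIRS = tuple((m, N_ORIENTATIONS - 1 - m) for m in range(N_ORIENTATIONS // 2))

#: 0-based indices of the two bins adjacent to the loading (X) axis
LOADING_AXIS_BINS = (7, 8)

#: 0-based indices of the two bins adjacent to the transverse (Y) axis
TRANSVERSE_BINS = (0, 15)


def reading_angles_deg() -> np.ndarray:
    """Azimuths of the 256 raw readings in degrees, shape (256,)."""
    return (np.arange(N_READINGS) + 0.5) * READING_SPACING_DEG


def axis_angles_deg() -> np.ndarray:
    """Azimuths of the 128 unique fibril axes in degrees, shape (128,)."""
    return (np.arange(N_AXES) + 0.5) * READING_SPACING_DEG


def in_plane_directions() -> np.ndarray:
    """Unit tangent-plane direction of each orientation bin, shape (16, 3)."""
    th = ORIENTATION_ANGLES
    return np.column_stack([np.sin(th), np.cos(th), np.zeros(N_ORIENTATIONS)])


def out_of_plane_directions(elevation_deg: float = 15.0) -> np.ndarray:
    """Unit direction of each out-of-plane fibril family, shape (16, 3).

    Shares the azimuth of the in-plane bin and is elevated
    ``elevation_deg`` above the tangent plane (towards +Z).
    """
    th = ORIENTATION_ANGLES
    al = np.deg2rad(elevation_deg)
    return np.column_stack(
        [
            np.sin(th) * np.cos(al),
            np.cos(th) * np.cos(al),
            np.full(N_ORIENTATIONS, np.sin(al)),
        ]
    )
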