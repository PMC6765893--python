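"""Processing of angular X-ray-scattering fibril-density profiles.

The pipeline mirrors how strip-extensometry scattering data are reduced
for use in a 16-orientation constitutive model:

1. :func:`normalize_total` — equate the total fibril content of each
   scanned point to 1.0, removing repeat-scan intensity variation
   (ex-vivo tissue cannot synthesise collagen, so the true total is
   constant).
2. :func:`fold_to_axes` — average point-symmetric readings (theta and
   theta + 180 degrees), leaving the 128 unique fibril axes.
3. :func:`reduce_orientations` — aggregate groups of 8 consecutive axes
   into the 16 orientation bins used by the numerical model.
4. :func:`delta_density` / :func:`symmetrize` — per-orientation density
   change relative to the unloaded state, averaged over pairs of
   orientations symmetric about the specimen's longitudinal axis.
5. :func:`average_regions` — collapse the 40 scan points of a strip
   specimen into the three distinctive regions A, B, C.
6. :func:`fit_trend` — least-squares fit of the piecewise-linear
   strain–reorientation trend (1 % threshold, 5 % knee) to a series of
   distributions measured at increasing strain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orientations import (
    N_AXES,
    N_ORIENTATIONS,
    N_READINGS,
    ORIENTATION_ANGLES,
    READING_SPACING_DEG,
    SYMMETRIC_PAIRS,
    reading_angles_deg,
)
from .trend import ReorientationTrend


class EmptyScanError(ValueError):
    """Raised when a profile carries no fibril content at all."""


class AsymmetryWarning(UserWarning):
    """Issued when a scan violates point symmetry beyond tolerance."""


class DegenerateSeriesWarning(UserWarning):
    """Issued when a strain series shows no change and a zero trend is returned."""


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass
class AngularProfile:
    """One raw 256-bin azimuthal fibril-density scan at a point and strain."""

    densities: np.ndarray
    point_id: str = ""
    strain: float = 0.0

    def __post_init__(self):
        d = np.asarray(self.densities, dtype=float)
        if d.shape != (N_READINGS,):
            raise ValueError(f"profile must have exactly {N_READINGS} readings, got {d.shape}")
        if np.any(d < 0):
            raise ValueError("fibril densities must be non-negative")
        self.densities = d

    @property
    def angles_deg(self) -> np.ndarray:
        return reading_angles_deg()

    @property
    def total(self) -> float:
        return float(self.densities.sum())

    def asymmetry(self) -> float:
        """Relative point-symmetry violation: max |d(theta) - d(theta+180)| / mean."""
        half = self.densities[:N_AXES]
        other = self.densities[N_AXES:]
        mean = self.densities.mean()
        if mean == 0.0:
            return 0.0
        return float(np.max(np.abs(half - other)) / mean)


@dataclass
class FibrilDistribution:
    """Discretised 16-orientation fibril density K.

    ``normalization`` records the convention the values follow:
    ``"total_one"`` (sum of K equals 1, the canonical pipeline mode),
    ``"mean_one"`` (average of K equals 1, the plotting convention) or
    ``"raw"`` (arbitrary intensity units).
    """

    K: np.ndarray
    normalization: str = "raw"

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        if K.shape != (N_ORIENTATIONS,):
            raise ValueError(f"K must have {N_ORIENTATIONS} entries, got {K.shape}")
        if np.any(K < -1e-12):
            raise ValueError("fibril densities must be non-negative")
        if self.normalization not in ("total_one", "mean_one", "raw"):
            raise ValueError(f"unknown normalization mode {self.normalization!r}")
        self.K = np.clip(K, 0.0, None)

    @property
    def theta(self) -> np.ndarray:
        return ORIENTATION_ANGLES

    @property
    def total(self) -> float:
        return float(self.K.sum())

    def rescaled(self, mode: str) -> "FibrilDistribution":
        """Return a copy rescaled to ``total_one`` or ``mean_one``."""
        if self.total <= 0.0:
            raise EmptyScanError("cannot rescale a distribution with zero total content")
        if mode == "total_one":
            return FibrilDistribution(self.K / self.total, "total_one")
        if mode == "mean_one":
            return FibrilDistribution(self.K / self.K.mean(), "mean_one")
        raise ValueError(f"unknown normalization mode {mode!r}")


@dataclass
class DeltaDistribution:
    """Signed change in fibril density per orientation at one strain level."""

    dK: np.ndarray
    strain: float

    def __post_init__(self):
        dK = np.asarray(self.dK, dtype=float)
        if dK.shape != (N_ORIENTATIONS,):
            raise ValueError(f"dK must have {N_ORIENTATIONS} entries")
        self.dK = dK


@dataclass
class StrainSeries:
    """Distributions measured at the same point/region at increasing strain."""

    strains: np.ndarray
    distributions: list[FibrilDistribution]

    def __post_init__(self):
        s = np.asarray(self.strains, dtype=float)
        if s.ndim != 1 or len(s) != len(self.distributions):
            raise ValueError("one distribution is required per strain level")
        if np.any(np.diff(s) <= 0):
            raise ValueError("strain levels must be strictly increasing")
        modes = {d.normalization for d in self.distributions}
        if len(modes) > 1:
            raise ValueError("all distributions in a series must share a normalization mode")
        self.strains = s


#: default strain levels at which scattering measurements were taken
MEASUREMENT_STRAINS = (0.0, 0.014, 0.028, 0.05, 0.08)


@dataclass(frozen=True)
class RegionMap:
    """Assignment of the 40 strip scan points to 5 groups and 3 regions.

    Points are ordered along the specimen axis and split into 5
    longitudinal groups of 8.  Mid-length symmetry pairs group 1 with 5
    and 2 with 4, collapsing the model to regions A (outer), B
    (intermediate) and C (central).
    """

    n_points: int = 40
    n_groups: int = 5

    def __post_init__(self):
        if self.n_points % self.n_groups:
            raise ValueError("points must divide evenly into groups")

    @property
    def group_size(self) -> int:
        return self.n_points // self.n_groups

    def group_of(self, point: int) -> int:
        """1-based group index of a 0-based point index."""
        return point // self.group_size + 1

    def region_of_group(self, group: int) -> str:
        pairing = {1: "A", 5: "A", 2: "B", 4: "B", 3: "C"}
        return pairing[group]

    def points_in_region(self, region: str) -> list[int]:
        return [
            p
            for p in range(self.n_points)
            if self.region_of_group(self.group_of(p)) == region
        ]


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------
def normalize_total(profile: AngularProfile) -> AngularProfile:
    """Scale a profile so its total fibril content equals exactly 1.0.

    Shape is preserved (every bin is scaled by the same factor).
    Raises :class:`EmptyScanError` for an all-zero profile.
    """
    total = profile.total
    if total <= 0.0:
        raise EmptyScanError(f"profile {profile.point_id!r} has no fibril content")
    return AngularProfile(profile.densities / total, profile.point_id, profile.strain)


def fold_to_axes(profile: AngularProfile, asymmetry_tol: float = 0.25) -> np.ndarray:
    """Collapse the 256 point-symmetric readings onto the 128 unique axes.

    Axis j carries the mean of readings j and j + 128.  A physically
    valid scan is point symmetric up to noise; if the relative
    asymmetry exceeds ``asymmetry_tol`` an :class:`AsymmetryWarning` is
    recorded and the mean is still taken.
    """
    asym = profile.asymmetry()
    if asym > asymmetry_tol:
        warnings.warn(
            f"profile {profile.point_id!r} violates point symmetry "
            f"(relative asymmetry {asym:.3f} > {asymmetry_tol}); folding anyway",
            AsymmetryWarning,
            stacklevel=2,
        )
    return 0.5 * (profile.densities[:N_AXES] + profile.densities[N_AXES:])


def reduce_orientations(axial: np.ndarray, n: int = N_ORIENTATIONS) -> FibrilDistribution:
    """Aggregate the 128 axial densities into ``n`` orientation bins.

    Bin i sums the ``128 / n`` consecutive axial values whose angles lie
    in the half-open window centred on theta_i; total content is
    conserved exactly.
    """
    axial = np.asarray(axial, dtype=float)
    if axial.shape != (N_AXES,):
        raise ValueError(f"expected {N_AXES} axial values, got {axial.shape}")
    if n <= 0 or N_AXES % n:
        raise ValueError(f"orientation count {n} must divide {N_AXES}")
    if n != N_ORIENTATIONS:
        # the model runs on 16 orientations; other divisors are allowed
        # for convergence experiments and return a plain array
        return axial.reshape(n, N_AXES // n).sum(axis=1)
    K = axial.reshape(n, N_AXES // n).sum(axis=1)
    return FibrilDistribution(K, "raw")


def profile_to_distribution(
    profile: AngularProfile, mode: str = "total_one", asymmetry_tol: float = 0.25
) -> FibrilDistribution:
    """Full single-point pipeline: normalise, fold, reduce, rescale."""
    axial = fold_to_axes(normalize_total(profile), asymmetry_tol)
    return reduce_orientations(axial).rescaled(mode)


def delta_density(K_eps: FibrilDistribution, K_0: FibrilDistribution, strain: float | None = None) -> DeltaDistribution:
    """Per-orientation density change ``K_eps - K_0`` (Delta-K at one strain)."""
    if K_eps.normalization != K_0.normalization:
        raise ValueError(
            f"cannot difference distributions with mismatched normalisations "
            f"({K_eps.normalization!r} vs {K_0.normalization!r})"
        )
    return DeltaDistribution(K_eps.K - K_0.K, strain=float(strain) if strain is not None else 0.0)


def symmetrize(d: DeltaDistribution) -> DeltaDistribution:
    """Average each pair of orientations symmetric about the loading axis.

    Both members of a pair (1,16), (2,15), ... receive the pair mean, so
    the output has at most 8 distinct values and the total is unchanged.
    Idempotent.
    """
    out = d.dK.copy()
    for m, n in SYMMETRIC_PAIRS:
        pair_mean = 0.5 * (out[m] + out[n])
        out[m] = pair_mean
        out[n] = pair_mean
    return DeltaDistribution(out, d.strain)


def average_regions(
    points: list[FibrilDistribution], region_map: RegionMap | None = None
) -> dict[str, FibrilDistribution]:
    """Collapse 40 per-point distributions into regions A, B and C.

    Region values are per-orientation arithmetic means over all points
    assigned to the region (16 points for A and B, 8 for C).
    """
    region_map = region_map or RegionMap()
    if len(points) != region_map.n_points:
        raise ValueError(f"expected {region_map.n_points} points, got {len(points)}")
    modes = {p.normalization for p in points}
    if len(modes) > 1:
        raise ValueError("all point distributions must share a normalization mode")
    mode = modes.pop()
    out = {}
    for region in ("A", "B", "C"):
        idx = region_map.points_in_region(region)
        out[region] = FibrilDistribution(
            np.mean([points[p].K for p in idx], axis=0), mode
        )
    return out


def fit_trend(
    series: StrainSeries,
    eps_threshold: float = 0.01,
    eps_mid: float = 0.05,
    eps_max: float = 0.08,
) -> ReorientationTrend:
    """Fit the piecewise-linear reorientation trend to a strain series.

    The observed per-orientation changes relative to the unloaded state
    are symmetry-averaged over orientation pairs and regressed, by
    linear least squares, onto the two-ramp basis

        dK(eps) = s_mid * (min(eps, eps_mid) - eps_t)_+  +  s_high * (eps - eps_mid)_+

    Slopes are expressed in mean-one density units (divided by the mean
    density of the unloaded distribution), then projected onto the
    conserving subspace (zero sum over orientations) to absorb residual
    noise.  A degenerate series with no change returns a zero trend and
    records a :class:`DegenerateSeriesWarning`.
    """
    strains = series.strains
    if len(strains) < 3 or strains[0] > eps_threshold or strains[-1] <= eps_mid:
        raise ValueError(
            "series must contain at least 3 strain levels spanning the trend knots"
        )
    K0 = series.distributions[0]
    scale = K0.K.mean()
    if scale <= 0:
        raise EmptyScanError("unloaded distribution has no content")

    deltas = np.array(
        [
            symmetrize(delta_density(d, K0, strain=s)).dK
            for s, d in zip(strains, series.distributions)
        ]
    )  # (n_strains, 16)

    if np.allclose(deltas, 0.0, atol=1e-15):
        warnings.warn(
            "strain series shows no density change; returning zero trend",
            DegenerateSeriesWarning,
            stacklevel=2,
        )
        z = np.zeros(N_ORIENTATIONS)
        return ReorientationTrend(z, z.copy(), eps_threshold, eps_mid, eps_max, residual_rms=0.0)

    ramp_mid = np.clip(strains, eps_threshold, eps_mid) - eps_threshold
    ramp_high = np.clip(strains - eps_mid, 0.0, None)
    X = np.column_stack([ramp_mid, ramp_high])  # (n_strains, 2)
    coef, *_ = np.linalg.lstsq(X, deltas, rcond=None)  # (2, 16)
    resid = deltas - X @ coef
    trend = ReorientationTrend(
        slope_mid=coef[0] / scale,
        slope_high=coef[1] / scale,
        eps_threshold=eps_threshold,
        eps_mid=eps_mid,
        eps_max=eps_max,
        residual_rms=float(np.sqrt(np.mean(resid**2)) / scale),
    )
    return trend.projected_conserving()


# ----------------------------------------------------------------------
# file interchange
# ----------------------------------------------------------------------
def read_scans_csv(path) -> list[AngularProfile]:
    """Read a long-format scan CSV (columns point_id, strain, angle_deg, density).

    Returns one :class:`AngularProfile` per (point_id, strain) pair,
    with readings ordered by angle.
    """
    df = pd.read_csv(path)
    required = {"point_id", "strain", "angle_deg", "density"}
    if not required.issubset(df.columns):
        raise ValueError(f"scan CSV must contain columns {sorted(required)}")
    profiles = []
    for (pid, strain), grp in df.groupby(["point_id", "strain"], sort=True):
        grp = grp.sort_values("angle_deg")
        profiles.append(AngularProfile(grp["density"].to_numpy(), str(pid), float(strain)))
    return profiles


def write_scans_csv(profiles: list[AngularProfile], path) -> None:
    """Write profiles to the long-format scan CSV."""
    frames = []
    for p in profiles:
        frames.append(
            pd.DataFrame(
                {
                    "point_id": p.point_id,
                    "strain": p.strain,
                    "angle_deg": p.angles_deg,
                    "density": p.densities,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def distributions_to_csv(dists: dict[str, FibrilDistribution], path) -> None:
    """Write named 16-orientation distributions to CSV (long format)."""
    rows = []
    for name, d in dists.items():
        for i in range(N_ORIENTATIONS):
            rows.append(
                {
                    "name": name,
                    "orientation": i + 1,
                    "theta_rad": ORIENTATION_ANGLES[i],
                    "K": d.K[i],
                    "normalization": d.normalization,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
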