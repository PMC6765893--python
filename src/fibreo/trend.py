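"""Piecewise-linear strain–reorientation trends.

A :class:`ReorientationTrend` stores, for each of the 16 orientation
bins, the change in fibril density dK as a continuous piecewise-linear
function of the axial engineering strain eps applied along the loading
axis (the axis between bins 8 and 9):

* ``dK = 0`` for ``eps <= eps_threshold`` (default 1 % strain — below
  this level the measured reorientation is negligible);
* slope ``slope_mid`` on ``(eps_threshold, eps_mid]`` (default knee at
  5 % strain);
* slope ``slope_high`` beyond ``eps_mid`` (experimentally the rate drops
  by roughly two thirds past the knee).

Trends are expressed in *mean-one* density units (average fibril density
across the 16 orientations equal to 1); the conservation correction of
the reorientation algorithm rescales them to the units of the local
distribution.  Orientations symmetric about the loading axis carry
identical functions, and a conserving trend sums to zero over the 16
bins at every strain so that reorientation transfers density without
creating or destroying it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .orientations import N_ORIENTATIONS, SYMMETRIC_PAIRS


@dataclass(frozen=True)
class ReorientationTrend:
    """Per-orientation piecewise-linear dK(eps) with fixed strain knots."""

    slope_mid: np.ndarray          # (16,) slope on (eps_threshold, eps_mid], mean-one units / strain
    slope_high: np.ndarray         # (16,) slope beyond eps_mid
    eps_threshold: float = 0.01
    eps_mid: float = 0.05
    eps_max: float = 0.08
    residual_rms: float | None = None  # RMS misfit of the least-squares fit, if fitted

    def __post_init__(self):
        sm = np.asarray(self.slope_mid, dtype=float)
        sh = np.asarray(self.slope_high, dtype=float)
        if sm.shape != (N_ORIENTATIONS,) or sh.shape != (N_ORIENTATIONS,):
            raise ValueError("trend slopes must have 16 entries")
        if not (0.0 <= self.eps_threshold < self.eps_mid < self.eps_max):
            raise ValueError("strain knots must satisfy 0 <= eps_threshold < eps_mid < eps_max")
        object.__setattr__(self, "slope_mid", sm)
        object.__setattr__(self, "slope_high", sh)

    # ------------------------------------------------------------------
    # evaluation
    # ------------------------------------------------------------------
    def evaluate(self, eps: float) -> np.ndarray:
        """dK for all 16 orientations at axial strain ``eps``.

        Negative strains contribute nothing (no trend was measured in
        compression).  Strains beyond ``eps_max`` are extrapolated with
        the reduced high-strain slope.
        """
        eps = float(eps)
        if eps <= self.eps_threshold:
            return np.zeros(N_ORIENTATIONS)
        mid = min(eps, self.eps_mid) - self.eps_threshold
        high = max(eps - self.eps_mid, 0.0)
        return self.slope_mid * mid + self.slope_high * high

    @property
    def reduction_factor(self) -> np.ndarray:
        """Ratio of high-strain to mid-range slope per orientation (nan where flat)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.slope_mid != 0.0, self.slope_high / self.slope_mid, np.nan)

    # ------------------------------------------------------------------
    # invariants
    # ------------------------------------------------------------------
    def is_conserving(self, tol: float = 1e-10) -> bool:
        """True when dK sums to zero over the 16 bins at every strain."""
        return abs(self.slope_mid.sum()) <= tol and abs(self.slope_high.sum()) <= tol

    def is_symmetric(self, tol: float = 1e-12) -> bool:
        """True when paired orientations (1,16), (2,15), ... carry equal functions."""
        for m, n in SYMMETRIC_PAIRS:
            if abs(self.slope_mid[m] - self.slope_mid[n]) > tol:
                return False
            if abs(self.slope_high[m] - self.slope_high[n]) > tol:
                return False
        return True

    def projected_conserving(self) -> "ReorientationTrend":
        """Remove the mean slope from each segment so the trend conserves exactly."""
        return replace(
            self,
            slope_mid=self.slope_mid - self.slope_mid.mean(),
            slope_high=self.slope_high - self.slope_high.mean(),
        )

    # ------------------------------------------------------------------
    # JSON interchange
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        out = {
            "units": "mean_one",
            "eps_threshold": self.eps_threshold,
            "eps_mid": self.eps_mid,
            "eps_max": self.eps_max,
            "slope_mid": self.slope_mid.tolist(),
            "slope_high": self.slope_high.tolist(),
            "reduction_factor": [None if np.isnan(r) else r for r in self.reduction_factor],
        }
        if self.residual_rms is not None:
            out["residual_rms"] = self.residual_rms
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ReorientationTrend":
        return cls(
            slope_mid=np.asarray(d["slope_mid"], dtype=float),
            slope_high=np.asarray(d["slope_high"], dtype=float),
            eps_threshold=float(d.get("eps_threshold", 0.01)),
            eps_mid=float(d.get("eps_mid", 0.05)),
            eps_max=float(d.get("eps_max", 0.08)),
            residual_rms=d.get("residual_rms"),
        )

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_file(cls, path: str | Path) -> "ReorientationTrend":
        return cls.from_dict(json.loads(Path(path).read_text()))


def zero_trend(
    eps_threshold: float = 0.01, eps_mid: float = 0.05, eps_max: float = 0.08
) -> ReorientationTrend:
    """A trend that produces no reorientation at any strain."""
    z = np.zeros(N_ORIENTATIONS)
    return ReorientationTrend(z, z.copy(), eps_threshold, eps_mid, eps_max)
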