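"""Time-dependent model inputs.

Two empirical curves drive the simulator: area-based net photosynthesis
A(DAS) (umol CO2 m^-2 s^-1), fitted as a third-order polynomial over days
after seeding, and the projected-to-total leaf area ratio r(DAS), fitted as
a power law.  The ratio quantifies leaf overlap: overlapped leaf area
photosynthesizes at a reduced rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import PhaseSchedule

__all__ = [
    "PhotosynthesisCurve",
    "OverlapRatioCurve",
    "fit_photo_curve",
    "fit_overlap_curve",
    "is_daylight",
]


@dataclass(frozen=True)
class PhotosynthesisCurve:
    """Cubic A(das) = c0 + c1*das + c2*das^2 + c3*das^3, clipped at a floor.

    Cubic tails extrapolated beyond the measured range are untrustworthy, so
    evaluations are clipped below at ``floor`` (>= 0).
    """

    coeffs: tuple[float, float, float, float]
    das_range: tuple[float, float] = (1.0, 90.0)
    floor: float = 0.0
    scale: float = 1.0  # multiplicative perturbation hook

    def __post_init__(self) -> None:
        if len(self.coeffs) != 4:
            raise ValueError("expected 4 cubic coefficients (c0..c3)")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")

    def __call__(self, das) -> float:
        c0, c1, c2, c3 = self.coeffs
        d = np.asarray(das, dtype=float)
        lo, hi = self.das_range
        if np.any(d < lo) or np.any(d > hi):
            raise ValueError(f"DAS {das} outside curve domain [{lo}, {hi}]")
        val = self.scale * (c0 + d * (c1 + d * (c2 + d * c3)))
        out = np.maximum(val, self.floor)
        return float(out) if out.ndim == 0 else out

    def scaled(self, factor: float) -> "PhotosynthesisCurve":
        return PhotosynthesisCurve(
            self.coeffs, self.das_range, self.floor, self.scale * factor
        )


@dataclass(frozen=True)
class OverlapRatioCurve:
    """Power law r(das) = a * das^b, clamped into (0, 1].

    ``on_area=True`` re-interprets the argument of the power law as total
    leaf area instead of DAS (the published plot uses leaf area; DAS keeps
    the driver decoupled from simulated state and is the default).
    """

    a: float
    b: float
    clamp: tuple[float, float] = (1e-6, 1.0)
    on_area: bool = False

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("power-law prefactor must be positive")
        lo, hi = self.clamp
        if not 0 < lo <= hi <= 1:
            raise ValueError("clamp bounds must satisfy 0 < lo <= hi <= 1")

    def __call__(self, x) -> float:
        xv = np.asarray(x, dtype=float)
        if np.any(xv <= 0):
            raise ValueError("power-law argument must be positive")
        val = self.a * np.power(xv, self.b)
        out = np.clip(val, self.clamp[0], self.clamp[1])
        return float(out) if out.ndim == 0 else out


def fit_photo_curve(points, das_range=None, floor: float = 0.0):
    """Least-squares cubic fit of photosynthesis measurements.

    Parameters
    ----------
    points : sequence of (das, A) pairs, at least 4
    das_range : optional explicit curve domain; defaults to the span of the
        points

    Returns
    -------
    (PhotosynthesisCurve, residuals ndarray)
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise ValueError("need at least 4 (das, A) points for a cubic fit")
    das, a = pts[:, 0], pts[:, 1]
    design = np.vander(das, 4, increasing=True)
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("rank-deficient design: DAS values must be distinct")
    coef, *_ = np.linalg.lstsq(design, a, rcond=None)
    resid = a - design @ coef
    rng = das_range if das_range is not None else (float(das.min()), float(das.max()))
    return PhotosynthesisCurve(tuple(coef), rng, floor), resid


def fit_overlap_curve(points, on_area: bool = False):
    """Log-log linear least-squares power-law fit of overlap-ratio points.

    Points are (das_or_area, ratio) with ratio in (0, 1]; at least 2 points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (x, ratio) points")
    x, r = pts[:, 0], pts[:, 1]
    if np.any(x <= 0) or np.any(r <= 0) or np.any(r > 1):
        raise ValueError("x must be positive and ratios in (0, 1]")
    b, loga = np.polyfit(np.log(x), np.log(r), 1)
    return OverlapRatioCurve(a=math.exp(loga), b=float(b), on_area=on_area)


def is_daylight(das: int, hour: int, schedule: PhaseSchedule) -> bool:
    """True during the light block, placed at hours [0, photoperiod).

    The model has no within-day asymmetry, so the placement of the light
    block is inconsequential; dawn is hour 0 by convention.
    """
    if not 0 <= hour < 24:
        raise ValueError("hour must lie in [0, 24)")
    return hour < schedule.photoperiod_h
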