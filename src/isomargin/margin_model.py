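"""Statistical CTV-to-PTV margin model under combined translational and rotational setup error.

In single-isocenter multiple-target (SIMT) cranial radiosurgery every lesion is
set up relative to one machine isocenter.  Residual translational setup error is
an isotropic 3-D normal displacement with standard deviation ``sigma_s`` (mm)
that is the same for every point of every target.  Residual rotational error is
a small random rotation about the isocenter with per-axis standard deviation
``sigma_d`` (degrees); its positional effect on a clinical-target-volume (CTV)
point grows linearly with the point's distance ``d`` from the isocenter,

    sigma_R(d) = 0.816 * (pi / 180) * d * sigma_d     [mm]

(the 0.816 factor maps the three rotational degrees of freedom onto an
equivalent isotropic positional SD; the printed 5-d.p. rounding of the
coefficient is 0.01424 mm per mm·degree).  Requiring that the planning target
volume (PTV) cover the displaced CTV point with probability ``alpha`` yields a
nonuniform, distance-dependent margin

    M(d) = chi_alpha * sqrt(sigma_s**2 + sigma_R(d)**2)
         = sqrt(M_S**2 + M_R(d)**2),

where ``chi_alpha`` is the square root of the alpha-quantile of the chi-squared
distribution with three degrees of freedom (2.795 for alpha = 0.95) and
``M_S = chi_alpha * sigma_s`` is the familiar uniform translational margin.

All public quantities are in millimetres and degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy import stats

__all__ = [
    "ROTATIONAL_MM_PER_MM_DEG",
    "SetupUncertainty",
    "MarginSample",
    "chi_alpha",
    "rotational_sd",
    "point_margin",
    "margins",
]

#: Conversion from (distance [mm] x rotational SD [deg]) to positional SD [mm].
#: Kept at full float precision; 0.01424 is its 5-d.p. printed rounding.
ROTATIONAL_MM_PER_MM_DEG: float = 0.816 * math.pi / 180.0


def chi_alpha(alpha: float) -> float:
    """Coverage multiplier: sqrt of the ``alpha``-quantile of chi-squared(3).

    Scales an isotropic positional SD into the radius of a sphere containing
    the random displacement with probability ``alpha``.  Strictly increasing
    in ``alpha``; ``chi_alpha(0.95)`` rounds to the conventional 2.795.

    Raises
    ------
    ValueError
        If ``alpha`` is not strictly inside (0, 1).
    """
    if not 0.0 < float(alpha) < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    return float(math.sqrt(stats.chi2.ppf(alpha, df=3)))


def rotational_sd(d, sigma_d):
    """Positional SD [mm] induced at distance ``d`` [mm] by rotational SD ``sigma_d`` [deg].

    Linear in both arguments: ``0.816 * (pi/180) * d * sigma_d``.  Accepts
    scalars or arrays of distances.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0.0):
        raise ValueError("distance d must be non-negative")
    if sigma_d < 0.0:
        raise ValueError("sigma_d must be non-negative")
    out = ROTATIONAL_MM_PER_MM_DEG * d * float(sigma_d)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SetupUncertainty:
    """Setup-uncertainty parameters of the margin model.

    Parameters
    ----------
    sigma_s : float
        Translational setup SD, mm (canonical stored parameter).
    sigma_d : float
        Rotational setup SD, degrees.
    alpha : float
        Coverage probability in (0, 1); default 0.95.

    The translational *margin* view ``m_s = chi_alpha * sigma_s`` is exposed as
    a derived property; :meth:`from_margin` constructs from it losslessly.
    """

    sigma_s: float
    sigma_d: float
    alpha: float = 0.95

    def __post_init__(self) -> None:
        if self.sigma_s < 0.0:
            raise ValueError("sigma_s must be non-negative")
        if self.sigma_d < 0.0:
            raise ValueError("sigma_d must be non-negative")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha!r}")

    @classmethod
    def from_margin(cls, m_s: float, sigma_d: float, alpha: float = 0.95) -> "SetupUncertainty":
        """Construct from the translational margin ``m_s = chi_alpha * sigma_s`` [mm]."""
        if m_s < 0.0:
            raise ValueError("m_s must be non-negative")
        return cls(sigma_s=m_s / chi_alpha(alpha), sigma_d=sigma_d, alpha=alpha)

    @cached_property
    def chi_alpha(self) -> float:
        return chi_alpha(self.alpha)

    @property
    def m_s(self) -> float:
        """Translational margin chi_alpha * sigma_s, mm."""
        return self.chi_alpha * self.sigma_s

    def margin(self, d):
        """Combined margin M(d) [mm] at distance(s) ``d`` [mm] from the isocenter."""
        sr = rotational_sd(d, self.sigma_d)
        out = self.chi_alpha * np.sqrt(self.sigma_s**2 + np.asarray(sr) ** 2)
        return out if out.ndim else float(out)

    def max_margin(self, d_max: float) -> float:
        """Upper bound on the margin for points no farther than ``d_max`` from the isocenter."""
        return float(self.margin(float(d_max)))


@dataclass(frozen=True)
class MarginSample:
    """Margin evaluated at one CTV boundary point.

    ``margin**2 == margin_translational**2 + margin_rotational**2`` and the
    combined margin is nondecreasing in ``distance_to_iso``.
    """

    point: np.ndarray
    distance_to_iso: float
    margin: float
    margin_translational: float
    margin_rotational: float


def point_margin(point, isocenter, u: SetupUncertainty) -> MarginSample:
    """Evaluate the nonuniform margin for a single CTV boundary point.

    The distance is the Euclidean norm of ``point - isocenter``; the combined
    margin is ``chi_alpha * sqrt(sigma_s**2 + (0.01424 * d * sigma_d)**2)``.
    """
    p = np.asarray(point, dtype=float).reshape(3)
    iso = np.asarray(isocenter, dtype=float).reshape(3)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(iso))):
        raise ValueError("point and isocenter must be finite")
    d = float(np.linalg.norm(p - iso))
    m_t = u.m_s
    m_r = u.chi_alpha * rotational_sd(d, u.sigma_d)
    return MarginSample(
        point=p,
        distance_to_iso=d,
        margin=float(math.hypot(m_t, m_r)),
        margin_translational=float(m_t),
        margin_rotational=float(m_r),
    )


def margins(points: np.ndarray, isocenter, u: SetupUncertainty) -> np.ndarray:
    """Vectorized combined margins [mm] for an (N, 3) array of boundary points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    iso = np.asarray(isocenter, dtype=float).reshape(3)
    d = np.linalg.norm(pts - iso, axis=1)
    return u.chi_alpha * np.sqrt(u.sigma_s**2 + (ROTATIONAL_MM_PER_MM_DEG * d * u.sigma_d) ** 2)
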