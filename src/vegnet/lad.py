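"""Campbell ellipsoidal leaf angle distribution: projection and extinction.

The ellipsoidal leaf angle distribution (LAD) of Campbell (1986) describes
leaf-normal zenith angles by a single parameter ``x``, the ratio of the
horizontal to the vertical semi-axis of the ellipsoid on which the leaf
normals are assumed to be distributed.  ``x = 1`` is the spherical
distribution, ``x > 1`` planophile-tending (flatter leaves), ``x < 1``
erectophile-tending (more vertical leaves).

For a beam at view zenith angle :math:`\\theta` the extinction coefficient is

.. math::

    K(\\theta, x) = \\frac{\\sqrt{x^2 + \\tan^2\\theta}}
                        {x + 1.702\\,(x + 1.12)^{-0.708}}

and the projection coefficient (G-function) is :math:`G = K\\cos\\theta`.
Near :math:`\\theta = 57.5^\\circ` — the "hinge" angle — G is close to 0.5
for every ``x``, which is why a single inversion coefficient
:math:`1/K(57.5^\\circ, x) \\approx 1.1` can be used to convert gap
probability to plant area index without knowing the leaf angle
distribution.

All angles at this interface are in degrees; conversion to radians happens
internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "HINGE_ZENITH_DEG",
    "EllipsoidalLAD",
    "ViewAngle",
    "extinction_coefficient",
    "projection_coefficient",
    "hinge_inverse_coefficient",
    "projection_curve_table",
]

#: The "hinge" view zenith angle (degrees) at which gap-fraction inversion
#: is nearly insensitive to the leaf angle distribution.
HINGE_ZENITH_DEG = 57.5


@dataclass(frozen=True)
class EllipsoidalLAD:
    """One-parameter ellipsoidal leaf angle distribution.

    Parameters
    ----------
    x : float
        Ratio of horizontal to vertical semi-axes of the leaf-normal
        ellipsoid; must be > 0.  ``x = 1`` is the spherical distribution.
    """

    x: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.x) or self.x <= 0:
            raise ValueError(f"LAD parameter x must be finite and > 0, got {self.x}")

    @property
    def mean_leaf_normal_zenith(self) -> float:
        """Mean leaf-normal zenith angle in degrees.

        Uses Campbell's (1990) approximation
        :math:`\\bar\\alpha \\approx 9.65 (3 + x)^{-1.65}` radians,
        a strictly decreasing function of ``x``.
        """
        return float(np.degrees(9.65 * (3.0 + self.x) ** -1.65))

    @classmethod
    def from_mean_zenith(cls, mean_zenith_deg: float) -> "EllipsoidalLAD":
        """Construct from a mean leaf-normal zenith angle (degrees)."""
        lo, hi = 1e-6, 1e6
        bounds = sorted(
            np.degrees(9.65 * (3.0 + np.array([lo, hi])) ** -1.65)
        )
        if not bounds[0] < mean_zenith_deg < bounds[1]:
            raise ValueError(
                f"mean zenith {mean_zenith_deg} deg outside representable "
                f"range ({bounds[0]:.3f}, {bounds[1]:.3f})"
            )
        x = brentq(
            lambda x: np.degrees(9.65 * (3.0 + x) ** -1.65) - mean_zenith_deg,
            lo,
            hi,
        )
        return cls(x=float(x))


@dataclass(frozen=True)
class ViewAngle:
    """View zenith angle in degrees, restricted to [0, 90)."""

    zenith: float = HINGE_ZENITH_DEG

    def __post_init__(self) -> None:
        if not (0.0 <= self.zenith < 90.0):
            raise ValueError(f"view zenith must be in [0, 90) deg, got {self.zenith}")


def _as_zenith_deg(theta) -> np.ndarray:
    z = np.asarray(theta.zenith if isinstance(theta, ViewAngle) else theta, dtype=float)
    if np.any(z < 0.0) or np.any(z >= 90.0):
        raise ValueError("view zenith must be in [0, 90) degrees")
    return z


def _as_x(lad) -> np.ndarray:
    x = np.asarray(lad.x if isinstance(lad, EllipsoidalLAD) else lad, dtype=float)
    if np.any(x <= 0.0):
        raise ValueError("LAD parameter x must be > 0")
    return x


def extinction_coefficient(theta, lad=EllipsoidalLAD()) -> float | np.ndarray:
    """Ellipsoidal extinction coefficient K(theta, x).

    Parameters
    ----------
    theta : ViewAngle, float or array
        View zenith angle(s), degrees in [0, 90).
    lad : EllipsoidalLAD, float or array
        Leaf angle distribution (or its ``x`` parameter directly).

    Returns
    -------
    K : float or ndarray
        Attenuation per unit plant area index along the slant path;
        K * cos(theta) is the projection coefficient G in (0, 1].
    """
    z = np.radians(_as_zenith_deg(theta))
    x = _as_x(lad)
    k = np.sqrt(x**2 + np.tan(z) ** 2) / (x + 1.702 * (x + 1.12) ** -0.708)
    return k if k.ndim else float(k)


def projection_coefficient(theta, lad=EllipsoidalLAD()) -> float | np.ndarray:
    """Projection coefficient (G-function): G = K(theta, x) * cos(theta)."""
    z = _as_zenith_deg(theta)
    g = extinction_coefficient(theta, lad) * np.cos(np.radians(z))
    return g if np.ndim(g) else float(g)


def hinge_inverse_coefficient(lad=EllipsoidalLAD()) -> float | np.ndarray:
    """Gap-to-PAI inversion coefficient at the hinge angle: 1/K(57.5deg, x).

    For any plausible leaf angle distribution this is close to 1.1, the
    fixed factor used in the cumulative-PAI inversion
    PAI(z) = -1.1 ln Pgap(z).
    """
    k = extinction_coefficient(HINGE_ZENITH_DEG, lad)
    inv = 1.0 / np.asarray(k)
    return inv if inv.ndim else float(inv)


def projection_curve_table(theta_deg=None, x_values=(0.5, 1.0, 2.0, 4.0)):
    """Tabulate G(theta, x) curve families for plotting/export.

    Returns a pandas DataFrame with columns ``theta_deg``, ``x``,
    ``mean_leaf_normal_zenith_deg`` and ``g``; the curve family crosses
    near theta = 57.5 degrees.
    """
    import pandas as pd

    if theta_deg is None:
        theta_deg = np.arange(0.0, 90.0, 1.0)
    theta_deg = np.asarray(theta_deg, dtype=float)
    frames = []
    for x in x_values:
        lad = EllipsoidalLAD(float(x))
        frames.append(
            pd.DataFrame(
                {
                    "theta_deg": theta_deg,
                    "x": float(x),
                    "mean_leaf_normal_zenith_deg": lad.mean_leaf_normal_zenith,
                    "g": projection_coefficient(theta_deg, lad),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
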