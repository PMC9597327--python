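"""Radiative field inside the two reactor geometries.

Light attenuates through the culture following the Beer-Lambert law with a
biomass absorption coefficient ``Ka`` that lumps absorption and scattering.
For the flat panel (one illuminated face, path length ``L``) the
culture-averaged intensity has a closed form; for the bubble column (three
light banks around a cylinder of radius ``R``) it is a double integral over
the cross-section of the sum of three attenuated contributions, one per
bank, evaluated by tensor-product quadrature.

Attenuation is one-dimensional (panel) / in-plane (column); there is no
vertical variation, no wall reflection and no explicit scattering phase
function — those effects are lumped into ``Ka``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import PchipInterpolator

__all__ = [
    "LightField",
    "LightFieldConvergenceError",
    "local_intensity",
    "average_intensity_flat_panel",
    "average_intensity_bubble_column",
    "column_chord_lengths",
    "ColumnLightCache",
    "write_radial_profile_csv",
]


class LightFieldConvergenceError(RuntimeError):
    """Raised when doubling the quadrature resolution changes the result
    by more than the requested tolerance."""


@dataclass
class LightField:
    """Culture-averaged intensity together with the geometry it came from."""

    Iav: float
    geometry: str
    attenuation_a: float  # dimensionless optical depth Ka*X*(length scale)


def _check_nonneg(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v!r}")


def local_intensity(Io: float, Ka: float, X, l):
    """Beer-Lambert local intensity ``Io * exp(-Ka*X*l)``.

    ``l`` is the distance from the illuminated surface (m).  Accepts
    array-valued ``X`` or ``l``.
    """
    _check_nonneg(Io=Io, Ka=Ka, X=float(np.min(X)), l=float(np.min(l)))
    return Io * np.exp(-Ka * np.asarray(X, dtype=float) * np.asarray(l, dtype=float))


def average_intensity_flat_panel(Io: float, Ka: float, X: float, L: float) -> float:
    """Culture-averaged intensity in a flat panel of light path ``L``.

    Analytic mean of the Beer-Lambert profile over the path:
    ``Io * (1 - exp(-a)) / a`` with optical depth ``a = Ka*X*L``.  A series
    branch handles ``a -> 0`` (the unattenuated limit ``Io``) without 0/0.
    """
    _check_nonneg(Io=Io, Ka=Ka, X=X, L=L)
    a = Ka * X * L
    if a < 1e-8:
        # 1 - a/2 + a^2/6 is the Taylor expansion of (1-e^-a)/a
        return Io * (1.0 - a / 2.0 + a * a / 6.0)
    return Io * (1.0 - np.exp(-a)) / a


def column_chord_lengths(r, theta, R: float):
    """Distances from the in-plane point ``(r, theta)`` to the three
    illuminated sides of a column of radius ``R``.

    Bank 1 and 2 face each other across the y-axis; bank 3 is rotated a
    quarter turn.  Each chord is a non-negative geometric length for every
    point inside the column (tiny negative rounding residues are clamped).
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    root_a = np.sqrt(np.maximum(R * R - (r * np.cos(theta)) ** 2, 0.0))
    root_b = np.sqrt(np.maximum(R * R - (r * np.sin(theta)) ** 2, 0.0))
    l1 = root_a - r * np.sin(theta)
    l2 = root_a + r * np.sin(theta)
    l3 = root_b - r * np.cos(theta)
    eps = 1e-12 * max(R, 1.0)
    for l in (l1, l2, l3):
        if np.any(l < -eps):
            raise AssertionError("negative chord length: geometry error")
    return np.maximum(l1, 0.0), np.maximum(l2, 0.0), np.maximum(l3, 0.0)


def _column_average(Io: float, KaX: float, R: float, n_r: int, n_theta: int) -> float:
    """Tensor-product quadrature of the three-bank attenuation integral.

    Gauss-Legendre nodes in r (mapped to [0, R]) and a uniform periodic
    rule in theta (trapezoid on a periodic integrand is spectrally
    accurate).  Returns
    ``(Io / (pi R^2)) * int_0^R int_0^2pi sum_i exp(-KaX * l_i) r dtheta dr``.
    """
    xr, wr = leggauss(n_r)
    r = 0.5 * R * (xr + 1.0)
    wr = 0.5 * R * wr
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    wt = 2.0 * np.pi / n_theta
    rg, tg = np.meshgrid(r, theta, indexing="ij")
    l1, l2, l3 = column_chord_lengths(rg, tg, R)
    integrand = np.exp(-KaX * l1) + np.exp(-KaX * l2) + np.exp(-KaX * l3)
    inner = integrand.sum(axis=1) * wt          # theta integral per radius
    total = float(np.sum(wr * r * inner))       # r integral with Jacobian r
    return Io * total / (np.pi * R * R)


def average_intensity_bubble_column(
    Io: float,
    Ka: float,
    X: float,
    R: float,
    n_r: int = 64,
    n_theta: int = 128,
    check_convergence: bool = True,
    conv_rtol: float = 5e-3,
) -> float:
    """Culture-averaged intensity in a three-bank bubble column.

    ``Io`` is the incident intensity *per bank*; the zero-biomass limit is
    exactly ``3 * Io`` because the three unattenuated contributions add.
    When ``check_convergence`` is set, the quadrature is repeated at double
    resolution and a relative change above ``conv_rtol`` raises
    :class:`LightFieldConvergenceError` with diagnostics.
    """
    _check_nonneg(Io=Io, Ka=Ka, X=X, R=R)
    if R == 0:
        raise ValueError("R must be > 0")
    KaX = Ka * X
    value = _column_average(Io, KaX, R, n_r, n_theta)
    if check_convergence:
        refined = _column_average(Io, KaX, R, 2 * n_r, 2 * n_theta)
        scale = max(abs(refined), 1e-12 * max(Io, 1.0))
        rel = abs(refined - value) / scale
        if rel > conv_rtol:
            raise LightFieldConvergenceError(
                f"column quadrature not converged: {n_r}x{n_theta} -> "
                f"{2*n_r}x{2*n_theta} changed Iav by {rel:.2e} "
                f"(> {conv_rtol:.1e}); Ka*X={KaX:.4g} m^-1, R={R} m"
            )
        value = refined
    return value


class ColumnLightCache:
    """Cached ``Iav`` for the bubble column as a function of optical
    density ``Ka*X`` (m⁻¹).

    The double integral depends on biomass and pigmentation only through
    the product ``Ka*X``, so during ODE integration a 1-D monotone
    (PCHIP) interpolant over that product replaces the quadrature.  The
    grid is log-like (dense near zero where Iav varies fastest);
    ``n_points`` controls the density.  Queries beyond the cached range
    fall back to direct quadrature.
    """

    def __init__(
        self,
        Io: float,
        R: float,
        kax_max: float = 2000.0,
        n_points: int = 160,
        n_r: int = 64,
        n_theta: int = 128,
    ):
        self.Io, self.R, self.kax_max = Io, R, kax_max
        self._n_r, self._n_theta = n_r, n_theta
        grid = np.concatenate(
            [[0.0], np.geomspace(1e-3, kax_max, n_points - 1)]
        )
        vals = np.array([_column_average(Io, s, R, n_r, n_theta) for s in grid])
        self._interp = PchipInterpolator(grid, vals, extrapolate=False)

    def __call__(self, Ka: float, X: float) -> float:
        s = Ka * X
        if s > self.kax_max:
            return _column_average(self.Io, s, self.R, self._n_r, self._n_theta)
        return float(self._interp(s))


def write_radial_profile_csv(
    path: str | Path,
    Io: float,
    Ka: float,
    X: float,
    R: float,
    n_r: int = 40,
    n_theta: int = 72,
) -> None:
    """Write the local three-bank intensity on an (r, theta) grid as CSV
    (columns r_m, theta_rad, intensity) for inspection/plotting."""
    r = np.linspace(0.0, R, n_r)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    rg, tg = np.meshgrid(r, theta, indexing="ij")
    l1, l2, l3 = column_chord_lengths(rg, tg, R)
    local = Io * (np.exp(-Ka * X * l1) + np.exp(-Ka * X * l2) + np.exp(-Ka * X * l3))
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["r_m", "theta_rad", "intensity"])
        for i in range(n_r):
            for j in range(n_theta):
                writer.writerow([f"{rg[i,j]:.6g}", f"{tg[i,j]:.6g}", f"{local[i,j]:.6g}"])
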