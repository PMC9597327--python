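"""Rate laws and composition correlations.

Growth couples a Monod-type light response (Hill exponent ``n``) with the
Droop cell-quota law: growth stops at the subsistence quota ``Q_min`` and
reaches ``mu_max`` at the storage capacity ``Q_max``.  The Droop factor is
normalized, ``(1 - Q_min/Q) / (1 - Q_min/Q_max)``, so that ``mu_max`` is
the actual maximum rate.  Nitrogen uptake follows Michaelis-Menten kinetics
in the external concentration, down-regulated linearly as the quota fills.

Composition is tied to nitrogen status through the quota: the absorption
coefficient falls linearly with Q as pigments are lost under starvation,
total fatty acids accumulate following a reciprocal power law in Q, and
the specific EPA content is constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import KineticParameters

__all__ = [
    "RateSet",
    "CompositionProfile",
    "growth_rate",
    "uptake_rate",
    "absorption_coefficient",
    "tfa_content",
    "composition",
    "rates",
]

#: tolerance within which a quota slightly outside [Q_min, Q_max] is
#: clamped rather than rejected (absorbs integrator rounding)
QUOTA_CLAMP_TOL = 1e-9


@dataclass
class RateSet:
    """Specific rates and optical state at one culture condition."""

    mu: float   # day^-1
    U: float    # mg N mg^-1 DCW day^-1
    Ka: float   # L mg^-1 m^-1


@dataclass
class CompositionProfile:
    """Fatty-acid composition at a given quota and biomass concentration."""

    C_TFA: float          # mg g^-1 DCW
    C_EPA: float          # mg g^-1 DCW
    epa_fraction: float   # C_EPA / C_TFA, dimensionless
    TFA_volumetric: float  # mg L^-1
    EPA_volumetric: float  # mg L^-1


def _clamped_quota(Q: float, p: KineticParameters, tol: float) -> float:
    if Q < p.Q_min - tol or Q > p.Q_max + tol:
        raise ValueError(
            f"quota Q={Q!r} outside [Q_min, Q_max]=[{p.Q_min}, {p.Q_max}] "
            "(beyond rounding tolerance; likely an integration bug)"
        )
    return min(max(Q, p.Q_min), p.Q_max)


def growth_rate(
    Iav: float, Q: float, p: KineticParameters, tol: float = QUOTA_CLAMP_TOL
) -> float:
    """Specific growth rate under combined light and nitrogen limitation.

    ``mu = mu_max * Iav^n / (K_I^n + Iav^n)
         * (1 - Q_min/Q) / (1 - Q_min/Q_max)``

    Monotone increasing in both ``Iav`` and ``Q``; zero at ``Iav = 0`` or
    ``Q = Q_min``; equal to ``mu_max`` at saturating light and full quota.
    """
    if Iav < 0:
        raise ValueError(f"Iav must be >= 0, got {Iav!r}")
    Q = _clamped_quota(Q, p, tol)
    if Iav == 0.0:
        return 0.0
    light = Iav**p.n / (p.K_I**p.n + Iav**p.n)
    droop = (1.0 - p.Q_min / Q) / (1.0 - p.Q_min / p.Q_max)
    return p.mu_max * light * droop


def uptake_rate(
    N: float, Q: float, p: KineticParameters, tol: float = QUOTA_CLAMP_TOL
) -> float:
    """Specific nitrogen uptake rate.

    ``U = U_max * N / (K_N + N) * (1 - Q/Q_max)``

    Zero when the medium is empty (``N = 0``) or the quota is full
    (``Q = Q_max``).  Uptake is decoupled from growth (Droop assumption):
    it does not stop in the dark.
    """
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N!r}")
    if Q > p.Q_max + tol:
        raise ValueError(f"quota Q={Q!r} exceeds Q_max={p.Q_max}")
    Q = min(Q, p.Q_max)
    return p.U_max * (N / (p.K_N + N)) * (1.0 - Q / p.Q_max)


def absorption_coefficient(Q: float, p: KineticParameters) -> float:
    """Biomass absorption coefficient from the linear quota correlation,
    ``Ka = ka_slope * Q + ka_intercept`` (L mg⁻¹ m⁻¹).

    Nitrogen-starved cells lose pigment, so Ka falls with the quota.
    """
    if Q < 0:
        raise ValueError(f"Q must be >= 0, got {Q!r}")
    return p.ka_slope * Q + p.ka_intercept


def tfa_content(Q: float, p: KineticParameters) -> float:
    """Specific total-fatty-acid content (mg g⁻¹ DCW), a reciprocal power
    law of the quota: ``C_TFA = tfa_coeff * Q^(-tfa_exponent) + tfa_offset``.

    Strictly decreasing in Q: nitrogen starvation channels fixed carbon
    into storage lipids.
    """
    if np.any(np.asarray(Q) <= 0):
        raise ValueError(f"Q must be > 0, got {Q!r}")
    return p.tfa_coeff * Q ** (-p.tfa_exponent) + p.tfa_offset


def composition(Q: float, X: float, p: KineticParameters) -> CompositionProfile:
    """Full composition profile at quota ``Q`` and biomass ``X``.

    The specific EPA content is constant (``epa_content``); the EPA
    fraction of total fatty acids therefore falls as TFA accumulate under
    nitrogen limitation.  Volumetric concentrations scale with biomass
    (mg g⁻¹ × mg L⁻¹ / 1000 → mg L⁻¹).
    """
    if X < 0:
        raise ValueError(f"X must be >= 0, got {X!r}")
    c_tfa = tfa_content(Q, p)
    c_epa = p.epa_content
    return CompositionProfile(
        C_TFA=c_tfa,
        C_EPA=c_epa,
        epa_fraction=c_epa / c_tfa,
        TFA_volumetric=c_tfa * X / 1000.0,
        EPA_volumetric=c_epa * X / 1000.0,
    )


def rates(Iav: float, N: float, Q: float, p: KineticParameters) -> RateSet:
    """Convenience bundle of the three rate laws at one condition."""
    return RateSet(
        mu=growth_rate(Iav, Q, p),
        U=uptake_rate(N, Q, p),
        Ka=absorption_coefficient(Q, p),
    )
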