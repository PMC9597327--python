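"""Domain types, units and parameter containers shared by all modules.

Units are fixed package-wide and assumed (never converted) everywhere:

========================  =========================
biomass ``X``             mg DCW L⁻¹
medium nitrogen ``N``     mg N L⁻¹
nitrogen quota ``Q``      mg N mg⁻¹ DCW
time                      day
light intensity           µmol photons m⁻² s⁻¹
length (path, radius)     m
absorption coefficient    L mg⁻¹ m⁻¹
specific fatty acids      mg g⁻¹ DCW
volumetric fatty acids    mg L⁻¹
========================  =========================
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "KineticParameters",
    "ReactorConfig",
    "CultureState",
    "MediumSpec",
    "F2_NITROGEN_MG_L",
    "validate_parameters",
    "literature_initial_parameters",
    "read_config",
    "write_config",
]

#: Nitrogen content of 1x f/2 medium: NaNO3 at 880 uM, 14 g N per mol.
F2_NITROGEN_MG_L = 880e-6 * 14.0 * 1000.0  # 12.32 mg N L^-1


@dataclass
class KineticParameters:
    """The eight kinetic constants of the growth/uptake model plus the
    empirical composition correlations.

    Defaults are the calibrated values for *P. tricornutum* grown
    photoautotrophically in flat-panel photobioreactors.  The empirical
    correlation coefficients (quota-dependent absorption coefficient,
    quota-dependent total-fatty-acid content, constant specific EPA
    content) live here too, so that a recalibrated model is a single
    object.
    """

    mu_max: float = 2.4       #: maximum specific growth rate, day^-1
    K_d: float = 0.010        #: biomass decay rate, day^-1
    Q_min: float = 0.034      #: minimum (subsistence) N quota, mg N mg^-1 DCW
    Q_max: float = 0.12       #: maximum N storage quota, mg N mg^-1 DCW
    U_max: float = 0.59       #: maximum N uptake rate, mg N mg^-1 DCW day^-1
    K_N: float = 0.010        #: half-saturation for N uptake, mg N L^-1
    K_I: float = 50.0         #: light half-saturation, umol m^-2 s^-1
    n: float = 1.9            #: light-response Hill exponent, dimensionless

    # Empirical correlations (quota -> optical / composition properties)
    ka_slope: float = 2.74    #: dKa/dQ, L mg^-1 m^-1 per quota unit
    ka_intercept: float = 0.21  #: Ka at Q=0, L mg^-1 m^-1
    tfa_coeff: float = 3.68     #: amplitude of the reciprocal TFA law
    tfa_exponent: float = 1.32  #: exponent of the reciprocal TFA law
    tfa_offset: float = 42.2    #: TFA content asymptote, mg g^-1 DCW
    epa_content: float = 55.0   #: constant specific EPA content, mg g^-1 DCW

    _FIELDS = (
        "mu_max", "K_d", "Q_min", "Q_max", "U_max", "K_N", "K_I", "n",
        "ka_slope", "ka_intercept", "tfa_coeff", "tfa_exponent",
        "tfa_offset", "epa_content",
    )

    #: the eight ODE-model parameters, in conventional order
    ODE_FIELDS = ("mu_max", "K_d", "Q_min", "Q_max", "U_max", "K_N", "K_I", "n")

    def validate(self) -> "KineticParameters":
        """Check every invariant; raise ``ValueError`` listing all violations."""
        problems = []
        for name in self._FIELDS:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not (v == v):  # NaN check
                problems.append(f"{name}: not a finite number ({v!r})")
            elif name == "K_d":
                # zero decay is a legitimate limiting case (and the exact
                # nitrogen-conservation regime); negative decay is not
                if v < 0:
                    problems.append(f"K_d: must be >= 0, got {v!r}")
            elif v <= 0:
                problems.append(f"{name}: must be strictly positive, got {v!r}")
        if self.Q_min > 0 and self.Q_max > 0 and not self.Q_min < self.Q_max:
            problems.append(
                f"Q_min: must be < Q_max (Q_min={self.Q_min!r}, Q_max={self.Q_max!r})"
            )
            problems.append(
                f"Q_max: must be > Q_min (Q_min={self.Q_min!r}, Q_max={self.Q_max!r})"
            )
        if self.n < 1:
            problems.append(f"n: exponent must be >= 1, got {self.n!r}")
        if problems:
            raise ValueError(
                "invalid kinetic parameters:\n  " + "\n  ".join(problems)
            )
        return self

    def replace(self, **changes: float) -> "KineticParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self._FIELDS}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "KineticParameters":
        known = {k: float(v) for k, v in d.items() if k in cls._FIELDS}
        unknown = set(d) - set(cls._FIELDS)
        if unknown:
            raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
        return cls(**known)


def validate_parameters(p: KineticParameters) -> KineticParameters:
    """Validate ``p`` and return it unchanged; see ``KineticParameters.validate``."""
    return p.validate()


def literature_initial_parameters() -> KineticParameters:
    """Literature / data-derived starting values used before calibration.

    These are the pre-fit initial guesses (growth and uptake constants from
    published work; quota bounds read off the first and last sampling days).
    """
    return KineticParameters(
        mu_max=2.0, K_d=0.01, Q_min=0.04, Q_max=0.13,
        U_max=0.5, K_N=0.01, K_I=60.0, n=1.9,
    )


@dataclass
class ReactorConfig:
    """Photobioreactor geometry and illumination.

    ``geometry`` is ``"flat_panel"`` (one illuminated face, light path
    ``path_length_L`` metres) or ``"bubble_column"`` (three light banks
    around a column of radius ``radius_R`` metres).
    ``incident_intensity_Io`` is the incident intensity per illuminated
    face/bank.  ``photoperiod_light_h`` is the number of illuminated hours
    per 24 h day.
    """

    geometry: str = "flat_panel"
    incident_intensity_Io: float = 350.0
    photoperiod_light_h: float = 12.0
    path_length_L: float | None = 0.05
    radius_R: float | None = None
    volume_L: float | None = None  # metadata only

    def validate(self) -> "ReactorConfig":
        problems = []
        if self.geometry not in ("flat_panel", "bubble_column"):
            problems.append(f"geometry: unknown geometry {self.geometry!r}")
        elif self.geometry == "flat_panel":
            if self.path_length_L is None or self.path_length_L <= 0:
                problems.append(
                    f"path_length_L: flat panel needs a positive light path, got {self.path_length_L!r}"
                )
        else:
            if self.radius_R is None or self.radius_R <= 0:
                problems.append(
                    f"radius_R: bubble column needs a positive radius, got {self.radius_R!r}"
                )
        if self.incident_intensity_Io < 0:
            problems.append("incident_intensity_Io: must be >= 0")
        if not 0.0 <= self.photoperiod_light_h <= 24.0:
            problems.append(
                f"photoperiod_light_h: must be in [0, 24], got {self.photoperiod_light_h!r}"
            )
        if problems:
            raise ValueError("invalid reactor config:\n  " + "\n  ".join(problems))
        return self

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "geometry": self.geometry,
            "incident_intensity_Io": float(self.incident_intensity_Io),
            "photoperiod_light_h": float(self.photoperiod_light_h),
        }
        for k in ("path_length_L", "radius_R", "volume_L"):
            v = getattr(self, k)
            if v is not None:
                d[k] = float(v)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ReactorConfig":
        # optional geometry fields absent from the mapping stay None
        # (to_dict omits them; the class defaults must not resurrect them)
        full: dict[str, Any] = {
            "path_length_L": None, "radius_R": None, "volume_L": None,
        }
        full.update(d)
        return cls(**full)


@dataclass
class CultureState:
    """Culture state at one instant: biomass, medium nitrogen, quota, time."""

    X: float                #: biomass, mg DCW L^-1
    N: float                #: medium nitrogen, mg N L^-1
    Q: float                #: nitrogen quota, mg N mg^-1 DCW
    t: float = 0.0          #: time, days

    def validate(self) -> "CultureState":
        if self.X < 0 or self.N < 0 or self.Q < 0:
            raise ValueError(
                f"culture state must be non-negative: X={self.X}, N={self.N}, Q={self.Q}"
            )
        return self


@dataclass
class MediumSpec:
    """Growth-medium nitrogen content.

    ``from_f2_multiple(k)`` converts a k-fold f/2 strength to mg N L⁻¹
    (1x f/2 supplies 880 µM NaNO₃, i.e. 12.32 mg N L⁻¹).
    """

    nitrogen_N0: float = F2_NITROGEN_MG_L
    description: str = ""

    def __post_init__(self) -> None:
        if self.nitrogen_N0 < 0:
            raise ValueError(f"nitrogen_N0 must be >= 0, got {self.nitrogen_N0!r}")

    @classmethod
    def from_f2_multiple(cls, k: float) -> "MediumSpec":
        if k < 0:
            raise ValueError("f/2 multiple must be >= 0")
        return cls(nitrogen_N0=k * F2_NITROGEN_MG_L, description=f"{k:g} x f/2")


# ---------------------------------------------------------------------------
# Flat key: value configuration files
# ---------------------------------------------------------------------------

def write_config(data: dict[str, Any], path: str | Path) -> None:
    """Write a flat ``key: value`` configuration file.

    Floats are written with ``repr`` so that reloading reproduces them
    bit-exactly.  Nested structures are rejected: the format is flat by
    design.
    """
    lines = []
    for key, value in data.items():
        if isinstance(value, dict | list | tuple):
            raise ValueError(f"config files are flat; field {key!r} is nested")
        if isinstance(value, float):
            lines.append(f"{key}: {value!r}")
        else:
            lines.append(f"{key}: {value}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_config(path: str | Path) -> dict[str, Any]:
    """Read a flat ``key: value`` configuration file (YAML-scalar values)."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} is not a flat key: value mapping")
    for key, value in data.items():
        if isinstance(value, dict | list):
            raise ValueError(f"config file {path}: field {key!r} is nested")
    return data
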