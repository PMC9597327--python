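"""Packaged reference scenarios for the two experimental set-ups.

Three scenarios ship with the package: the 5 L flat-panel batch reference
(4x f/2 medium, 350 µmol m⁻² s⁻¹, 12:12 h light:dark, light path 0.05 m,
initial OD 0.05) and the two 50 L bubble-column batches (three banks of
360 µmol m⁻² s⁻¹ each, 16:8 h, radius 0.095 m, initial OD 0.08) under
nitrogen-limited (5x f/2) and nitrogen-sufficient (nitrate boosted to
15x f/2) media.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import CultureState, KineticParameters, MediumSpec, ReactorConfig
from .simulator import LightSchedule, initial_biomass_from_od

__all__ = ["Scenario", "SCENARIOS", "get_scenario"]


@dataclass
class Scenario:
    name: str
    reactor: ReactorConfig
    schedule: LightSchedule
    medium: MediumSpec
    initial_od550: float
    duration_days: float
    description: str = ""

    def initial_state(self, p: KineticParameters) -> CultureState:
        """Nutrient-replete inoculum: quota at Q_max, biomass from the OD."""
        return CultureState(
            X=initial_biomass_from_od(self.initial_od550, p),
            N=self.medium.nitrogen_N0,
            Q=p.Q_max,
            t=0.0,
        )

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "initial_od550": self.initial_od550,
            "duration_days": self.duration_days,
            "nitrogen_N0": self.medium.nitrogen_N0,
            "medium": self.medium.description,
            "light_hours": self.schedule.light_hours,
        }
        d.update(self.reactor.to_dict())
        return d


SCENARIOS: dict[str, Scenario] = {
    "5L_flat_panel_4xf2": Scenario(
        name="5L_flat_panel_4xf2",
        reactor=ReactorConfig(
            geometry="flat_panel",
            incident_intensity_Io=350.0,
            photoperiod_light_h=12.0,
            path_length_L=0.05,
            volume_L=5.0,
        ),
        schedule=LightSchedule(light_hours=12.0),
        medium=MediumSpec.from_f2_multiple(4),
        initial_od550=0.05,
        duration_days=16.0,
        description="5 L flat-panel batch reference, 4x f/2 medium",
    ),
    "50L_column_N_limited": Scenario(
        name="50L_column_N_limited",
        reactor=ReactorConfig(
            geometry="bubble_column",
            incident_intensity_Io=360.0,
            photoperiod_light_h=16.0,
            radius_R=0.095,
            path_length_L=None,
            volume_L=50.0,
        ),
        schedule=LightSchedule(light_hours=16.0),
        medium=MediumSpec.from_f2_multiple(5),
        initial_od550=0.08,
        duration_days=14.0,
        description="50 L bubble column, nitrogen-limited (5x f/2)",
    ),
    "50L_column_N_sufficient": Scenario(
        name="50L_column_N_sufficient",
        reactor=ReactorConfig(
            geometry="bubble_column",
            incident_intensity_Io=360.0,
            photoperiod_light_h=16.0,
            radius_R=0.095,
            path_length_L=None,
            volume_L=50.0,
        ),
        schedule=LightSchedule(light_hours=16.0),
        medium=MediumSpec(
            nitrogen_N0=MediumSpec.from_f2_multiple(15).nitrogen_N0,
            description="15 x f/2 nitrate (other nutrients 5x)",
        ),
        initial_od550=0.08,
        duration_days=14.0,
        description="50 L bubble column, nitrogen-sufficient (15x f/2 nitrate)",
    ),
}


def get_scenario(name: str) -> Scenario:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None
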