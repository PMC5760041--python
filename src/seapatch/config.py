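"""Simulation configuration: parameter blocks, YAML round trip, defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml

from .economics import EconomicParams
from .fleet import CatchabilityParams, FleetParams

__all__ = ["PopulationParams", "SimConfig", "load_config", "save_config",
           "default_config"]


@dataclass(frozen=True)
class PopulationParams:
    natural_mortality_per_year: float = 0.58
    mean_weight_kg: float = 0.5395

    def __post_init__(self) -> None:
        if self.natural_mortality_per_year < 0 or self.mean_weight_kg <= 0:
            raise ValueError("mortality must be >= 0 and weight > 0")


@dataclass(frozen=True)
class SimConfig:
    """Everything a simulation run needs apart from the initial state."""

    population: PopulationParams = field(default_factory=PopulationParams)
    catchability: CatchabilityParams = field(default_factory=CatchabilityParams)
    fleet: FleetParams = field(default_factory=FleetParams)
    economics: EconomicParams = field(default_factory=EconomicParams)
    horizon_days: int = 240
    season_days: int = 148          # survey-to-survey reporting window
    max_trips_per_day: float | None = None   # scenario cap; None = status quo

    def __post_init__(self) -> None:
        if self.horizon_days < 1:
            raise ValueError("horizon must be at least one day")
        if not 1 <= self.season_days <= self.horizon_days:
            raise ValueError("season window must fit inside the horizon")
        if self.max_trips_per_day is not None and self.max_trips_per_day < 0:
            raise ValueError("effort cap must be non-negative")

    def with_cap(self, cap: float | None) -> "SimConfig":
        from dataclasses import replace
        return replace(self, max_trips_per_day=cap)

    def with_fleet(self, **kwargs) -> "SimConfig":
        from dataclasses import replace
        return replace(self, fleet=replace(self.fleet, **kwargs))


def _from_mapping(doc: dict) -> SimConfig:
    pop = PopulationParams(**doc.get("population", {}))
    cat = CatchabilityParams(**doc.get("catchability", {}))
    flt_kwargs = dict(doc.get("fleet", {}))
    econ_kwargs = dict(doc.get("economics", {}))
    # opportunity cost is a fleet-decision number; accept it in either block
    if "opportunity_cost" in flt_kwargs:
        econ_kwargs.setdefault("opportunity_cost", flt_kwargs["opportunity_cost"])
    flt = FleetParams(**{k: v for k, v in flt_kwargs.items()
                         if k in FleetParams.__dataclass_fields__})
    econ = EconomicParams(**econ_kwargs)
    sim = doc.get("simulation", {})
    return SimConfig(population=pop, catchability=cat, fleet=flt, economics=econ,
                     horizon_days=int(sim.get("horizon_days", 240)),
                     season_days=int(sim.get("season_days", 148)),
                     max_trips_per_day=sim.get("max_trips_per_day"))


def load_config(path: str | Path) -> SimConfig:
    """Load a SimConfig from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return _from_mapping(doc)


def save_config(config: SimConfig, path: str | Path) -> None:
    doc = {
        "population": asdict(config.population),
        "catchability": asdict(config.catchability),
        "fleet": asdict(config.fleet),
        "economics": asdict(config.economics),
        "simulation": {"horizon_days": config.horizon_days,
                       "season_days": config.season_days,
                       "max_trips_per_day": config.max_trips_per_day},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_config() -> SimConfig:
    """The packaged default parameterisation (2013 Yucatan season)."""
    ref = resources.files("seapatch.data").joinpath("params.yaml")
    with resources.as_file(ref) as path:
        return load_config(path)
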