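"""World configuration: every model rate, geometry and timestep in one place.

All parameters are plain dataclass fields so a run is fully specified by a
``WorldConfig`` plus a seed; YAML round-tripping is provided for the CLI.
Units are minutes and micrometres throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .agents import CycleParams
from .errors import ConfigurationError
from .immune_interactions import InteractionRates, RecruitmentParams
from .lymph_node import LymphNodeParams
from .mechanics import MechanicsParams
from .motility import MotilityParams

__all__ = ["EcmParams", "FieldParams", "WorldConfig", "apply_overrides", "PATIENT_PARAMETERS"]


@dataclass
class EcmParams:
    """Elasto-plastic tether constants shared by all parenchymal cells."""

    r_E: float = 0.05  # elastic coefficient (1/min)
    r_P: float = 5e-4  # plastic relaxation rate (1/min)
    d_max: float = 1.5  # maximum tolerated deformation (µm)


@dataclass
class FieldParams:
    """Diffusion/decay/secretion constants of the two substrates."""

    D_tnf: float = 555.56  # µm²/min
    lambda_tnf: float = 1.02e-2  # 1/min
    D_debris: float = 555.56  # µm²/min
    lambda_debris: float = 1.0e-3  # 1/min
    tnf_secretion_rate: float = 1.0  # substrate/min per secreting macrophage


@dataclass
class WorldConfig:
    # geometry
    domain_size: float = 700.0  # square tissue patch side (µm)
    voxel_size: float = 20.0
    vascular_fraction: float = 0.088
    # initial cell counts
    initial_cancer: int = 5
    initial_macrophages: int = 50
    initial_dcs: int = 10
    cell_radius: float = 8.4  # live-cell radius, all types (µm)
    # schedule
    duration: float = 14400.0  # 10 days (min)
    snapshot_interval: float = 480.0  # 8 h → 31 snapshots over 10 days
    population_interval: float = 60.0  # population time-series cadence
    dt_diffusion: float = 0.01
    dt_mechanics: float = 0.1
    dt_phenotype: float = 6.0
    seed: int = 0
    # death/digestion clocks
    tau_clear: float = 480.0  # corpse clearance time (min)
    # parameter blocks
    cycle: CycleParams = field(default_factory=CycleParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    ecm: EcmParams = field(default_factory=EcmParams)
    motility: MotilityParams = field(default_factory=MotilityParams)
    fields: FieldParams = field(default_factory=FieldParams)
    recruit_m: RecruitmentParams = field(
        default_factory=lambda: RecruitmentParams(r_recruit=2e-8, rho_min=2e-6, rho_sat=2e-5)
    )
    recruit_d: RecruitmentParams = field(
        default_factory=lambda: RecruitmentParams(r_recruit=1e-8, rho_min=2e-6, rho_sat=2e-5)
    )
    rates: InteractionRates = field(default_factory=InteractionRates)
    ln: LymphNodeParams = field(default_factory=LymphNodeParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        for name in ("dt_diffusion", "dt_mechanics", "dt_phenotype"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if _remainder(self.duration, self.snapshot_interval) > 1e-9:
            raise ConfigurationError("snapshot_interval must divide duration")
        if _remainder(self.snapshot_interval, self.dt_phenotype) > 1e-9:
            raise ConfigurationError("dt_phenotype must divide snapshot_interval")
        if _remainder(self.dt_phenotype, self.dt_mechanics) > 1e-9:
            raise ConfigurationError("dt_mechanics must divide dt_phenotype")
        if self.dt_diffusion > self.dt_mechanics and _remainder(
            self.dt_mechanics, self.dt_diffusion
        ) > 1e-9:
            raise ConfigurationError("dt_diffusion must not exceed dt_mechanics")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "WorldConfig":
        data = dict(data)
        for name, sub in _BLOCKS.items():
            if name in data and isinstance(data[name], dict):
                data[name] = sub(**data[name])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


_BLOCKS = {
    "cycle": CycleParams,
    "mechanics": MechanicsParams,
    "ecm": EcmParams,
    "motility": MotilityParams,
    "fields": FieldParams,
    "recruit_m": RecruitmentParams,
    "recruit_d": RecruitmentParams,
    "rates": InteractionRates,
    "ln": LymphNodeParams,
}


def _remainder(a: float, b: float) -> float:
    q = a / b
    return abs(q - round(q)) * b


# The ten varied virtual-patient parameters, mapped onto config locations:
# six recruitment-linked, three lymph-node T-cell-production, one DC egress.
PATIENT_PARAMETERS: dict[str, tuple[str, str]] = {
    "r_recruit_M": ("recruit_m", "r_recruit"),
    "rho_min_M": ("recruit_m", "rho_min"),
    "rho_sat_M": ("recruit_m", "rho_sat"),
    "r_recruit_D": ("recruit_d", "r_recruit"),
    "rho_min_D": ("recruit_d", "rho_min"),
    "rho_sat_D": ("recruit_d", "rho_sat"),
    "pi_T": ("ln", "pi_T"),
    "kappa_T": ("ln", "kappa_T"),
    "delta_C": ("ln", "delta_C"),
    "r_leave": ("rates", "r_leave"),
}


def apply_overrides(config: WorldConfig, overrides: dict) -> WorldConfig:
    """Return a copy of config with named patient parameters replaced."""
    cfg = WorldConfig.from_dict(config.to_dict())
    for name, value in overrides.items():
        if name not in PATIENT_PARAMETERS:
            raise ConfigurationError(f"unknown patient parameter {name!r}")
        block, attr = PATIENT_PARAMETERS[name]
        setattr(getattr(cfg, block), attr, float(value))
    return cfg
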