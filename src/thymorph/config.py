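"""Run configuration: every tunable of the simulator in one
YAML-serialisable object with a lossless load -> save -> load round trip."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .energy import EnergyParameters
from .ic import SyntheticICParams
from .mesh import CellType
from .polarity import LumenParams, PolarityParams
from .populations import EndothelialParams, ProliferationParams
from .rearrange import RearrangementThresholds
from .signalling import ChemotaxisParams, MorphogenParams

__all__ = ["RunConfig", "load_config", "save_config"]


def _energy_to_dict(p: EnergyParameters) -> dict:
    return {
        "K": {t.value: v for t, v in p.K.items()},
        "Gamma": {t.value: v for t, v in p.Gamma.items()},
        "A0_init": {t.value: v for t, v in p.A0_init.items()},
        "Lambda": {f"{a}|{b}": v for (a, b), v in sorted(p.Lambda.items())},
    }


def _energy_from_dict(d: dict) -> EnergyParameters:
    p = EnergyParameters(
        K={CellType(k): v for k, v in d["K"].items()},
        Gamma={CellType(k): v for k, v in d["Gamma"].items()},
        A0_init={CellType(k): v for k, v in d["A0_init"].items()},
    )
    for key, v in d["Lambda"].items():
        a, b = key.split("|")
        p.set_lambda(a, b, v)
    return p


@dataclass
class RunConfig:
    """Full description of a simulation run.

    Durations are hours; the default time step of 0.001 h keeps the
    forward-Euler integration stable at the default stiffnesses.
    Cadences are expressed in integration steps: the morphogen field is
    re-solved quasi-statically every ``field_cadence`` steps, and
    biological events (divisions, rearrangement triggers, polarity,
    branch addition) are processed every ``event_cadence`` steps, a
    granularity far below any biological timescale in the model.
    """

    duration: float = 72.0
    dt: float = 0.001
    seed: int = 0

    # module toggles
    chemotaxis_enabled: bool = True
    vegfa_ko: bool = False
    polarity_enabled: bool = True
    proliferation_enabled: bool = True
    branch_addition_enabled: bool = True
    corridors_enabled: bool = True

    # scheduling
    event_cadence: int = 10
    field_cadence: int = 50
    polarity_cadence: int = 50
    stats_interval: float = 0.5
    snapshot_interval: float = 0.0  # 0 disables snapshots

    # synthetic initial condition
    n_epithelial: int = 200

    # parameter blocks
    energy: EnergyParameters = field(default_factory=EnergyParameters.default)
    prolif: ProliferationParams = field(default_factory=ProliferationParams)
    endo: EndothelialParams = field(default_factory=EndothelialParams)
    morphogen: MorphogenParams = field(default_factory=MorphogenParams)
    chemotaxis: ChemotaxisParams = field(default_factory=ChemotaxisParams)
    polarity: PolarityParams = field(default_factory=PolarityParams)
    lumen: LumenParams = field(default_factory=LumenParams)
    thresholds: RearrangementThresholds = field(
        default_factory=RearrangementThresholds
    )
    ic: SyntheticICParams = field(default_factory=SyntheticICParams)

    def __post_init__(self):
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    _BLOCKS = (
        ("prolif", ProliferationParams),
        ("endo", EndothelialParams),
        ("morphogen", MorphogenParams),
        ("chemotaxis", ChemotaxisParams),
        ("polarity", PolarityParams),
        ("lumen", LumenParams),
        ("thresholds", RearrangementThresholds),
        ("ic", SyntheticICParams),
    )

    @classmethod
    def reference(cls, dt: float = 0.001, **kwargs) -> "RunConfig":
        """A run configuration whose scheduling cadences are expressed
        in real time rather than steps: events every 0.01 h, morphogen
        solve and polarity update every 0.05 h, whatever the ``dt``.
        Keeps coarse-step runs dynamically equivalent to the
        fine-step reference."""
        scale = dt / 0.001
        return cls(
            dt=dt,
            event_cadence=max(1, round(10 / scale)),
            field_cadence=max(1, round(50 / scale)),
            polarity_cadence=max(1, round(50 / scale)),
            **kwargs,
        )

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            name = f.name
            val = getattr(self, name)
            if name == "energy":
                out[name] = _energy_to_dict(val)
            elif dataclasses.is_dataclass(val):
                out[name] = dataclasses.asdict(val)
            else:
                out[name] = val
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        block_types = dict(cls._BLOCKS)
        for key, val in d.items():
            if key == "energy":
                kwargs[key] = _energy_from_dict(val)
            elif key in block_types:
                kwargs[key] = block_types[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))
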