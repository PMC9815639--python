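"""Pipeline configuration: YAML <-> dataclasses, validated up front."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml

from .bench import MODEL_NAMES, TuneConfig
from .errors import ConfigurationError
from .simulate import DriftModel, HerdProfile
from .windows import WindowConfig


@dataclass
class SweepConfig:
    enabled: bool = False
    window_days: tuple[int, ...] = (7, 14, 21)
    tb_windows: tuple[tuple[int, int], ...] = ((-35, 10), (-49, 10), (-10, 5))
    model: str = "rf"
    seeds: tuple[int, ...] = (0,)


@dataclass
class EvaluateConfig:
    regimes: tuple[str, ...] = ("CV", "LOOP")
    test_fraction: float = 0.25
    split_seed: int = 0
    sweep: SweepConfig = field(default_factory=SweepConfig)

    def __post_init__(self) -> None:
        for r in self.regimes:
            if r not in ("CV", "LOOP"):
                raise ConfigurationError(f"unknown regime {r!r}")
        if not (0.0 < self.test_fraction < 1.0):
            raise ConfigurationError("test_fraction must be in (0, 1)")


@dataclass
class SimulationConfig:
    herds: list[HerdProfile] = field(default_factory=list)
    drift: DriftModel = field(default_factory=DriftModel)
    missing_rate: float = 0.02
    seed: int = 0


@dataclass
class BenchConfig:
    models: tuple[str, ...] = MODEL_NAMES
    tune: TuneConfig = field(default_factory=TuneConfig)

    def __post_init__(self) -> None:
        unknown = [m for m in self.models if m not in MODEL_NAMES]
        if unknown:
            raise ConfigurationError(f"unknown model name(s) {unknown}; choose from {MODEL_NAMES}")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    windows: WindowConfig = field(default_factory=WindowConfig)
    bench: BenchConfig = field(default_factory=BenchConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    input_dir: str | None = None  # ingest real CSVs instead of simulating

    # ------------------------------------------------------------- loaders
    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        sim = d.get("simulation", {})
        herds = [
            HerdProfile(**{**h, "pigs_per_pen": tuple(h["pigs_per_pen"])})
            for h in sim.get("herds", [])
        ]
        drift = DriftModel(**sim.get("drift", {}))
        win_d = dict(d.get("windows", {}))
        if "tb_window" in win_d:
            win_d["tb_window"] = tuple(win_d["tb_window"])
        if "variables" in win_d:
            win_d["variables"] = tuple(win_d["variables"])
        ben = d.get("bench", {})
        tune = TuneConfig(**ben.get("tune", {}))
        ev = dict(d.get("evaluate", {}))
        sweep = SweepConfig(**ev.pop("sweep", {}))
        if isinstance(sweep.tb_windows, list):
            sweep.tb_windows = tuple(tuple(t) for t in sweep.tb_windows)
        if isinstance(sweep.window_days, list):
            sweep.window_days = tuple(sweep.window_days)
        if isinstance(sweep.seeds, list):
            sweep.seeds = tuple(sweep.seeds)
        if "regimes" in ev:
            ev["regimes"] = tuple(ev["regimes"])
        return PipelineConfig(
            simulation=SimulationConfig(
                herds=herds,
                drift=drift,
                missing_rate=sim.get("missing_rate", 0.02),
                seed=sim.get("seed", 0),
            ),
            windows=WindowConfig(**win_d),
            bench=BenchConfig(models=tuple(ben.get("models", MODEL_NAMES)), tune=tune),
            evaluate=EvaluateConfig(**ev, sweep=sweep),
            input_dir=d.get("input_dir"),
        )

    @staticmethod
    def from_yaml(path: str) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
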