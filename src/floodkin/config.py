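"""TOML run configuration: scenario, method, engine and output blocks.

Two unit modes are supported so literature-style values can be written
verbatim:

* ``reduced`` (default): kT = 1, D0 = 1, dimensionless lengths/times;
* ``physical``: energies in kcal/mol at 310 K (kT = 0.616 kcal/mol),
  lengths in angstrom, times in picoseconds.  Conversion to reduced
  units happens here, at the configuration boundary, and nowhere else.

Unknown keys are rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import units
from .errors import ConfigError
from .surfaces import SCENARIO_LABELS

# method-block defaults mirror the clay study set-up: 7 kcal/mol bias
# cutoff, excluded region |y| > 8.5 A, gamma 10, deposition every 500 steps
DEFAULT_BARRIER_KCAL = 7.0
DEFAULT_Y_EXCL_ANGSTROM = 8.5
DEFAULT_GAMMA = 10.0
DEFAULT_PACE = 500
DEFAULT_N_RUNS_BIASED = 25
DEFAULT_N_RUNS_UNBIASED = 10


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in [{where}]")


@dataclass(frozen=True)
class MethodConfig:
    name: str = "opes_f"
    barrier: float = units.kcal_per_mol_to_kt(DEFAULT_BARRIER_KCAL)
    gamma: float = DEFAULT_GAMMA
    pace: int = DEFAULT_PACE
    y_excl: float = DEFAULT_Y_EXCL_ANGSTROM
    n_components: int = 3
    n_runs: int = DEFAULT_N_RUNS_BIASED

    def as_method_config(self) -> dict:
        return {
            "barrier": self.barrier,
            "gamma": self.gamma,
            "pace": self.pace,
            "y_excl": self.y_excl,
            "n_components": self.n_components,
        }


@dataclass(frozen=True)
class EngineConfig:
    dt: float = 1e-3
    max_steps: int = 1_000_000
    kt: float = 1.0
    d0: float = 1.0
    seed: int = 0
    record_stride: int = 1


@dataclass(frozen=True)
class OutputConfig:
    directory: str = "."
    stride: int = 1


@dataclass(frozen=True)
class RunConfig:
    unit_mode: str = "reduced"
    scenario_label: str = "interlayer_center"
    scenario_overrides: dict = field(default_factory=dict)
    method: MethodConfig = field(default_factory=MethodConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    output: OutputConfig = field(default_factory=OutputConfig)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "unit_mode": self.unit_mode,
                "scenario": [self.scenario_label, self.scenario_overrides],
                "method": vars(self.method).copy(),
                "engine": vars(self.engine).copy(),
                "output": vars(self.output).copy(),
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read and validate a TOML run configuration."""
    try:
        raw = tomllib.loads(Path(path).read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: invalid TOML: {exc}") from exc
    _check_keys(raw, {"unit_mode", "scenario", "method", "engine", "output"}, "top level")

    unit_mode = raw.get("unit_mode", "reduced")
    if unit_mode not in units.UNIT_MODES:
        raise ConfigError(f"unit_mode must be one of {units.UNIT_MODES}")
    physical = unit_mode == "physical"

    def energy_in(value: float) -> float:
        return units.kcal_per_mol_to_kt(value) if physical else value

    scen = dict(raw.get("scenario", {}))
    _check_keys(
        scen,
        {"label", "start_position", "absorbing_threshold", "surface_params"},
        "scenario",
    )
    label = scen.pop("label", "interlayer_center")
    if label not in SCENARIO_LABELS:
        raise ConfigError(f"scenario.label must be one of {SCENARIO_LABELS}")

    meth = dict(raw.get("method", {}))
    _check_keys(
        meth,
        {"name", "barrier", "gamma", "pace", "y_excl", "n_components", "n_runs"},
        "method",
    )
    name = meth.get("name", "opes_f")
    if name not in ("unbiased", "gambes", "opes_f"):
        raise ConfigError("method.name must be unbiased, gambes or opes_f")
    method = MethodConfig(
        name=name,
        barrier=energy_in(float(meth.get("barrier", DEFAULT_BARRIER_KCAL if physical else units.kcal_per_mol_to_kt(DEFAULT_BARRIER_KCAL)))),
        gamma=float(meth.get("gamma", DEFAULT_GAMMA)),
        pace=int(meth.get("pace", DEFAULT_PACE)),
        y_excl=float(meth.get("y_excl", DEFAULT_Y_EXCL_ANGSTROM)),
        n_components=int(meth.get("n_components", 3)),
        n_runs=int(
            meth.get(
                "n_runs",
                DEFAULT_N_RUNS_UNBIASED if name == "unbiased" else DEFAULT_N_RUNS_BIASED,
            )
        ),
    )

    eng = dict(raw.get("engine", {}))
    _check_keys(eng, {"dt", "max_steps", "kt", "d0", "seed", "record_stride"}, "engine")
    engine = EngineConfig(
        dt=float(eng.get("dt", 1e-3)),
        max_steps=int(eng.get("max_steps", 1_000_000)),
        kt=float(eng.get("kt", 1.0)),
        d0=float(eng.get("d0", 1.0)),
        seed=int(eng.get("seed", 0)),
        record_stride=int(eng.get("record_stride", 1)),
    )

    out = dict(raw.get("output", {}))
    _check_keys(out, {"directory", "stride"}, "output")
    output = OutputConfig(
        directory=str(out.get("directory", ".")), stride=int(out.get("stride", 1))
    )

    return RunConfig(
        unit_mode=unit_mode,
        scenario_label=label,
        scenario_overrides=scen,
        method=method,
        engine=engine,
        output=output,
    )


# ---------------------------------------------------------------------------
# minimal TOML emission (flat tables of scalars only)


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    return '"' + str(value).replace('"', '\\"') + '"'


def dumps_table(name: str, block: dict) -> str:
    lines = [f"[{name}]"]
    lines += [f"{key} = {_fmt(val)}" for key, val in block.items()]
    return "\n".join(lines) + "\n"


def parse_surface_toml(text: str):
    """Rebuild a surface (and optionally a scenario) from TOML blocks."""
    from .surfaces import PotentialSurface, ScenarioSpec

    raw = tomllib.loads(text)
    if "surface" not in raw:
        raise ConfigError("missing [surface] block")
    sblock = dict(raw["surface"])
    name = sblock.pop("name", None)
    if name is None:
        raise ConfigError("[surface] block needs a 'name' key")
    surface = PotentialSurface.from_params(name, sblock)
    if "scenario" not in raw:
        return surface
    sc = dict(raw["scenario"])
    _check_keys(
        sc,
        {"label", "start_position", "absorbing_threshold", "temperature_kt",
         "diffusion_coefficient_d0", "two_sided"},
        "scenario",
    )
    return ScenarioSpec(
        surface=surface,
        start_position=float(sc["start_position"]),
        absorbing_threshold=float(sc["absorbing_threshold"]),
        label=str(sc.get("label", "custom")),
        temperature_kt=float(sc.get("temperature_kt", 1.0)),
        diffusion_coefficient_d0=float(sc.get("diffusion_coefficient_d0", 1.0)),
        two_sided=bool(sc.get("two_sided", True)),
    )
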