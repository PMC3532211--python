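"""Configuration handling: parameter files and run configurations.

Parameter sets live in a structured YAML file with one block per species
and one for the resource base (see ``data/default_params.yaml`` for the
shipped default).  Loading is strict: unknown keys are rejected by name,
and all domain invariants of the parameter dataclasses are enforced.

A :class:`RunConfig` captures everything needed to reproduce an analysis
run -- parameter file, overlap, effort grid, seed -- and is serialized
alongside the outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .params import (
    ModelParams,
    ParameterError,
    ResourceParams,
    SpeciesParams,
    StageParams,
)

_RESOURCE_KEYS = {"r", "K_m", "K_p", "R_h", "omega"}
_SPECIES_KEYS = {
    "L_J", "L_LJ", "L_A", "lw_a", "lw_b", "W_avg", "L_avg",
    "I_max", "z", "T", "delta", "mu", "price", "f",
}
_STAGE_MAP_KEYS = {"W_avg": {"J", "LJ", "A"}, "L_avg": {"J", "LJ", "A"},
                   "I_max": {"J", "LJ", "A"}, "z": {"J_LJ", "LJ_A"},
                   "f": {"LJ", "A"}}


def default_config_path() -> Path:
    """Path to the packaged default parameter file."""
    return Path(resources.files("mixedfishery").joinpath("data/default_params.yaml"))


def _reject_unknown(mapping: dict, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ParameterError(f"unknown key(s) in {context}: {sorted(unknown)}")


def _species_from_dict(name: str, d: dict) -> SpeciesParams:
    _reject_unknown(d, _SPECIES_KEYS, f"species '{name}'")
    missing = _SPECIES_KEYS - set(d)
    if missing:
        raise ParameterError(f"missing key(s) in species '{name}': {sorted(missing)}")
    for key, stages in _STAGE_MAP_KEYS.items():
        _reject_unknown(d[key], stages, f"species '{name}' field '{key}'")
    stages = {
        "J": StageParams(
            I_max=float(d["I_max"]["J"]), W_avg=float(d["W_avg"]["J"]),
            L_avg=float(d["L_avg"]["J"]), z=float(d["z"]["J_LJ"]), f=0.0,
        ),
        "LJ": StageParams(
            I_max=float(d["I_max"]["LJ"]), W_avg=float(d["W_avg"]["LJ"]),
            L_avg=float(d["L_avg"]["LJ"]), z=float(d["z"]["LJ_A"]),
            f=float(d["f"]["LJ"]),
        ),
        "A": StageParams(
            I_max=float(d["I_max"]["A"]), W_avg=float(d["W_avg"]["A"]),
            L_avg=float(d["L_avg"]["A"]), z=None, f=float(d["f"]["A"]),
        ),
    }
    return SpeciesParams(
        name=name, stages=stages, T=float(d["T"]), delta=float(d["delta"]),
        mu=float(d["mu"]), price=float(d["price"]), lw_a=float(d["lw_a"]),
        lw_b=float(d["lw_b"]), L_J=float(d["L_J"]), L_LJ=float(d["L_LJ"]),
        L_A=float(d["L_A"]),
    )


def params_from_dict(doc: dict) -> ModelParams:
    """Build a :class:`ModelParams` from a parsed configuration mapping."""
    _reject_unknown(doc, {"resources", "species"}, "parameter file")
    for key in ("resources", "species"):
        if key not in doc:
            raise ParameterError(f"parameter file is missing the '{key}' block")
    _reject_unknown(doc["resources"], _RESOURCE_KEYS, "resources block")
    _reject_unknown(doc["species"], {"plaice", "sole"}, "species block")
    res = ResourceParams(**{k: float(v) for k, v in doc["resources"].items()})
    species = {
        name: _species_from_dict(name, doc["species"][name])
        for name in ("plaice", "sole")
    }
    return ModelParams(plaice=species["plaice"], sole=species["sole"], resources=res)


def params_to_dict(params: ModelParams) -> dict:
    """Inverse of :func:`params_from_dict` (round-trip safe)."""
    out: dict = {
        "resources": {
            "r": params.resources.r, "K_m": params.resources.K_m,
            "K_p": params.resources.K_p, "R_h": params.resources.R_h,
            "omega": params.resources.omega,
        },
        "species": {},
    }
    for name in ("plaice", "sole"):
        sp = params.species(name)
        out["species"][name] = {
            "L_J": sp.L_J, "L_LJ": sp.L_LJ, "L_A": sp.L_A,
            "lw_a": sp.lw_a, "lw_b": sp.lw_b,
            "W_avg": {s: sp.stages[s].W_avg for s in ("J", "LJ", "A")},
            "L_avg": {s: sp.stages[s].L_avg for s in ("J", "LJ", "A")},
            "I_max": {s: sp.stages[s].I_max for s in ("J", "LJ", "A")},
            "z": {"J_LJ": sp.stages["J"].z, "LJ_A": sp.stages["LJ"].z},
            "T": sp.T, "delta": sp.delta, "mu": sp.mu, "price": sp.price,
            "f": {"LJ": sp.stages["LJ"].f, "A": sp.stages["A"].f},
        }
    return out


def load_params(path: str | Path | None = None) -> ModelParams:
    """Load a parameter file (the packaged default when ``path`` is None)."""
    path = default_config_path() if path is None else Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ParameterError(f"parameter file {path} is not a mapping")
    return params_from_dict(doc)


def save_params(params: ModelParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(params), fh, sort_keys=False)


def config_hash(params: ModelParams) -> str:
    """Short stable hash of a parameter set, for output provenance headers."""
    canonical = yaml.safe_dump(params_to_dict(params), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


@dataclass
class RunConfig:
    """Fully explicit description of one analysis run."""

    params_file: str | None = None   # None -> packaged default
    omega: float = 0.0
    effort_max: float | None = None  # None -> adaptive doubling search
    effort_steps: int = 201
    seed: int = 0
    out_dir: str = "results"
    extinction_tol: float = 1e-9
    residual_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ParameterError(f"omega must lie in [0, 1], got {self.omega}")
        if self.effort_steps < 1:
            raise ParameterError("effort_steps must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        allowed = set(cls.__dataclass_fields__)
        _reject_unknown(doc, allowed, "run configuration")
        return cls(**doc)

    def load_model_params(self) -> ModelParams:
        return load_params(self.params_file).with_omega(self.omega)
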