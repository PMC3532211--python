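"""Parameter and state containers for the two-species stage-structured model.

The model tracks nine biomass densities (all in g L^-1): three resources
(the plaice-exclusive resource ``R_p``, the sole-exclusive resource ``R_s``
and the shared resource ``R_sh``) and three life stages -- small juveniles
(J), large juveniles (LJ) and adults (A) -- for each of the two consumer
species.  The fixed component order of state and derivative vectors is

    (R_p, R_s, R_sh, J_p, LJ_p, A_p, J_s, LJ_s, A_s)

and is exported as :data:`STATE_VARS`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

SPECIES = ("plaice", "sole")
STAGES = ("J", "LJ", "A")

#: Fixed component order of state and derivative vectors.
STATE_VARS = ("R_p", "R_s", "R_sh", "J_p", "LJ_p", "A_p", "J_s", "LJ_s", "A_s")

#: Index of the first stage component of each species in the state vector.
SPECIES_SLICE = {"plaice": slice(3, 6), "sole": slice(6, 9)}


class ParameterError(ValueError):
    """Raised when a parameter value violates its domain constraints."""


@dataclass(frozen=True)
class StageParams:
    """Per-stage biological and fishery parameters.

    Attributes
    ----------
    I_max : float
        Mass-specific maximum ingestion rate (g g^-1 d^-1).
    W_avg : float
        Average individual wet weight in the stage (g).
    L_avg : float
        Average individual length in the stage (cm).
    z : float or None
        Ratio of body mass at stage entry to body mass at stage exit
        (dimensionless, 0 < z < 1).  ``None`` for the adult stage, which
        does not mature further.
    f : float
        Relative catchability (d^-1 per unit effort); 0 for small
        juveniles, which are not retained by the gear.
    """

    I_max: float
    W_avg: float
    L_avg: float
    z: float | None = None
    f: float = 0.0

    def __post_init__(self) -> None:
        if not self.I_max > 0:
            raise ParameterError(f"I_max must be positive, got {self.I_max}")
        if not (self.W_avg > 0 and self.L_avg > 0):
            raise ParameterError("W_avg and L_avg must be positive")
        if self.z is not None and not 0 < self.z < 1:
            raise ParameterError(f"z must lie in (0, 1), got {self.z}")
        if self.f < 0:
            raise ParameterError(f"catchability f must be >= 0, got {self.f}")


@dataclass(frozen=True)
class SpeciesParams:
    """All per-species biology and fishery parameters.

    ``stages`` maps stage labels ("J", "LJ", "A") to :class:`StageParams`.
    ``T`` is the mass-specific maintenance rate (g g^-1 d^-1), ``delta``
    the food conversion (assimilation-to-growth) factor, ``mu`` the
    background mortality (d^-1) and ``price`` the market price of landed
    biomass (EUR kg^-1).  ``lw_a``/``lw_b`` are the coefficients of the
    length-weight relationship W = a L^b (W in g, L in cm) and
    ``L_J`` < ``L_LJ`` < ``L_A`` are the stage-boundary lengths (cm):
    size at settlement, minimum size retained by the gear, and minimum
    landing size (= maturation size).
    """

    name: str
    stages: dict[str, StageParams]
    T: float
    delta: float
    mu: float
    price: float
    lw_a: float
    lw_b: float
    L_J: float
    L_LJ: float
    L_A: float

    def __post_init__(self) -> None:
        if set(self.stages) != set(STAGES):
            raise ParameterError(f"stages must be keyed by {STAGES}")
        if not self.T > 0:
            raise ParameterError("maintenance rate T must be positive")
        if not 0 < self.delta < 1:
            raise ParameterError("conversion factor delta must lie in (0, 1)")
        if not self.mu > 0:
            raise ParameterError("background mortality mu must be positive")
        if self.price < 0:
            raise ParameterError("price must be >= 0")
        if not self.L_J < self.L_LJ < self.L_A:
            raise ParameterError("stage boundaries must satisfy L_J < L_LJ < L_A")
        for name in ("J", "LJ"):
            if self.stages[name].z is None:
                raise ParameterError(f"stage {name} requires a z ratio")

    def stage(self, name: str) -> StageParams:
        return self.stages[name]


@dataclass(frozen=True)
class ResourceParams:
    """Shared resource-dynamics parameters.

    Resources follow semi-chemostat dynamics dR/dt = r (K - R) minus
    consumption.  ``K_m`` is the total maximum density on the sole side,
    split by the overlap fraction ``omega`` into a sole-exclusive part
    (1 - omega) K_m and a shared part omega K_m; ``K_p`` is the
    plaice-exclusive resource maximum.  ``R_h`` is the Holling type-II
    half-saturation density.  All densities in g L^-1, r in d^-1.
    """

    r: float
    K_m: float
    K_p: float
    R_h: float
    omega: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r", "K_m", "K_p", "R_h"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive")
        if not 0.0 <= self.omega <= 1.0:
            raise ParameterError(f"omega must lie in [0, 1], got {self.omega}")


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set: both species plus the resource base."""

    plaice: SpeciesParams
    sole: SpeciesParams
    resources: ResourceParams

    def species(self, name: str) -> SpeciesParams:
        if name == "plaice":
            return self.plaice
        if name == "sole":
            return self.sole
        raise KeyError(name)

    def with_omega(self, omega: float) -> "ModelParams":
        return replace(self, resources=replace(self.resources, omega=omega))

    def with_catchability(self, species: str, stage: str, f: float) -> "ModelParams":
        """Return a copy with one stage's catchability replaced."""
        sp = self.species(species)
        stages = dict(sp.stages)
        stages[stage] = replace(stages[stage], f=f)
        sp_new = replace(sp, stages=stages)
        return replace(self, **{species: sp_new})


class SystemState:
    """Nine non-negative biomass densities in the fixed component order.

    Thin wrapper around a length-9 float array; named accessors follow
    :data:`STATE_VARS`.
    """

    __slots__ = ("values",)

    def __init__(self, values: Iterable[float]):
        arr = np.asarray(values, dtype=float).copy()
        if arr.shape != (9,):
            raise ValueError(f"state must have 9 components, got shape {arr.shape}")
        if np.any(np.isnan(arr)):
            raise ValueError("state contains NaN")
        if np.any(arr < 0):
            raise ValueError("state components must be non-negative")
        self.values = arr

    @classmethod
    def from_components(cls, **kwargs: float) -> "SystemState":
        return cls([kwargs.get(name, 0.0) for name in STATE_VARS])

    def __getattr__(self, name: str) -> float:
        try:
            return float(self.values[STATE_VARS.index(name)])
        except ValueError:
            raise AttributeError(name) from None

    def species_total(self, species: str) -> float:
        return float(self.values[SPECIES_SLICE[species]].sum())

    def to_array(self) -> np.ndarray:
        return self.values.copy()

    def asdict(self) -> dict[str, float]:
        return {name: float(v) for name, v in zip(STATE_VARS, self.values)}

    def __repr__(self) -> str:  # pragma: no cover
        parts = ", ".join(f"{k}={v:.6g}" for k, v in self.asdict().items())
        return f"SystemState({parts})"


@dataclass(frozen=True)
class SpeciesCatch:
    """Per-species harvesting flows at one state and effort.

    ``landings`` and ``discards`` are biomass flows (g L^-1 d^-1);
    ``discard_ratio`` is discards/landings (NaN when landings are zero
    and discards are positive); ``revenue`` is in EUR L^-1 d^-1.
    """

    landings: float
    discards: float
    discard_ratio: float
    revenue: float


@dataclass(frozen=True)
class FisheryMetrics:
    plaice: SpeciesCatch
    sole: SpeciesCatch
    revenue_total: float = field(default=0.0)

    def catch(self, species: str) -> SpeciesCatch:
        return getattr(self, species)


def effort_value(E: float) -> float:
    """Validate a fishing-effort value (arbitrary intensity unit, >= 0)."""
    E = float(E)
    if math.isnan(E) or E < 0:
        raise ParameterError(f"effort must be >= 0, got {E}")
    return E
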