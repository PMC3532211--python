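"""The stage-structured biomass dynamics of two competing, harvested stocks.

Each species is represented by the biomass densities of three life stages
(small juveniles J, large juveniles LJ, adults A) feeding on an exclusive
resource plus a shared resource.  Resources follow semi-chemostat dynamics
dR/dt = r (K - R) minus consumption; consumers feed through a Holling
type-II functional response over the summed availability of their two
resources.  Net biomass production nu = delta * intake - maintenance
drives growth, maturation between stages and (for adults) reproduction;
negative nu acts as starvation biomass loss and shuts maturation and
reproduction off.  Large juveniles and adults suffer fishing mortality
f * E; caught adults are landed, caught large juveniles are discarded.

The overlap fraction omega splits the sole-side resource maximum K_m into
a sole-exclusive part (1 - omega) K_m and a shared part omega K_m, so
omega = 0 decouples the species and omega = 1 forces sole to live entirely
on the resource it shares with plaice.
"""

from __future__ import annotations

import math

import numpy as np

from .params import (
    FisheryMetrics,
    ModelParams,
    ParameterError,
    SpeciesCatch,
    SystemState,
    effort_value,
)

__all__ = [
    "split_resource_maxima",
    "ingestion",
    "net_production",
    "maturation_rate",
    "fishing_mortality",
    "rhs",
    "fishery_metrics",
    "default_seed_state",
]

_STAGE_IDX = {"J": 0, "LJ": 1, "A": 2}


def split_resource_maxima(K_m: float, omega: float) -> tuple[float, float]:
    """Split the sole-side resource maximum by the overlap fraction.

    Returns ``(K_sole, K_shared) = ((1 - omega) K_m, omega K_m)``; the two
    parts always sum to ``K_m`` exactly.
    """
    if not 0.0 <= omega <= 1.0:
        raise ParameterError(f"omega must lie in [0, 1], got {omega}")
    if not K_m > 0:
        raise ParameterError(f"K_m must be positive, got {K_m}")
    return (1.0 - omega) * K_m, omega * K_m


def ingestion(
    R_own: float, R_sh: float, I_max: float, R_h: float
) -> tuple[float, float, float]:
    """Total mass-specific intake over two resources, Holling type II.

    Intake saturates in the summed availability of the exclusive and the
    shared resource,

        IR = I_max (R_own + R_sh) / (R_h + R_own + R_sh),

    and is split between the two resources in proportion to their
    densities (no preference).  Returns ``(total, frac_own, frac_shared)``
    with ``frac_own + frac_shared = 1`` whenever the total is positive.
    """
    if R_own < 0 or R_sh < 0:
        raise ParameterError("resource densities must be >= 0")
    if not R_h > 0:
        raise ParameterError("half-saturation constant R_h must be positive")
    avail = R_own + R_sh
    if avail == 0.0:
        return 0.0, 0.0, 0.0
    total = I_max * avail / (R_h + avail)
    return total, R_own / avail, R_sh / avail


def net_production(IR: float, delta: float, T: float) -> float:
    """Net mass-specific biomass production nu = delta * IR - T.

    Negative values signal starvation: maintenance exceeds assimilated
    intake and the stage loses biomass.
    """
    if IR < 0:
        raise ParameterError(f"intake must be >= 0, got {IR}")
    return delta * IR - T


def maturation_rate(nu: float, mu_total: float, z: float) -> float:
    """Biomass maturation rate out of a stage.

    For positive net production nu the stage matures at

        gamma = (nu - mu) / (1 - z^(1 - mu/nu)),

    where mu is the stage's total (background + fishing) mortality and z
    the stage's entry-to-exit mass ratio.  The expression has a removable
    singularity at nu = mu, evaluated by its limit -nu / ln z.  When
    nu <= 0 the stage starves and maturation stops (gamma = 0).
    """
    if not 0.0 < z < 1.0:
        raise ParameterError(f"z must lie in (0, 1), got {z}")
    if mu_total < 0:
        raise ParameterError("total mortality must be >= 0")
    if nu <= 0.0:
        return 0.0
    log_z = math.log(z)
    t = (1.0 - mu_total / nu) * log_z
    if t == 0.0:
        # removable singularity at nu = mu_total
        return -nu / log_z
    if t > 700.0:  # z^x would overflow; gamma underflows to 0
        return 0.0
    # expm1 keeps full precision arbitrarily close to the singularity
    return (nu - mu_total) / -math.expm1(t)


def fishing_mortality(f: float, E: float) -> float:
    """Fishing mortality F = f * E (linear in effort, per-stage catchability)."""
    if f < 0:
        raise ParameterError(f"catchability must be >= 0, got {f}")
    return f * effort_value(E)


class PackedParams:
    """Parameter arrays laid out for fast evaluation of the RHS.

    Species axis order is (plaice, sole), matching the state layout.
    """

    __slots__ = (
        "r", "R_h", "K", "I_max", "f", "z", "T", "delta", "mu", "price", "omega",
    )

    def __init__(self, params: ModelParams, omega: float | None = None):
        res = params.resources
        self.omega = res.omega if omega is None else float(omega)
        K_s, K_sh = split_resource_maxima(res.K_m, self.omega)
        self.r = res.r
        self.R_h = res.R_h
        self.K = np.array([res.K_p, K_s, K_sh])
        sp = [params.plaice, params.sole]
        self.I_max = np.array([[s.stages[st].I_max for st in ("J", "LJ", "A")] for s in sp])
        self.f = np.array([[s.stages[st].f for st in ("J", "LJ", "A")] for s in sp])
        self.z = np.array([[s.stages["J"].z, s.stages["LJ"].z] for s in sp])
        self.T = np.array([s.T for s in sp])
        self.delta = np.array([s.delta for s in sp])
        self.mu = np.array([s.mu for s in sp])
        self.price = np.array([s.price for s in sp])


def _rhs_packed(y: np.ndarray, p: PackedParams, E: float) -> np.ndarray:
    """Time derivative of the 9-component state (no validation, clips at 0)."""
    y = np.maximum(y, 0.0)
    R = y[:3]  # R_p, R_s, R_sh
    d = np.empty(9)
    cons = np.zeros(3)  # consumption drain per resource
    for s in range(2):  # 0 = plaice, 1 = sole
        own = s  # plaice eats R[0], sole eats R[1]
        B = y[3 + 3 * s: 6 + 3 * s]
        denom = p.R_h + R[own] + R[2]
        # per-unit-biomass intake of each stage, split over the resources
        intake_per_cap = (R[own] + R[2]) / denom
        nu = p.delta[s] * p.I_max[s] * intake_per_cap - p.T[s]
        cons[own] += (p.I_max[s] * R[own] / denom) @ B
        cons[2] += (p.I_max[s] * R[2] / denom) @ B
        mu_tot = p.mu[s] + p.f[s] * E
        nu_J, nu_LJ, nu_A = nu
        gamma_J = maturation_rate(nu_J, mu_tot[0], p.z[s, 0])
        gamma_LJ = maturation_rate(nu_LJ, mu_tot[1], p.z[s, 1])
        repro = max(nu_A, 0.0)  # adult surplus goes to offspring
        J, LJ, A = B
        d[3 + 3 * s] = repro * A + nu_J * J - gamma_J * J - mu_tot[0] * J
        d[4 + 3 * s] = gamma_J * J + nu_LJ * LJ - gamma_LJ * LJ - mu_tot[1] * LJ
        d[5 + 3 * s] = gamma_LJ * LJ + (nu_A - repro) * A - mu_tot[2] * A
    d[:3] = p.r * (p.K - R) - cons
    return d


def rhs(
    state: SystemState | np.ndarray,
    params: ModelParams,
    E: float = 0.0,
    omega: float | None = None,
) -> np.ndarray:
    """Time derivative of the full state (g L^-1 d^-1), fixed component order.

    ``state`` may be a :class:`SystemState` or a length-9 array.  Negative
    or NaN inputs are rejected.
    """
    y = state.to_array() if isinstance(state, SystemState) else np.asarray(state, float)
    if y.shape != (9,):
        raise ParameterError(f"state must have 9 components, got {y.shape}")
    if np.any(np.isnan(y)) or np.any(y < 0):
        raise ParameterError("state must be non-negative and free of NaN")
    return _rhs_packed(y, PackedParams(params, omega), effort_value(E))


def fishery_metrics(
    state: SystemState | np.ndarray,
    params: ModelParams,
    E: float,
) -> FisheryMetrics:
    """Landings, discards, discard ratio and revenue at a state and effort.

    Only adults are landed (flow f_A E A, g L^-1 d^-1); caught large
    juveniles are discarded (flow f_LJ E LJ).  Revenue per species is
    price (EUR kg^-1) times the landings flow converted from g to kg, so
    revenue carries the volumetric unit EUR L^-1 d^-1.  The discard ratio
    discards/landings is 0 when both flows vanish and NaN when only
    landings do.
    """
    E = effort_value(E)
    y = state.to_array() if isinstance(state, SystemState) else np.asarray(state, float)
    if np.any(y < 0):
        raise ParameterError("state must be non-negative")
    catches = {}
    total_rev = 0.0
    for i, name in enumerate(("plaice", "sole")):
        sp = params.species(name)
        LJ, A = y[4 + 3 * i], y[5 + 3 * i]
        landings = sp.stages["A"].f * E * A
        discards = sp.stages["LJ"].f * E * LJ
        if landings > 0:
            ratio = discards / landings
        else:
            ratio = 0.0 if discards == 0.0 else math.nan
        revenue = sp.price * (landings / 1000.0)  # g -> kg
        catches[name] = SpeciesCatch(landings, discards, ratio, revenue)
        total_rev += revenue
    return FisheryMetrics(plaice=catches["plaice"], sole=catches["sole"],
                          revenue_total=total_rev)


def default_seed_state(
    params: ModelParams,
    omega: float | None = None,
    consumer_density: float = 1e-3,
    species: tuple[str, ...] = ("plaice", "sole"),
) -> SystemState:
    """Standard initial state: resources at their maxima, small consumer seed.

    Every stage of each seeded species starts at ``consumer_density``
    g L^-1; omitting a species from ``species`` leaves it at zero.
    """
    p = PackedParams(params, omega)
    y = np.zeros(9)
    y[:3] = p.K
    if "plaice" in species:
        y[3:6] = consumer_density
    if "sole" in species:
        y[6:9] = consumer_density
    return SystemState(y)
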