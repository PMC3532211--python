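"""Equilibrium computation and bifurcation-style sweeps over effort/overlap.

Equilibria are found by integrating the stiff system until the state stops
moving, then polishing the endpoint with a damped Newton iteration (Powell
hybrid) on ``rhs = 0``.  A species whose total biomass falls below the
extinction tolerance is clamped to zero and the reduced system re-polished,
which keeps the solver off numerically meaningless shadow branches.

Sweeps use natural-parameter continuation: each grid point is warm-started
from the previous equilibrium, following the branch from the unfished
(or non-overlapping) end upward.  Extinction thresholds are located by
bisection on the persistence boundary; revenue maxima are refined by
bounded scalar minimization on re-solved equilibria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar, root

from .model import PackedParams, _rhs_packed, fishery_metrics
from .params import (
    SPECIES,
    SPECIES_SLICE,
    STATE_VARS,
    FisheryMetrics,
    ModelParams,
    SystemState,
    effort_value,
)

__all__ = [
    "EquilibriumRecord",
    "EffortCurve",
    "OmegaCurve",
    "RevenueMaximum",
    "RevenueAnalysis",
    "solve_equilibrium",
    "sweep_effort",
    "sweep_omega",
    "find_extinction_effort",
    "find_exclusion_omega",
    "find_effort_max",
    "refine_extinction_from_bracket",
    "analyze_revenue_curve",
]

#: Total-biomass density below which a species is recorded extinct (g L^-1).
EXTINCTION_TOL = 1e-9

#: Max-norm residual required of a converged equilibrium (g L^-1 d^-1).
RESIDUAL_TOL = 1e-9


@dataclass
class EquilibriumRecord:
    """One computed equilibrium with its setting and diagnostics."""

    omega: float
    E: float
    state: SystemState
    metrics: FisheryMetrics
    residual_norm: float
    converged: bool
    method: str
    t_integrated: float
    extinct: dict[str, bool]

    def species_present(self) -> tuple[str, ...]:
        return tuple(s for s in SPECIES if not self.extinct[s])

    def row(self) -> dict:
        out = {"omega": self.omega, "E": self.E}
        out.update(self.state.asdict())
        for s in SPECIES:
            c = self.metrics.catch(s)
            out[f"landings_{s}"] = c.landings
            out[f"discards_{s}"] = c.discards
            out[f"discard_ratio_{s}"] = c.discard_ratio
            out[f"revenue_{s}"] = c.revenue
        out["revenue_total"] = self.metrics.revenue_total
        out["residual_norm"] = self.residual_norm
        out["converged"] = self.converged
        return out


def _species_totals(y: np.ndarray) -> dict[str, float]:
    return {s: float(y[SPECIES_SLICE[s]].sum()) for s in SPECIES}


def _apply_extinctions(y: np.ndarray, extinct_tol: float) -> dict[str, bool]:
    """Clamp species below the extinction tolerance to zero, in place."""
    flags = {}
    for s in SPECIES:
        sl = SPECIES_SLICE[s]
        if y[sl].sum() < extinct_tol:
            y[sl] = 0.0
            flags[s] = True
        else:
            flags[s] = False
    return flags


def _polish(
    y: np.ndarray,
    p: PackedParams,
    E: float,
    extinct_tol: float,
    resid_tol: float,
) -> tuple[np.ndarray, dict[str, bool], bool, float]:
    """Damped-Newton polish of an integration endpoint.

    Species that the polish drives below the extinction tolerance (or
    negative) are clamped to zero and the reduced system re-solved, up to
    three times.  Returns (state, extinct flags, success, residual norm).
    """
    y = np.maximum(np.asarray(y, float).copy(), 0.0)
    extinct = _apply_extinctions(y, extinct_tol)
    for _ in range(3):
        active = np.ones(9, dtype=bool)
        for s in SPECIES:
            if extinct[s]:
                active[SPECIES_SLICE[s]] = False
        template = y.copy()

        def fun(x: np.ndarray) -> np.ndarray:
            full = template.copy()
            full[active] = x
            return _rhs_packed(full, p, E)[active]

        sol = root(fun, y[active], method="hybr", options={"xtol": 1e-13})
        full = template.copy()
        full[active] = sol.x
        # negative components beyond round-off mean this branch does not
        # exist here: the offending species is extinct at this effort
        newly = False
        for s in SPECIES:
            sl = SPECIES_SLICE[s]
            if not extinct[s] and (
                full[sl].sum() < extinct_tol or full[sl].min() < -1e-10
            ):
                extinct[s] = True
                newly = True
        full = np.where((full < 0) & (full > -1e-10), 0.0, full)
        if newly:
            y = np.maximum(full, 0.0)
            _apply_extinctions(y, extinct_tol)
            continue
        if np.any(full < 0):
            return np.maximum(full, 0.0), extinct, False, math.inf
        resid = float(np.max(np.abs(_rhs_packed(full, p, E))))
        return full, extinct, bool(sol.success) and resid < resid_tol, resid
    resid = float(np.max(np.abs(_rhs_packed(y, p, E))))
    return y, extinct, resid < resid_tol, resid


def _jacobian(y: np.ndarray, p: PackedParams, E: float) -> np.ndarray:
    """Forward-difference Jacobian of the RHS (forward keeps states >= 0)."""
    f0 = _rhs_packed(y, p, E)
    J = np.empty((9, 9))
    for j in range(9):
        h = 1e-7 * max(abs(y[j]), 1e-4)
        yp = y.copy()
        yp[j] += h
        J[:, j] = (_rhs_packed(yp, p, E) - f0) / h
    return J


#: Upper bound on the real part of any Jacobian eigenvalue (d^-1) for an
#: equilibrium to count as attracting (covers invasion rates of clamped
#: species as well as local stability of the persisting ones).
_STABILITY_TOL = 1e-8


def _is_attracting(y: np.ndarray, p: PackedParams, E: float) -> bool:
    eig = np.linalg.eigvals(_jacobian(y, p, E))
    return bool(np.max(eig.real) < _STABILITY_TOL)


def solve_equilibrium(
    params: ModelParams,
    omega: float | None = None,
    E: float = 0.0,
    init: SystemState | np.ndarray | None = None,
    *,
    t_max: float = 2.0e6,
    settle_tol: float = 1e-7,
    extinct_tol: float = EXTINCTION_TOL,
    resid_tol: float = RESIDUAL_TOL,
) -> EquilibriumRecord:
    """Find the stable equilibrium reached from ``init`` at the given setting.

    When ``init`` is a warm start (e.g. the neighbouring equilibrium of a
    continuation sweep) a damped-Newton polish is attempted directly; the
    result is accepted only if the polished state is an attracting
    equilibrium (all Jacobian eigenvalues in the left half-plane, which
    also rejects extinct states that an absent species could re-invade).
    Otherwise the system is integrated (LSODA) in chunks of growing length
    until the relative state change over a chunk falls below
    ``settle_tol``, and the endpoint is Newton-polished.  A species whose
    total biomass drops below ``extinct_tol`` is clamped to zero.  If the
    polish never converges within the integration budget the record is
    returned with ``converged=False`` -- never a silent wrong answer.
    """
    from .model import default_seed_state

    E = effort_value(E)
    p = PackedParams(params, omega)
    warm_start = init is not None
    if init is None:
        init = default_seed_state(params, omega)
    y = init.to_array() if isinstance(init, SystemState) else np.asarray(init, float)
    y = np.maximum(y.copy(), 0.0)
    _apply_extinctions(y, extinct_tol)

    if warm_start:
        y_pol, extinct, ok, resid = _polish(y, p, E, extinct_tol, resid_tol)
        if ok and _is_attracting(y_pol, p, E):
            state = SystemState(np.maximum(y_pol, 0.0))
            return EquilibriumRecord(
                omega=p.omega, E=E, state=state,
                metrics=fishery_metrics(state, params, E),
                residual_norm=resid, converged=True,
                method="newton", t_integrated=0.0, extinct=extinct,
            )

    def fun(t, yy):
        return _rhs_packed(yy, p, E)

    t, chunk = 0.0, 2000.0
    best: tuple[np.ndarray, dict, bool, float] | None = None
    while t < t_max:
        sol = solve_ivp(fun, (0.0, chunk), y, method="LSODA",
                        rtol=1e-8, atol=1e-12)
        y_new = np.maximum(sol.y[:, -1], 0.0)
        _apply_extinctions(y_new, extinct_tol)
        change = float(np.max(np.abs(y_new - y) / (1e-12 + np.abs(y_new))))
        y = y_new
        t += chunk
        chunk = min(chunk * 2.0, 6.4e4)
        if change < settle_tol:
            best = _polish(y, p, E, extinct_tol, resid_tol)
            if best[2]:
                break
            y = best[0]
    else:
        best = _polish(y, p, E, extinct_tol, resid_tol)

    y_fin, extinct, ok, resid = best
    state = SystemState(np.maximum(y_fin, 0.0))
    return EquilibriumRecord(
        omega=p.omega, E=E, state=state,
        metrics=fishery_metrics(state, params, E),
        residual_norm=resid, converged=ok,
        method="integrate+newton", t_integrated=t, extinct=extinct,
    )


# ---------------------------------------------------------------------------
# Sweeps


@dataclass
class EffortCurve:
    """Equilibria along an increasing effort grid at fixed overlap."""

    omega: float
    records: list[EquilibriumRecord]
    #: per species: (E_last_present, E_first_extinct) grid bracket, or None
    extinction_brackets: dict[str, tuple[float, float] | None] = field(
        default_factory=dict
    )

    @property
    def efforts(self) -> np.ndarray:
        return np.array([r.E for r in self.records])

    def revenue_total(self) -> np.ndarray:
        return np.array([r.metrics.revenue_total for r in self.records])

    def stage_biomass(self, species: str, stage: str) -> np.ndarray:
        return np.array([getattr(r.state, f"{stage}_{species[0]}") for r in self.records])

    def species_biomass(self, species: str) -> np.ndarray:
        return np.array([r.state.species_total(species) for r in self.records])

    def extinction_effort(self, species: str) -> float:
        """Grid estimate (bracket midpoint) of the extinction effort."""
        br = self.extinction_brackets.get(species)
        return math.inf if br is None else 0.5 * (br[0] + br[1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.row() for r in self.records])


def _extinction_brackets(
    grid: np.ndarray, records: list[EquilibriumRecord]
) -> dict[str, tuple[float, float] | None]:
    out: dict[str, tuple[float, float] | None] = {}
    for s in SPECIES:
        out[s] = None
        for i in range(1, len(records)):
            if not records[i - 1].extinct[s] and records[i].extinct[s]:
                out[s] = (float(grid[i - 1]), float(grid[i]))
                break
    return out


def sweep_effort(
    params: ModelParams,
    omega: float,
    E_grid: np.ndarray,
    continuation: bool = True,
    init: SystemState | None = None,
    **solve_kw,
) -> EffortCurve:
    """Solve equilibria along an increasing effort grid.

    With ``continuation=True`` (default) each point is warm-started from
    the previous equilibrium, following the branch from low effort upward;
    otherwise every point starts from the standard seed state.
    """
    E_grid = np.asarray(E_grid, float)
    if len(E_grid) > 1 and np.any(np.diff(E_grid) <= 0):
        raise ValueError("effort grid must be strictly increasing")
    records = []
    warm = init
    for E in E_grid:
        rec = solve_equilibrium(params, omega, float(E), init=warm, **solve_kw)
        records.append(rec)
        if continuation:
            warm = rec.state
        else:
            warm = init
    return EffortCurve(
        omega=omega, records=records,
        extinction_brackets=_extinction_brackets(E_grid, records),
    )


@dataclass
class OmegaCurve:
    """Equilibria along an overlap grid at fixed effort."""

    E: float
    records: list[EquilibriumRecord]
    #: omega above which sole is competitively excluded (bisection), or inf
    exclusion_omega: dict[str, float] = field(default_factory=dict)

    @property
    def omegas(self) -> np.ndarray:
        return np.array([r.omega for r in self.records])

    def species_biomass(self, species: str) -> np.ndarray:
        return np.array([r.state.species_total(species) for r in self.records])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.row() for r in self.records])


def sweep_omega(
    params: ModelParams,
    omega_grid: np.ndarray,
    E: float = 0.0,
    continuation: bool = True,
    **solve_kw,
) -> OmegaCurve:
    """Solve equilibria along an increasing resource-overlap grid.

    Detects, per species, the overlap at which it is competitively
    excluded (bisection on the persistence boundary) whenever the grid
    brackets such a crossing.
    """
    omega_grid = np.asarray(omega_grid, float)
    records = []
    warm: SystemState | None = None
    for w in omega_grid:
        rec = solve_equilibrium(params, float(w), E, init=warm, **solve_kw)
        records.append(rec)
        warm = rec.state if continuation else None
    exclusion: dict[str, float] = {}
    for s in SPECIES:
        exclusion[s] = math.inf
        for i in range(1, len(records)):
            if not records[i - 1].extinct[s] and records[i].extinct[s]:
                exclusion[s] = find_exclusion_omega(
                    params, s, E,
                    lo=float(omega_grid[i - 1]), hi=float(omega_grid[i]),
                    warm=records[i - 1].state, **solve_kw,
                )
                break
    return OmegaCurve(E=E, records=records, exclusion_omega=exclusion)


def _bisect_boundary(solve_at, lo, hi, rel_tol):
    """Bisection on a persistence boundary.  ``solve_at(x)`` returns
    (persists, warm_state); ``lo`` must persist, ``hi`` must not."""
    while hi - lo > rel_tol * max(hi, 1e-30):
        mid = 0.5 * (lo + hi)
        persists, _ = solve_at(mid)
        if persists:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_exclusion_omega(
    params: ModelParams,
    species: str = "sole",
    E: float = 0.0,
    lo: float = 0.0,
    hi: float = 1.0,
    rel_tol: float = 1e-4,
    warm: SystemState | None = None,
    **solve_kw,
) -> float:
    """Overlap fraction at which ``species`` is competitively excluded."""
    warm_state = warm

    def solve_at(w):
        nonlocal warm_state
        rec = solve_equilibrium(params, w, E, init=warm_state, **solve_kw)
        if not rec.extinct[species]:
            warm_state = rec.state
        return not rec.extinct[species], rec.state

    persists_lo, _ = solve_at(lo)
    if not persists_lo:
        return math.nan
    persists_hi, _ = solve_at(hi)
    if persists_hi:
        return math.inf
    return _bisect_boundary(solve_at, lo, hi, rel_tol)


def find_extinction_effort(
    params: ModelParams,
    omega: float,
    species: str,
    rel_tol: float = 1e-4,
    E_cap: float = 1.0e6,
    **solve_kw,
) -> float:
    """Effort threshold above which ``species`` goes extinct.

    Doubling search for an extinct bracket followed by bisection on the
    persistence boundary (warm-started from the last persisting state).
    Returns ``inf`` for an unfishable species (all catchabilities zero)
    and ``NaN`` if the species is already absent at E = 0.
    """
    sp = params.species(species)
    if sp.stages["LJ"].f == 0.0 and sp.stages["A"].f == 0.0:
        return math.inf
    warm_state: SystemState | None = None

    def solve_at(E):
        nonlocal warm_state
        rec = solve_equilibrium(params, omega, E, init=warm_state, **solve_kw)
        if not rec.extinct[species]:
            warm_state = rec.state
        return not rec.extinct[species], rec.state

    persists, _ = solve_at(0.0)
    if not persists:
        return math.nan
    E_lo, E_hi = 0.0, 1.0
    while solve_at(E_hi)[0]:
        E_lo = E_hi
        E_hi *= 2.0
        if E_hi > E_cap:
            return math.inf
    return _bisect_boundary(solve_at, E_lo, E_hi, rel_tol)


def find_effort_max(
    params: ModelParams, omega: float, margin: float = 1.1, **solve_kw
) -> float:
    """Smallest power-of-two effort at which both species are extinct,
    times a small margin -- the default upper end of effort grids."""
    warm: SystemState | None = None
    E = 1.0
    while E < 1.0e6:
        rec = solve_equilibrium(params, omega, E, init=warm, **solve_kw)
        if all(rec.extinct[s] for s in SPECIES):
            return E * margin
        warm = rec.state
        E *= 2.0
    return math.inf


# ---------------------------------------------------------------------------
# Revenue-curve analysis


@dataclass
class RevenueMaximum:
    """One local maximum of the combined revenue curve."""

    E: float
    revenue: float
    revenue_by_species: dict[str, float]
    species_present: tuple[str, ...]


@dataclass
class RevenueAnalysis:
    maxima: list[RevenueMaximum]
    modality: str  # "flat", "unimodal", "bimodal" or "multimodal"
    global_max: RevenueMaximum | None
    #: True when the revenue-optimal effort lies beyond plaice extinction
    global_max_beyond_plaice_extinction: bool | None
    #: bisected plaice extinction effort (inf if plaice never goes extinct)
    E_star_plaice: float = math.inf


def refine_extinction_from_bracket(
    params: ModelParams,
    omega: float,
    species: str,
    bracket: tuple[float, float],
    warm: SystemState | None = None,
    rel_tol: float = 1e-4,
    **solve_kw,
) -> float:
    """Bisect a grid-detected persistence boundary down to ``rel_tol``."""
    warm_state = warm

    def solve_at(E):
        nonlocal warm_state
        rec = solve_equilibrium(params, omega, E, init=warm_state, **solve_kw)
        if not rec.extinct[species]:
            warm_state = rec.state
        return not rec.extinct[species], rec.state

    return _bisect_boundary(solve_at, bracket[0], bracket[1], rel_tol)


def _grid_local_maxima(values: np.ndarray) -> list[int]:
    """Indices of interior local maxima, tolerant of flat plateaus."""
    runs: list[tuple[int, int, float]] = []
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[j + 1] == values[i]:
            j += 1
        runs.append((i, j, values[i]))
        i = j + 1
    idx = []
    for k in range(1, len(runs) - 1):
        if runs[k][2] > runs[k - 1][2] and runs[k][2] > runs[k + 1][2]:
            idx.append((runs[k][0] + runs[k][1]) // 2)
    return idx


def analyze_revenue_curve(
    curve: EffortCurve,
    params: ModelParams | None = None,
    refine: bool = True,
    **solve_kw,
) -> RevenueAnalysis:
    """Locate and classify the maxima of the combined revenue curve.

    Grid maxima (strict neighbour comparison, plateau-tolerant) are
    refined by bounded scalar maximization over the bracketing grid cell,
    re-solving the equilibrium at each probe effort (requires ``params``).
    """
    if len(curve.records) < 3:
        raise ValueError("revenue analysis needs a curve with >= 3 points")
    E_grid = curve.efforts
    rev = curve.revenue_total()
    if np.all(rev == 0.0):
        return RevenueAnalysis([], "flat", None, None)
    maxima: list[RevenueMaximum] = []
    for i in _grid_local_maxima(rev):
        lo, hi = E_grid[max(i - 1, 0)], E_grid[min(i + 1, len(E_grid) - 1)]
        if refine and params is not None:
            warm = curve.records[i].state
            cache: dict[float, EquilibriumRecord] = {}

            def negrev(E: float) -> float:
                rec = solve_equilibrium(params, curve.omega, float(E),
                                        init=warm, **solve_kw)
                cache[float(E)] = rec
                return -rec.metrics.revenue_total

            res = minimize_scalar(negrev, bounds=(lo, hi), method="bounded",
                                  options={"xatol": (hi - lo) * 1e-3})
            rec = cache[float(res.x)]
        else:
            rec = curve.records[i]
        maxima.append(RevenueMaximum(
            E=rec.E, revenue=rec.metrics.revenue_total,
            revenue_by_species={s: rec.metrics.catch(s).revenue for s in SPECIES},
            species_present=rec.species_present(),
        ))
    modality = {0: "flat", 1: "unimodal", 2: "bimodal"}.get(len(maxima), "multimodal")
    global_max = max(maxima, key=lambda m: m.revenue, default=None)
    beyond = None
    E_star = math.inf
    br = curve.extinction_brackets.get("plaice")
    if br is not None:
        if params is not None:
            i_lo = int(np.searchsorted(E_grid, br[0]))
            E_star = refine_extinction_from_bracket(
                params, curve.omega, "plaice", br,
                warm=curve.records[i_lo].state, **solve_kw,
            )
        else:
            E_star = 0.5 * (br[0] + br[1])
    if global_max is not None:
        beyond = global_max.E > E_star
    return RevenueAnalysis(maxima, modality, global_max, beyond, E_star)
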