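"""Calibration of large-juvenile catchabilities to target discard fractions.

The gear retains large juveniles that are below the landing size; their
caught biomass is discarded.  Historical observations constrain the
discard fraction -- discarded biomass over landed biomass -- rather than
the large-juvenile catchability f_LJ itself, so f_LJ is tuned by scalar
root-finding: find the f_LJ whose *equilibrium* discard fraction matches
the target.  Because the equilibrium stage structure itself depends on
f_LJ, every probe re-solves the equilibrium.

Tuning is done in the absence of resource competition (omega = 0), where
the two species are uncoupled and two independent one-dimensional
root-finds suffice.  The reference effort defaults to E = 1, the effort
at which the adult catchabilities reproduce the assessment-derived
fishing mortalities; it is an explicit argument so the assumption can be
overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .equilibrium import solve_equilibrium
from .params import SPECIES, ModelParams, ParameterError, SystemState

__all__ = ["discard_fraction_at", "tune_catchability", "TuningResult"]


def discard_fraction_at(
    params: ModelParams,
    omega: float = 0.0,
    E: float = 1.0,
    init: SystemState | None = None,
    **solve_kw,
) -> dict[str, float]:
    """Equilibrium discard fraction (discards/landings) per species.

    Solves the equilibrium at the given overlap and effort and returns the
    realized discarded-over-landed biomass fraction for each species.  An
    extinct species has no defined fraction and is reported as NaN.
    """
    rec = solve_equilibrium(params, omega, E, init=init, **solve_kw)
    out = {}
    for s in SPECIES:
        out[s] = math.nan if rec.extinct[s] else rec.metrics.catch(s).discard_ratio
    return out


@dataclass
class TuningResult:
    """Outcome of one catchability calibration."""

    f_LJ: dict[str, float]
    achieved: dict[str, float]
    target: dict[str, float]
    E_ref: float
    omega: float
    iterations: dict[str, int]


def _realized_fraction(params, species, omega, E, warm, solve_kw):
    rec = solve_equilibrium(params, omega, E, init=warm[0], **solve_kw)
    if not rec.extinct[species]:
        warm[0] = rec.state
    if rec.extinct[species]:
        return math.nan
    return rec.metrics.catch(species).discard_ratio


def tune_catchability(
    params: ModelParams,
    omega: float = 0.0,
    E_ref: float = 1.0,
    targets: dict[str, float] | None = None,
    rel_tol: float = 1e-6,
    f_bracket: tuple[float, float] = (1e-9, 1e-3),
    max_expand: int = 10,
    **solve_kw,
) -> TuningResult:
    """Tune per-species large-juvenile catchabilities to target discard fractions.

    For each species, solves ``discard_fraction(f_LJ) = target`` by Brent
    root-finding; the realized fraction is evaluated at the re-solved
    equilibrium, warm-started between probes.  The initial bracket is
    expanded geometrically (up to ``max_expand`` times) if it does not
    straddle the target; failure to bracket raises with diagnostics.
    """
    if targets is None:
        targets = {"plaice": 0.3, "sole": 0.1}
    for s, t in targets.items():
        if not 0.0 < t < 1.0:
            raise ParameterError(f"target discard fraction for {s} must be in (0,1)")
    tuned: dict[str, float] = {}
    achieved: dict[str, float] = {}
    iters: dict[str, int] = {}
    for species, target in targets.items():
        warm = [None]
        count = [0]

        def objective(f_LJ: float) -> float:
            count[0] += 1
            trial = params.with_catchability(species, "LJ", f_LJ)
            frac = _realized_fraction(trial, species, omega, E_ref, warm, solve_kw)
            if math.isnan(frac):
                raise ParameterError(
                    f"{species} does not persist at omega={omega}, E={E_ref}"
                )
            return frac - target

        lo, hi = f_bracket
        g_lo, g_hi = objective(lo), objective(hi)
        n = 0
        while g_lo * g_hi > 0 and n < max_expand:
            if g_lo > 0:   # even the smallest f_LJ overshoots
                lo /= 100.0
                g_lo = objective(lo)
            else:          # largest f_LJ still undershoots
                hi *= 10.0
                g_hi = objective(hi)
            n += 1
        if g_lo * g_hi > 0:
            raise ParameterError(
                f"could not bracket the target discard fraction for {species}: "
                f"f in [{lo:g}, {hi:g}] gives fractions "
                f"[{g_lo + target:g}, {g_hi + target:g}], target {target}"
            )
        f_star = brentq(objective, lo, hi, xtol=1e-16, rtol=8.9e-16)
        # verify the round trip at the tuned value
        frac = objective(f_star) + target
        if abs(frac - target) > rel_tol * target:
            raise ParameterError(
                f"tuning for {species} did not converge: achieved {frac}, "
                f"target {target}"
            )
        tuned[species] = f_star
        achieved[species] = frac
        iters[species] = count[0]
    return TuningResult(
        f_LJ=tuned, achieved=achieved, target=dict(targets),
        E_ref=E_ref, omega=omega, iterations=iters,
    )
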