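"""Flux balance analysis for one species: LP construction, two-stage solve,
and knockout-mutant generation.

The LP is the standard FBA problem

    maximize   v_biomass
    subject to S v = 0          (steady state, one row per metabolite)
               l <= v <= u      (flux bounds, possibly overridden per solve)

with one extension: for every growth-coupled secretion ``(met, rate)`` the
mass-balance row of ``met`` gains ``+rate`` in the biomass column. The row
then reads ``-v_exchange + rate * v_biomass + (transport terms) = 0`` — i.e.
the cell sources ``rate`` mmol of the metabolite per gDW of new biomass and
pushes it out through the exchange reaction, which is exactly the coupled
secretion flux ``v_exchange = rate * mu`` when only the exchange touches the
metabolite. The stored model stoichiometry is never edited.

After the growth maximum ``mu*`` is found, an optional second stage fixes
``v_biomass = mu*`` and minimizes the sum of absolute fluxes. This breaks
ties among alternate optima deterministically — important because the
identity and magnitude of secreted byproducts drive cross-feeding dynamics
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .errors import NumericalError
from .model_io import StoichModel

#: numeric tolerance for feasibility/optimality handed to HiGHS
DEFAULT_TOLERANCE = 1e-9

_HIGHS_OPTIONS = {
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-10,
}

BoundsOverride = Mapping[str, tuple[float, float]]


@dataclass
class FBASolution:
    status: str  # "optimal" | "infeasible"
    growth_rate: float  # 1/h
    fluxes: dict[str, float]  # mmol/gDW/h

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def build_lp(model: StoichModel, overrides: BoundsOverride | None = None):
    """Return (S', lower, upper) for the model's LP.

    ``S'`` is the stoichiometric matrix with coupled-secretion source terms
    injected into the biomass column. ``overrides`` replaces stored bounds
    per reaction id for this solve only.
    """
    met_idx = model.metabolite_index
    rxn_idx = model.reaction_index
    n_m, n_r = len(model.metabolites), len(model.reactions)
    S = np.zeros((n_m, n_r))
    lower = np.empty(n_r)
    upper = np.empty(n_r)
    for j, r in enumerate(model.reactions):
        for met, coef in r.stoichiometry.items():
            S[met_idx[met], j] = coef
        lower[j], upper[j] = r.lower_bound, r.upper_bound

    if overrides:
        for rid, (lb, ub) in overrides.items():
            if rid not in rxn_idx:
                raise KeyError(
                    f"bounds override names unknown reaction {rid!r}"
                )
            if lb > ub:
                raise ValueError(
                    f"override for {rid!r}: lower bound {lb} > upper bound {ub}"
                )
            j = rxn_idx[rid]
            lower[j], upper[j] = lb, ub

    bio = rxn_idx[model.biomass_reaction_id]
    for c in model.coupled_secretions:
        S[met_idx[c.metabolite_id], bio] += c.rate
    return S, lower, upper


def solve_fba(
    model: StoichModel,
    overrides: BoundsOverride | None = None,
    tie_break: str = "flux_min",
    tolerance: float = DEFAULT_TOLERANCE,
) -> FBASolution:
    """Two-stage FBA solve.

    Stage 1 maximizes the biomass flux. Stage 2 (``tie_break="flux_min"``)
    fixes the biomass flux at its optimum and minimizes the total absolute
    flux, selecting a unique, parsimonious flux distribution among alternate
    optima. An infeasible LP (e.g. a knockout that disconnects an enforced
    demand) is reported as ``status="infeasible"`` with zero growth and no
    fluxes, not as an error: biologically it is simply "no growth".
    """
    S, lower, upper = build_lp(model, overrides)
    n_m, n_r = S.shape
    bio = model.reaction_index[model.biomass_reaction_id]

    c = np.zeros(n_r)
    c[bio] = -1.0
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(n_m),
        bounds=list(zip(lower, upper)),
        method="highs",
        options=_HIGHS_OPTIONS,
    )
    if res.status == 2:  # infeasible
        return FBASolution(status="infeasible", growth_rate=0.0, fluxes={})
    if res.status != 0:
        raise NumericalError(
            f"LP solver failed for model {model.species_id!r}: "
            f"status={res.status} ({res.message})"
        )
    mu = float(res.x[bio])
    v = res.x

    if tie_break == "flux_min":
        v = _minimize_total_flux(S, lower, upper, bio, mu)
    elif tie_break != "none":
        raise ValueError(f"unknown tie_break {tie_break!r}")

    fluxes = {r.id: float(v[j]) for j, r in enumerate(model.reactions)}
    mu = float(v[bio])
    if mu == 0.0:
        mu = 0.0  # normalize -0.0
    return FBASolution(status="optimal", growth_rate=mu, fluxes=fluxes)


def _minimize_total_flux(S, lower, upper, bio, mu):
    """Stage 2: min sum |v| subject to S v = 0, bounds, v_bio = mu.

    Linearized with auxiliary variables t_j >= |v_j| (two inequality rows
    per reaction). Never changes the growth rate: v_bio is pinned.
    """
    n_m, n_r = S.shape
    lb = lower.copy()
    ub = upper.copy()
    lb[bio] = ub[bio] = mu

    # variables x = [v, t]
    c = np.concatenate([np.zeros(n_r), np.ones(n_r)])
    A_eq = np.hstack([S, np.zeros((n_m, n_r))])
    I = np.eye(n_r)
    A_ub = np.vstack([np.hstack([I, -I]), np.hstack([-I, -I])])
    b_ub = np.zeros(2 * n_r)
    t_ub = np.maximum(np.abs(lb), np.abs(ub))
    bounds = list(zip(lb, ub)) + list(zip(np.zeros(n_r), t_ub))

    res = linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(n_m),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=bounds,
        method="highs",
        options=_HIGHS_OPTIONS,
    )
    if res.status != 0:
        raise NumericalError(
            f"flux-minimization stage failed: status={res.status} ({res.message})"
        )
    return res.x[:n_r]


def apply_knockout(model: StoichModel, reaction_id: str) -> StoichModel:
    """Return a copy of the model with one reaction's bounds set to (0, 0).

    The original model is left untouched. Exchange reactions are legal
    targets like any other reaction (knocking out O2 exchange forces
    fermentation, for example).
    """
    return model.with_reaction_bounds(reaction_id, 0.0, 0.0)


def enumerate_knockouts(model: StoichModel) -> list[str]:
    """All single-reaction mutant specifications, in model file order."""
    return [r.id for r in model.reactions]
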