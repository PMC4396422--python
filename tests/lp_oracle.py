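"""Independent oracles for FBA solves on small networks.

Two routes that share no code with the package's LP layer:

* ``vertex_maximize``: brute-force enumeration of the vertices of the
  feasible polytope {S v = 0, l <= v <= u}. Every vertex fixes
  n - rank(S) fluxes at a bound; the rest are solved linearly. The LP
  optimum of a bounded LP is attained at a vertex, so the best feasible
  vertex objective is the exact optimum.
* ``toy_e_growth`` / ``toy_s_growth``: closed forms for the toy models'
  growth maxima, read straight off the yield parameters.
"""

import itertools

import numpy as np


def model_matrices(model):
    """Build (S', lower, upper, biomass_col) directly from the containers,
    including the growth-coupled secretion source terms."""
    met_idx = {m.id: i for i, m in enumerate(model.metabolites)}
    n_m, n_r = len(model.metabolites), len(model.reactions)
    S = np.zeros((n_m, n_r))
    lower = np.zeros(n_r)
    upper = np.zeros(n_r)
    bio = None
    for j, r in enumerate(model.reactions):
        for met, coef in r.stoichiometry.items():
            S[met_idx[met], j] = coef
        lower[j], upper[j] = r.lower_bound, r.upper_bound
        if r.id == model.biomass_reaction_id:
            bio = j
    for c in model.coupled_secretions:
        S[met_idx[c.metabolite_id], bio] += c.rate
    return S, lower, upper, bio


def vertex_maximize(S, lower, upper, objective_col, feas_tol=1e-8):
    """Max of x[objective_col] over {S x = 0, l <= x <= u} by vertex enumeration.

    Returns None if no feasible vertex exists (infeasible LP).
    """
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S, tol=1e-9)
    free = n - rank
    best = None
    for fixed_idx in itertools.combinations(range(n), free):
        rem = [j for j in range(n) if j not in fixed_idx]
        A = S[:, rem]
        for vals in itertools.product(*[(lower[j], upper[j]) for j in fixed_idx]):
            b = -S[:, list(fixed_idx)] @ np.asarray(vals)
            sol, _, rk, _ = np.linalg.lstsq(A, b, rcond=None)
            if rk < len(rem):
                continue
            x = np.zeros(n)
            x[list(fixed_idx)] = vals
            x[rem] = sol
            if np.max(np.abs(S @ x)) > feas_tol:
                continue
            if np.any(x < lower - feas_tol) or np.any(x > upper + feas_tol):
                continue
            if best is None or x[objective_col] > best:
                best = float(x[objective_col])
    return best


def oracle_growth(model, overrides=None):
    """Maximum growth rate of a small model by vertex enumeration.

    ``overrides`` replaces bounds by reaction id, mirroring the solver API.
    """
    S, lower, upper, bio = model_matrices(model)
    if overrides:
        rxn_idx = {r.id: j for j, r in enumerate(model.reactions)}
        for rid, (lb, ub) in overrides.items():
            lower[rxn_idx[rid]] = lb
            upper[rxn_idx[rid]] = ub
    mu = vertex_maximize(S, lower, upper, bio)
    return 0.0 if mu is None else max(0.0, mu)


def toy_e_growth(params, lactose_cap, o2_cap, met_cap):
    """Closed-form growth maximum of the toy auxotroph under uptake caps.

    Aerobic catabolism is preferred up to the O2 cap, fermentation takes the
    remaining lactose, maintenance ATP is paid off the top, and methionine
    can cap growth independently. Returns 0 if maintenance cannot be met.
    """
    a = min(lactose_cap, o2_cap / params.o2_per_lactose)
    f = lactose_cap - a
    atp = params.atp_per_lactose_aerobic * a + params.atp_per_lactose_fermentative * f
    if atp < params.maintenance_atp:
        return 0.0
    mu = (atp - params.maintenance_atp) / params.atp_per_biomass
    return min(mu, met_cap / params.met_per_biomass)


def toy_s_growth(params, acetate_cap, o2_cap):
    """Closed-form growth maximum of the toy secretor under uptake caps."""
    r = min(acetate_cap, o2_cap / params.o2_per_acetate)
    return params.atp_per_acetate * r / params.atp_per_biomass
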