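"""Dynamic FBA for a well-mixed co-culture in a single box.

Each timestep: (1) Michaelis-Menten uptake bounds are computed for every
species from the *same* snapshot of the shared metabolite pools; (2) each
species' FBA is solved independently; (3) if the total requested drawdown
of a finite pool exceeds what is there, per-species uptake allowances for
that pool are rescaled proportionally and the step is re-solved; (4)
biomass is updated by forward Euler, B <- B * (1 + (mu - d) * dt), with an
unconditional death rate d; (5) pools are updated from the exchange fluxes,
pools <- pools + sum_s v_ex,s * B_s * dt (positive exchange flux secretes).

The default scheme is simultaneous (all species see the same environment
snapshot and pool updates are accumulated in sorted species order), so the
trajectory is independent of the order species are listed in. A sequential
randomized update order — the scheme some community-dFBA platforms use —
is available via ``update_order="random"`` for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import OverdrawError
from .fba_core import FBASolution, solve_fba
from .model_io import StoichModel


@dataclass
class Environment:
    """Shared extracellular pools in a fixed, well-mixed volume.

    ``pools`` holds amounts in mmol. Metabolites in ``unlimited`` behave as
    if held at saturating concentration: uptake is never limited by them and
    their pool entries are never decremented.
    """

    volume: float  # liters
    pools: dict[str, float]
    unlimited: set[str] = field(default_factory=set)

    def copy(self) -> "Environment":
        return Environment(self.volume, dict(self.pools), set(self.unlimited))

    def to_dict(self) -> dict:
        return {
            "volume_l": self.volume,
            "pools": {k: float(v) for k, v in sorted(self.pools.items())},
            "unlimited": sorted(self.unlimited),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Environment":
        return cls(
            volume=float(d["volume_l"]),
            pools={k: float(v) for k, v in d["pools"].items()},
            unlimited=set(d.get("unlimited", [])),
        )

    def write_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def read_json(cls, path) -> "Environment":
        import json

        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SimulationConfig:
    dt: float = 0.1  # h
    duration: float = 10.0  # h
    km_um: float = 10.0  # Michaelis constant, micromolar
    vmax: float = 10.0  # mmol/gDW/h
    death_rate: float = 0.01  # 1/h
    box_edge_mm: float = 0.5
    rescale_iterations: int = 10
    tolerance: float = 1e-12  # pools with |amount| below this are clamped to 0
    tie_break: str = "flux_min"
    update_order: str = "simultaneous"  # or "random"
    seed: int | None = None

    def n_steps(self) -> int:
        n = self.duration / self.dt
        if self.dt <= 0 or self.duration <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration ({self.duration} h) must be a positive multiple of dt ({self.dt} h)"
            )
        return int(round(n))


@dataclass
class SpeciesState:
    model: StoichModel
    biomass: float  # gDW


@dataclass
class Trajectory:
    """Time series of a community simulation.

    ``times``, per-species ``biomass`` and per-metabolite ``pools`` have
    one entry per recorded time point (n_steps + 1); ``growth_rates`` and
    ``exchange_fluxes`` have one entry per step (the value applied over the
    interval starting at that time).
    """

    times: np.ndarray  # h
    biomass: dict[str, np.ndarray]  # gDW
    pools: dict[str, np.ndarray]  # mmol
    growth_rates: dict[str, np.ndarray]  # 1/h, per step
    exchange_fluxes: list[dict[str, dict[str, float]]]  # per step: species -> rxn -> flux

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.biomass)

    def final_biomass(self, species_id: str) -> float:
        return float(self.biomass[species_id][-1])

    def initial_biomass(self, species_id: str) -> float:
        return float(self.biomass[species_id][0])

    def biomass_gain(self, species_id: str) -> float:
        return self.final_biomass(species_id) - self.initial_biomass(species_id)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_h, species_id, biomass_g, plus one column per pool."""
        rows = []
        for sid in self.species_ids:
            for k, t in enumerate(self.times):
                row = {"time_h": float(t), "species_id": sid,
                       "biomass_g": float(self.biomass[sid][k])}
                for met in sorted(self.pools):
                    row[f"pool_{met}_mmol"] = float(self.pools[met][k])
                rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path, provenance: dict | None = None) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            for key, value in (provenance or {}).items():
                fh.write(f"# {key}: {value}\n")
            df.to_csv(fh, index=False, float_format="%.12g")


def uptake_bound(
    pool_amount: float,
    env: Environment,
    config: SimulationConfig,
    metabolite_id: str | None = None,
) -> float:
    """Maximum uptake flux (mmol/gDW/h) allowed by Michaelis-Menten kinetics.

    Returns ``Vmax * c / (Km + c)`` with concentration ``c = pool / volume``
    in mmol/L and Km converted from micromolar. Unlimited metabolites are at
    saturation and return Vmax.
    """
    if metabolite_id is not None and metabolite_id in env.unlimited:
        return config.vmax
    if pool_amount <= 0:
        return 0.0
    c = pool_amount / env.volume  # mmol/L
    km = config.km_um * 1e-3  # uM -> mmol/L
    return config.vmax * c / (km + c)


def _exchange_map(model: StoichModel) -> dict[str, str]:
    """metabolite id -> exchange reaction id."""
    return {
        r.exchanged_metabolite: r.id
        for r in model.reactions
        if r.is_exchange and r.exchanged_metabolite is not None
    }


def _env_overrides(model: StoichModel, env: Environment, config: SimulationConfig):
    overrides = {}
    for met, rid in _exchange_map(model).items():
        r = model.reaction(rid)
        cap = uptake_bound(env.pools.get(met, 0.0), env, config, met)
        overrides[rid] = (max(r.lower_bound, -cap), r.upper_bound)
    return overrides


def _solve_all(states, overrides_by_sid, config) -> dict[str, FBASolution]:
    return {
        st.model.species_id: solve_fba(
            st.model, overrides_by_sid[st.model.species_id], tie_break=config.tie_break
        )
        for st in states
    }


def step_community(
    states: Sequence[SpeciesState],
    env: Environment,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
):
    """Advance the community by one timestep.

    Returns ``(new_states, new_env, solutions)`` where ``solutions`` maps
    species id to the :class:`FBASolution` used for the step. Inputs are not
    modified.
    """
    if config.update_order == "random":
        if rng is None:
            rng = np.random.default_rng(config.seed)
        return _step_sequential(states, env, config, rng)
    return _step_simultaneous(states, env, config)


def _requested_drawdown(states, solutions, ex_maps, config):
    """Per finite pool: total uptake requested this step, in mmol (sorted-id sums)."""
    requested: dict[str, float] = {}
    shares: dict[str, dict[str, float]] = {}  # met -> sid -> uptake flux
    for st in sorted(states, key=lambda s: s.model.species_id):
        sid = st.model.species_id
        sol = solutions[sid]
        for met, rid in ex_maps[sid].items():
            flux = sol.fluxes.get(rid, 0.0)
            if flux < 0:
                requested[met] = requested.get(met, 0.0) + (-flux) * st.biomass * config.dt
                shares.setdefault(met, {})[sid] = -flux
    return requested, shares


def _step_simultaneous(states, env, config):
    ex_maps = {st.model.species_id: _exchange_map(st.model) for st in states}
    overrides = {st.model.species_id: _env_overrides(st.model, env, config) for st in states}
    solutions = _solve_all(states, overrides, config)

    # proportional rescale of uptake allowances for overdrawn finite pools
    for _ in range(config.rescale_iterations):
        requested, shares = _requested_drawdown(states, solutions, ex_maps, config)
        overdrawn = [
            met
            for met, req in requested.items()
            if met not in env.unlimited
            and req > env.pools.get(met, 0.0) + max(1e-15, 1e-12 * req)
        ]
        if not overdrawn:
            break
        for met in overdrawn:
            ratio = env.pools.get(met, 0.0) / requested[met]
            for st in states:
                sid = st.model.species_id
                if sid in shares.get(met, {}):
                    rid = ex_maps[sid][met]
                    lb, ub = overrides[sid][rid]
                    overrides[sid][rid] = (-shares[met][sid] * ratio, ub)
        solutions = _solve_all(states, overrides, config)
    else:
        requested, _ = _requested_drawdown(states, solutions, ex_maps, config)
        still = [
            met
            for met, req in requested.items()
            if met not in env.unlimited
            and req > env.pools.get(met, 0.0) * (1 + 1e-9) + 1e-15
        ]
        if still:
            raise OverdrawError(
                f"pools {still} remain overdrawn after "
                f"{config.rescale_iterations} rescale iterations"
            )

    new_env = env.copy()
    # pool updates accumulated in sorted species order for order invariance
    for st in sorted(states, key=lambda s: s.model.species_id):
        sid = st.model.species_id
        sol = solutions[sid]
        for met, rid in ex_maps[sid].items():
            if met in env.unlimited:
                continue
            flux = sol.fluxes.get(rid, 0.0)
            if flux != 0.0:
                new_env.pools[met] = new_env.pools.get(met, 0.0) + flux * st.biomass * config.dt
    _clamp_pools(new_env, config)

    new_states = [
        replace(
            st,
            biomass=max(
                0.0,
                st.biomass
                * (1.0 + (solutions[st.model.species_id].growth_rate - config.death_rate) * config.dt),
            ),
        )
        for st in states
    ]
    return new_states, new_env, solutions


def _step_sequential(states, env, config, rng):
    """Randomized sequential update: each species sees the pools left by the
    species before it in a shuffled order. Provided for comparison with the
    default simultaneous scheme; not order invariant by construction."""
    order = list(range(len(states)))
    rng.shuffle(order)
    work_env = env.copy()
    solutions: dict[str, FBASolution] = {}
    new_states: list[SpeciesState | None] = [None] * len(states)
    for i in order:
        st = states[i]
        sub_states, work_env, sub_sol = _step_simultaneous([st], work_env, config)
        new_states[i] = sub_states[0]
        solutions[st.model.species_id] = sub_sol[st.model.species_id]
    return new_states, work_env, solutions


def _clamp_pools(env: Environment, config: SimulationConfig) -> None:
    for met, amount in env.pools.items():
        if met in env.unlimited:
            continue
        if config.tolerance > 0 and abs(amount) < config.tolerance:
            env.pools[met] = 0.0
        elif amount < 0:
            if amount > -1e-9:
                env.pools[met] = 0.0
            else:
                raise OverdrawError(f"pool {met!r} went negative: {amount}")


def simulate_community(
    models: Sequence[StoichModel] | StoichModel,
    env: Environment,
    config: SimulationConfig,
    initial_biomass: float | dict[str, float] = 3e-7,
) -> Trajectory:
    """Run the dFBA loop for ``duration / dt`` steps and record everything.

    ``models`` is one or two species; ``initial_biomass`` (gDW) may be a
    scalar applied to all species or a mapping by species id. The final
    biomasses of the returned trajectory are the (E, S) outcomes a knockout
    screen records.
    """
    if isinstance(models, StoichModel):
        models = [models]
    sids = [m.species_id for m in models]
    if len(set(sids)) != len(sids):
        raise ValueError(f"species ids must be unique, got {sids}")

    def b0(sid: str) -> float:
        if isinstance(initial_biomass, dict):
            return float(initial_biomass[sid])
        return float(initial_biomass)

    n = config.n_steps()
    states = [SpeciesState(model=m, biomass=b0(m.species_id)) for m in models]
    env = env.copy()
    # track every pool any species can exchange, plus whatever the env provides
    tracked = set(env.pools)
    for m in models:
        tracked |= set(_exchange_map(m))
    for met in tracked:
        env.pools.setdefault(met, 0.0)

    times = np.arange(n + 1) * config.dt
    biomass = {sid: np.zeros(n + 1) for sid in sids}
    pools = {met: np.zeros(n + 1) for met in sorted(tracked)}
    growth = {sid: np.zeros(n) for sid in sids}
    fluxes: list[dict[str, dict[str, float]]] = []

    rng = np.random.default_rng(config.seed) if config.update_order == "random" else None

    for sid, st in zip(sids, states):
        biomass[sid][0] = st.biomass
    for met in pools:
        pools[met][0] = env.pools[met]

    for k in range(n):
        try:
            states, env, solutions = step_community(states, env, config, rng=rng)
        except OverdrawError as exc:
            raise OverdrawError(f"step {k} (t={k * config.dt:g} h): {exc}") from exc
        step_fluxes: dict[str, dict[str, float]] = {}
        for st in states:
            sid = st.model.species_id
            biomass[sid][k + 1] = st.biomass
            growth[sid][k] = solutions[sid].growth_rate
            step_fluxes[sid] = {
                rid: solutions[sid].fluxes.get(rid, 0.0)
                for rid in _exchange_map(st.model).values()
            }
        for met in pools:
            pools[met][k + 1] = env.pools[met]
        fluxes.append(step_fluxes)

    return Trajectory(
        times=times,
        biomass=biomass,
        pools=pools,
        growth_rates=growth,
        exchange_fluxes=fluxes,
    )
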