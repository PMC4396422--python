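"""The knockout screen: every single-reaction mutant of a focal species,
paired with an unperturbed partner, simulated under each growth condition.

Essentiality follows the empirical convention: a reaction is essential in a
condition if the mutant's biomass gain over the simulation horizon is below
2% of the unperturbed organism's gain in that condition. Monoculture
essentiality is assessed with the focal species alone in the supplemented
(competition) medium, which contains every nutrient the pair can exchange.

Each mutant is evaluated independently against precomputed unperturbed
trajectories — no shared mutable state — so evaluations may be run
concurrently; the serial driver here simply loops.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .community_dfba import Environment, SimulationConfig, Trajectory, simulate_community
from .errors import ExtinctCommunityError, ModelValidationError
from .fba_core import apply_knockout, enumerate_knockouts
from .model_io import StoichModel, validate_model
from .robustness_metrics import ecd, normalized_bm, normalized_percent_e

PAIR_CONDITIONS = ("cooperation", "competition")


@dataclass
class ScreenConfig:
    focal_species: str = "E"
    conditions: tuple[str, ...] = ("cooperation", "competition")
    essentiality_threshold: float = 0.02
    substantive_threshold: float = 0.01
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    initial_biomass: float = 3e-7  # gDW per species
    e_species_id: str = "E"  # which species the E of the metrics refers to

    def __post_init__(self):
        for name in ("essentiality_threshold", "substantive_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        for c in self.conditions:
            if c not in ("cooperation", "competition", "monoculture"):
                raise ValueError(f"unknown condition {c!r}")


@dataclass
class KnockoutRecord:
    reaction_id: str
    condition: str
    E_final: float
    S_final: float
    ECD: float
    pctE_norm: float  # NaN if the community went extinct
    BM_norm: float
    essential_monoculture: bool
    essential_cooperation: bool | None
    essential_competition: bool | None


@dataclass
class ScreenResult:
    unperturbed: dict[str, tuple[float, float]]  # condition -> (E_final, S_final)
    records: list[KnockoutRecord]
    provenance: dict


def call_essential(
    mutant_traj: Trajectory,
    unperturbed_traj: Trajectory,
    threshold: float,
    species: str,
) -> bool:
    """Essentiality call from two trajectories of the same condition/horizon.

    Essential iff the mutant's biomass gain (final - initial) is below
    ``threshold`` times the unperturbed gain; if the unperturbed organism
    itself did not gain biomass, essential iff the mutant also failed to.
    """
    if len(mutant_traj.times) != len(unperturbed_traj.times) or not np.allclose(
        mutant_traj.times, unperturbed_traj.times
    ):
        raise ValueError("trajectories cover different horizons")
    gain_mut = mutant_traj.biomass_gain(species)
    gain_ref = unperturbed_traj.biomass_gain(species)
    if gain_ref <= 0:
        return gain_mut <= 0
    return gain_mut / gain_ref < threshold


def _finals(traj: Trajectory, e_id: str, other_id: str | None) -> tuple[float, float]:
    E = traj.final_biomass(e_id) if e_id in traj.biomass else 0.0
    S = traj.final_biomass(other_id) if other_id and other_id in traj.biomass else 0.0
    return E, S


def _metrics(E, S, Eu, Su):
    try:
        pctE = normalized_percent_e(E, S, Eu, Su)
    except ExtinctCommunityError:
        pctE = math.nan
    return ecd(E, S, Eu, Su), pctE, normalized_bm(E, S, Eu, Su)


def run_screen(
    focal: StoichModel,
    partner: StoichModel,
    config: ScreenConfig,
    env_factory: Callable[[str], Environment] | None = None,
    mutant_order: Sequence[str] | None = None,
) -> ScreenResult:
    """Simulate every single-reaction knockout of ``focal`` in every condition.

    The unperturbed pair is simulated once per condition, the unperturbed
    focal monoculture once (in the supplemented medium), then each mutant is
    simulated against the unperturbed partner in each pair condition and
    alone for the monoculture essentiality call. Deterministic for a given
    config; ``mutant_order`` changes only the evaluation order, never the
    result (records come back in model file order).
    """
    for m in (focal, partner):
        violations = validate_model(m)
        if violations:
            raise ModelValidationError(violations)
    if env_factory is None:
        from .synthetic_models import make_environment

        env_factory = make_environment

    sim = config.simulation
    b0 = config.initial_biomass
    e_id = config.e_species_id if config.e_species_id in (
        focal.species_id,
        partner.species_id,
    ) else focal.species_id
    other_of = {
        focal.species_id: partner.species_id,
        partner.species_id: focal.species_id,
    }

    pair_conditions = [c for c in config.conditions if c in PAIR_CONDITIONS]

    unpert_traj: dict[str, Trajectory] = {}
    for condition in pair_conditions:
        unpert_traj[condition] = simulate_community(
            [focal, partner], env_factory(condition), sim, initial_biomass=b0
        )
    mono_ref = simulate_community(
        [focal], env_factory("monoculture"), sim, initial_biomass=b0
    )

    unperturbed: dict[str, tuple[float, float]] = {}
    for condition in pair_conditions:
        unperturbed[condition] = _finals(unpert_traj[condition], e_id, other_of[e_id])
    if "monoculture" in config.conditions:
        unperturbed["monoculture"] = _finals(mono_ref, e_id, None)

    order = list(mutant_order) if mutant_order is not None else enumerate_knockouts(focal)
    known = set(enumerate_knockouts(focal))
    unknown = [r for r in order if r not in known]
    if unknown or len(set(order)) != len(known):
        raise KeyError(f"mutant_order must be a permutation of the reactions; bad: {unknown}")

    by_reaction: dict[str, dict] = {}
    for rid in order:
        mutant = apply_knockout(focal, rid)
        entry: dict = {"trajs": {}, "flags": {}}
        try:
            mono_traj = simulate_community(
                [mutant], env_factory("monoculture"), sim, initial_biomass=b0
            )
            entry["flags"]["monoculture"] = call_essential(
                mono_traj, mono_ref, config.essentiality_threshold, focal.species_id
            )
            if "monoculture" in config.conditions:
                entry["trajs"]["monoculture"] = mono_traj
            for condition in pair_conditions:
                traj = simulate_community(
                    [mutant, partner], env_factory(condition), sim, initial_biomass=b0
                )
                entry["trajs"][condition] = traj
                entry["flags"][condition] = call_essential(
                    traj, unpert_traj[condition], config.essentiality_threshold,
                    focal.species_id,
                )
        except Exception as exc:
            raise type(exc)(
                f"mutant {rid!r}: {exc}"
            ) from exc
        by_reaction[rid] = entry

    records: list[KnockoutRecord] = []
    for rid in enumerate_knockouts(focal):  # model file order, independent of eval order
        entry = by_reaction[rid]
        flags = entry["flags"]
        for condition in config.conditions:
            traj = entry["trajs"][condition]
            partner_id = other_of[e_id] if condition in PAIR_CONDITIONS else None
            E, S = _finals(traj, e_id, partner_id)
            Eu, Su = unperturbed[condition]
            ECD, pctE, BM = _metrics(E, S, Eu, Su)
            records.append(
                KnockoutRecord(
                    reaction_id=rid,
                    condition=condition,
                    E_final=E,
                    S_final=S,
                    ECD=ECD,
                    pctE_norm=pctE,
                    BM_norm=BM,
                    essential_monoculture=flags["monoculture"],
                    essential_cooperation=flags.get("cooperation"),
                    essential_competition=flags.get("competition"),
                )
            )

    provenance = {
        "focal_species": focal.species_id,
        "partner_species": partner.species_id,
        "focal_checksum": focal.checksum(),
        "partner_checksum": partner.checksum(),
        "conditions": ",".join(config.conditions),
        "essentiality_threshold": config.essentiality_threshold,
        "substantive_threshold": config.substantive_threshold,
        "initial_biomass_g": config.initial_biomass,
        "dt_h": sim.dt,
        "duration_h": sim.duration,
        "km_um": sim.km_um,
        "vmax_mmol_per_g_h": sim.vmax,
        "death_rate_per_h": sim.death_rate,
        "tie_break": sim.tie_break,
        "update_order": sim.update_order,
    }
    return ScreenResult(unperturbed=unperturbed, records=records, provenance=provenance)


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

_COLUMNS = [
    "reaction_id",
    "condition",
    "E_final",
    "S_final",
    "ECD",
    "pctE_norm",
    "BM_norm",
    "essential_monoculture",
    "essential_cooperation",
    "essential_competition",
]


def write_screen_tsv(result: ScreenResult, path) -> None:
    """One row per KnockoutRecord, preceded by a provenance comment block."""
    df = pd.DataFrame([{c: getattr(r, c) for c in _COLUMNS} for r in result.records])
    with open(path, "w") as fh:
        for key, value in result.provenance.items():
            fh.write(f"# {key}: {value}\n")
        for condition, (E, S) in result.unperturbed.items():
            fh.write(f"# unperturbed_{condition}: {E:.12g}\t{S:.12g}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_screen_tsv(path) -> ScreenResult:
    provenance: dict = {}
    unperturbed: dict[str, tuple[float, float]] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                key, _, value = line[2:].rstrip("\n").partition(": ")
                if key.startswith("unperturbed_"):
                    E, S = value.split("\t")
                    unperturbed[key[len("unperturbed_"):]] = (float(E), float(S))
                else:
                    provenance[key] = value
            else:
                body.write(line)
    body.seek(0)
    df = pd.read_csv(body, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        for flag in ("essential_cooperation", "essential_competition"):
            if pd.isna(d[flag]):
                d[flag] = None
            else:
                d[flag] = bool(d[flag])
        d["essential_monoculture"] = bool(d["essential_monoculture"])
        records.append(KnockoutRecord(**d))
    return ScreenResult(unperturbed=unperturbed, records=records, provenance=provenance)
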