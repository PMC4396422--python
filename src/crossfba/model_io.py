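"""Stoichiometric model containers and I/O.

A :class:`StoichModel` is the in-memory form of one species' metabolic
network: metabolites split into extracellular and cytosolic compartments,
reactions with flux bounds, a biomass pseudo-reaction whose flux is the
specific growth rate (1/h), and optional growth-coupled secretions
(mmol secreted per gDW of new biomass).

The on-disk canonical format is a small JSON dialect (read *and* write).
SBML Level 3 with FBC flux bounds is supported for import only, via
cobrapy/libsbml; its bounds and boundary reactions are mapped onto the same
containers and sign conventions.

Sign convention for exchange reactions: the single extracellular metabolite
carries coefficient -1, so positive flux secretes into the environment and
negative flux is uptake.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from .errors import FormatError, ModelValidationError

COMPARTMENTS = ("extracellular", "cytosol")

#: default magnitude for flux bounds absent from a model file
DEFAULT_BOUND = 1000.0


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"


@dataclass(frozen=True)
class Reaction:
    """One reaction: stoichiometry (negative coefficient = consumed) and bounds.

    Units: mmol/gDW for coefficients, mmol/gDW/h for bounds (1/h for the
    biomass reaction).
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    is_exchange: bool = False
    exchanged_metabolite: str | None = None


@dataclass(frozen=True)
class CoupledSecretion:
    """A secretion flux tied to growth: v_exchange = rate * mu.

    ``rate`` is mmol secreted per gDW of new biomass.
    """

    metabolite_id: str
    rate: float


@dataclass
class StoichModel:
    species_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    coupled_secretions: list[CoupledSecretion] = field(default_factory=list)

    # ---- lookups -------------------------------------------------------

    @property
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def reaction(self, reaction_id: str) -> Reaction:
        try:
            return self.reactions[self.reaction_index[reaction_id]]
        except KeyError:
            raise KeyError(
                f"model {self.species_id!r} has no reaction {reaction_id!r}"
            ) from None

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchange_for(self, metabolite_id: str) -> Reaction | None:
        for r in self.reactions:
            if r.is_exchange and r.exchanged_metabolite == metabolite_id:
                return r
        return None

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "metabolites": [
                {"id": m.id, "name": m.name, "compartment": m.compartment}
                for m in self.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": {k: float(v) for k, v in r.stoichiometry.items()},
                    "lower_bound": float(r.lower_bound),
                    "upper_bound": float(r.upper_bound),
                    "is_exchange": bool(r.is_exchange),
                    **(
                        {"exchanged_metabolite": r.exchanged_metabolite}
                        if r.exchanged_metabolite is not None
                        else {}
                    ),
                }
                for r in self.reactions
            ],
            "biomass_reaction_id": self.biomass_reaction_id,
            "coupled_secretions": [
                {"metabolite_id": c.metabolite_id, "rate": float(c.rate)}
                for c in self.coupled_secretions
            ],
        }

    def checksum(self) -> str:
        """SHA-256 of the canonical JSON serialization (provenance anchor)."""
        payload = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(payload.encode()).hexdigest()

    def with_reaction_bounds(self, reaction_id: str, lower: float, upper: float) -> "StoichModel":
        """Copy of the model with one reaction's bounds replaced."""
        idx = self.reaction_index
        if reaction_id not in idx:
            raise KeyError(
                f"model {self.species_id!r} has no reaction {reaction_id!r}"
            )
        reactions = list(self.reactions)
        reactions[idx[reaction_id]] = replace(
            reactions[idx[reaction_id]], lower_bound=lower, upper_bound=upper
        )
        return StoichModel(
            species_id=self.species_id,
            metabolites=list(self.metabolites),
            reactions=reactions,
            biomass_reaction_id=self.biomass_reaction_id,
            coupled_secretions=list(self.coupled_secretions),
        )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_model(model: StoichModel) -> list[str]:
    """Check every structural invariant; return a (possibly empty) list of violations.

    Violations are returned, never raised, so callers can report all of them
    at once.
    """
    violations: list[str] = []
    met_ids = [m.id for m in model.metabolites]
    if len(set(met_ids)) != len(met_ids):
        dupes = sorted({m for m in met_ids if met_ids.count(m) > 1})
        violations.append(f"duplicate metabolite ids: {dupes}")
    rxn_ids = [r.id for r in model.reactions]
    if len(set(rxn_ids)) != len(rxn_ids):
        dupes = sorted({r for r in rxn_ids if rxn_ids.count(r) > 1})
        violations.append(f"duplicate reaction ids: {dupes}")
    if not model.reactions:
        violations.append("model has no reactions")

    met_set = set(met_ids)
    compartment = {m.id: m.compartment for m in model.metabolites}
    for m in model.metabolites:
        if m.compartment not in COMPARTMENTS:
            violations.append(
                f"metabolite {m.id!r}: unknown compartment {m.compartment!r}"
            )

    exchanged: set[str] = set()
    for r in model.reactions:
        for met in r.stoichiometry:
            if met not in met_set:
                violations.append(
                    f"reaction {r.id!r} references unknown metabolite {met!r}"
                )
        if r.lower_bound > r.upper_bound:
            violations.append(
                f"reaction {r.id!r}: lower_bound {r.lower_bound} > upper_bound {r.upper_bound}"
            )
        if r.is_exchange:
            if len(r.stoichiometry) != 1:
                violations.append(
                    f"exchange reaction {r.id!r} must touch exactly one metabolite"
                )
            else:
                (met, coef), = r.stoichiometry.items()
                if coef != -1:
                    violations.append(
                        f"exchange reaction {r.id!r}: coefficient of {met!r} is {coef}, must be -1"
                    )
                if compartment.get(met) != "extracellular":
                    violations.append(
                        f"exchange reaction {r.id!r}: metabolite {met!r} is not extracellular"
                    )
                if r.exchanged_metabolite not in (None, met):
                    violations.append(
                        f"exchange reaction {r.id!r}: exchanged_metabolite "
                        f"{r.exchanged_metabolite!r} does not match {met!r}"
                    )
                exchanged.add(met)

    extracellular = {m.id for m in model.metabolites if m.compartment == "extracellular"}
    for met in sorted(extracellular - exchanged):
        violations.append(
            f"extracellular metabolite {met!r} has no exchange reaction"
        )

    if model.biomass_reaction_id not in set(rxn_ids):
        violations.append(
            f"biomass reaction {model.biomass_reaction_id!r} not in model"
        )

    for c in model.coupled_secretions:
        if c.rate < 0:
            violations.append(
                f"coupled secretion of {c.metabolite_id!r}: negative rate {c.rate}"
            )
        if c.metabolite_id not in exchanged:
            violations.append(
                f"coupled secretion metabolite {c.metabolite_id!r} has no exchange reaction"
            )
    return violations


def _checked(model: StoichModel) -> StoichModel:
    violations = validate_model(model)
    if violations:
        raise ModelValidationError(violations)
    return model


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _reaction_from_dict(d: dict) -> Reaction:
    reversible = bool(d.get("reversible", True))
    lb = d.get("lower_bound", -DEFAULT_BOUND if reversible else 0.0)
    ub = d.get("upper_bound", DEFAULT_BOUND)
    is_exchange = bool(d.get("is_exchange", False))
    exchanged = d.get("exchanged_metabolite")
    if is_exchange and exchanged is None and len(d.get("stoichiometry", {})) == 1:
        (exchanged,) = d["stoichiometry"]
    return Reaction(
        id=d["id"],
        stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
        lower_bound=float(lb),
        upper_bound=float(ub),
        is_exchange=is_exchange,
        exchanged_metabolite=exchanged,
    )


def _model_from_dict(d: dict) -> StoichModel:
    try:
        return StoichModel(
            species_id=d["species_id"],
            metabolites=[
                Metabolite(
                    id=m["id"],
                    name=m.get("name", ""),
                    compartment=m.get("compartment", "cytosol"),
                )
                for m in d["metabolites"]
            ],
            reactions=[_reaction_from_dict(r) for r in d["reactions"]],
            biomass_reaction_id=d["biomass_reaction_id"],
            coupled_secretions=[
                CoupledSecretion(c["metabolite_id"], float(c["rate"]))
                for c in d.get("coupled_secretions", [])
            ],
        )
    except KeyError as exc:
        raise FormatError(f"JSON model missing required key: {exc}") from exc


def _read_json(path: Path) -> StoichModel:
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"{path}: top-level JSON value must be an object")
    return _model_from_dict(data)


# ---------------------------------------------------------------------------
# SBML import (via cobrapy / libsbml)
# ---------------------------------------------------------------------------

def _read_sbml(path: Path) -> StoichModel:
    import cobra

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml reports its own line/element context
        raise FormatError(f"{path}: SBML parse failure: {exc}") from exc

    boundary_ids = {r.id for r in cm.boundary}
    extracellular = {
        m.id for r in cm.boundary for m in r.metabolites
    }

    metabolites = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment="extracellular" if m.id in extracellular else "cytosol",
        )
        for m in cm.metabolites
    ]

    reactions: list[Reaction] = []
    for r in cm.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        lb, ub = float(r.lower_bound), float(r.upper_bound)
        is_ex = r.id in boundary_ids and len(stoich) == 1
        exchanged = None
        if is_ex:
            (met, coef), = stoich.items()
            if coef > 0:  # normalize to the secretion-positive convention
                stoich = {met: -coef}
                lb, ub = -ub, -lb
            if abs(stoich[met]) != 1:
                stoich = {met: -1.0}
            exchanged = met
        reactions.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                is_exchange=is_ex,
                exchanged_metabolite=exchanged,
            )
        )

    biomass = None
    for r in cm.reactions:
        if r.objective_coefficient:
            biomass = r.id
            break
    if biomass is None:
        raise ModelValidationError(
            [f"{path}: SBML model declares no objective (biomass) reaction"]
        )

    return StoichModel(
        species_id=cm.id or path.stem,
        metabolites=metabolites,
        reactions=reactions,
        biomass_reaction_id=biomass,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_model(
    path,
    format: str = "auto",
    blocked_reactions: Sequence[str] = (),
    coupled_secretions: Sequence[CoupledSecretion] = (),
) -> StoichModel:
    """Read a stoichiometric model and return it validated.

    Parameters
    ----------
    path
        Model file (JSON dialect or SBML Level 3 + FBC).
    format
        ``"json"``, ``"sbml"`` or ``"auto"`` (by file extension:
        ``.xml``/``.sbml`` is SBML, anything else JSON).
    blocked_reactions
        Reaction ids whose bounds are zeroed at load time. This is how
        load-time network edits such as a *metB* block are expressed —
        the same mechanism as a knockout.
    coupled_secretions
        Extra growth-coupled secretions to attach (e.g. methionine at
        0.5 mmol/gDW of new biomass for a secretor strain); SBML has no
        native encoding for these.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "sbml":
        model = _read_sbml(path)
    elif format == "json":
        model = _read_json(path)
    else:
        raise ValueError(f"unknown model format {format!r}")

    for rid in blocked_reactions:
        model = model.with_reaction_bounds(rid, 0.0, 0.0)
    if coupled_secretions:
        model.coupled_secretions = list(model.coupled_secretions) + list(coupled_secretions)
    return _checked(model)


def write_model(model: StoichModel, path, format: str = "json") -> None:
    """Write a validated model to the JSON dialect.

    The written file round-trips: ``read_model(path)`` returns a model equal
    field-by-field to ``model``.
    """
    if format != "json":
        raise ValueError("only the JSON dialect is writable")
    _checked(model)
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=False)
        fh.write("\n")
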