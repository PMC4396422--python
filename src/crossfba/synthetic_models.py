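"""Hand-solvable toy models of the cross-feeding pair, and the study environments.

The pair emulates the engineered consortium the analysis assumes:

* **E-like** (``toy_E``): a lactose consumer that is a methionine auxotroph
  (its biomass reaction consumes methionine it cannot synthesize — the
  *metB*-block analogue), catabolizes lactose either aerobically
  (high ATP yield) or fermentatively (low ATP yield), and excretes acetate
  as its reduced-carbon byproduct either way. A non-growth ATP maintenance
  demand forces carbon metabolism even at zero growth; this is what lets a
  methionine-starved cell trickle acetate to its partner and jump-start the
  mutualism, exactly as genome-scale models do through their maintenance
  reaction.
* **S-like** (``toy_S``): an acetate respirer whose methionine secretion is
  stoichiometrically coupled to growth (0.5 mmol per gDW of new biomass).

All catabolic yields are small integers so every FBA optimum can be
enumerated by hand. With the defaults, biomass per mmol O2 is higher for
the E-like model (0.3 vs 0.15 gDW/mmol aerobically, more if it ferments):
the efficiency asymmetry that shapes competition for oxygen. The biomass
methionine demand (0.15 mmol/gDW, the order of genome-scale biomass
compositions) against the 0.5 mmol/gDW secretion coupling sets the
frequency-dependent species ratio of the mutualism, keeping the E-like
consumer the dominant member as observed for the real pair.
"""

from __future__ import annotations

from dataclasses import dataclass

from .community_dfba import Environment
from .errors import ModelValidationError
from .model_io import CoupledSecretion, Metabolite, Reaction, StoichModel, validate_model

#: environment constants of the study conditions
LACTOSE_MMOL = 1.2e-5
O2_MMOL = 6.2e-5
BOX_EDGE_MM = 0.5
INITIAL_BIOMASS_G = 3e-7


@dataclass(frozen=True)
class ToyParams:
    """Stoichiometric yields of the toy pair (all mmol per mmol, except as noted)."""

    atp_per_lactose_aerobic: float = 6.0
    atp_per_lactose_fermentative: float = 2.0
    acetate_per_lactose: float = 2.0
    o2_per_lactose: float = 2.0
    atp_per_acetate: float = 3.0
    o2_per_acetate: float = 2.0
    atp_per_biomass: float = 10.0  # mmol ATP per gDW
    met_per_biomass: float = 0.15  # mmol methionine per gDW (auxotroph demand)
    met_secretion_coupling: float = 0.5  # mmol secreted per gDW of new biomass
    maintenance_atp: float = 1.0  # mmol ATP/gDW/h, non-growth demand

    def validate(self) -> list[str]:
        violations = []
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                violations.append(f"{name} must be positive")
        if self.atp_per_lactose_aerobic <= self.atp_per_lactose_fermentative:
            violations.append(
                "aerobic ATP yield must exceed the fermentative yield"
            )
        # gDW per mmol O2, purely aerobic routes
        e_eff = (self.atp_per_lactose_aerobic / self.atp_per_biomass) / self.o2_per_lactose
        s_eff = (self.atp_per_acetate / self.atp_per_biomass) / self.o2_per_acetate
        if e_eff <= s_eff:
            violations.append(
                "E-like biomass per O2 must exceed S-like "
                f"({e_eff:g} <= {s_eff:g})"
            )
        return violations


def _mets(pairs):
    return [Metabolite(id=i, name=n, compartment=c) for i, n, c in pairs]


def make_toy_pair(params: ToyParams = ToyParams()) -> tuple[StoichModel, StoichModel]:
    """Build the validated (E-like, S-like) fixture pair."""
    violations = params.validate()
    if violations:
        raise ModelValidationError(violations)
    p = params

    e_model = StoichModel(
        species_id="E",
        metabolites=_mets(
            [
                ("lcts_e", "lactose", "extracellular"),
                ("o2_e", "oxygen", "extracellular"),
                ("ac_e", "acetate", "extracellular"),
                ("met_e", "methionine", "extracellular"),
                ("lcts_c", "lactose", "cytosol"),
                ("o2_c", "oxygen", "cytosol"),
                ("ac_c", "acetate", "cytosol"),
                ("met_c", "methionine", "cytosol"),
                ("atp_c", "ATP", "cytosol"),
                ("adp_c", "ADP", "cytosol"),
            ]
        ),
        reactions=[
            Reaction("EX_lcts", {"lcts_e": -1}, is_exchange=True, exchanged_metabolite="lcts_e"),
            Reaction("EX_o2", {"o2_e": -1}, is_exchange=True, exchanged_metabolite="o2_e"),
            Reaction("EX_ac", {"ac_e": -1}, is_exchange=True, exchanged_metabolite="ac_e"),
            Reaction("EX_met", {"met_e": -1}, is_exchange=True, exchanged_metabolite="met_e"),
            Reaction("T_lcts", {"lcts_e": -1, "lcts_c": 1}),
            Reaction("T_o2", {"o2_e": -1, "o2_c": 1}),
            Reaction("T_ac", {"ac_c": -1, "ac_e": 1}),
            Reaction("T_met", {"met_e": -1, "met_c": 1}),
            Reaction(
                "CATAB_AER",
                {
                    "lcts_c": -1,
                    "o2_c": -p.o2_per_lactose,
                    "adp_c": -p.atp_per_lactose_aerobic,
                    "atp_c": p.atp_per_lactose_aerobic,
                    "ac_c": p.acetate_per_lactose,
                },
                lower_bound=0.0,
            ),
            Reaction(
                "CATAB_FERM",
                {
                    "lcts_c": -1,
                    "adp_c": -p.atp_per_lactose_fermentative,
                    "atp_c": p.atp_per_lactose_fermentative,
                    "ac_c": p.acetate_per_lactose,
                },
                lower_bound=0.0,
            ),
            Reaction(
                "MAINT",
                {"atp_c": -1, "adp_c": 1},
                lower_bound=p.maintenance_atp,
            ),
            Reaction(
                "BIOMASS",
                {
                    "atp_c": -p.atp_per_biomass,
                    "adp_c": p.atp_per_biomass,
                    "met_c": -p.met_per_biomass,
                },
                lower_bound=0.0,
            ),
        ],
        biomass_reaction_id="BIOMASS",
    )

    s_model = StoichModel(
        species_id="S",
        metabolites=_mets(
            [
                ("ac_e", "acetate", "extracellular"),
                ("o2_e", "oxygen", "extracellular"),
                ("met_e", "methionine", "extracellular"),
                ("ac_c", "acetate", "cytosol"),
                ("o2_c", "oxygen", "cytosol"),
                ("atp_c", "ATP", "cytosol"),
                ("adp_c", "ADP", "cytosol"),
            ]
        ),
        reactions=[
            Reaction("EX_ac", {"ac_e": -1}, is_exchange=True, exchanged_metabolite="ac_e"),
            Reaction("EX_o2", {"o2_e": -1}, is_exchange=True, exchanged_metabolite="o2_e"),
            Reaction("EX_met", {"met_e": -1}, is_exchange=True, exchanged_metabolite="met_e"),
            Reaction("T_ac", {"ac_e": -1, "ac_c": 1}),
            Reaction("T_o2", {"o2_e": -1, "o2_c": 1}),
            Reaction(
                "RESP",
                {
                    "ac_c": -1,
                    "o2_c": -p.o2_per_acetate,
                    "adp_c": -p.atp_per_acetate,
                    "atp_c": p.atp_per_acetate,
                },
                lower_bound=0.0,
            ),
            Reaction(
                "BIOMASS",
                {"atp_c": -p.atp_per_biomass, "adp_c": p.atp_per_biomass},
                lower_bound=0.0,
            ),
        ],
        biomass_reaction_id="BIOMASS",
        coupled_secretions=[CoupledSecretion("met_e", p.met_secretion_coupling)],
    )

    for model in (e_model, s_model):
        violations = validate_model(model)
        if violations:
            raise ModelValidationError(violations)
    return e_model, s_model


def make_environment(condition: str, scale: float = 1.0) -> Environment:
    """Build one of the three study environments.

    ``cooperation``: finite lactose (1.2e-5 mmol, limiting) and O2
    (6.2e-5 mmol) only — minimal medium forcing the mutualism.
    ``competition`` / ``monoculture``: the same plus unlimited acetate and
    methionine, which removes the interdependence; oxygen becomes limiting.
    ``scale`` multiplies the finite pools (e.g. for yield-ceiling checks).
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    if condition not in ("cooperation", "competition", "monoculture"):
        raise ValueError(f"unknown condition {condition!r}")
    volume_l = (BOX_EDGE_MM * 0.1) ** 3 * 1e-3  # mm -> cm, cm^3 -> L
    pools = {"lcts_e": LACTOSE_MMOL * scale, "o2_e": O2_MMOL * scale}
    unlimited: set[str] = set()
    if condition in ("competition", "monoculture"):
        pools["ac_e"] = 0.0
        pools["met_e"] = 0.0
        unlimited = {"ac_e", "met_e"}
    return Environment(volume=volume_l, pools=pools, unlimited=unlimited)
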