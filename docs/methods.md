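# Methods

This note documents the models, numerics and design choices behind
`crossfba`, in the spirit of a methods appendix. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The simulated system

Two species interact only through a shared, well-mixed extracellular
environment: a lactose-consuming methionine auxotroph ("E") and an
acetate-respiring methionine secretor ("S"). In lactose minimal medium the
pair is an obligate mutualism — E cannot grow without S's methionine, S
cannot grow without E's acetate. Adding unlimited acetate and methionine
turns the interaction into competition for the finite oxygen. The
*monoculture* condition used for baseline essentiality calls is the focal
species alone in the supplemented medium.

## Flux balance analysis

Each species' metabolism is a stoichiometric LP: maximize the biomass flux
μ (1/h) subject to steady state `S v = 0` and flux bounds. Two extensions:

- **Growth-coupled secretion.** A coupling `(m, r)` means the cell secretes
  `r` mmol of metabolite `m` per gDW of new biomass. It is enforced inside
  the LP by adding `+r` to the biomass column of `m`'s mass-balance row —
  a growth-proportional source that must leave through `m`'s exchange
  reaction. When only the exchange touches `m` this is algebraically the
  equality `v_ex = r·μ`. The stored stoichiometry is never edited, so
  models round-trip unchanged.
- **Two-stage solve.** Alternate optima are ubiquitous in FBA, and the
  *identity* of secreted byproducts drives cross-feeding, so determinism
  matters. After maximizing μ, a second stage pins `v_biomass = μ` and
  minimizes `Σ|v|` (flux splitting via auxiliary variables `t ≥ |v|`).
  The second stage cannot change μ; tests assert agreement to 1e-9. A
  `tie_break="none"` switch skips stage 2.

Infeasible LPs map to `μ = 0` with no fluxes rather than an error: a
knockout that disconnects an enforced demand is biologically "no growth",
and the death term then takes over in the dynamics. Solves use HiGHS
(through scipy) with primal/dual feasibility tolerances of 1e-10; package
level feasibility checks use 1e-9.

## Dynamic FBA

Single box, volume `(0.5 mm)³ = 1.25e-7 L`; no spatial structure. Per step
(default `dt = 0.1 h`, horizon 10 h):

1. Uptake bounds per species per exchanged metabolite from the same
   environment snapshot: `v_max·c/(K_m + c)` with `c = pool/volume`,
   defaults `K_m = 10 μM`, `v_max = 10 mmol/gDW/h`. Metabolites flagged
   *unlimited* return `v_max` exactly and their pools are never
   decremented — saturation without bookkeeping infinities.
2. Independent FBA solves per species.
3. **Overdraw control.** If the total requested drawdown of a finite pool
   exceeds the pool, each requester's uptake bound for that metabolite is
   reset to its requested flux times `pool/requested_total` and the step is
   re-solved (up to `rescale_iterations`, default 10). Resetting to scaled
   *fluxes* (not scaled original bounds) guarantees the next total cannot
   exceed the pool, so one re-solve per contested pool usually suffices;
   a pool still overdrawn after the loop raises an error naming it.
4. Euler biomass update `B ← B·(1 + (μ − d)·dt)` with the death rate
   `d = 0.01/h` applied every step, growing or not.
5. Pool update `pool ← pool + Σ_s v_ex,s·B_s·dt`, accumulated in sorted
   species-id order so the trajectory is invariant to how the species list
   is ordered. Pools with `|amount| < tolerance` (default 1e-12 mmol,
   ~1e-7 of the initial lactose pool) are clamped to zero.

The default scheme is simultaneous; a seeded `update_order="random"` mode
(sequential updates in shuffled order, the scheme of some community-dFBA
platforms) exists for comparison but is not used by any default analysis.
Euler (not exponential) growth matches the forward-Euler convention of
established community-dFBA platforms at this step size.

## The toy pair

The fixture models are built for hand verification: every optimum is a
vertex of a polytope small enough to enumerate. Yields (per mmol): lactose
→ 6 ATP + 2 acetate aerobically (2 O₂) or 2 ATP + 2 acetate fermentatively;
acetate → 3 ATP (2 O₂); biomass costs 10 ATP plus, for E, 0.15 mmol
methionine per gDW. S carries the 0.5 mmol/gDW methionine secretion
coupling. Three structural features mirror the real consortium:

- **Auxotrophy**: E has no methionine synthesis; its biomass demand must be
  met by uptake.
- **Maintenance.** E carries a non-growth ATP demand (1 mmol/gDW/h, lower
  bound on an ATP→ADP reaction). This is not a decoration: with zero
  growth and parsimonious fluxes, a maintenance-free auxotroph would take
  up nothing and secrete nothing, and the mutualism could never start.
  With it, a methionine-starved E still ferments/respires lactose and
  trickles acetate (flux 1/3 at zero growth), which feeds S, whose growth
  secretes methionine, which starts E growing — the jump-start. It also
  makes maintenance the example of a *cooperation-only essential* reaction.
- **Efficiency asymmetry**: E makes 0.3 gDW per mmol O₂ aerobically (more
  when fermenting, which uses none) against S's 0.15; the parameter
  validator rejects parameter sets that break this.

The methionine biomass coefficient (0.15 mmol/gDW, the order found in
genome-scale biomass compositions) against the 0.5 coupling sets the
mutualism's frequency-dependent ratio: cumulative growth locks near
ΔB_E ≈ (0.5/0.15)·ΔB_S while methionine is limiting, keeping E the dominant
member. Hand optima used as test oracles: μ_E = (6·5 + 2·5 − 1)/10 = 3.9/h
at uptake caps of 10 (O₂ limits aerobic flux to 5, fermentation takes the
rest), 2.9/h without fermentation, 0 without methionine; μ_S = 3·5/10 =
1.5/h with methionine secretion 0.75 mmol/gDW/h.

### What the toy does and does not show

The toy reproduces the *mechanistic structure*: obligate mutualism in
minimal medium, independence when supplemented, identical monoculture and
competition essentiality sets, cooperation-only essentiality of
maintenance, and composition shifts toward S when E loses oxygen
utilization. It does not reproduce genome-scale *magnitudes or counts*
(287 essential reactions, specific σ values), nor E's dominance under
competition — with a single carbon source and only eight non-exchange
reactions, the toy's competitive endpoint is set by lactose exhaustion
rather than by a large flexible network. Passing toy tests therefore
validates the engine and metrics, not quantitative claims about the real
consortium; those require the published reconstructions (iJO1366, iRR1083)
dropped into `models/`.

## Screen and statistics

Every reaction of the focal model is a mutant (bounds zeroed; exchange
reactions included; load-time "blocked reactions" such as a *metB* block
use the same mechanism). Each mutant runs against the unperturbed partner
in each condition, starting from 3e-7 g of each species; mutants whose
initial LP is infeasible are simulated anyway and simply decay. Essentiality
compares biomass *gain* (final − initial) with the unperturbed gain at a 2%
threshold — gain, not final biomass, so a decaying inoculum does not count
as growth; if the unperturbed reference itself failed to gain, the mutant
is essential iff it also failed. Records are keyed (reaction, condition)
and independent of evaluation order.

Summaries use the sample standard deviation (n−1). Reactions essential in
*any* context are excluded from the "non_essential" rows; both inclusion
modes are reported. The Levene test is mean-centered, with the p-value from
the F upper tail (scipy's survival function, i.e. the regularized
incomplete beta) floored in reports at 2.2e-16, the conventional printing
floor of the reference statistical software. If every within-group absolute
deviation is identical the statistic is degenerate: equal nonzero spreads
report W = 0, p = 1; all-constant groups are reported as a degeneracy note
rather than a number. Substantive counts use an inclusive ≥ 1% departure of
%E or BM from 1. Cross-condition R² is computed over mutants non-essential
in both conditions by default (`include_essential_in_r2` switches this, as
large-effect essential mutants can dominate the correlation). Extinct
communities (E+S = 0) have undefined composition and are recorded as
missing, excluding them from %E statistics.

## Problem sizes and determinism

Default analyses use the toy pair: a full screen is 12 mutants × (2 pair
conditions + 1 monoculture) ≈ 39 ten-hour simulations, a few thousand LPs,
well under a minute on one core. The acceptance script simulates one
unperturbed cooperative co-culture (100 steps) and evaluates the ECD
identity on its outcome. Nothing in the default pipeline is stochastic; the
seed only drives the optional randomized update order, and rerunning any
command reproduces outputs byte-for-byte (numbers serialized at 12
significant digits).

## Known limitations

- Single well-mixed box; no diffusion, lattices, or more than two species.
- Reaction-level knockouts only; no gene–protein–reaction mapping, so
  validation against gene-knockout essentiality data is out of scope.
- Parsimonious (min Σ|v|) tie-breaking is one defensible convention; a
  platform with randomized update order and no secondary objective can
  produce slightly different byproduct spectra, which is why small effects
  below the 1% substantive cutoff should not be interpreted.
- SBML import trusts FBC bounds and the declared objective; models without
  an objective are rejected rather than guessed. Model checksums are
  stamped into all outputs so results can be traced to exact inputs.
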