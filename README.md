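# crossfba

Dynamic-FBA co-culture simulation and single-reaction knockout screens for
quantifying how ecological context — cooperation versus competition —
changes the genetic robustness of microbial species and the communities
they form.

The package is aimed at researchers in microbial systems biology who want
to ask: *if I break one reaction in one member of a two-species community,
how much does the community change, and does the answer depend on whether
the species need each other?* The motivating system is an engineered
consortium of a methionine-auxotrophic *E. coli*-like lactose consumer and
an *S. enterica*-like acetate respirer that secretes methionine in
proportion to its growth. In lactose minimal medium the pair is an obligate
mutualism; with acetate and methionine supplied the same pair merely
competes for oxygen.

## What it computes

**Community dynamics** come from dynamic flux balance analysis (dFBA) in a
single well-mixed box. Each timestep, every species solves

```
max  v_biomass          s.t.  S v = 0,   l ≤ v ≤ u
```

with uptake bounds from shared metabolite pools via Michaelis-Menten
kinetics, `v_max · c/(K_m + c)`, followed by a second LP stage that fixes
the growth optimum μ and minimizes Σ|v| so byproduct spectra are unique.
Growth-coupled secretion (0.5 mmol methionine per gDW of new biomass) is an
equality constraint tied to the biomass flux. Biomass follows forward Euler,
`B ← B·(1 + (μ − d)·dt)`, with an unconditional death rate `d`, and pools
update exactly as `Δpool = Σ_s v_ex,s · B_s · dt`.

**The screen** knocks out each reaction of a focal species in turn (bounds
set to zero), pairs the mutant with the unperturbed partner under each
condition, and records final biomasses after 10 h. A reaction is *essential*
in a condition if the mutant's biomass gain is below 2% of the unperturbed
gain.

**Robustness metrics** compare each mutant community `(E, S)` with the
unperturbed `(E_u, S_u)` of the same condition:

- Euclidean community distance `ECD = 100·‖(E−E_u, S−S_u)‖ / ‖(E_u, S_u)‖`
- normalized composition `%E = (E/(E+S)) / (E_u/(E_u+S_u))`
- normalized biomass `BM = (E+S) / (E_u+S_u)`

Condition-level summaries give per-metric standard deviations (with and
without essential reactions), a mean-centered Levene test of variance
equality between conditions, counts of *substantive* knockouts (≥ 1% shift
in %E or BM), and cross-condition Pearson R² of mutant effects.

Models are read from a small JSON dialect (read/write) or SBML Level 3 +
FBC (import), including load-time reaction blocks (the *metB* analogue) and
attached secretion couplings. A built-in, hand-solvable toy pair
(`make_toy_pair`) reproduces the system's three mechanisms — methionine
auxotrophy, acetate cross-feeding, and the biomass-per-O₂ asymmetry between
the species — so the whole pipeline runs in seconds with no downloads.

## Worked example

```python
from crossfba import ScreenConfig, make_toy_pair, run_screen, summarize_screen

e_model, s_model = make_toy_pair()
result = run_screen(e_model, s_model, ScreenConfig())
tables = summarize_screen(result, ScreenConfig())
```

Running `python examples/03_knockout_screen.py` (the same computation)
prints, among other things:

```
24 records (12 mutants x 2 conditions)

unperturbed cooperation  E 6.426e-06 g, S 5.593e-06 g
unperturbed competition  E 4.893e-06 g, S 6.891e-06 g

essential in monoculture/competition (7): BIOMASS, EX_ac, EX_lcts, EX_met, T_ac, T_lcts, T_met
additionally essential in cooperation: MAINT
```

Reading: starting from 3×10⁻⁷ g inocula, both species grow in both
conditions, with the consumer dominant in the mutualism. Seven reactions
(carbon in, acetate out, methionine in, biomass) are lethal everywhere; the
ATP maintenance demand is lethal *only under cooperation*, because the
acetate trickle it forces at zero growth is what jump-starts the metabolic
exchange — knock it out and neither partner ever starts growing. The same
script prints the σ, Levene, substantive-count and R² tables.

Other entry points: `examples/01_toy_models_fba.py` (single FBA solves with
hand-checkable optima), `examples/02_cooperation_vs_competition.py`
(obligate mutualism versus independence), and a CLI —
`crossfba make-toy | simulate | screen | stats` — for shell-driven runs
with provenance-stamped CSV/TSV outputs.

Genome-scale reproduction of the published consortium uses the iJO1366 and
iRR1083 reconstructions; place them as `models/iJO1366.xml` and
`models/iRR1083.xml` (they are not redistributable here) and the
genome-scale acceptance tests will run the same pipeline on them.

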