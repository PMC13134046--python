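# Methods

## Scope and model class

`gutgem` implements steady-state constraint-based analysis of genome-scale
metabolic models (GEMs): flux balance analysis (FBA), parsimonious FBA
(pFBA), flux variability analysis (FVA), gene/reaction essentiality,
thermodynamic directionality curation with energy-generating-cycle (EGC)
screening, ranked gap-reaction integration, GIMME transcriptome
contextualization, and fixed-abundance community modeling with
cross-feeding inference. The steady-state assumption (**S**·*v* = 0)
means all predictions are flux capabilities of a network under bounds, not
kinetics; alternate optima are endemic, and every reported point
distribution is therefore a pFBA (or lexicographic) representative.

## Numerical core

All linear programs go through a single minimal solver contract backed by
HiGHS (`scipy.optimize.linprog`). Choices that matter:

- **Zero-flux tolerance**: 1e-6 mmol/gDW/h everywhere a flux is compared
  with zero (blocked reactions, EGC positivity, cross-feeding calls,
  pruning). This is the LP noise floor, configurable per call.
- **pFBA**: stage 1 maximizes the objective; stage 2 splits every reaction
  into nonnegative forward/reverse parts with unit weights, pins the
  objective with a 1e-12 relative slack, and minimizes the sum. Net-bound
  side constraints are added only for reactions whose bounds exclude zero.
- **FVA**: the objective floor is fraction × optimum minus a 1e-9 absolute
  guard; `fraction=0` drops the floor (used for blocked-reaction
  detection). Ranges are monotone in the fraction by construction.
- **Deletions** use plain FBA — only the optimum matters against the
  *f*_ess threshold. A knockout sets bounds of all GPR-disabled reactions
  to zero; it never edits the network.
- **Infeasible/unbounded** statuses are reported faithfully rather than
  coerced; essentiality and GIMME refuse to run when wild-type growth is
  zero, since their definitions presuppose growth.

## Thermodynamic curation

Directionality uses the ±30 kJ/mol convention on transformed reaction
Gibbs energies (ΔrG′ estimated externally, e.g. at pH 6, 310 K, ionic
strength 0.25 M; the table records its conditions for provenance):
strictly below −30 ⇒ forward-only, strictly above +30 ⇒ reverse-only,
boundary values stay reversible. "Forward" is the written direction of the
stoichiometry. Exchanges are never clamped; a clamp that would invert
bounds is reported and skipped. The operation is idempotent and monotone
in ΔrG′.

EGC screening closes every exchange, adds one dissipation probe per energy
currency (ATP, GTP, NADH, NADPH, FADH2, proton-motive force; textbook
hydrolysis stoichiometries, configurable), and maximizes the probe flux. A
positive or unbounded maximum exposes a cycle, reported with its active
reactions. Currencies whose metabolites a model lacks are skipped with a
notice. During candidate integration, EGC repair removes only reactions
added in that call, greedily worst-ranked first, and the returned model is
re-screened until clean; "flux inflation" after integration is reported as
a growth ratio but never acted on automatically, since no quantitative
rule exists.

## Media

Exchange caps follow the COBRA sign convention (uptake negative). Where
only paired concentrations are available, the cap is the finite-difference
specific flux v = (Ct − C0)/(Δt·X) — exactly invertible, which the tests
exploit for parameter recovery. The amino-acid bulk default is
0.5 mmol/gDW/h uptake. Unlisted exchanges follow a closed-uptake policy
(secretion open) so defined-medium simulations cannot import phantom
nutrients.

## GIMME

Gene counts are CPM-normalized; the expression threshold is the
70th-percentile CPM computed over model genes present in the profile (not
the whole transcriptome), matching how contextualization is normally
scoped. "Above the 70th percentile" = highly expressed; equivalently the
top 30% — both phrasings appear in the literature and are consistent only
under this reading, which is the one adopted. Reaction scores aggregate
GPRs with AND = min / OR = max. Penalties c_i = max(0, t − score_i) apply
to gene-associated, non-blocked reactions only; blocked reactions are
excluded so the objective never pays for impossible flux. The solve is
lexicographic: minimal penalty, then maximal growth at that penalty, then
minimal total flux — without the tie-breaks the penalty LP is degenerate
whenever zero penalty is attainable, and the returned distribution would
be arbitrary. Pruning deactivates (bounds to zero, never deletes)
low-flux reactions that are gene-associated, non-spontaneous, and not
essential; exchanges are also left alone.

## Community modeling

Members are merged block-diagonally: all ids are namespaced per species,
member exchanges become transfer reactions into a shared extracellular
pool (positive flux = secretion into the pool), and each pool metabolite
gets one community-level exchange. Member bounds are scaled by relative
abundance a_k, so member flux variables are per gDW of community biomass
and pool balances add coherently; the community objective is the plain sum
of the scaled member biomass fluxes, i.e. the abundance-weighted sum of
the members' specific growth rates. A single member at a = 1 reduces
exactly to its monoculture model (identity property, tested to 1e-9
relative). Community media cap the pool exchanges and are not scaled.

Cross-feeding is classified from community FVA (default 90% of the
community optimum) over transfer reactions: max > tol ⇒ production,
min < −tol ⇒ consumption, both ⇒ bidirectional; a metabolite with a
producer and a distinct consumer is cross-fed. Edges whose largest |flux|
is below 0.01 mmol/gDW/h are flagged low-level. Networks export to SIF or
GraphML.

## Synthetic scenarios and what they do (not) show

The generators in `gutgem.synth` are pure functions of their seed and
produce integer-stoichiometry, hand-checkable networks:

- **Toy anaerobe** (43 reactions, 30 genes): lumped glycolysis yields
  2 acetyl-CoA + 2 ATP + 2 NADH per glucose (uptake cap 10); butyrate via
  acetyl-CoA consumes 2 NADH and nets +1 ATP through the CoA-transferase +
  acetate-kinase couple, while the lumped kinase-style step nets 0, making
  the transferase route strictly preferred; the methylmalonyl-CoA
  propionate branch is the only other NADH sink, coupling growth
  (1 acetyl-CoA + 4 ATP per unit) to fermentation; the five-step lysine
  branch (Table-style ids LYSAM…AB3CL with their two-subunit AND and
  isozyme OR GPRs) is redox-neutral and costs 2 ATP of ABC transport, so
  it is strictly suboptimal by ΔμB = L/5 — zero at the optimum, positive
  in 90% FVA, and active once the ATP cost is dropped and the acetyl-CoA
  condensation disabled. Closed-form ground truth: growth 6.0, butyrate
  4.0, propionate 6.0, acetate 0. Cellobiose uptake is closed in the
  default medium, leaving its transporter blocked.
- **Expression profiles**: all highly expressed genes share one seed-drawn
  count so the 70th-percentile CPM equals their common value and penalties
  fall exclusively on the designated low genes. This is deliberate: the
  counts only need to straddle the threshold; no RNA-seq dispersion or
  library-composition realism is modeled, so passing tests say nothing
  about threshold robustness on noisy real profiles.
- **Community** (degrader → fermenter → utilizer, abundances 0.59 / 0.26 /
  0.15): the degrader hydrolyses a polymer and is nitrogen-capped, leaking
  glucose as a public good; the fermenter converts glucose (3 per biomass
  unit) with growth-coupled acetate/acetaldehyde/malate by-products; the
  utilizer — the sole butyrate producer — grows only on those by-products
  and cannot grow in monoculture. Malate is additionally supplied in the
  medium so the fermenter can both secrete and import it, exercising the
  bidirectional edge class. The engineered edge list is recovered exactly.
- **Random tiny models** (≤ 8 reactions, finite bounds bracketing zero)
  feed the vertex-enumeration oracle: FBA optima must match exhaustive
  enumeration to 1e-9 relative and pFBA totals must not exceed the best
  enumerated optimal vertex.

These toys validate the algorithms' correctness and their engineered
qualitative behaviors (route preference, condition-driven switching,
syntrophy). They do not validate quantitative agreement with measured
growth or SCFA fluxes of real organisms, which depends on curated GEMs,
measured media, and real transcriptomes supplied by the user.

## Ground-truth verification

Ground truths for ≤ 8-reaction models come from the brute-force vertex
enumerator (independent of the HiGHS engine). The 43-reaction anaerobe is
beyond enumeration; its stored truths are derived by hand from the closed-
form energy/redox accounting above and re-verified in the test suite
against cobrapy/GLPK as an independent implementation — cobrapy is never
used as the computational path.

## Problem sizes

Default verification runs 200 random tiny models for the oracle sweep,
100 draws for cap recovery, and the fixed toy scenarios; the whole suite
and the acceptance script each finish in well under a minute on one CPU.

## Known limitations

- No loopless FBA or full thermodynamics-based flux analysis; the ΔrG′
  rule is a directionality heuristic, and ΔG′ estimation itself is out of
  scope (tables are inputs).
- No dynamic community modeling: abundances are fixed inputs; no host
  compartment; no prediction of abundance shifts.
- SBML support targets Level 3 + FBC (bound parameters) with a fallback to
  reversibility-flag defaults; exotic dialects (kinetic-law bounds) are not
  parsed.
- Percentile semantics use linear interpolation; other quantile
  conventions shift the threshold for small gene sets.
- The exchange auto-detector assumes single-metabolite boundary reactions
  in the declared extracellular compartment; sink/demand reactions on
  internal metabolites need the explicit flag.
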