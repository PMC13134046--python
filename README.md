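# gutgem

Constraint-based metabolic modeling of gut anaerobes: thermodynamic
curation, transcriptome contextualization, and community cross-feeding
inference — the workflow used to interrogate short-chain-fatty-acid (SCFA)
producers such as *Flavonifractor plautii* in defined gut media, packaged
as a reusable, fully tested library with synthetic toy scenarios so every
stage runs without external downloads.

## Who this is for

Microbial systems biologists working with genome-scale metabolic models
(GEMs) of gut bacteria who need to (i) curate draft reconstructions
(directionality from ΔrG′, energy-generating-cycle screening, ranked
gap-reaction integration), (ii) simulate growth and fermentation-product
secretion under defined media, (iii) contextualize a model with RNA-seq via
GIMME, and (iv) assemble fixed-abundance multi-species communities and read
cross-feeding interactions off flux variability analysis.

## The model

A GEM is a stoichiometric matrix **S** (metabolites × reactions) with flux
bounds *l* ≤ *v* ≤ *u* (mmol/gDW/h; uptake negative, secretion positive)
and gene–protein–reaction (GPR) boolean rules. Core computations:

- **FBA** — max *c*ᵀ*v* s.t. **S** *v* = 0, *l* ≤ *v* ≤ *u* (biomass
  objective, 1/h).
- **pFBA** — fix the FBA optimum, then min Σ|*vᵢ*| (reversible reactions
  split into nonnegative forward/reverse parts): a representative
  distribution free of gratuitous cycles.
- **FVA** — per-reaction min/max flux subject to objective ≥ fraction ×
  optimum (default 90%).
- **Essentiality** — single gene/reaction deletions; essential when
  knockout growth < *f*_ess × wild type (default 0.9).
- **Thermodynamic directionality** — ΔrG′ < −30 kJ/mol ⇒ forward-only,
  ΔrG′ > +30 ⇒ reverse-only, |ΔrG′| ≤ 30 ⇒ reversible; followed by an
  energy-generating-cycle (EGC) screen that closes all exchanges and
  maximizes per-currency dissipation probes (ATP, NADH, …).
- **GIMME** — min Σ *cᵢ*|*vᵢ*| with *cᵢ* = max(0, *t* − scoreᵢ), where *t*
  is the 70th-percentile CPM over model genes and reaction scores come from
  GPRs (AND = min, OR = max), subject to growth ≥ 90% of optimum; low-flux,
  non-essential, non-spontaneous, gene-associated reactions are then
  deactivated.
- **Community FBA** — member models merged block-diagonally through a
  shared extracellular pool; member bounds scaled by relative abundance
  *aₖ* so fluxes are per gDW of community; the community objective is the
  abundance-weighted sum of member biomass fluxes. Cross-feeding edges are
  classified from community FVA of the transfer reactions (max > 0 ⇒
  production, min < 0 ⇒ consumption, both ⇒ bidirectional).

All LPs are solved with HiGHS (scipy); an independent brute-force
vertex-enumeration oracle ships in `gutgem.oracle` for tiny models.

## Worked example

The built-in toy anaerobe (43 reactions) has competing butyrate routes —
the acetyl-CoA pathway with CoA-transferase (BUTCT2) or kinase-style
(BUTKr) terminal steps, a lysine branch carrying a 2-ATP transport cost,
and a 4-aminobutanoate branch — plus a methylmalonyl-CoA propionate branch:

```python
from gutgem import pfba, fva, single_gene_deletion
from gutgem.synth import make_toy_anaerobe

sc = make_toy_anaerobe()
sol = pfba(sc.model, sc.medium)
print(f"growth     {sol.objective_value:.2f} 1/h")
print(f"butyrate   {sol.fluxes['EX_but_e']:.2f} via BUTCT2={sol.fluxes['BUTCT2']:.2f}")
print(f"propionate {sol.fluxes['EX_ppa_e']:.2f}")
print(f"lysine use {sol.fluxes['LYSAM']:.2f}")
print("lysine FVA max at 90%:", round(fva(sc.model, sc.medium, 0.9,
                                          ['LYSAM'])['LYSAM'][1], 2))
```

prints

```
growth     6.00 1/h
butyrate   4.00 via BUTCT2=4.00
propionate 6.00
lysine use -0.00
lysine FVA max at 90%: 0.5
```

Glucose (capped at 10 mmol/gDW/h) is fermented to butyrate through the
ATP-yielding CoA-transferase step and to propionate (the only other NADH
sink), while the energetically costly lysine route carries zero flux at
the optimum yet remains feasible in FVA — the condition-driven behavior
that flips once the transport ATP cost is removed. Gene knockouts flag the
glucose transporter, glycolysis, acetate kinase and the propionate-cycle
genes as essential at *f*_ess = 0.9.

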