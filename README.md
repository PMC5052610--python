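# aobr

Hydraulic, community-diversity and COD-removal analysis for split-feeding
compartmental baffled bioreactors.

Multi-compartment anaerobic/oxic baffled reactors (A/OBRs) treat
high-strength waste streams such as foodwaste anaerobic digestate. Instead
of feeding all influent to the first compartment, the flow can be split
among several compartments (e.g. 6:3:1 or 6:2:2 over compartments 1/3/5)
to spread the organic load. Assessing such a design needs three pieces of
bookkeeping, and this package implements all of them as a tested pipeline
for reactor engineers and environmental microbiologists:

1. **Hydraulics (residence time distribution).** An impulse of conservative
   tracer (e.g. KCl) is injected with the feed and the effluent
   concentration C(t) is sampled. On dimensionless axes θ = t/HRT and
   C_θ = C/C₀, the curve's moments give the mean θ_m and variance σ_θ²,
   from which:
   - tanks-in-series number **N = 1/σ_θ²** (N → 1: completely mixed,
     N → ∞: plug flow),
   - dispersion number **D/μL = σ_θ²/2** (small-dispersion closed form; a
     closed-vessel implicit fit is also provided), classified as plug flow
     below 0.02 and completely mixed above 0.2,
   - measured HRT = θ_m · HRT_nominal,
   - hydraulic dead space **V_d/V_T = 1 − θ_m^[0,2]**, one minus the
     centroid of the curve truncated at θ = 2.
2. **Community diversity.** From a gel band-intensity table (lane × band),
   the Shannon–Wiener index **H′ = −Σ Pᵢ ln Pᵢ** with Pᵢ the relative
   intensity of band i.
3. **COD removal.** Per-compartment removal referenced to the total fed
   COD, `removal_i = Q_i (C_in,i − C_eff,i) / (Q_total · C_feed) × 100 %`,
   which telescopes so the contributions sum to the overall removal even
   under split feeding; stage means ± sd and one-way ANOVA for group
   comparison.

A compartmental simulator (tanks in series with split feed, stiff ODE
integration of the tracer balance, first-order steady-state COD kinetics)
generates synthetic data for every stage, so the whole chain is testable
without wet-lab input.

## Worked example

Simulate the three feeding strategies of a 6-compartment, 17.88 L reactor
at 0.37 L/h (nominal HRT 48.3 h) and summarize their hydraulics:

```sh
aobr demo --outdir demo --seed 1
```

```
reactor     hrt_h  variance  dispersion_number  n_tanks  dead_space_pct mixing_class
     R1 48.286076  0.164965           0.082482 6.061905        2.626829 intermediate
     R2 48.115580  0.298767           0.149383 3.347095        7.722050 intermediate
     R3 48.199248  0.344058           0.172029 2.906484        8.984344 intermediate
```

R1 feeds everything upstream; R2 and R3 split the feed 6:3:1 and 6:2:2
over compartments 1/3/5. Splitting the feed broadens the residence-time
distribution — part of the flow traverses fewer tanks — so the variance
rises from the ideal Erlang value 1/6 to ≈ 0.30–0.34, the equivalent tank
number drops from ≈ 6 to ≈ 3, the dispersion number rises to ≈ 0.15 and
the truncated-centroid dead-space reading rises to ≈ 8–9 %. Note the mean
residence time stays at the nominal HRT for every split (each feed
fraction still sweeps the whole accessible volume); it is the *shape* of
the curve that changes. The same run writes the tracer curves, a
synthetic-gel diversity table and a per-compartment COD-removal table to
`demo/`.

The same stages are available as subcommands on your own CSV data
(`aobr rtd`, `aobr diversity`, `aobr performance`) and as plain library
calls (`aobr.summarize_rtd`, `aobr.diversity_table`,
`aobr.per_compartment_removal`).

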