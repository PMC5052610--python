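# Methods

## Reactor model

The reactor is a chain of `n_compartments` well-mixed tanks. Fresh feed of
total flow Q (L/h) may enter several compartments according to
`feed_split`, a non-negative vector summing to 1; flow accumulates down
the chain, so compartment *i* discharges
`Q_i = Q · Σ_{j≤i} feed_split_j`. Each compartment is a single ideal CSTR:
the physical sub-division of each compartment into down-flow and up-flow
sections is not modelled, matching the granularity at which the
tanks-in-series analysis itself describes the reactor. No biofilm, gas
phase, pH or nitrogen chemistry is represented.

Defaults describe the study conditions: 6 compartments, 17.88 L total,
0.37 L/h (nominal HRT 48.3 h), feed strategies all-upstream, 6:3:1 and
6:2:2 over compartments 1/3/5.

### Tracer experiment

The tracer balance is linear,

    V_i dC_i/dt = Q_{i−1} C_{i−1} − Q_i C_i ,

fresh feed carrying no tracer but adding flow. The impulse is an initial
condition, not a forcing term: the injected mass is placed in the
compartments in proportion to the feed split (the tracer enters with the
influent, so under split feeding the slug divides among the feed points;
an integer `injection_compartment` forces it into one tank instead, and
for all-upstream feeding the two coincide). A finite `pulse_duration`
replaces the impulse by a rectangular feed pulse of the same mass for
sensitivity checks. Integration uses `scipy.integrate.solve_ivp` (LSODA,
rtol 1e-8, atol 1e-12); sampling defaults to every 6 h out to 3 nominal
HRTs.

The normalization reference is C₀ = injected mass / total volume — the
concentration the pulse would have if instantly mixed through the whole
reactor — so a single ideal CSTR gives C_θ(0) = 1.

A consequence worth stating: for any feed split in which all compartments
carry flow, the *mean* of the effluent RTD is exactly V/Q (θ_m = 1). This
is the standard residence-time theorem — every feed fraction ultimately
sweeps the same accessible volume at the same total throughput. Split
feeding therefore does not shift the ideal-model mean; it broadens the
distribution (earlier breakthrough, larger σ_θ²). Measured HRTs that
deviate from nominal in real reactors reflect non-idealities (channeling,
dead zones, truncation of the sampled curve) that the ideal chain does not
contain.

Observation noise is multiplicative gamma noise with unit mean and a
stated coefficient of variation (gamma keeps concentrations positive);
`noise_cv = 0` (the default, matching the noise level the study reports —
none) leaves the curve untouched. Every stochastic operation takes an
explicit seed; there is no global random state.

### Steady-state COD profile

A stylized first-order scenario exercises the bookkeeping: compartment *i*
mixes its upstream effluent with any local feed stream (flow-weighted),
then `effluent = influent / (1 + k_i τ_i)` with τ_i = V_i/Q_i. The solve
is a single downstream sweep; a compartment with zero through-flow is
stagnant and carries zero substrate. Rate constants are free parameters of
the scenario, not calibrated quantities.

## RTD analysis

* **Moments** are trapezoidal quadrature on the sampled grid — no
  smoothing, interpolation or tail extrapolation. When a truncation bound
  is given the curve is cut there, linearly interpolating the endpoint.
* **Dead space** uses the truncated-centroid strategy:
  V_d/V_T = 1 − θ_m^[0,2], clamped to [0, 1]. The quantity depends only on
  the mean of the curve and the area below θ = 2, which is what published
  dead-space figures for such reactors are computed from; for an ideal
  CSTR it evaluates analytically to
  1 − (1 − 3e⁻²)/(1 − e⁻²) ≈ 0.313, consistent with the ≈ 32 % figures
  reported for near-single-tank behaviour. The strategy sits behind a
  registry so alternatives can be added without touching callers.
* **Tanks-in-series** N = 1/σ_θ², reported unrounded and clamped below at
  1 (a variance above 1 has no tank interpretation).
* **Dispersion number** defaults to the small-dispersion closed form
  d = σ_θ²/2, which is the relation behind the published split-feed values
  (0.28 → 0.14, 0.30 → 0.15). The closed-vessel relation
  σ_θ² = 2d − 2d²(1 − e^{−1/d}) is available as a method flag and is
  inverted by bracketed bisection (xtol 1e-10); it is only defined for
  σ_θ² < 1.
* **Classification**: plug flow below D/μL = 0.02, completely mixed above
  0.2. The published thresholds are strict inequalities, so the boundary
  values themselves are classed intermediate.

## Diversity

H′ = −Σ Pᵢ ln Pᵢ over relative band intensities, natural log.
Published H′ values in this setting (≈ 0.7–1.3 with a handful of bands per
lane) are consistent with the natural-log convention, which is also the
usual one for this index. Zero-intensity bands are dropped before
normalization (equivalent to 0·ln 0 = 0, but explicit). The synthetic gel
generator draws lane profiles from a symmetric Dirichlet; its
concentration parameter tunes expected evenness, and per-lane totals are
randomized to mimic exposure differences, which H′ is invariant to.

## COD bookkeeping

Per-compartment removal is mass-based and referenced to the **total** fed
COD: removal_i = Q_i (C_in,i − C_eff,i) / (Q C_feed) × 100 %. For regular
feeding this reduces to the plain concentration ratio
(influent − effluent)/initial influent; for split feeding it is the choice
that makes the contributions telescope to the overall removal
1 − C_effluent/C_feed when all feed streams share one strength. (Whether
split-feed removal figures should be referenced to the first stream only
or to the total feed is genuinely ambiguous in this field's reporting; the
total-feed convention is adopted here for its conservation property.)

Operating stages default to days 1–14 / 15–28 / 29–35 and are
overridable. Stage summaries use the arithmetic mean and sample (n−1)
standard deviation. Group comparison is classical one-way ANOVA
(`scipy.stats.f_oneway`) with significance flagged at P < 0.05.

## What the synthetic data does and does not show

The generator reproduces the *ideal* hydraulics of the geometry: Erlang
responses, split-feed superposition, exact mass conservation, first-order
COD profiles. It contains no back-mixing between compartments, no
channeling, no biological dead space and no measurement drift. Passing
tests therefore demonstrate that the analysis chain recovers known
parameters from curves of the kind the model produces — not that an ideal
chain reproduces every published number for a real reactor. In particular
the regular-feeding reactor's published trio (σ² = 0.47, N = 1.35,
D/μL = 0.33) is mutually inconsistent under the fitting relations
(1/0.47 = 2.13; 0.47/2 = 0.235), so no simulator setting could match all
three; the package reports the relation-implied values and the test suite
asserts exactly that.

## Numerical choices and problem sizes

* ODE tolerance rtol 1e-8 / atol 1e-12; tracer curves for parameter
  recovery use 0.5 h sampling over 10–12 nominal HRTs, which bounds
  quadrature truncation of the variance below the 2 % recovery tolerance.
* Mass-conservation checks use a 10-HRT horizon; the truncated tail is
  O(e^{−10}) and dominated by the 0.5 % tolerance.
* Monte-Carlo sizes: 10,000 draws for the noise-calibration check, 1,000
  lanes for the diversity-ordering check, 1,000 null simulations for ANOVA
  type-I calibration — all chosen to keep sampling error a factor of a few
  below the asserted bands.
* Bisection tolerances: closed-vessel inversion xtol 1e-10; entropy-target
  profile construction in tests bisects 200 iterations (machine precision).

## Known limitations

* No back-mixing term, so low tank numbers (N ≪ compartment count) seen in
  real baffled reactors cannot be generated by the simulator.
* The dead-space estimate inherits the truncated-centroid definition's
  bias for long-tailed curves sampled coarsely.
* Diversity input is an already-quantified intensity matrix; no gel image
  processing, band calling or lane alignment.
* The COD scenario is first-order and steady-state only — no inhibition,
  salinity effects or transients.
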