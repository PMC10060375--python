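# Methods

`nanocascade` models the kinetics of multienzyme cascades assembled on
nanoparticle (NP) scaffolds — quantum dots (QDs) and nanoplatelets (NPLs)
cross-linked into clusters by multivalent His6-tagged enzymes — together
with the plate-reader data analysis used to characterize them. This note
records the models, their assumptions, the defaults, and what the synthetic
data do and do not establish.

## Cascade kinetic model

Each reaction step uses an irreversible single-limiting-substrate
Michaelis–Menten rate law:

    v_k = kcat_k · n_k · [E_k] · S/(K_M,k + S) · ∏_c C/(C + K_cof)

* **Active-site convention.** Turnover numbers in the packaged enzyme table
  are per monomer, while enzyme concentrations throughout the package refer
  to the holoenzyme; the simulator therefore multiplies `[E]` by the
  oligomeric subunit count `n` (1, 2 or 4) to obtain the catalytic-site
  concentration. This convention is applied identically in `simulate` and
  `tau_analytic`.
* **Cofactor factor.** Every consumed co-substrate (ATP, ADP, NAD+, NADH,
  inorganic phosphate) contributes a hyperbolic availability factor
  `C/(C + K_cof)` with `K_cof = 10 µM` by default. Assay cofactors are
  saturating (mM scale), so the factor is ≈1 throughout normal operation;
  its only job is to let pools deplete smoothly instead of clamping rates
  discontinuously, which would break the stiff ODE solver.
* **Irreversibility.** Reverse (gluconeogenic) reactions are not modelled.
  Two enzymes in the table (phosphoglucose isomerase and phosphoglycerate
  kinase) were characterized in the direction opposite to pathway flux;
  their constants are used unchanged for the forward step and carry a
  `direction_note`.
* **Triose bookkeeping.** Aldolase splits fructose-1,6-bisphosphate into
  one DHAP and one G3P; triose phosphate isomerase converts DHAP to G3P
  irreversibly. Hence two NADH per glucose in the excess-cofactor limit —
  an invariant the tests check against the closed-form mass balance.
* **Saccharification stoichiometry (9E/10E).** Maltoheptaose (7 glucose
  units) is lumped as amylase → 3 maltose + 1 glucose, maltase →
  2 glucose per maltose; invertase splits sucrose into glucose + fructose
  with fructose left as a dead-end species.
* **Integration.** `scipy.integrate.solve_ivp` with LSODA, `rtol = 1e-8`,
  `atol = 1e-6 µM`: nM enzymes against mM substrates span six orders of
  magnitude and the system is stiff. Cofactor-couple totals (NAD+ + NADH,
  ATP + ADP) are conserved by construction of the stoichiometry and are
  verified to drift less than 10× the absolute tolerance. Trajectories are
  clipped at zero after integration (wiggle at the `atol` scale only).

Units are µM, seconds, and µM/s everywhere internally; I/O converts
explicitly (Beer–Lambert with ε(NADH, 340 nm) = 6220 M⁻¹cm⁻¹).

## Transient time

For a sequential cascade with N intermediate-consuming steps the lag before
steady-state product flux is

    τ = Σ_j K_M,j / (V_j − v₀),

with `v₀` the first enzyme's velocity at the assay substrate concentration
(evaluated at the initial concentration; all assays run the first substrate
saturating). A step with `V_j ≤ v₀` cannot reach steady state and is
reported as an infinite transient rather than a negative number.

Empirically, τ is the x-intercept of the late-time linear portion of a
progress curve. The window rule (shared `LinearRegionPolicy`):

1. candidate windows span ≥ 20% of the curve and ≥ 20 samples, with linear
   R² ≥ 0.995;
2. a curvature gate requires the quadratic term of a local parabola fit to
   contribute ≤ 2% of the window's rise — R² alone accepts short stretches
   of smoothly accelerating curves, and this gate is what makes a curve
   that never reaches steady state (e.g. a dilute free-enzyme control)
   correctly raise "no linear region";
3. among passing windows the steepest wins (earliest start on ties), and
   the window is then extended toward late time while the criteria hold.
   The extension matters statistically: picking the steepest of many
   overlapping windows is an extreme-value selection whose noise bias is
   damped by refitting over the longer window. On closed-form lag curves
   the estimator is exact to ≤ 0.2% noiseless and recovers τ with ≈ 0.1–3%
   median error at 0.002 AU read noise.

τ standard errors propagate from the fit covariance of slope and intercept.

The diffusion-limited-regime check compares the catalytic rate `kcat`
against the encounter scale `min([E],[I])^{2/3}·D` after converting
concentrations to number densities (molecules/µm³) so the ratio is
dimensionless. The criterion is a proportionality, so the crossover factor
(default 1) marks an order-of-magnitude boundary, not a sharp threshold.

## Reproducing the no-channeling transient time

The reference computation simulates the seven-enzyme glucose → 3-PG cascade
with free-enzyme constants at the fixed assay concentrations (Glk 5.5,
PGI 1, PFK 9, FBA 12, TPI 1, GPD 27, PGK 7.5 nM) under the standard assay
conditions (10 mM glucose, 7.5 mM ATP, 7.5 mM ADP, 1.13 mM NAD+, 4 mM
phosphate, 60 s sampling over 16 h) and reports the NADH asymptote
x-intercept: τ ≈ 11,350 s. The analytic sum over the same constants gives
≈ 28,000 s; the difference is expected — the slow high-K_M steps (GPD, PGK)
have not fully converged to their steady-state pools within the assay span,
so the finite-window x-intercept undershoots the asymptotic theory. The
empirical estimate is the comparable quantity for plate-reader data.

## Progress-curve analysis

Initial rates use the earliest contiguous window with ≥ 10 samples,
R² ≥ 0.99 and ≤ 10% depletion (relative to the curve's span — the assays
monitor a species proportional to consumed substrate). Michaelis–Menten
fitting is nonlinear least squares (`lmfit`) for `V_max` and `K_M` with
`kcat = V_max/[E]` on the active-site concentration; a warning fires when
the titration does not span the fitted K_M (only `V_max/K_M` is then
identified — the Fisher information for the pair degenerates). Bound/free
fold-change tables flag a ratio "NS" when its ~95% interval (log-normal
error propagation) includes 1; the underlying study reports NS calls
without a stated test, so this is a deliberate, conservative convention.

## Stoichiometry optimization

Two consecutive rounds of coordinate search over copies-per-NP ratios:
round 1 sweeps multiplicative factors ×½, ×1, ×2, ×4 per enzyme; round 2
refines with ×0.75–×1.5. Sweeps repeat within a round until no move
improves the objective (default: monitored-species displacement at
30,000 s, simulated; negative analytic τ is available). The incumbent is
kept, so the objective is non-decreasing across rounds; ties break toward
the smallest total enzyme concentration. A candidate exceeding the optional
concentration budget is projected back onto the budget simplex (uniform
rescale, clipped to bounds) so the search can move along the constraint.

A caution from the toy analysis: the textbook "rate-matching" optimum
V₁ = V₂ holds for a budgeted two-step cascade only when the two rates have
equal marginal cost (equal kcat) — in the general saturated case the
finite-horizon optimum overdrives the first step, because a slightly
supersaturated downstream step trades a small standing intermediate pool
for a much shorter lag. The optimizer is therefore validated against an
exhaustive grid oracle rather than against that folklore closed form.

## Cluster assembly

* **Poisson loading:** copies of one enzyme per NP at mean stoichiometry r
  follow Poisson(r), truncated at the particle's site budget and
  renormalized.
* **Capacity:** an enzyme's footprint is a disc of radius
  `0.066·(oligomer MW in Da)^{1/3}` nm (the standard minimal protein
  radius). Spheres offer the shell at contact radius `4π(R+r)²`; platelets
  their two large faces. Square packing gives the minimum, hexagonal the
  maximum. This reproduces, e.g., 7–9 phosphofructokinase tetramers on a
  4 nm QD against the tabulated estimate of 5–9.
* **Aggregation:** enzymes first adsorb at Langmuir equilibrium with
  Kd = 1 nM (the His6–ZnS affinity), which fixes the occupied/free site
  split; at high protein/NP ratios surfaces are nearly saturated and
  bridging is suppressed. Clusters then coagulate by a thinned Gillespie
  scheme with the Brownian kernel `K(i,j) = (r_i+r_j)(1/r_i+1/r_j)`,
  `r ∝ size^{1/3}`, a ×2 collision factor for platelets, in a volume set
  by the particle concentration, halting at a fixed dimensionless assembly
  time (`sim_time = 0.15`) that leaves aggregation partial, as a finite
  incubation does. A merge consumes one spare His6 terminus on the donor
  (so monomeric linkers can never bridge) and one free site on the
  acceptor; NP count is conserved exactly.

Only orderings and monotone trends are asserted against the cluster-size
observations: simulated means rise from ≈ 1.0 to ≈ 9 NPs/cluster across a
0.63→25 nM particle sweep at fixed enzyme, and high protein/NP ratios give
smaller clusters than low ones. Absolute TEM cluster sizes are
experimental, depend on grid deposition, and are deliberately not
calibrated.

## Synthetic data

The generators emulate the study's raw data: 340 nm NADH absorbance
sampled every 60 s with additive Gaussian read noise (σ = 0.002 AU),
triplicate Michaelis–Menten titrations spanning 0.2–5× K_M with 5%
multiplicative rate noise, and closed-form lag curves
`P(t) = v_ss(t − τ(1 − e^{−t/τ}))` with exactly known τ. They do **not**
emulate pipetting/evaporation drift, temperature gradients across plates,
enzyme inactivation over multi-day runs, or NP scattering baselines —
passing recovery tests on these synthetics demonstrates estimator
correctness under the stated noise model, not robustness to every artifact
of real plate data.

## Known limitations

* No spatial reaction–diffusion model of clusters: channeling enters only
  through the regime criterion and the bound-vs-free kinetic contexts, as
  there is no mechanistic channeling rate law to implement.
* No temperature or pH dependence of rates.
* The aggregation simulator's absolute scales (particles per nM, assembly
  time) are simulation conveniences; only their relative trends are
  meaningful.
* Thermodynamic profiling covers the two steps with tabulated reaction
  energies (GPD +15.9, PGK −20.2 kJ/mol); unknown values are reported as
  unknown, never imputed.
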