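# nanocascade

Kinetic modelling and data analysis for multienzyme cascades self-assembled
on nanoparticle scaffolds.

When sequential enzymes of a pathway (here: saccharification plus oxidative
glycolysis, glucose → 3-phosphoglycerate and onward to lactate) are
clustered on quantum dots or nanoplatelets by their multivalent His6 tags,
the cascade can access *substrate channeling*: intermediates are consumed
by the next enzyme before diffusing into bulk, collapsing the lag phase of
the coupled reaction. The experimental signature is the **transient time**
τ — the x-intercept of the late-time linear portion of a progress curve —
which for a Michaelis–Menten cascade with N intermediate-consuming steps is

    τ = Σ_j K_M,j / (V_j − v₀),        V_j = kcat_j · n_j · [E_j]

with v₀ the first enzyme's velocity; in the strong-channeling limit τ → 0.
Channeling is observable only in the diffusion-limited regime, where the
catalytic rate exceeds the encounter scale min([E],[I])^⅔·D.

The package provides, as composable library modules plus a thin CLI:

* `cascade` — pathway presets (4E, 7E, 8E, 9E, 10E) with explicit
  stoichiometry and cofactor mass balance, simulated as stiff ODEs with
  irreversible Michaelis–Menten rate laws; branch competitors (glucose
  oxidase) and per-step thermodynamic profiling with bottleneck flags.
* `progress` — Beer–Lambert conversion of 340 nm NADH absorbance, initial
  rates from early linear windows, Michaelis–Menten fitting (`lmfit`), and
  bound/free fold-enhancement tables with NS flags.
* `transient` — analytic τ, empirical τ by regression x-intercept with a
  principled linear-region detector, and the diffusion-limited-regime check.
* `optimize` — two-round coordinate optimization of enzyme copies per
  nanoparticle under capacity and budget constraints.
* `clusters` — Poisson loading statistics, geometric packing capacity per
  nanoparticle, and a stochastic Brownian-kernel aggregation simulator for
  cluster-size distributions.
* `synth` — synthetic plate-reader data with known ground truth for every
  stage.

A packaged enzyme table (`src/nanocascade/data/enzymes.toml`) carries the
apparent kinetic constants of all 14 enzymes, free and on-particle, their
oligomeric states, and per-nanoparticle assembly capacities.

## Worked example

Simulate the seven-enzyme glucose → 3-PG cascade with free-enzyme
constants at the fixed assay concentrations and estimate its transient
time:

```python
import nanocascade as nc

spec = nc.build_cascade("7E")
cond = nc.assay_conditions("7E")          # 10 mM glucose, 1.13 mM NAD+, 16 h
res = nc.simulate(spec, cond, nc.FIG_RATIO_CONCS_7E)   # Glk 5.5 ... PGK 7.5 nM

curve = nc.ProgressCurve(res.time, res.monitored(), "concentration", "7E free")
est = nc.tau_empirical(curve)
print(f"tau = {est.tau:.0f} +/- {est.tau_stderr:.0f} s")
print(f"v_ss = {est.v_ss*1e3:.1f} nM/s, window = {est.window}")
print(f"final NADH = {res.monitored()[-1]:.0f} uM")
```

prints

```
tau = 11350 +/- 56 s
v_ss = 45.9 nM/s, window = (24000.0, 36780.0)
final NADH = 1130 uM
```

i.e. freely diffusing enzymes at low-nM concentrations need ~3 hours to
reach steady-state NADH flux (~46 nM/s over the fitted window), and the
reaction finally exhausts the 1.13 mM NAD+ pool. The analytic per-step
decomposition shows where the lag lives — in the high-K_M steps:

```python
per_step, total, v0 = nc.tau_analytic(spec, nc.FIG_RATIO_CONCS_7E, 10_000.0)
# [('PGI', 80), ('PFK', 603), ('FBA', 1604), ('TPI', 4776),
#  ('GPD', 11019), ('PGK', 9771)]  -> total ~27,900 s
```

(The asymptotic sum exceeds the finite-window x-intercept because the slow
GPD/PGK pools have not fully converged within the 16 h assay; see
`docs/methods.md`.) A channeled cascade — simulated with the on-particle
("bound") kinetic context, or measured on real clusters — shows a much
smaller τ.

The same workflow runs from the shell:

```
nanocascade report --out-dir out/          # simulate 7E + tau, JSON summary
nanocascade synth --kind lag --tau 2520 --sigma 0.002 --out lag.csv
nanocascade tau --curves lag.csv --out tau.csv
nanocascade optimize --preset 7E --np-conc 6.25 --out ratios.csv
nanocascade aggregate --np-conc 25 --seed 1 --out clusters.csv
```

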