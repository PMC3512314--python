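# pullwork

Free-energy bounds from steered-pull nonequilibrium work.

`pullwork` is a small Python library for analysing constant-velocity,
harmonic-spring pulling experiments of the kind used to rip a ligand out of
its receptor binding pocket (steered MD / AFM-style pulling). It turns
replica sets of pull trajectories — time series of spring-end position,
pulled-group centre-of-mass position and applied force — into mechanical
work distributions, and from them computes upper bounds on the unbinding
free energy. The motivating application is ligand unbinding such as
acetylsalicylic acid (aspirin) leaving human serum albumin, where the
experimental affinity constant gives an independent free-energy reference.

## The estimators

For N_s replica pulls with terminal works W_i (at a fixed production cutoff
of the pull coordinate), the package computes the two classical bounds:

* the plain average, `W^a = (1/N_s) Σ W_i`,
* the finite-sampling Jarzynski estimator,
  `W^x = −kBT · ln[(1/N_s) Σ exp(−W_i/kBT)]`,

which satisfy, in expectation, `ΔG ≤ ⟨⟨W^x⟩⟩ ≤ ⟨⟨W^a⟩⟩` — the Jarzynski
identity `⟨e^(−W/kBT)⟩ = e^(−ΔG/kBT)` makes `W^x` a consistent, sharper
upper bound on the free-energy change that converges to ΔG as N_s → ∞.
Around the estimators the library provides:

* a synthetic steered-pull generator (overdamped Langevin particle dragged
  by a moving harmonic spring out of a model binding well), with the exact
  ΔG available by quadrature — an oracle to validate the whole chain;
* XVG (xmgrace pull-dialect) readers/writers and replica-set pairing;
* trapezoidal work integration in both the control-parameter and
  centre-of-mass-path conventions;
* seeded bootstrap errors, viscous (solvent-drag baseline) correction with
  quadrature error propagation, and `ΔG = kBT ln Ka` affinity conversion;
* replica-averaged force profiles, the error-bar-crossing convergence
  criterion with doubled production cutoff, binding-pocket-plane region
  partitioning, and work-histogram population summaries;
* a one-config pipeline (`run_pipeline`) plus a thin `pullwork` CLI.

## Worked example

`examples/01_pull_and_estimate.py` simulates the default experiment —
30 replicas pulled out of a 14 kBT Gaussian well at v = 2.5 over a
spring-end travel of 5 (reduced units, kBT = 1), plus a flat-potential
viscous control — and prints:

```
protocol: k = 10, v = 2.5, travel = 5 (reduced units, kBT = 1)
bound:     W^a =  32.52 ± 0.98 kBT,  W^x =  25.87 ± 0.73 kBT   (N_s = 30)
viscous:   W^a =  12.83 ± 0.76 kBT,  W^x =   6.92 ± 1.47 kBT
corrected: W^x =  18.95 ± 1.64 kBT
exact dG (quadrature oracle) = 13.22 kBT
ordering dG <= W^x <= W^a: True (margins 12.65 and 6.65 kBT)
```

Reading: the pull is strongly dissipative, so the plain average `W^a`
overshoots the true free-energy change by ~19 kBT; the Jarzynski estimator
`W^x` recovers a much tighter bound, and subtracting the viscous baseline
tightens it further, while the exact quadrature ΔG stays below both — the
ordering the theory guarantees in expectation. The other examples cover the
affinity conversion and viscous-correction arithmetic for the HSA–aspirin
numbers (`02`), force-profile convergence diagnostics and work histograms
(`03`), and the XVG round trip (`04`).

The same analysis runs from a config file:

```sh
pullwork run --config run.json --outdir out/ --seed 1
pullwork affinity --ka 18790 --temperature 300
```

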