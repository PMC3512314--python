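# Methods

## Model and estimators

The analysis chain targets constant-velocity, harmonic-spring pulling: a
control parameter z(t) = z0 + v·t drags a pulled group through a spring of
stiffness k, and the mechanical work accumulated along each replica is the
input to free-energy estimation. Two work conventions are implemented. The
*control-parameter* convention integrates the spring force component along
the pull axis against z(t); this is the work conjugate to the schedule, for
which the Jarzynski identity ⟨e^(−W/kBT)⟩ = e^(−ΔG/kBT) is exact. The
*com-path* convention integrates each force component against the matching
centre-of-mass position component, which is how pull records are usually
plotted; for stiff springs the two agree to O(γv·F̄/k), and the gap shrinks
monotonically with k. The control-parameter convention is the default.

From the N_s terminal works at a production cutoff the package computes the
plain average W^a and the finite-sampling Jarzynski estimator
W^x = −kBT·ln[(1/N_s)Σ e^(−W_i/kBT)], evaluated as a shifted log-sum-exp so
that works of arbitrary magnitude in kBT neither underflow nor overflow.
Per sample, W^x ≤ W^a with equality only for constant works (Jensen); in
expectation ΔG ≤ ⟨⟨W^x⟩⟩ ≤ ⟨⟨W^a⟩⟩. The per-experiment statement
ΔG ≤ W^x is *not* an identity — a finite sample can dip below ΔG — so the
ordering check asserts Jensen unconditionally but reports the ΔG bound as a
statistical statement.

Uncertainties: seeded bootstrap (B = 1000 by default) is the primary error
bar for both estimators, with SD/√N_s kept as the naive cross-check for
W^a and a delta-method linearisation for W^x. The bootstrap is the
defensible default for the nonlinear W^x, whose sampling distribution is
left-skewed. The viscous correction subtracts the flat-potential (solvent
drag only) estimate from the bound one, propagating errors in quadrature;
raw values are retained and display rounding to the coarser input precision
is a separate presentation step.

The affinity conversion ΔG = kBT·ln(Ka·c°) uses a 1 M standard
concentration inside the logarithm and follows the positive-magnitude
convention for the unbinding comparison (the binding free energy proper is
the negative of this value). The same convention governs the quadrature
oracle below: ΔG is the free-energy *cost* of extraction, positive for a
binding well. A consequence worth noting: for a flat potential, confining
the particle to a reference interval twice the bound length yields
−kBT·ln 2 (an entropic gain), not a positive cost.

## The synthetic generator

The generator emulates the statistical structure of a solvated pulling
experiment with the minimal model that still admits an exact answer: one
overdamped Langevin degree of freedom,

    γ dx = [−U'(x) + k(z(t) − x)] dt + √(2γkBT) dW,

integrated by Euler–Maruyama. A hard stability guard requires
dt·(k + max|U''|)/γ < 0.1; first-order integration is sufficient because
every acceptance-facing quantity is statistical and dt sits well inside the
guard. U is a Gaussian well (binding pocket), a double well, or identically
zero (the viscous control). In 3-D mode the pull runs along a configurable
unit axis (the axis construction from a ligand COM and a three-point
centroid is provided); off-axis components feel only the spring's
transverse restoring force.

Initial conditions are drawn from the equilibrium distribution of the
extended Hamiltonian H(x; z0) = U(x) + k/2(x − z0)² by exact inverse-CDF
sampling — the Jarzynski identity presumes an equilibrium start, and a
deterministic start measurably biases the work distribution. At T = 0 the
dynamics is deterministic and starts at the configured x0. Every replica
owns a generator seeded `[config.seed, replica_seed]` and pre-draws its
noise in fixed-size chunks, so a replica is bit-identical whether simulated
alone or inside a vectorised batch.

Two exact oracles accompany the generator. `analytic_delta_g` integrates
e^(−U/kBT) over a bound and a reference interval by adaptive quadrature
(relative accuracy 1e-8, shift-stabilised against deep wells).
`analytic_pull_delta_g` does the same for the extended Hamiltonian at the
initial and final spring positions; this is the exact target the work
conjugate to z(t) converges to in the quasistatic limit and is the
reference used in the ordering and convergence studies (verified directly:
at v = 0.05 the estimator lands within ~0.1 kBT of it).

### Reference scenario and what it does (not) show

Defaults, in reduced units (kB = 1, T = 1, γ = 1): well depth ε = 14 kBT,
width σ = 0.6, spring k = 10, pull rate v = 2.5, duration ts = 2 (travel
v·ts = 5), dt = 5e-4, 30 replicas — a scaled-down analogue of a 30-replica,
0.01 nm/ps × 500 ps protocol with a k = 1000 kJ/(mol·nm²) spring at 300 K.
The exact ΔG of the reference pull is 13.22 kBT.

Three considerations fix this point, chosen once:

* *Regime fidelity.* Real pocket-extraction pulls at these rates are
  strongly dissipative (mean work a multiple of ΔG); the defaults give
  W^a ≈ 2.4 ΔG with pocket forces, not solvent drag, dominating.
* *Population separation.* The bound and viscous terminal-work
  distributions must be distinguishable (standardised mean difference
  ≈ 3–4, Gaussian overlap ≈ 0.05–0.1 here), which bounds the drag work
  γvL from above relative to the well contribution.
* *Estimator statistics.* The per-experiment bound ΔG ≤ W^x at N_s = 30 is
  reliable only when dissipation dominates the work fluctuations — in the
  quasistatic limit W^x fluctuates symmetrically about ΔG and the
  one-sided bound fails half the time by construction. The defaults put
  the 30-pull failure probability at the percent level.

The spring is deliberately soft (k = 10): a single Langevin particle's
thermal force noise scales as √(k·kBT), and a stiff spring buries the well
force under noise, washing out the force-profile structure the convergence
diagnostics read. At k = 10 the bound and viscous |F| profiles separate
while the particle escapes (displacement ≈ 1–2.6) and merge afterwards.

What passing on this system shows: the estimators, the work integration,
the convergence/partition/histogram operators and the pipeline behave
correctly on data with the right statistical anatomy (equilibrium starts,
harmonic-spring force records, right-skew-free near-Gaussian work
populations, a dissipation-dominated regime). What it cannot show: anything
about force-field accuracy, solvent structure, pull-path optimality or
multidimensional pocket topography — the generator has one slow degree of
freedom and a memoryless thermostat, and real pull records bring slower
orthogonal relaxation and path-dependent dissipation that no 1-D model
reproduces.

## Profile analysis choices

Force profiles pool |F| across replicas into displacement bins (default
width: travel/100) and report per-bin mean and SD (ddof = 1). "Error bars
cross" is operationalised as overlap of the mean ± m·SD intervals
(multiplier configurable, default 1) sustained for `m_consecutive` bins
(default 3), searched *after* the first bin at which the profiles are
separated; profiles that never separate cross at the first bin. The search
offset matters for thermal single-particle records, where both force
distributions coincide for a short unloaded transient before the spring
engages — a literal "first sustained overlap" would fire there. The
production cutoff is twice the crossing displacement, clamped to the
available travel.

Histogram overlays are moment-matched Gaussians (sample mean and SD, not a
fit); separation is reported as the standardised mean difference
|μ₁ − μ₂|/√((σ₁² + σ₂²)/2) plus the Gaussian overlap coefficient
∫min(φ₁, φ₂) (closed form 2Φ(−|Δμ|/2σ) at equal widths, quadrature
otherwise). The binding-pocket plane's normal is oriented by positive
projection onto the pull direction, making "crossing" sign-unambiguous; a
sample exactly on the plane counts as crossed.

## Numerical and I/O details

* Internal energies are kept in kBT; joules and kJ/mol appear only at the
  I/O boundary (the gromacs↔SI conversion lives at one declared point and
  is involutive to 1e-12).
* XVG output uses a fixed header order and 17-significant-digit floats, so
  writes are bit-identical and read→write→read is the identity.
* Duplicate time stamps on read (checkpoint-restart concatenation) keep the
  first occurrence with a warning; comma decimal separators are rejected
  rather than locale-guessed.
* Work integration is trapezoidal (exact for linear integrands, standard on
  non-uniform grids); local backtracking of the pulled point is kept signed
  — rectification would bias work upward. Cutoff evaluation interpolates
  linearly between bracketing samples and is exact on grid points.
* Bootstrap, simulation and pipeline seeds are all explicit and recorded in
  the run manifest; identical config + seed reproduces every number.

## Known limitations

Single reaction coordinate; no bidirectional (forward/reverse) estimators
or cumulant expansions; no stiff-spring second-order corrections; the
viscous control assumes the drag coefficient is unchanged by removing the
receptor; the error-bar-crossing criterion inherits the arbitrariness of
its SD multiplier and run length, which are exposed as parameters rather
than resolved. Validation study sizes (100 × 30 pulls for the ordering
study, 20–30 replicas per rate for convergence) were chosen as the smallest
that give stable percent-level statistics for the properties under test.
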