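# Methods

## Reduced units

All theory quantities are dimensionless: lengths in segment lengths σ,
forces in k_BT/σ, time in ησ²/k_BT and friction in units of the solvent
friction per monomer η.  The MD engine works in LJ units (ε = σ = m = 1,
k_BT = 1.2); conversions live in `units_mapping` and
`MDConfig.time_unit` / `MDConfig.dimensionless_force`.  Note that the
product f̃·w̃ that enters the friction inversion equals f·w/(ησ)
regardless of whether the reduced units are built on k_BT or on ε, so
extracted friction values do not depend on that choice.

## Chain statistics (`chain_model`)

The interpolation formula for R̃N is evaluated in the algebraically
equivalent form R̃N² = R̃F²·g(x) + 2ℓ̃pN·g(y) with
g(z) = 1 − (1 − e^{−z})/z.  `g` and the derivative bracket in G are
computed with `expm1` and switch to cubic Taylor series below z = 1e-4:
the rod limit R̃N → N relies on cancellation to second order in z, and
the series form preserves it to machine precision.  Contour length is a
positive real throughout (the front ODE needs non-integer N).  Regime
boundaries (N/ℓ̃p = 4 and 400) are classification defaults only — the
formula itself is evaluated identically everywhere.

Two properties of the formula worth knowing:

* the approach of d ln R̃N/d ln N to the Flory exponent ν = 0.588 is
  very slow — the Gaussian term decays only as N^{−0.176}, so the local
  slope is ≈ 0.575 at N = 10¹² and reaches ν only near N ~ 10³⁰.
  Consequently the rescaled translocation exponent at N₀ = 10¹⁰ is
  ≈ 1.562, approaching its 1 + ν = 1.588 asymptote from below.
* the rod bound R̃N/N ≥ 0.999 at N/ℓ̃p < 1e-4 holds for moderate N;
  the excluded-volume exponential argument grows as N^{0.42}/ℓ̃p^{0.4},
  so very long chains need disproportionately large ℓ̃p.

## Tension-propagation solver (`iftp_solver`)

`solve` integrates the (s̃, R̃) system in time with an adaptive RK45
(rtol 1e-8, atol 1e-10 defaults) and event-based stage switching:
TP → PP when Ñ = R̃ + s̃ reaches N₀, termination at s̃ = N₀.  The
initial state has `n_init = 1` bead under tension (R̃(0) = R̃N(1)),
which avoids the R̃ = 0 singularity; τ̃ is insensitive (< 0.2%) to
n_init ∈ [0.5, 2].  When the TP denominator 2R̃ − (G + H) falls below
1e-9 × 2R̃ the front is propagated instantaneously (rod-like chains).
Waiting times are crossing-time differences of integer s̃ obtained by
root-finding on the dense ODE output.

`closed_form_tau` evaluates the quadrature expression with adaptive
Gauss–Kronrod integration; it is an independent code path used to
cross-check `solve` (they agree to ~1e-5 relative; the test suite
enforces 1% on a (ℓ̃p, N₀) grid).  Under the s-only friction model the
TP/PP friction-difference correction term vanishes identically; the
residual it would capture is precisely the measured solve-vs-closed-form
gap.

The tension-front profile R̃(s̃) is friction-independent: during TP it
solves s̃ = N − R̃N(N) on the equilibrium manifold (inverted by
bisection), after which R̃ = N₀ − s̃.  This is what makes waiting-time
inversion of MD data well-posed.

## Trans-side friction (`trans_friction`)

The three-regime model (growth c₁·R̃x, plateau η_sat, exponential decay
to η_inf with scale λ) is continuous at both breakpoints by
construction; s₁ is derived from continuity, never stored.  The default
growth mode is linear in s̃ (a stiff trans segment aligned with the
drive, R̃x ≈ s̃); this choice also makes the rigid-rod special case
η̃TS(s̃) = s̃ reproduce the closed-form rod translocation time
(η̃pN₀ + N₀²)/f̃ exactly.  A `chain_model_rx` mode using the
equilibrium end-to-end distance of the trans segment is provided.

The shipped reference calibration (`data/reference_friction.json`) keeps
the published friction levels η_sat = 10.63 and η_inf = 5.5 for the
reference case (N₀ = 64, κ_b = 30, f = 20) and takes the breakpoints
and decay scale from this package's own 200-run MD extraction (buckling
onset s₁ ≈ 30, decay onset s₂ = 41, λ = 9.8); the raw extracted trace
ships alongside as `data/reference_trace_md.csv`.  Note that our own
extraction plateaus near 7 rather than 10.63 (see "Known limitations"),
so a least-squares fit with the published levels pinned is degenerate —
the hybrid above is an explicit design choice, not a fit result.

## MD engine (`md_engine`)

Kremer–Grest-style bead-spring chain: WCA excluded volume between all
bead pairs and against 16 static pore beads (circle of diameter 3σ at
x = 0), FENE bonds (k = 30, R₀ = 1.5σ; equilibrium bond length
b₀ ≈ 0.961σ), bending penalty κ_b(1 − cos θ), and a 9-3 wall on |x|
truncated and shifted at its minimum 3^{1/6}σ so it is purely
repulsive.  The wall is felt by beads radially outside the pore-bead
circle (ρ > 1.5σ); inside that lumen the pore beads themselves gate
passage (a bead cannot reach the exemption boundary at small |x|
without a large WCA penalty, so the boundary discontinuity is
energetically irrelevant).  The driving force acts on beads with
|x| ≤ σ/2 (pore thickness σ, membership by half-thickness).

Integration is BAOAB: velocity half-kick, half-drift, exact
Ornstein–Uhlenbeck velocity refresh with variance (1 − e^{−2γΔt})k_BT/m
(the discrete realization of the ⟨ξξ'⟩ = 2ηk_BT δ fluctuation–
dissipation relation), half-drift, half-kick; Δt = 0.005 LJ time.
Equipartition holds to a few per mil at this step.  A FENE bond at or
beyond R₀ aborts the run naming the bond (the signature of a too-large
step).  Randomness comes from a per-run seed; identical seeds give
bit-identical trajectories.

Initial states are drawn from a discrete worm-like-chain sampler whose
bond angles follow the exact Boltzmann weight of the bending potential
(overlaps below 0.9σ rejected), so replicas start inside the
equilibrium ensemble and short MD relaxations suffice; the
translocation protocol tethers the head bead at the pore center with a
stiff spring (200 ε/σ²) during a drive-off equilibration of 10⁵ steps,
then releases it and switches the drive on.  Chains that retract fully
to the cis side trigger a restart from a fresh configuration.  The
trans-side bead count is last-passage filtered, so recrossings are not
double counted; first-passage times are also recorded (the two agree
closely at f = 20).

Measurement conventions: the theory's segment is identified with the
mean bond length, so MD distances are divided by b₀ and an N-bead chain
counts N − 1 segments.  With this convention the free-chain
⟨R_ee²⟩^{1/2} at κ_b = 30 matches the interpolation formula within ~3%
for N = 16–64.

### Pore-friction calibration

η̃p is the theory's one free parameter.  The head bead starts inside
the pore, so its waiting time carries no drag information, and the
first few beads carry a flux-establishment transient; intercept-style
estimates from the small-s̃ region are therefore unstable.  The default
calibration instead runs a fully flexible (κ_b = 0) control ensemble —
for flexible chains the trans-side drag is absorbable into the pore
term — and averages f̃w̃(s̃) − R̃(s̃) over interior beads, with the
flexible front profile built from an effective persistence length
matched to the measured flexible-chain end-to-end distance (≈ 0.8
segments).  This yields η̃p ≈ 5 ± 0.5 for the reference pore geometry.

## Scaling analysis (`scaling_analysis`)

τ(N₀) scans use the closed form by default (usable to astronomical
N₀); effective exponents are ordinary least-squares slopes over three
consecutive (ln N₀, ln τ) points attached to the middle N₀.  The pore
coefficient a_p = η̃p/f̃ is taken exactly from the closed form, never
refit.  Extending the N₀ = 64 friction calibration across a scan is the
single largest modeling judgment in the package: the default policy
scales the decay breakpoint s₂ proportionally with N₀ (fixed buckled
fraction) while keeping c₁, η_sat, η_inf and λ fixed — which, by
continuity, keeps the growth/plateau breakpoint at η_sat/c₁.  Nothing
in the theory pins this dependence; the policy is a caller-replaceable
strategy object.

## What the synthetic data do and do not emulate

The MD engine *is* the validation data source: equilibrium chain sizes,
translocation times, waiting times and friction traces are generated by
it, not loaded from files.  It emulates a driven, coarse-grained,
implicit-solvent chain without hydrodynamic interactions, electrolyte
screening or membrane elasticity; agreement of the IFTP theory with it
therefore says nothing about those effects in real nanopore
experiments.  The experiment-comparison workflow (`map_experiment`)
fits a single global time factor in log space, so it tests only the
*scaling* of dwell times with length, not absolute times.

## Known limitations

* The trans-side friction extracted by this package's MD pipeline
  reproduces the three-regime structure qualitatively (growth, broad
  maximum near s̃ ≈ 30–41, settling toward a terminal value) but its
  levels — plateau ≈ 7, terminal ≈ 6 with the flexible-control η̃p —
  sit below the published reference values 10.63 and 5.5.  The
  inversion is ill-conditioned: at the plateau the trans term is ~15%
  of Γ̃, so ~10% differences in waiting times or in the η̃p split move
  the extracted level by ~30%.  The original extraction procedure
  (binning, smoothing, pore-friction calibration) is not described in
  the sources available to this package, and no parameter here was
  adjusted to force agreement.
* The deterministic strong-stretching theory omits thermal fluctuations
  of the translocation coordinate and the trumpet/stem-flower regimes;
  it is quantitative only for strong driving.
* The interpolation formula does not recover the perturbative
  small-excluded-volume limit, and its approach to the asymptotic
  excluded-volume exponent is extremely slow (see above).
* The voltage mapping (f = 10 ↔ ~221 mV from the printed constants,
  conventionally rounded to 200 mV) is approximate at the ~10% level
  and is flagged as such in the API.
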