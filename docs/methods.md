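# Methods

This note records the modelling conventions, numerical choices and known
limitations behind `semiflex`.  Everything quantitative stated here is
recomputed by the test suite or by `scripts/acceptance.py`; nothing is
asserted from memory.

## Worm-like chain

The chain is parameterized by arc length `s`; in 2D a configuration is
the tangent-angle field `θ(s)` and the bending energy is
`(B/2)∫(θ′)² ds`, giving Gaussian independent increments with
`var(δθ) = δs/ℓ`, `ℓ = B/kT`.  This convention reproduces
`C(s) = e^{−s/2ℓ}` exactly in 2D; the 3D correlation decays twice as
fast because two transverse directions decorrelate the tangent.  The
factor-2 difference between conventions is easy to get wrong, so it is
pinned by unit tests at `s = 2ℓ` (2D) and `s = ℓ` (3D).

`Re²` and `Rg²` follow from the double integrals of `C`; the closed
forms are evaluated with `expm1` and a Taylor branch (`S/2ℓ < 10⁻²`) so
the rod limit `Re² → S²`, `Rg² → S²/12` is reached without cancellation.
The same routines accept complex decay lengths — the arc/arc model
needs them.

**Discrete sampler.**  Chains are sampled with fixed step `b`, bond
angles cumulated from Gaussian increments, first bond along the x-axis.
Angles belong to bonds (mid-segment convention); bond–bond correlations
are measured at integer multiples of `b`.  The squared radius of
gyration of a sampled chain uses trapezoidal (arc-length) node weights:
plain node averaging overweights the two chain ends — the nodes farthest
from the centroid — by `O(1/N)`, a ~2% bias at `N = 100` that the
weighted estimator removes.

**Persistence-length estimator.**  Least squares on `log C(s)` over
`s ∈ [b, min(ℓ_guess, S/4)]`, with `ℓ_guess` from the first `1/e`
crossing (falling back to `S/4` for chains too short to cross).
Non-positive correlations shrink the window with a warning; a
non-negative fitted slope returns `ℓ = ∞` with the flag `"rigid"`.
Recovery is within 3% at 10⁴ chains for `ℓ/b ∈ {5, 10, 50}` and within
5% in the stiff short-chain regime (`ℓ = 100b`, `S = 50b`).

## Squeezed helix

Planar confinement couples curvature to twist: `κ(s) = ω₁ sin ψ(s)` and
`ψ″ + (Bω₁²/2C) sin 2ψ = 0`.  The bulk revolving solutions are
`ψ = am(s/λ | m)` in the **parameter** convention of the elliptic
integrals (`E(0) = π/2`, `E(1) = 1`); the modulus-vs-parameter ambiguity
is fixed by the anchor `m = 1` at `γ = 1` and unit-tested.  The kink
width `λ = sqrt(mC/B)/ω₁` is pinned uniquely by requiring the amplitude
profile to satisfy the pendulum equation; that residual is checked
spectrally (the profile is linear-plus-periodic, so the periodic part is
differentiated by FFT over exactly one period) to below 10⁻⁶.  For
`m = 1` the amplitude degenerates to the gudermannian kink
`ψ = 2 arctan(e^{s/λ}) − π/2`, the only closed form consistent with
`ψ(0) = 0` and `ψ(±∞) = ±π/2`.

**Selection rule.**  The energy-density minimum satisfies `m E(m) = γ`
with `γ = 4ω₁²B/(π²ω₃²C)`.  Numerically `m E(m)` is *not* strictly
monotone on `(0,1]`: it peaks at ≈1.0087 near `m ≈ 0.966` before
returning to 1.  For `γ < 1` the crossing on the rising branch is unique
and found by bracketed bisection to 10⁻¹²; `γ = 1` is returned as the
homoclinic `m = 1` exactly; `γ > 1` yields the circular ground state.
A consequence worth knowing: as `γ → 1⁻` the selected `m` tends to the
rising-branch root of `m E(m) = 1` (≈0.91), not continuously to 1 — the
often-quoted approximation `m ≈ γ` near threshold is rough.

**Dense/dilute boundary.**  Kinks separate curvature plateaus only while
the half-period of the amplitude, `2K(m)` in scaled units, exceeds the
soliton core (≈4 scaled units, the span over which the homoclinic kink
completes most of its swing).  A literal "spacing = width" criterion is
unattainable — the spacing is `2K(m)λ ≥ πλ` by construction — so the
plateau-existence criterion `2K(m) = 4` defines the threshold,
`γ_dense = m_c E(m_c) ≈ 0.82`.  It classifies the reference cases
`γ = 0.997` (dilute) and `γ = 0.52` (dense) correctly.

Finite-length boundary conditions are not solved; profiles are the bulk
solution truncated to `[−L/2, L/2]`.  Oscillating-pendulum (`m > 1`)
branches are excluded as ground states.

## Arc/arc twist-kink gas

Kinks are pointlike, non-interacting, Poisson with mean
`⟨k⟩ = (S/b)e^{−E}`; arcs carry curvature `±ω` and flexural noise
factorizes into a Gaussian convolution of variance `S/ℓ`.

**Deflection distribution.**  The continuous part
`(⟨k⟩/2ωS) e^{−⟨k⟩}[I₀(z) + I₁(z)/w]`, `z = ⟨k⟩w`,
`w = sqrt(1 − (θ/ωS)²)`, plus atoms `e^{−⟨k⟩}/2` at `±ωS`.  The
removable `w → 0` singularity of the `I₁` term is evaluated by its limit
`⟨k⟩/2`.  Densities are stored as *cell averages* on a uniform grid,
integrated per cell in the variable `θ = ωS sin α` where the integrand
is smooth through the support edge; this keeps the normalization
`2·atom + ∫density = 1` to ~10⁻¹² where pointwise trapezoids stall at
~10⁻⁴ against the square-root edge.  The flexural convolution is a
discrete FFT convolution with an erf-integrated Gaussian kernel
(discrete mass exactly 1); the atoms convolve analytically into shifted
Gaussians.  Grids refine automatically until the Gaussian width spans
≥4 cells.

**Correlation and moments.**  `C(s) = A₁e^{−s/2ℓ₁} + A₂e^{−s/2ℓ₂}` with
`1/2ℓ_{1,2} = (e^{−E}/b)(1 ∓ sqrt(1 − ω²b²e^{2E})) + 1/2ℓ` and
`A_{1,2} = 1/2 ± 1/(2 sqrt(1 − ω²b²e^{2E}))`.  The bracket placement is
not assumed: it is the unique choice satisfying `C(0) = 1` and
`C′(0) = 0`, independently confirmed by the telegraph-process
derivation, and both limit reductions (`ω → 0` pure WLC; `E → ∞` damped
cosine) are asserted to 10⁻¹⁰.  `Re²`/`Rg²` apply the same linear
combination to the WLC closed forms at the complex `ℓ₁, ℓ₂`; imaginary
parts are asserted below 10⁻⁹ and discarded.  The transform-domain
partition function `Z(q,p) = (p + e^{−E})/(p² + q²ω²b² − e^{−2E})` is
cross-checked by numerical Laplace transform of its arc-length-domain
inverse.

**Samplers.**  The full-chain sampler draws kink count, positions and
initial sign, and integrates curvature with mid-segment bond angles
(second-order accurate positions).  The end-deflection sampler computes
`θ(S) = ±ω·(alternating arc sum) + Gaussian` directly — identical in law
and fast enough for 10⁶-sample Kolmogorov–Smirnov comparisons (observed
KS distance ≈ 10⁻³ against the gridded distribution).

## Adsorption and chemisorption

All scaling laws carry **unit prefactors** and are tested as
order-of-magnitude statements or as exponents; none is asserted exact.
Piecewise laws are continuous at their internal boundaries by
construction.

**Loop-exponent Monte Carlo.**  The measured object is the equilibrium
wall-contact probability of a grafted, wall-avoiding chain:
free chains are launched grazing from the wall, the hard wall is applied
by rejection (all node heights positive), and
`P(s) = Prob(height(s) < b | survival over the whole chain)`.
Conditioning on *future* survival is essential: it selects near-grazing
returns, which is precisely the orientational constraint that makes the
stiff-loop weight `s^{−5/2}` rather than the first-passage law
(`∼ s^{−5/4}`) that an unconditioned launched-trajectory count decays
with.  The estimator reproduces `−3/2` on a pure random walk (where that
value is exact) to three decimals.  Fit windows: stiff `[4b, ℓ]`;
flexible `[8ℓ, 0.8S]` with the known remainder-tail weight
`(S−s)^{−1/2}` divided out — the flexible asymptote needs `s ≫ ℓ`, and
at the reference condition (`ℓ = 10b`, `S = 250b`) the finite-chain
estimate centres near −1.42, approaching −3/2 from above as `S` grows.

**Proximal layer.**  The loop-height map `z = s^{3/2}/ℓ^{1/2}` converts
the stiff-loop mass distribution `Z_l(s)·s` into `c(z) ∝ z^{−4/3}`;
both a quadrature differentiation of the cumulative relation and an
inverse-CDF Monte-Carlo superposition reproduce the slope.

**Zipping kinetics.**  Gillespie competition with rates frozen between
events: zip steps of size `s₀` at rate `q s₀/b` versus nucleation at
rate `(q/b)∫P(s)ds`.  A nucleation event *preempts* single-front zipping
when the loop is flexible-scale and spans at least half the unzipped
remainder (`max(ℓ, R/2) < s < R`); smaller loops merely open extra local
zipping fronts and rejoin the same process.  Counting any `s > ℓ`
nucleation instead would tie the crossover to `ℓ^{4/3}` rather than the
correct `S* ∼ ℓ²/s₀ = ℓ^{5/3}b^{−2/3}` — the distant-loop hazard is
dominated by loops comparable to the remaining length.  Because the front
ladder is deterministic between events, the first preemption step is
sampled exactly by inverse CDF on the cumulative hazard.  The 50% point
sits within a factor 3 of `S*` at moderate stiffness (checked at
`ℓ/b = 50`); the pure `ℓ^{5/3}` exponent emerges on the stiff decade
`ℓ/b ∈ [10³, 10⁴]` (intermediate-filament to F-actin range) because the
prefactor carries slowly decaying `ℓ^{−1/3}` corrections from the onset
of the flexible-loop regime.

**Crossing statistics.**  `P(θ) = sin(θ)/2` on `(0, π)`; the alignment
probability doubles the small-angle cumulative by symmetry and is
evaluated from the exact cumulative, `1 − cos θ_max ≈ θ_max²/2` with
`θ_max = (b/ℓ)^{1/3}`.

## Bistability

The bundle energy `(1/2)∫[Bθ′² + K(θ − θ̄)²]ds` is minimized exactly on
a grid (KKT solve with the imposed-arc curvature and the gauge
`θ̄ = 0` as linear constraints).  The exponential screening of the
response over `λ = sqrt(B/K)` is recovered from the numerical minimizer
to within 2%, and the arc-energy regimes `l²` (below `λ`) and `l³`
(above) are continuous at `l = λ` with unit prefactors.

Tail-induced buckling: threshold `k_crit = 12B/d³`; the quoted
bistable-curvature amplitude uses a unit prefactor
`sqrt(1 − k_crit/k)/d`, while the Landau functional with constants
`C₁, C₂` (defaults 1, exposed) has its minimum at
`sqrt(C₁(1 − k_crit/k)/2C₂)/d` — both are provided and the
`sqrt(C₁/2C₂)` relation is unit-tested.  Domain walls are computed by
L-BFGS with analytic gradients on the `φ⁴`-type functional with ends
pinned at `∓κ*`; the wall is tanh-like and its width grows
monotonically with the hyper-stiffness `H` (default `k d⁵`).

## Polymorphic microtubule

The annulus is partitioned into `N` angular sectors (one per
protofilament, layer boundary at `R_m`); preferred strains are `ε_i > 0`
inside and `ε_o < 0` outside for switched sectors.  The elastic energy
is an exactly integrable quadratic form; the closed moment-based form is
cross-checked against tensor Gauss–Legendre quadrature (per-layer radial
× per-sector angular panels) to ~10⁻¹⁰ relative.  Curvature and stretch
decouple (`∫ρ⃗ dA = 0`), so minimization is a linear solve.

The polymorphic potential is *constructed*, not transcribed: for each
block angle `φ_p`, `e_el + e_switch + Fε̄ + Mκ` is minimized over
`(κ, ε̄)` and referenced to `φ_p = 0`.  In units of `Bκ₁²`
(`B = Y I_κ`) this construction is algebraically identical to

    V(φ_p) = −(c_p/2)φ_p² + f φ_p − m sin(φ_p/2) − (1/2) sin²(φ_p/2),

with `c_p = Y S₀′²/(A B κ₁²)` from the stretch frustration of partially
switched rings; the identity is asserted to 10⁻¹⁰ in the tests, and the
rescaled loads map to physical ones via `M = m Bκ₁` and a force chosen
so the total linear coefficient (external force + lattice strain terms +
`ΔG`-linear switching term) equals `f Bκ₁²`.  The sign of `κ₁` encodes
the bending direction; magnitudes are compared where direction is
irrelevant.

Block aggregation — a single contiguous block minimizes the energy at
fixed switched count — holds because the curvature reward maximizes
`|Σ_k e^{iφ_k}|²`; it is verified exhaustively for `N = 13` and up to 6
switched dimers.  Phase diagrams rank the straight-long (`φ_p = 0`),
curved (interior minimum, located by bounded refinement) and
straight-short (`φ_p = 2π`) states; hysteresis sweeps follow the nearest
local minimum under quasi-static changes of `f` and record discontinuous
jumps.

**Demo geometry.**  `demo_cross_section()` is a synthetic illustration:
radii 8.4 / 10.45 / 12.5 (microtubule-like, layer boundary midway),
strains `ε_i = 0.04`, `ε_o = −0.0692` chosen so the fully switched state
is 2% shorter and `|κ₁| ≈ (670 length units)⁻¹`, i.e. of order
(1 µm)⁻¹ for nanometre units.  It is not a fitted structure; all
geometry-dependent results are demonstrations, and the radii/strains are
ordinary user inputs.

## Polymer presets

Presets store literature `(ℓ, b)` pairs in nanometres.  Hyaluronan is
quoted with two persistence-length ranges; each ships as a preset at the
range midpoint (4.5 and 8.5 nm).  The quoted aspect ratio of PDADMAC
(5.3) is inconsistent with its own `ℓ/b = 3.0/0.47 ≈ 6.4` and is flagged
(`ratio_consistent=False`).  Regenerating the chemisorption table with
unit prefactors reproduces the quoted `s₀`/`S*` cells within 10% for all
presets except the PDADMAC and F-actin `S*` cells (36% and 28% off —
the sources of those two quoted numbers evidently used different
rounding or prefactors); those two are checked within a factor 1.5.

## What the Monte-Carlo oracles do and do not show

The samplers realize the *ideal* models: no excluded volume, no
multi-chain interactions, hard walls only, quasi-equilibrium
(reaction-limited) chemisorption kinetics.  Agreement between samplers
and closed forms validates the mathematics of those models, not their
applicability to any particular experiment.  Problem sizes in the
default test run (e.g. 6×10⁶ launched chains for the loop exponents,
10⁶ deflection samples, 400 kinetic runs per chain length) were chosen
so statistical error sits well below each stated tolerance.

## Known limitations

- Finite-length squeelix boundary layers and thermally activated
  `m > 1` branches are out of scope.
- The arc/arc model omits twist fluctuations beyond kink number and
  position, and the force response is linear only.
- Adsorption scaling laws are order-of-magnitude by construction; no
  prefactor should be quoted from this package.
- The zipping KMC treats sub-remainder nucleation as neutral; layer
  build-up with excluded volume between chains is not simulated.
- The microtubule model is a single-cross-section, single-block theory;
  lattice cooperativity along the filament axis is not included.
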