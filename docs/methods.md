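# Methods

## Scope and model

`compactmix` predicts the compactibility profile (tensile strength σ vs
porosity ε) of a multicomponent powder compact from the pure components'
Ryshkewitch–Duckworth (R–D) parameters and the mixture composition.

The physical picture: a tablet fails when interparticle contacts across the
fracture plane are separated. Contacts are grouped into *interaction
clusters* of n particles. Assuming random mixing of particles of similar
size and shape, cluster membership is a multinomial draw weighted by volume
fraction, and a cluster's strength is the geometric mean of its particles'
cohesive strengths (the Berthelot combining rule applied particle-wise;
a cluster of one material contributes that material's full cohesive
strength, mixed clusters contribute intermediate adhesive strengths). The
mixture strength is the probability-weighted expectation of cluster strength:

    σ_mix(ε) = Σ_k  n!/(Π k_j!) Π V_j^{k_j}  ·  Π σ_j(ε)^{k_j/n}

with σ_j(ε) each component's R–D strength evaluated at the *same* porosity
ε. This porosity matching is the load-bearing contract of
`predict_mixture_profile`: components are compared at equal consolidation,
never at equal pressure.

Useful identities, all property-tested:

- Multinomial theorem ⇒ σ_mix = (Σ_j V_j σ_j^{1/n})^n, the weighted power
  mean of exponent 1/n. Hence predictions are strictly decreasing in n for
  non-degenerate inputs, the linear rule (arithmetic mean) bounds above,
  the power law Π σ_j^{V_j} (geometric mean, n → ∞ limit) bounds below.
- Order 2 with arithmetic-mean adhesive strength collapses algebraically to
  the linear rule — the classical pairwise model.
- In an equal-parts binary mixture the purely cohesive cluster fraction is
  2·(1/2)^n: 50 % at order 2, 3.125 % (≈3 %) at order 6.

## Parameters and units

| quantity | units | default | meaning |
|---|---|---|---|
| σ₀ | MPa | fitted | zero-porosity tensile strength |
| k | – | fitted | bonding capacity (decay rate in ε) |
| n (order) | – | 4 | particles per interaction cluster |
| W, D, t | g, mm, mm | – | tablet weight, diameter, thickness |
| F | N | – | diametral failure force |
| ρ | g/cm³ | – | true (skeletal) density |

Units are fixed (g / mm / N / g·cm⁻³ → MPa), matching standard compaction
instrumentation; the mm³→cm³ conversion in the porosity formula is internal.
The default order n = 4 reflects that four-particle clusters consistently
give the most accurate mixture predictions and agree with observed
contacts-broken-per-particle counts in the pharmaceutically relevant
porosity range; it is exposed as a parameter everywhere.

## R–D fitting

`fit_rd` minimizes squared residuals in *linear* strength space
(`scipy.optimize.curve_fit`), initialized from ordinary least squares on
ln σ vs ε. Linear-space fitting avoids the log transform's overweighting of
weak, high-porosity tablets; the log-space estimate is retained as the
fallback carried by a fit-failure error. Zero-strength observations
(tablets that failed to form) are excluded from the fit and counted in the
profile's `n_excluded`; replicates are unweighted. Residuals are stored on
the profile so either fitting convention can be audited. At least three
points with positive strength and at least two distinct porosities are
required. Evaluating a fitted profile outside its fitted porosity window is
permitted — profiles are used on continuous ε ranges — but emits an
`ExtrapolationWarning`.

## Numerical choices

- Multinomial probabilities and geometric means are computed in log space;
  multinomial coefficients use exact integer arithmetic up to n = 20 and
  log-gamma beyond, so orders in the hundreds are evaluable.
- Cluster enumeration is over *compositions* of n into m parts
  (stars-and-bars, C(n+m−1, m−1) types); the exponential enumeration over
  all mⁿ ordered particle sequences lives only in the test suite, as the
  independent oracle the closed form must match (1e−12 relative).
- Zero-strength components: any cluster containing one contributes zero
  strength, and the power law returns 0 when such a component is present
  with V > 0. This is the continuous σ → 0 limit.
- Compositions are normalized exactly on construction; inputs whose
  fractions deviate from 1 by more than 1e−6 are rejected, not rescaled.
- Model ranking ties break toward the simpler model (classical one-formula
  rules, then lower cluster order).
- The large-order asymptote check (order 200 within 0.1 % of the power law)
  uses component strength ratios ≤ 3: the convergence is O(1/n) with
  constant V_A V_B (ln σ_A/σ_B)²/2, so at ratio 10 matching 0.1 % would
  require n ≈ 1300. This is a property of the model, not of the
  implementation.

## Evaluation

RMSE = √(Σ(σ_measured − σ_predicted)²/n), computed per mixture and pooled.
The pooled ("global") RMSE pools residuals across mixtures rather than
averaging per-mixture RMSEs, which keeps the identity
global² = Σ n_m·RMSE_m²/Σ n_m exact and weights mixtures by their point
counts. Predictions are evaluated at each measured tablet's actual porosity,
with component strengths taken from the fitted continuous profiles (raw
points are not interpolated).

## Synthetic studies

The generator emulates a standard compaction study: 13 mm flat-faced
tablets at 0.5 g target weight, porosity levels 0.10–0.30, three replicates
per level. Strength noise is multiplicative lognormal (sd 0.05 by default —
tensile-strength scatter scales with magnitude), dimension noise additive
Gaussian (default 0). The default material pair is one strong binder
(σ₀ = 10 MPa, k = 8, ρ = 1.5) and one weak material (σ₀ = 1 MPa, k = 9,
ρ = 1.6), giving strength ratios of roughly 10–16× over the studied
porosities: mixtures of similar-strength components make all mixing rules
converge and cannot discriminate between them, so the discriminative
strong/weak regime is the informative default. Mixture datasets use the
standard 75–25 / 50–50 / 25–75 volume-fraction ratios. All randomness flows
from a single integer seed through per-stream `numpy` generators; identical
seeds give byte-identical output tables.

What the generator does *not* emulate: particle size/shape distributions,
segregation or non-random mixing, surface-area-weighted contact
probabilities, lubricant and tooling effects, viscoelastic relaxation, and
porosity-dependent noise structure. Passing recovery tests on these
fixtures therefore demonstrates correctness of the estimators and the
model-selection machinery under the model's own assumptions, not robustness
of the physical model to real powders that violate them.

## Design space

`design_space` sweeps a simplex lattice of compositions × a porosity grid,
predicts σ_mix per cell under a chosen model, and masks cells inside a
target strength window. For binary systems at fixed porosity the
interaction prediction is strictly monotone in the stronger component's
volume fraction, so the acceptable region is a single contiguous interval —
asserted by a dense-grid scan in the tests.

## Known limitations

- Volume fraction stands in for contact surface area; materials with very
  different particle size or shape will violate the multinomial contact
  assumption.
- The R–D form is assumed valid over the whole evaluated porosity range;
  extrapolation beyond the fitted window is flagged but not prevented.
- RMSE comparison is descriptive; no significance testing or
  cross-validation is performed.
- Cluster enumeration cost grows as C(n+m−1, m−1); practical for the
  supported regimes (n ≤ a few hundred, m ≤ ~6), not for many-component
  blends at extreme order.
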