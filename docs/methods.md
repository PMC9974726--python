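# Methods

## Model

The simulator implements Darwinian dynamics driven by a fitness
generating function. A community of n clones is described by strategy
and density vectors (u, x). A clone's per-capita growth rate is the
G-function evaluated at its own strategy, and its strategy climbs the
local fitness gradient:

    dx_i/dt = x_i · G(v, u, x, t)|_{v=u_i}
    du_i/dt = k_i · dG/dv|_{v=u_i}

This is a mean-field, deterministic description: clones are infinitely
divisible densities, strategy change is gradient ascent on the (moving)
adaptive landscape, and the evolvability k — the lumped effect of
mutation rate and genetic architecture — is a fixed constant per clone.
No demographic stochasticity, no spatial structure, no explicit
genetics, and k does not respond to stress; those are deliberate
non-goals.

Three G-function families are implemented (see the README for the
formulas): basic logistic growth with Gaussian strategy-dependent
carrying capacity; the same with a Gaussian niche-overlap competition
kernel, each clone retaining its own K(v) (the per-clone form — the
population-level weighted-average capacity variant is not implemented);
and logistic growth minus a Gaussian drug-kill profile applied from a
treatment start time `time_G` onwards. The drug family is written for
a monomorphic population; the implementation accepts a general (u, x)
pair and couples clones through total density (equivalent to a
competition kernel ≡ 1), so multi-clone treated communities are well
defined.

All strategy kernels are even around their modes, which implies the
mirror symmetry used in tests: negating all initial strategies negates
the strategy trajectories and leaves densities unchanged.

## Parameters and defaults

| Parameter | Meaning | Units | Control value |
|---|---|---|---|
| r | intrinsic growth rate (ln 2 / doubling time) | 1/time | 0.25 |
| K_m | absolute carrying capacity | cells | 100 |
| σ_k² | breadth of the carrying-capacity Gaussian | trait² | 12.5 |
| k | trait evolvability | trait²/time | 0.2 |
| x₀, v₀ | initial density / strategy per clone | cells, trait | 10, 3 |
| σ_a² | competition-kernel breadth | trait² | 2 (narrow) / 50 (broad) |
| s_m | maximal drug kill rate | 1/time | 0.2 (package default) |
| u_opt | strategy the drug targets | trait | 0 |
| σ_t² | drug generality (kill-profile breadth) | trait² | 0.8 (package default) |
| time_G | treatment start | time | 600 or ∞ |

Time is abstract ("time steps" treated as continuous); strategies are
dimensionless trait units.

The configuration parameter for the competition kernel is the variance
σ_a² throughout (one upstream figure caption refers to "σ_a = 50" while
the accompanying text and the kernel definition use σ_a² = 50; the
variance reading is used here).

**s_m and σ_t² are this package's own defaults** — the source scenarios
do not print them. They were chosen once so that at treatment onset
(x ≈ K_m, v ≈ 0) the kill term's curvature beats the capacity term's,
i.e. s_m/σ_t² > r·x/(K_m·σ_k²) = 0.02, turning v = 0 from the fitness
peak into a valley. With s_m = 0.2, σ_t² = 0.8 the post-treatment
resistant strategy settles at |u*| ≈ 2.03 with density ≈ 79.6: the
qualitative treated phenotype (bimodal landscape, resistant strategy
strictly between the drug optimum and the initial displacement, reduced
equilibrium density). Quantities that depend on these two defaults are
treated as qualitative, never as reproduction targets.

## Numerics

- **Integration**: scipy `solve_ivp` with DOP853, rel_tol 1e−8,
  abs_tol 1e−10 by default; output sampled on 1501 uniform points
  unless a grid is given. The treatment onset is a genuine
  discontinuity in t, so integration is split at `time_G` and, inside
  the pre-onset segment, the model is evaluated at
  min(t, nextafter(time_G, −∞)) — the solver can never sample the
  post-onset kill term early. Halving tolerances moves the endpoints of
  the bundled scenarios by < 1e−8 (tested).
- **Gradients**: all three families supply closed-form dG/dv; a central
  finite difference with step 1e−6·max(1, |v|) is available both as a
  fallback for user models without one and as the independent
  cross-check (agreement < 1e−6 relative is part of the test suite).
- **Stationarity**: "final" values are never trusted from the horizon
  alone; `run_to_stationarity` integrates in chunks of 2000 time units
  (tight 1e−10/1e−12 tolerances) until the RHS max-norm drops below
  1e−8 (1e−11 where equilibrium cross-checks at 1e−6 are asserted), and
  every trajectory records its final RHS norm in metadata.
- **Negative densities** are clipped to zero in sampled output and
  counted in metadata; the RHS treats negative excursions as zero. An
  optional extinction threshold zeroes and freezes a clone via a
  terminal integration event. Optional strategy bounds (the strategy
  set U) are enforced by projection: outward velocity is zeroed at a
  bound and sampled strategies are clipped. Both are off by default, as
  in the bundled scenarios.
- **Equilibria**: the 2n-dimensional system {G_i = 0, dG/dv_i = 0} is
  solved by Powell hybrid, then Levenberg–Marquardt, then a damped
  Newton iteration using the pseudoinverse of a finite-difference
  Jacobian. The pseudoinverse route matters when competitors are
  functionally identical: the density split between them is a neutral
  direction, the Jacobian is singular, and roots form a continuum — the
  solver returns the converged root nearest the supplied guess.
  Multi-start includes the strategy-sign-flipped guess to land on
  symmetric partners. Classification uses the sign of d²G/dv² (central
  difference of the analytic gradient, step 1e−4·max(1,|v|));
  |d²G/dv²| < 1e−8 is reported as `degenerate`, never silently rounded.
- **Landscapes**: extrema are sign changes of the discrete slope with a
  local parabolic refinement; plateaus inherit the preceding slope
  sign; boundary grid points are never reported as extrema. Local
  maxima within 1e−9 of the global grid maximum are flagged `co_peak`
  (the equal-fitness-peaks situation that signals potential
  diversification). Default grid v ∈ [−10, 10], 401 points.
- The morph count is an input everywhere (the guess fixes it);
  automatic detection of evolutionary branching is out of scope.

## Design notes and findings

- With σ_a² < σ_k² the dimorphic coexistence point of the competition
  model — closed form u* = ±sqrt((σ_a²/2)·ln((2σ_k²−σ_a²)/σ_a²)), each
  clone at K(u*)/(1 + e^(−2u*²/σ_a²)) — is convergent-stable under the
  two-clone dynamics but sits at a fitness **minimum**, and G(v) > 0
  for strategies far outside the residents (the Gaussian kernel decays
  faster than the Gaussian capacity, so G → r as |v| → ∞). The maximum
  principle therefore correctly reports it as invadable. This is the
  well-known degeneracy of Gaussian–Gaussian competition models, in
  which branching can in principle continue indefinitely; the package
  reports it honestly rather than labelling the point an ESS.
- The dimorphic displacement u*(σ_a²) is **not monotone**: it vanishes
  at both ends of (0, σ_k²) and peaks in between (near σ_a² ≈ 5 for
  σ_k² = 12.5). Intuition: a very narrow kernel removes the incentive
  to diverge at all (any separation already escapes competition), a
  near-capacity-breadth kernel makes divergence useless.
- Under a broad kernel with asymmetric starting strategies, the clone
  starting nearer v = 0 outgrows its competitor at finite times, but
  the symmetric model has a neutral density direction at u = (0, 0), so
  deterministic exclusion does not occur; the tests assert the
  finite-time ordering only.
- Scenario horizons: bundled presets integrate to t = 1500. The
  slowest bundled mode (broad-kernel strategy relaxation, ≈ 0.003/time)
  is the reason equilibrium cross-checks for that scenario run to
  t = 3000 or to explicit stationarity instead.

## What passing tests do and do not show

The scenarios are fully synthetic and desk-scale: smooth Gaussian
kernels, one or two clones, no noise. Agreement with printed
equilibrium values and orderings validates the integrator, gradients,
and solvers — it says nothing about how faithfully a logistic/Gaussian
G-function describes any real tumour, where carrying capacities,
competition coefficients and kill profiles must be fitted to assay
data and where stochasticity, space and plasticity can dominate.
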