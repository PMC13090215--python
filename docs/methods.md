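# Methods

## Model and assumptions

The microscopic object is a metapopulation of `K` demes at positions
`l/K ∈ (0, 1]`, each of fixed size `N`. All dynamics are specified by a
`ModelKernels` bundle: the pairwise resampling rate `c(r, x, y)` (the rate
at which an `x` individual is replaced by a `y` copy; selection lives
here), the per-capita mutation rate `θ(r, x)` with mutant law `Q`, and the
migration kernel `λ((r, x), (r', y))`, scaled by `γ/K` in the microscopic
model so that mutation and migration share one slow timescale. All
kernels are assumed non-negative, bounded and measurable; the bundle
carries explicit finite bounds `c̄`, `θ̄`, `λ̄` that are required up front
and checked opportunistically at every evaluation — a kernel exceeding its
bound aborts the run, because every thinning scheme in the package leans
on those bounds for exactness. Continuity/Hölder regularity of
user-supplied kernels (needed for the limit theorems themselves) is the
user's responsibility and is not verified.

Traits are vectors in `R^d` compared by exact bit equality: mutation
almost surely creates a brand-new value, which matches the atomic-measure
formalism and lets states be stored as per-patch trait→count maps.

## Level by level

**Microscopic Gillespie (`micro`).** Exact stochastic simulation
(exponential waits at the total rate, proportional channel choice), no
tau-leaping, because the trajectories feed limit-law tests that assume
exactness. Events whose source and target traits are bit-identical change
nothing; the simulator enumerates only ordered pairs with *distinct*
traits. This is a pure no-op suppression — the law of the trait
configuration is unchanged — but it is the decisive optimisation: a
monomorphic deme generates no resampling events at all, so the cost of a
run scales with the number of mutation/migration episodes and their
fixation battles rather than with the overwhelming background resampling
activity. The generator formally also counts self-pairs; these are no-ops
too and are treated identically. The same suppression is applied to
migration events between identical traits. Rates are cached per patch and
per ordered patch pair and only rows touching the patch hit by the last
event are rebuilt.

**Fixation probability (`kernels`).** The closed form
`α = (Σ ρ^k)^{-1}` is evaluated through the geometric identity
`(1 − ρ)/(1 − ρ^N)`, with a direct small sum near `ρ = 1` (where the
identity is ill-conditioned) and a log-space branch
`α ≈ (ρ − 1) ρ^{−N}` when `ρ^N` would overflow. An independent oracle
solves the first-step linear system of the two-type birth–death chain; the
two agree to 1e−12 on a (ρ, N) grid, which is a standing test. The
invader-slot gradient identity `∇₂α(x,x) = (N−1)/(2N) ∇₂Fit(x,x)` is
checked by central finite differences with default step `h_fd = 1e−5`
(balancing `O(h²)` truncation against `O(eps/h)` round-off for O(1)
kernels). The homogeneous and heterogeneous statements of the limit write
this gradient in different argument slots because the position argument is
dropped in the homogeneous notation; the package exposes a single
`selection_gradient` (gradient in the invading trait, evaluated at
`y = x`) to make that off-by-one-slot bug impossible.

**Substitution sequences (`tss`).** Exact thinning: mutation proposals at
`N θ̄` per patch accepted with `(θ/θ̄) α(y, x)`; migration proposals at
`N² λ̄ (K−1)/K` per patch with the source patch uniform on the other
`K − 1`, accepted with `(λ/λ̄) α` — this reproduces the target rate
`(N²/K) Σ_{l'≠l} λ α` exactly without building K² rate tables, and is
valid because `α` is itself a probability. Acceptance ratios are recorded
per channel; a computed acceptance above 1 (a bound violation) aborts.
Continuous mutation laws use propose-then-accept; discrete laws
additionally get exact rate sums in `tss_rates`.

**Mean field (`meanfield`).** The limiting weak equation is solved *only*
for finitely supported measures (finite trait set, discrete mutation law
or mutation off), where it closes into a conservative ODE on atom weights,
integrated with adaptive explicit RK (rtol 1e−8). Mass conservation is a
test target, never an enforcement: weights are not renormalised.
General/continuous-mutation measures are the particle system's job: `M`
interacting particles with thinned jumps, partner drawn among the other
`M − 1` (self-exclusion mirrors the pre-limit sum over distinct patches;
either choice carries O(1/M) bias). The jump kernel's left-limit measure
and the current state coincide between jump times, so the simulator uses
the current empirical state. `chaos_diagnostics` reports mean pairwise
correlations of a bounded tagged statistic across replicates (with a
`3/sqrt(n_rep)` null band) and two-sample KS distances of marginals.

**Replicator (`replicator`).** `a_ij = G(x^i, x^j)` is computed on the
upper triangle and negated, so antisymmetry is exact in floating point
(`relative_fitness` likewise computes `log c_f − log c_b` so its
antisymmetry is exact). The ODEs use DOP853 with rtol 1e−10 — the systems
are non-stiff but conservation-sensitive over the long exclusion horizons.
The spatial system discretises the position integral by a uniform midpoint
rule (`m` configurable, default 32), which is positivity-preserving and
matches the equal-patch-size convention; `m = 1` collapses exactly onto
the mean-weight ODE. "Invasion" is declared numerically at
`w̄ ≥ 1 − 1e−3` by the configured horizon, since the underlying statement
is asymptotic. The interior equilibrium is a strictly positive null vector
of `A` (nullspace for a 1-d kernel, a small LP for degenerate ones); when
it exists, `Σ w*_i log w̄_i` is conserved, which the cycling tests assert
to 1e−6. The vanishing-mutation-step limit object is represented directly
by the mutation-free flow; the Hölder-metric convergence *rate* of that
limit is proof apparatus and is not estimated.

**Canonical jump-diffusion (`canonical`).** Drift
`(N−1)/2 · θ Σ ∇₂Fit`, diffusion factor `sqrt(θ) σ` with `σ` the
symmetric PSD square root of `Σ` (any square root works; the symmetric one
is a determinate choice). Euler–Maruyama (default `dt = 1e−3`) for the
continuous part; jumps are thinned against `N² λ̄` with exact exponential
clocks read at the most recent Euler node, so jump intensities carry no
extra dt bias. Environment particles carry i.i.d. uniform positions frozen
for the whole run — the environment flow transports mass only in the trait
coordinate, so its position marginal stays Lebesgue. A random initial
environment law would require averaging over environment replicates; only
deterministic-or-sampled initial environments are supported.

## Synthetic scenarios and what they do (and do not) show

There are no external data; every study condition is a named kernel preset
with analytic bounds and covariances: `neutral`, `directional_1d`
(`c = exp(s(y−x))`, so `Fit = 2s(y−x)`), `gaussian_stabilizing`
(log-quadratic `c`, fitness peaked at `x₀`), and the exclusion/cycling
migration kernels `λα = x(1+y)/N²` and `λα = (1 + sin 2π(x−y))/N²` on
traits {0.2, 0.5, 0.8} with uniform initial weights. The discrete
`two_trait` kernel (selective advantage 2 for the invading trait) powers
the exact-rate substitution checks. The sign/parameterisation conventions
of the presets are the package's own and are documented per preset; they
are chosen for analytic transparency, not realism — none of these
scenarios emulate empirical trait distributions, demography or
environmental noise, so passing tests demonstrate internal consistency of
the scaling limits, not fit to real data.

## Problem sizes of the verification experiments

The cross-level experiments (`metamoran.experiments`) run at sizes chosen
so each comparison has resolving power while a full verification pass
stays around a minute on one CPU:

* micro vs TSS: `K = 5`, `N = 5`, `γ = 1e−3`, horizon 0.5 in rescaled
  time, 1000 replicates per level, two-sample z-test on per-patch
  substitution counts;
* propagation of chaos: `K ∈ {20, 50, 200}` with 400/300/200 replicates,
  8 tagged patches (28 pairs averaged), MV reference at `M = 2000`;
  correlations are averaged over pairs because a single pair's correlation
  estimate at `n ≈ 200` replicates has standard error comparable to the
  signal at `K = 200`;
* neutral substitution rate: `K = 100`, `θ = 1`, `T = 50` (≈5000 events);
* canonical variance: `M = 2000`, `dt = 0.01`, `t = 1` — for constant
  coefficients the Euler scheme is exact in law, so the coarser step
  trades nothing;
* tagged vs environment: `M = 1500` environment particles, 400 tagged
  paths, stabilizing selection with migration, KS at the 1% level;
* small-mutation trend: `ε ∈ {0.5, 0.25, 0.1}`, `M = 400` particles, KS
  against an `M = 1500` canonical ensemble averaged over 4 replicates per
  `ε`. The `ε` ladder is deliberately coarse: the KS gap between
  consecutive `ε` values must exceed the two-sample KS sampling noise
  (≈0.06 at these sample sizes) for the monotone trend to be identifiable;
  a finer ladder at these sample sizes measures noise, not convergence.

## Known limitations

* The atomic-measure solver requires finite trait support; continuous
  mutation goes through particles only.
* Only equal deme sizes are implemented (the weight-system generalisation
  to non-uniform sizes is noted in the literature but not developed here).
* Spatially explicit lattices, varying `N`, and diploid genetics are out
  of scope; the migration kernel interface is the only spatial structure.
* The classification of long-term antisymmetric Lotka–Volterra behaviour
  beyond the strict-dominance and interior-equilibrium cases is not
  attempted.
* Statistical level-vs-level tests compare marginals, jump counts and
  correlations; no pathwise coupling between levels is constructed.
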