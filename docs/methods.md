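# Methods

## Model

`metalv` simulates a metacommunity of `S` species over `M` well-mixed
patches coupled by all-to-all migration. The abundance `N_iu` of species
`i` in patch `u` follows generalized Lotka–Volterra dynamics

    dN_iu/dt = N_iu [ B_iu − N_iu − Σ_j A_ij,u N_ju ] + Σ_v D_uv (N_iv − N_iu),

with carrying capacities `B_iu` (1 by default), quenched random
interactions `A_ij,u`, and uniform migration `D_uv = d/(M−1)` off the
diagonal. An extinction rule supplements the ODEs: whenever a species is
below the cutoff `N_c` in *every* patch at a checkpoint, it is removed
permanently. `1/N_c` is the absolute population-size scale: the cutoff
is where "abundance" stops meaning many individuals.

Interactions are unstructured: each directed pair `(i, j)` is non-zero
with probability `c` (one Bernoulli draw shared by all patches — a pair
interacts everywhere or nowhere), and conditional on interacting the
patch values are jointly Gaussian, marginally `Normal(mu_A, sd_A²)`,
with equicorrelation `rho` between patches. The construction
`A = mu_A + sd_A(√rho·z_shared + √(1−rho)·z_patch)` realizes the
equicorrelation exactly at O(1) cost per entry. Negative `rho` (legal
down to `−1/(M−1)`) falls back to an exact Cholesky draw. An optional
reciprocal correlation `gamma` couples `A_ij` and `A_ji`; when it is
non-zero the sparsity mask is drawn per unordered pair so the reciprocal
coefficient always exists (`gamma = 1` then gives exactly symmetric
matrices).

The disorder is summarized by two scales computed over the *full* entry
distribution, zeros included:

    mu_tot = c·S·mu_A,     sigma² = c·S·(sd_A² + (1−c)·mu_A²).

This convention reduces to `sigma = sd_A √S` at full connectance and is
the scaling in which the high-diversity phase structure (equilibrium,
fluctuating, unbounded) is expressed.

## Numerical integration

Between extinction checkpoints (default spacing 1 time unit) the ODEs
are integrated with SciPy's adaptive RK45 (`rtol=1e-6`, `atol=1e-12`),
in linear abundance space; values in `(−1e-9, 0)` after a step are
clamped to zero, anything more negative aborts. Log-space integration
was rejected because extinct (exactly zero) coordinates are legitimate
states. Extinct species are excised from the working arrays, so long
runs get cheaper as the transient sheds species; a desk-scale run
(S=250, M=8, horizon 10⁴) takes on the order of a minute on one core.
Checkpointed (rather than continuous-event) extinction tests make runs
exactly reproducible and match the modeling intent: the cutoff is a
demographic recipe, not a dynamical event. `checkpoint_dt` is exposed.

Initial conditions default to i.i.d. uniform `[0.1, 1]` per
species-patch; any O(1) positive start reaches the same statistical
steady state.

The *annealing* protocol that converts a fluctuating state into an
equilibrium of the same system raises the working cutoff geometrically
(factor `10^(1/4)`) and re-integrates at each stage. A stage keeps
integrating in chunks while the raised cutoff is still removing species
or while the fixed-point residual is still decaying; it gives up at a
stage budget (2000 time units) and raises the cutoff again, failing
outright if the cutoff reaches 1.0 (the carrying-capacity scale). The
fixed-point criterion is `max |dN/dt| / max(N, N_c) < tol` over live
coordinates.

## Observables

Two-time statistics are measured over a stationary window (default: the
last half of the run, validated by a split-half drift test at 5% on the
mean abundance and the diversity). The averaging population is the set
of species alive through the window, over all patches, with connected
correlations (each pair's own time mean removed); the autocorrelation
average `C_N(τ)` uses FFTs with per-lag unbiased normalization. The
noise kernel is `C_ξ = σ²·C_N`, its strength `std(ξ) = √C_ξ(0)`, and the
integrated power `W` is the **two-sided** integral of `C_ξ`, truncated
at the first lag where the kernel stays below a noise floor (twice the
per-lag scatter of the outer half of lags). The two-sided convention
makes the extinction exponent `a = 2N*/W` come out as the
drift-over-diffusion ratio of log-abundance (effective diffusion
`W/2`), and is recorded in the kernel metadata.

The migration contribution `(dN/dt)_diff = Σ_v D_uv (N_iv − N_iu)` is
negative for sources (net exporters) and positive for sinks; a
species-patch pair is *persistent* when `|mean| ≥ sd` over the window,
both moments temporal. Inter-patch synchrony is the mean Pearson
correlation of a species' fluctuations between patch pairs.

## Dynamical mean-field theory

For large disordered pools the many-species system maps onto a single
*representative metapopulation*,

    dN_u/dt = N_u (N*_u − N_u + ξ_u(t)) + Σ_v D_uv (N_v − N_u),

with quenched multivariate-Gaussian characteristic abundances `N*_u` and
Gaussian colored noise `ξ_u(t)`, independent between patches by default
(cross-patch noise correlation is small in the asynchronous regime and
exposed as an override). The stationary closure implemented is

    mean(N*)       = B − mu_tot·⟨N⟩_pool
    C_ξ(τ)         = σ²·C_N(τ)                (connected, within patch)
    var(N*)        = σ²·⟨N̄_u²⟩_pool           (persistent plateau)
    cov(N*_u,N*_v) = σ²·rho·⟨N̄_u N̄_v⟩_pool,

with every pool average counting extinct species as zero abundance.
`phi`, the fraction of species with long-term presence, is
`P(max_u N*_u > 0)` under the converged Gaussian (one source patch
suffices); the finite-horizon survival fraction would overcount slowly
decaying species.

The solver iterates: draw `N*` vectors, simulate the representative
process under the current kernel (exponential-Euler on the
multiplicative part, explicit migration; positivity-preserving down to
arbitrary small abundances), re-measure the pool statistics, map them
through the closure, and damp the update (default damping 0.3; the
package's own studies use 0.5 for speed). Common random numbers — the
same noise seeds every iteration — make the iteration map deterministic
so it can converge to solver precision; the convergence test bounds the
relative change of the mean and of the kernel, the latter against a
scale floored at 1% of `σ²⟨N̄²⟩` so that the equilibrium branch (kernel
shrinking geometrically to zero) terminates. Colored noise is sampled
by circulant embedding (Davies–Harte), with negative circulant
eigenvalues clipped (warned) and each complex draw yielding two real
paths.

A `phi_fix` mode evaluates the theory *at a pinned diversity*: the
contributing pool is restricted to the surviving realizations with the
highest effective characteristic abundance, keeping a fraction
`phi_fix` of the pool. Fluctuating states form a continuum in
diversity, and a finite simulation settles below the maximal-diversity
state the unconstrained closure selects; pinning asks the theory about
the state actually reached.

The static (equilibrium) cavity theory closes on truncated-Gaussian
moments: with no reciprocal correlation the survivors obey
`N = max(0, B − mu_tot·m + σ√q·z)`, giving `w₂(Δ) = 1/σ²` with
`Δ = (B − mu_tot·m)/(σ√q)`, survival fraction `phi = Φ(Δ)` and the
maximal-diversity bound `S·phi`. The response correction vanishes at
`gamma = 0` and is therefore omitted.

### Known quantitative limitation

At moderate pool sizes the Gaussian dynamic closure overestimates
fluctuation amplitudes. On the S=100, M=4 validation fixture, feeding
the *simulation-measured* kernel and `N*` statistics into the
representative process reproduces the simulation's stationary abundance
histogram to a Kolmogorov–Smirnov distance below 0.07 and the static
plateau exactly — the mapping itself is quantitatively sound — but
returns about 1.5× the per-species temporal variance. The true
interaction noise is strongly non-Gaussian (excess kurtosis ≈ 10), yet
driving with empirical noise samples removes only a small part of the
excess; the remaining damping in the full system is state-dependent
feedback between a species and the community response to it, which the
`gamma = 0` closure has no channel for. Iterated, the amplification
carries the unconstrained solver to a wilder self-consistent branch
(larger `std(ξ)`, lower `phi`) than the simulation reaches. Static
predictions (`phi`, moments, the `N*` distribution) are much less
affected. Fixtures with a weaker mean interaction load — where this
feedback parameter `mu_tot²/S` would be small — are not available at
S=100: the Gaussian interaction ensemble there either equilibrates or
enters the unbounded-growth phase.

## Extinction-time scaling

The mean first-passage time below `N_c` scales as `τ·(1/N_c)^a` with
`a = 2N*/W`: deep excursions of log-abundance are drift `N*` against
effective diffusion `W/2`. With `M` asynchronously forced patches the
species must crash everywhere at once and the exponent compounds to
`M·a_eff`, with `a_eff = 2N*_eff/W` built from an effective cross-patch
characteristic abundance. The default aggregator for `N*_eff` is the
patch maximum (one source patch dominates rescue); a migration-weighted
soft-max is exposed, and the fitted exponents are insensitive to the
choice at the level of the fit's standard error for similar patches.

First-passage sweeps simulate the representative process in resumable
blocks (bounding the colored-noise memory; blocks are much longer than
the correlation time, so fresh noise at block boundaries leaves escape
statistics unchanged), detect passage with checkpointed all-patch
threshold tests (the same convention as the deterministic simulator),
and fit ordinary least squares on log mean time vs log(1/N_c). Censored
realizations enter through the exponential-tail estimate
`(Σ observed + n_censored·T)/n_absorbed`, which reduces to the plain
mean when everything absorbs. The finite-depth prefactor biases the
fitted slope upward when `a·ln(1/N_c)` is only a few; exponent
comparisons (e.g. the M=2 doubling check) are therefore made in matched
asymptotic-depth windows, with the single-patch grid going twice as
deep as the two-patch grid.

## Stability and the diversity sweep

The community Jacobian at a state is assembled analytically over live
species-patch coordinates (validated against finite differences at
1e-6 relative); `lambda_stab` is the maximal real eigenvalue part,
with |Re λ| < 1e-10 treated as exact zeros and excluded. Putative fixed
points at diversities where the dynamics fluctuate are obtained by
hybrid root-finding seeded at the time-averaged abundances; a live
species must be positive in every patch at an interior fixed point
(migration feeds its sinks — typical sink abundances can be 1e-10), so
infeasible species flagged by negative root components are dropped and
the solve repeated.

The diversity sweep probes one metacommunity at decreasing diversity:
measure `std(ξ)` over three replicate windows (after a settle window
absorbing the post-removal transient), record `lambda_stab` of the
putative fixed point, then remove a batch (default 5) of the most
extinction-prone species — ranked by lowest time-averaged
max-over-patch abundance, a monotone proxy for `N*_eff` and hence for
the extinction exponent. Near the onset diversity the dynamics are
metastable: isolated visits to marginally stable equilibria above the
boundary do occur, so the onset is read as the first *sustained*
change walking up from low diversity. The continuum study is run on
the M=8 reference metacommunity, where the boundary (at these
parameters, between 79 and 85 surviving species) is sharp.

## Synthetic study conditions, sizes and what they show

All inputs are internally sampled; there is no external data. The two
reference experiments use the pool statistics S=250, c=1/8,
mean(A)=0.3, std(A)=0.45 — single patch for the equilibrium experiment,
M=8 patches at rho=0.95 for the fluctuating one. Migration and cutoff
default to d=0.01 and N_c=1e-8, chosen inside the stated admissible
ranges (d ≲ 0.1; N_c far below the 1e-2–1e-1 regime that forces
equilibria). Desk-scale horizons are 10⁴ time units (presets expose
10⁵); the source/sink persistence fractions and diversity are stable
from ~5·10³ onward at these parameters. The scaled validation fixture
(S=100, M=4, c=1, mean 0.1, sd 0.3, rho 0.9) is dense so that each
species averages over the full pool; it is used for
theory-vs-simulation comparisons, where its smaller size keeps the
solver cheap. At this size the dense Gaussian ensemble sits close to
the unbounded-growth boundary — a minority of quenched draws contain
runaway mutualistic loops and diverge — so the fixture is used with a
quenched draw inside the bounded phase, and ensemble-replicated studies
use the sparse reference system instead.

The generator draws exactly the Gaussian, unstructured ensembles the
model assumes. Passing tests therefore validate the implementation and
the theory's internal consistency under those assumptions — they say
nothing about structured networks (trophic levels, modularity),
non-Gaussian interaction distributions, demographic stochasticity, or
spatially explicit (nearest-neighbour) landscapes, all of which are out
of scope. Patch-dependent carrying capacities are accepted as a
user-supplied `B` matrix but no distribution for them is modeled.

## Reproducibility

Every stochastic step is seeded: the quenched disorder by
`EnsembleParams.seed`, initial conditions and solver noise by explicit
seed arguments, and experiment drivers record the config hash, seed
list and package version in their reports. Re-running any config
byte-reproduces all CSV/JSON outputs.
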