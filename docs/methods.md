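# Methods

## Processes and assumptions

Population growth is modeled as a continuous-time Markov jump process on
integer sizes. In the pure-birth formulation the only event is
`N → N + 1` at total rate `B(N) = b N^α (1 − (N/K)^β)^γ` (Gompertz:
`b N log(K/N)`), so `K` is absorbing and sizes are visited in order. The
stochastic solvers require `α = 1`: only then does the jump process have
the corresponding deterministic equation as its mean-field limit, so
stochastic-vs-deterministic comparisons are well posed (constructing a
rate sequence with `α ≠ 1` raises an error; the deterministic operations
accept general `α`). Time is measured in units of `1/b`; all defaults use
`b = 1`.

The birth-death variant adds `N → N − 1` at rate `d·N`. Only `N = 0` is
absorbing there; at `N = K` births stop but deaths continue — this corner
is not dictated by the jump-process definition elsewhere and was fixed for
internal consistency.

## Exact solvers and numerics

Four independent routes to `P_{N₀,N}(t)` are implemented and cross-checked
against each other in the test-suite:

1. **Hypoexponential closed forms.** The density of the hitting time of
   `N` dispatches on degeneracy grouping of the rates: Erlang (all equal),
   the distinct-rate alternating sum, and the partially degenerate case
   whose partial-fraction coefficients `C_{i,k}` are computed by the
   logarithmic-derivative recursion (derivatives of
   `log ∏(s+λ_j)^{-n_j}` are elementary power sums). Two rates are grouped
   when they differ by less than `1e-9` relative to the largest rate —
   this catches the logistic model's exact mirror degeneracy
   `B(N) = B(K−N)` while leaving genuinely distinct Richards/Blumberg
   rates alone. The alternating sums are catastrophically ill-conditioned
   for long chains of nearby rates; the estimated cancellation (largest
   term magnitude over result magnitude) is monitored and the evaluation
   falls back to arbitrary precision (mpmath, digits scaled to the
   estimated loss, capped at 300) whenever more than ~6 digits would be
   lost. At K = 100 this makes the closed forms slow-but-correct; they are
   retained as cross-checks.
2. **Spectral solution.** The generator is lower bidiagonal, so its
   eigenvalues are `−B(N)` and the solution is a weighted sum of
   exponentials — algebraically identical to the distinct-rate
   hypoexponential form, and therefore evaluated through the same guarded
   code path. It is defined only for pairwise-distinct rates; degenerate
   sequences raise an error naming the colliding states.
3. **Uniformization** (production default for chains longer than 40
   rates): Poisson randomization of the uniformized discrete chain, with
   the Poisson series truncated at the `1e-16` survival quantile. This is
   unconditionally stable and costs O(Λ·t_max · K) per time grid.
4. **Master-equation oracle:** direct stiff integration (LSODA,
   rtol 1e-10, atol 1e-13) of the coupled probability ODEs — deliberately
   independent of the analytic forms, and used as ground truth.

Tiny negative probabilities from round-off are clamped to zero and rows
renormalized; the clamp magnitude and the pre-normalization row-sum
deviation are recorded on every distribution and asserted `< 1e-9`.

Deterministic trajectories use the closed forms where they exist
(logistic, Richards, Gompertz, exponential) and adaptive integration
(LSODA, rtol 1e-10, atol 1e-12) for Blumberg, chosen so integration error
is negligible against the stochastic effects under study. Note that for
Blumberg with γ > 1 the approach to `K` is algebraic (~t⁻²), not
exponential.

## Moment closures

For the logistic model the first two raw-moment equations are closed by
expressing `⟨N³⟩` through `(⟨N⟩, ⟨N²⟩)` under an assumed distribution
family: binomial, lognormal, Nåsell-Poisson, new-Poisson, normal, and
separable derivative-matching (the last two of lognormal/SDM coincide
algebraically). The degenerate `mean_field` closure (`⟨N²⟩ = ⟨N⟩²`)
recovers the deterministic logistic equation exactly and is integrated as
a one-dimensional system. `b ≠ 1` is handled by time rescaling. If a
closure drives the variance negative the integration continues but the
first violation time is recorded on the returned trajectory
(`invalid_from`); none of the six closures violates validity on the
reference parameter set (K=100, N₀=1).

## Simulation

Single trajectories use a per-call seeded numpy Generator. Ensemble
statistics use dedicated fast paths: the pure-birth ensemble exploits the
fact that jump times are cumulative sums of independent exponentials with
fixed rates (fully vectorized); birth-death, community and serial-passage
ensembles are numba-compiled Gillespie kernels. Per-replicate seeds are
derived from the master seed via `numpy.random.SeedSequence`, making
ensembles reproducible and order-independent.

The rapid-extinction probability `(d/b)^{N₀}` (Gompertz:
`(d/(b log(K/N₀)))^{N₀}`, using that family's density-dependent initial
per-capita rate) comes from the *linear* birth-death process, i.e. assumes
density independence during the early phase. For bounded models at finite
K the true early-extinction probability is slightly larger (e.g. 0.509 vs
0.500 for logistic K=100, d/b=0.5, N₀=1, by the exact first-passage
formula), so the simulation validation of this formula is run in the
density-independent (exponential-family) regime, where the linear-process
law is exact. Extinction runs are stopped early once a replicate reaches
30 individuals: the probability of extinction after that point is
`(d/b)^30`, far below Monte-Carlo resolution.

## Community dynamics

Two strains (rates `bM`, `bW`, relative fitness `r = bM/bW`) share one
carrying capacity; each birth is a mutant with probability
`Γ(N,n) = rn/((r−1)n+N)`. The composition given total size obeys a
Pólya-type recursion (computed in float by default, exact rationals
optionally for validation at small K), and composition-averaged total
rates feed the single-population machinery to give the law of `N` and,
mixed with the composition table, the marginal law of the mutant count.
The generalization beyond the logistic family multiplies both strains'
rates by the family's per-capita density factor `g(N) = B(N)/(bN)` — the
unique choice that keeps `Γ` model-independent.

**Known approximation.** For `r = 1` this construction is exact (and the
package tests it at machine precision). For `r ≠ 1` the conditional
composition at a *fixed time* is not exactly the hitting-time composition:
mutant-heavy communities grow faster, which tilts the composition given
`N(t)=N` relative to the recursion's law. The resulting bias is small —
for the reference community (logistic K=100, bM=1.1, bW=1, N₀=2, n₀=1)
the mutant-count mean deviates from 2×10⁵-replicate simulations by at most
~2% of the saturation abundance, an order of magnitude smaller than the
mean-field error — but it is systematic and resolvable at 10⁵ replicates.
The tests therefore bound it explicitly rather than asserting agreement at
Monte-Carlo precision. Fixation probabilities computed downstream are
insensitive to it (agreement with simulation within Monte-Carlo error at
10⁵ replicates).

## Serial passage

A growth phase of length τ is followed by a binomial bottleneck to
`N₀ = D·K` individuals (draws with replacement; the hypergeometric variant
is out of scope). The post-bottleneck mutant count is a Markov chain whose
transition rows mix `Binom(N₀, n/N)` over the exact joint law of `(N, n)`
at τ (stochastic chain) or use the single fraction `n(τ)/N(τ)` from the
mean-field ODEs (deterministic chain). Fixation probabilities come from
the resolvent of the continuous-time embedding with absorbing rows/columns
removed; the embedding preserves absorption probabilities, which the tests
verify against brute-force iteration of the discrete chain.

## Problem sizes used in validation

Exhaustive analytic cross-checks run at K ≤ 30 with spot checks at K=100;
ensemble comparisons use 2×10⁴–10⁵ replicates (10⁵ for the headline
simulation-consistency and serial-passage checks, with the dilution sweep
restricted to D ∈ {0.02, 0.04, 0.1, 0.2}); smaller counts are used where a
3-standard-error band is already decisive. These sizes were chosen so the
whole validation remains a desk-scale computation.

## Limitations

- Stochastic solvers cover pure-birth dynamics only (`d = 0`, `α = 1`);
  with deaths, the exact transient law is not implemented — only
  simulation and the deterministic ODE.
- The community solution is exact for neutral strains and a tight,
  documented approximation otherwise (see above).
- No inference: the package computes forward distributions, not parameter
  estimates from data.
- Environmental (extrinsic) noise, multi-strain communities and
  strain-specific carrying capacities are not modeled.
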