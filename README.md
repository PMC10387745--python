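# purebirth

Exact stochastic dynamics of nonlinear population growth.

Deterministic growth equations (logistic, Blumberg, Richards, Gompertz) are
the workhorses of microbiology and ecology, yet when a population starts
from a few individuals they systematically **overestimate** the mean of the
underlying stochastic birth process — by up to ~30% for common parameter
choices. `purebirth` implements the growth laws as continuous-time
pure-birth Markov processes and solves their master equation *exactly*, so
the full time-dependent population-size distribution — not just a mean — is
available for any of the models. It is aimed at quantitative microbiologists,
ecologists and evolutionary biologists who fit growth curves, model
microbial communities, or design serial-passage (experimental evolution)
protocols.

## The model

A population of size `N` grows by single births at total rate

    B(N) = b N^α (1 − (N/K)^β)^γ,

which contains the classical models as special cases of the exponents
(logistic: α=β=γ=1; Blumberg: β=1; Richards: α=γ=1; Gompertz is the β→0
limit, B(N) = b N log(K/N)). The carrying capacity `K` is an absorbing
state. Because sizes are visited in order, the hitting time of size `N` is
a sum of independent exponentials with rates `B(N₀) … B(N−1)` — a
hypoexponential random variable — and the occupation probabilities are

    P_{N₀,N}(t) = H_t(B_{N₀}, …, B_N) / B(N),

with `H_t` the hypoexponential density (Erlang, distinct-rate, and
partially degenerate closed forms are all handled, including the logistic
model's exact mirror degeneracy B(N) = B(K−N)). Alongside the closed forms
the package provides a spectral (eigendecomposition) solution, a
numerically robust uniformization solver, a stiff ODE master-equation
oracle, the moment hierarchy with six classical moment closures, seeded
Gillespie simulation, exact two-strain community dynamics, and fixation
probabilities under growth-dilution cycles.

## Worked example

```python
import numpy as np
from purebirth import (GrowthModel, exact_distribution,
                       deterministic_trajectory, relative_error)

model = GrowthModel(family="gompertz", b=1.0, K=100)
t = np.arange(0, 15.0001, 0.05)

dist = exact_distribution(model, N0=1, times=t)   # full P_{1,N}(t)
mean = dist.mean()                                # exact stochastic mean
det = deterministic_trajectory(model, 1, t)       # closed-form ODE solution
eta = relative_error(det, mean)
print(f"max relative error of the deterministic curve: {eta.max():.1%}")
```

prints

```
max relative error of the deterministic curve: 11.5%
```

i.e. even for the mildest of the four growth laws the deterministic curve
overshoots the true mean of the stochastic process by ~12% when growth
starts from a single cell; for Richards (β=2) the overshoot reaches ~31%.

The same machinery drives the applications:

```python
from purebirth import GrowthModel, PassageSpec, bottleneck_matrix_stochastic, fixation_probability

spec = PassageSpec(model=GrowthModel(family="logistic", K=100),
                   bW=1.0, bM=1.1, D=0.04, tau=3.0)
p = fixation_probability(bottleneck_matrix_stochastic(spec), n0=2)
print(f"fixation probability of the fitter mutant: {p:.4f}")
```

prints `fixation probability of the fitter mutant: 0.6227` — the mean-field
(deterministic-growth) version of the same chain gives 0.7229, a
substantial overestimate.

A command-line interface mirrors the library
(`purebirth exact|simulate|closure|community|passage`, see `--help`); every
run writes a self-describing CSV with a commented parameter header.

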