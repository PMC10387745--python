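"""Exact dynamics of a two-strain community under shared density limitation.

A mutant strain (intrinsic birth rate bM) and a wild-type strain (bW)
compete under a single carrying capacity K; the relative fitness is
r = bM/bW.  Because every birth increases the total size N by one, the
composition (mutant count n) given N is independent of time and obeys the
Pólya-type recursion

    P(N+1, n) = (1 - Γ(N, n)) P(N, n) + Γ(N, n-1) P(N, n-1),

where Γ(N, n) = r n / ((r - 1) n + N) is the probability that a given
birth is a mutant.  Averaging the strain birth rates over the composition
yields effective total rates B_N for the community, and the single-
population pure-birth machinery then gives the exact law of N and,
marginally, of n.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.integrate import solve_ivp

from . import exact_solution as xs
from .growth_models import GrowthModel, population_birth_rate

__all__ = [
    "CommunitySpec",
    "CompositionDistribution",
    "mutant_birth_probability",
    "composition_recursion",
    "aggregate_rates",
    "community_size_distribution",
    "mutant_count_distribution",
    "deterministic_community",
]


@dataclass(frozen=True)
class CommunitySpec:
    """Two strains sharing one growth-law shape and carrying capacity."""

    model: GrowthModel
    bW: float
    bM: float
    N0: int
    n0: int

    def __post_init__(self):
        if not (self.bW > 0 and self.bM > 0):
            raise ValueError("strain birth rates must be > 0")
        if not 0 <= self.n0 <= self.N0 <= self.model.K:
            raise ValueError("need 0 <= n0 <= N0 <= K")

    @property
    def r(self) -> float:
        """Relative fitness bM/bW (> 1 favors the mutant)."""
        return self.bM / self.bW

    @property
    def K(self) -> int:
        return self.model.K


@dataclass
class CompositionDistribution:
    """Conditional law P(n | N) of the mutant count given the total size.

    ``table[N - N0]`` is the probability vector over n = 0..N (entries
    outside the reachable band n0 <= n <= N - N0 + n0 are zero)."""

    N0: int
    n0: int
    K: int
    table: list   # table[j][n] = P(N0 + j, n | N0, n0)

    def prob(self, N: int, n: int) -> float:
        row = self.table[N - self.N0]
        return float(row[n]) if 0 <= n < len(row) else 0.0

    def conditional_mean(self) -> np.ndarray:
        """E[n | N] for N = N0..K."""
        return np.array([float(np.dot(np.arange(len(row)), row))
                         for row in self.table])


def mutant_birth_probability(r: float, N: int, n: int) -> float:
    """Probability Γ(N, n) = r n / ((r - 1) n + N) that the next birth is a
    mutant, given n mutants among N individuals."""
    if not 0 <= n <= N or N < 1:
        raise ValueError("need 0 <= n <= N, N >= 1")
    return r * n / ((r - 1.0) * n + N)


def composition_recursion(spec: CommunitySpec, exact: bool = False) -> CompositionDistribution:
    """Fill the composition table P(n | N) for N = N0..K from the point
    mass at (N0, n0).  ``exact=True`` uses rational arithmetic (intended
    for small K in validation runs)."""
    N0, n0, K = spec.N0, spec.n0, spec.K
    r = Fraction(spec.bM).limit_denominator(10**12) / Fraction(spec.bW).limit_denominator(10**12) \
        if exact else spec.r
    zero = Fraction(0) if exact else 0.0
    one = Fraction(1) if exact else 1.0
    row = [zero] * (N0 + 1)
    row[n0] = one
    table = [np.array([float(x) for x in row])] if not exact else [list(row)]
    prev = row
    for N in range(N0, K):
        nxt = [zero] * (N + 2)
        for n in range(len(prev)):
            p = prev[n]
            if p == 0:
                continue
            gam = r * n / ((r - one) * n + N) if n > 0 else zero
            nxt[n] += (one - gam) * p
            nxt[n + 1] += gam * p
        table.append(list(nxt) if exact else np.array([float(x) for x in nxt]))
        prev = nxt
    if exact:
        table = [np.array([float(x) for x in row_]) for row_ in table]
    return CompositionDistribution(N0=N0, n0=n0, K=K, table=table)


def aggregate_rates(spec: CommunitySpec, composition: CompositionDistribution | None = None
                    ) -> xs.RateSequence:
    """Composition-averaged total birth rates of the community,

        B_N = g(N) (bM E[n|N] + bW (N - E[n|N])),

    where g(N) is the family's per-capita density factor (logistic:
    1 - N/K).  These drive the exact law of the total size N."""
    if composition is None:
        composition = composition_recursion(spec)
    N0, K = spec.N0, spec.K
    sizes = np.arange(N0, K)
    g = np.asarray(population_birth_rate(spec.model, sizes), dtype=float) \
        / (spec.model.b * sizes)
    mean_n = composition.conditional_mean()[: K - N0]
    B = g * (spec.bM * mean_n + spec.bW * (sizes - mean_n))
    return xs.RateSequence(N0=N0, K=K, rates=tuple(B))


def community_size_distribution(spec: CommunitySpec, times,
                                method: str = "auto") -> xs.SizeDistribution:
    """Exact time-dependent law of the total community size N, via the
    pure-birth solution applied to the aggregated rates."""
    seq = aggregate_rates(spec)
    return xs.distribution_from_rates(seq.rates, spec.N0, spec.K, times, method=method)


def mutant_count_distribution(spec: CommunitySpec, times, method: str = "auto"):
    """Marginal law P(n, t) of the mutant count: the size distribution mixed
    with the composition table.  Returns (n values 0..K, probs[t, n])."""
    comp = composition_recursion(spec)
    sdist = community_size_distribution(spec, times, method=method)
    K = spec.K
    probs = np.zeros((sdist.times.size, K + 1))
    for j, row in enumerate(comp.table):       # N = N0 + j
        probs[:, : len(row)] += np.outer(sdist.probs[:, j], row)
    return np.arange(K + 1), probs


def deterministic_community(spec: CommunitySpec, times):
    """Mean-field community ODEs, generalized with the per-capita factor
    g(N): dn/dt = bM n g(N), dN/dt = (bM n + bW (N - n)) g(N).
    Returns (n(t), N(t))."""
    t = np.asarray(times, dtype=float)
    model, K = spec.model, float(spec.K)

    def g_of(N):
        N = min(max(N, 1e-12), K)
        return float(population_birth_rate(model, N)) / (model.b * N) if N > 0 else 0.0

    def rhs(_t, y):
        n, N = y
        g = g_of(N)
        return [spec.bM * n * g, (spec.bM * n + spec.bW * (N - n)) * g]

    t_max = float(t[-1]) if t.size and t[-1] > 0 else 1e-12
    sol = solve_ivp(rhs, (0.0, t_max), [float(spec.n0), float(spec.N0)],
                    t_eval=t, method="LSODA", rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"community ODE failed: {sol.message}")
    return sol.y[0], sol.y[1]
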