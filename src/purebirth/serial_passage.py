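"""Fixation probability of a mutant under repeated growth-dilution cycles.

A community of post-bottleneck size N0 = D*K grows for a time τ and is then
diluted back to N0 individuals by binomial sampling (draws with
replacement) of the mutant fraction.  The mutant count after successive
bottlenecks forms a Markov chain on 0..N0 with absorbing states 0 (loss)
and N0 (fixation).  Two transition matrices are built:

* stochastic — the growth phase is described by the exact community
  solution: the bottleneck law is a binomial mixed over the exact joint
  distribution of (N, n) at τ;
* deterministic — the growth phase is described by the mean-field ODEs, so
  each row is a single binomial at the deterministic fraction n(τ)/N(τ).

The fixation probability from n0 mutants is obtained from the resolvent of
the continuous-time embedding of the chain:
p_fix = -sum_i Π_{i→N0} (R̃^{-1})_{i,n0}, with R̃ the rate matrix restricted
to the transient states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import (CommunitySpec, community_size_distribution,
                        composition_recursion, deterministic_community)
from .growth_models import GrowthModel

__all__ = [
    "PassageSpec",
    "BottleneckChain",
    "bottleneck_matrix_stochastic",
    "bottleneck_matrix_deterministic",
    "fixation_probability",
    "pfix_dilution_sweep",
]


@dataclass(frozen=True)
class PassageSpec:
    """Serial-passage protocol: strains, dilution ratio D = N0/K and growth
    time τ between bottlenecks."""

    model: GrowthModel
    bW: float
    bM: float
    D: float
    tau: float

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("growth time tau must be > 0")
        N0 = self.D * self.model.K
        if abs(N0 - round(N0)) > 1e-9 or round(N0) < 2:
            raise ValueError("D*K must be an integer >= 2")

    @property
    def N0(self) -> int:
        return int(round(self.D * self.model.K))


@dataclass
class BottleneckChain:
    """Transition matrix Π over post-bottleneck mutant counts 0..N0 and the
    rate matrix R of its continuous-time embedding (R_ij = Π_{j→i} off the
    diagonal, columns summing to zero)."""

    Pi: np.ndarray

    def __post_init__(self):
        Pi = np.asarray(self.Pi, dtype=float)
        rows = Pi.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > 1e-9:
            raise ValueError("bottleneck matrix rows must sum to 1")
        self.Pi = Pi

    @property
    def N0(self) -> int:
        return self.Pi.shape[0] - 1

    @property
    def R(self) -> np.ndarray:
        R = self.Pi.T.copy()
        np.fill_diagonal(R, 0.0)
        np.fill_diagonal(R, -R.sum(axis=0))
        return R

    @property
    def R_reduced(self) -> np.ndarray:
        """R with the absorbing rows and columns (0 and N0) removed."""
        return self.R[1:-1, 1:-1]


def _binomial_mixture_row(N0: int, weights: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """sum_j w_j Binom(N0, p_j) as a pmf vector over 0..N0."""
    ls = np.arange(N0 + 1)
    pm = stats.binom.pmf(ls[None, :], N0, fractions[:, None])
    return weights @ pm


def bottleneck_matrix_stochastic(spec: PassageSpec, method: str = "auto") -> BottleneckChain:
    """Bottleneck transition matrix under the exact stochastic growth law.

    For each transient starting count k, the composition recursion and the
    aggregated-rate size distribution at τ give the joint law of (N, n);
    the row is the binomial Binom(N0, n/N) mixed over that joint law."""
    N0, K = spec.N0, spec.model.K
    Pi = np.zeros((N0 + 1, N0 + 1))
    Pi[0, 0] = 1.0
    Pi[N0, N0] = 1.0
    for k in range(1, N0):
        cspec = CommunitySpec(model=spec.model, bW=spec.bW, bM=spec.bM,
                              N0=N0, n0=k)
        comp = composition_recursion(cspec)
        sdist = community_size_distribution(cspec, [spec.tau], method=method)
        pN = sdist.probs[0]                     # over N = N0..K
        weights, fracs = [], []
        for j, row in enumerate(comp.table):    # N = N0 + j
            N = N0 + j
            w = pN[j] * row
            nz = np.nonzero(w)[0]
            weights.append(w[nz])
            fracs.append(nz / N)
        weights = np.concatenate(weights)
        fracs = np.concatenate(fracs)
        Pi[k] = _binomial_mixture_row(N0, weights, fracs)
    return BottleneckChain(Pi=Pi)


def bottleneck_matrix_deterministic(spec: PassageSpec) -> BottleneckChain:
    """Bottleneck matrix with the growth phase replaced by the mean-field
    ODE solution: each row is a single binomial at p = n(τ)/N(τ)."""
    N0 = spec.N0
    Pi = np.zeros((N0 + 1, N0 + 1))
    Pi[0, 0] = 1.0
    Pi[N0, N0] = 1.0
    ls = np.arange(N0 + 1)
    for k in range(1, N0):
        cspec = CommunitySpec(model=spec.model, bW=spec.bW, bM=spec.bM,
                              N0=N0, n0=k)
        n_tau, N_tau = deterministic_community(cspec, [0.0, spec.tau])
        p = float(n_tau[-1] / N_tau[-1])
        Pi[k] = stats.binom.pmf(ls, N0, p)
    return BottleneckChain(Pi=Pi)


def fixation_probability(chain: BottleneckChain, n0: int) -> float:
    """Probability that the mutant fixes (reaches N0) starting from n0.

    Boundary starts return 0 or 1 directly; otherwise the absorbing-chain
    resolvent formula p_fix = -sum_i Π_{i→N0} (R̃^{-1})_{i,n0} is used."""
    N0 = chain.N0
    if not 0 <= n0 <= N0:
        raise ValueError("need 0 <= n0 <= N0")
    if n0 == 0:
        return 0.0
    if n0 == N0:
        return 1.0
    Rr = chain.R_reduced
    rhs = np.zeros(N0 - 1)
    rhs[n0 - 1] = 1.0
    x = np.linalg.solve(Rr, rhs)        # column n0 of R̃^{-1}
    pfix = -float(chain.Pi[1:N0, N0] @ x)
    return min(max(pfix, 0.0), 1.0)


def pfix_dilution_sweep(model: GrowthModel, bW: float, bM: float, tau: float,
                        D_values, method: str = "auto") -> pd.DataFrame:
    """Fixation probability across dilution ratios, with n0 = N0/2, under
    both the stochastic and the deterministic growth descriptions."""
    rows = []
    for D in D_values:
        spec = PassageSpec(model=model, bW=bW, bM=bM, D=float(D), tau=tau)
        N0 = spec.N0
        n0 = N0 // 2
        p_sto = fixation_probability(bottleneck_matrix_stochastic(spec, method=method), n0)
        p_det = fixation_probability(bottleneck_matrix_deterministic(spec), n0)
        rows.append(dict(D=float(D), N0=N0, n0=n0,
                         pfix_stochastic=p_sto, pfix_deterministic=p_det))
    return pd.DataFrame(rows)
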