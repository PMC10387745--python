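"""Generalized-logistic growth models.

A population of size ``N`` grows at a total rate ``B(N)`` derived from the
generalized logistic law

    dN/dt = B(N) = b * N**alpha * (1 - (N/K)**beta)**gamma,

which contains the classical exponential (Malthusian), logistic, Blumberg,
Richards and Gompertz models as special cases of the exponents
(alpha, beta, gamma).  All bounded families satisfy B(0) = B(K) = 0: an
empty population cannot grow, and no population grows past the carrying
capacity K.  An optional per-capita death rate ``d`` turns the pure-birth
process into a birth-death process (deterministic form: dN/dt = B(N) - d*N).

Every other module consumes :class:`GrowthModel` instances built here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FAMILIES",
    "GrowthModel",
    "population_birth_rate",
    "birth_rates",
    "inflection_size",
    "deterministic_trajectory",
    "deterministic_birth_death_trajectory",
    "rapid_extinction_probability",
]

FAMILIES = ("exponential", "logistic", "blumberg", "richards", "gompertz")

#: exponents fixed by each family; None means the exponent is free.
_FAMILY_EXPONENTS = {
    "exponential": dict(alpha=1.0, beta=0.0, gamma=0.0),
    "logistic": dict(alpha=1.0, beta=1.0, gamma=1.0),
    "blumberg": dict(alpha=None, beta=1.0, gamma=None),
    "richards": dict(alpha=1.0, beta=None, gamma=1.0),
    # gompertz is the beta -> 0 limit of the generalized law: B = b N log(K/N)
    "gompertz": dict(alpha=1.0, beta=0.0, gamma=1.0),
}

# ODE tolerances for families without closed forms (Blumberg, birth-death).
_RTOL = 1e-10
_ATOL = 1e-12


@dataclass(frozen=True)
class GrowthModel:
    """A named growth rate law B(N) with its parameters.

    Parameters
    ----------
    family
        One of ``exponential``, ``logistic``, ``blumberg``, ``richards``,
        ``gompertz``.
    b
        Intrinsic per-capita birth rate (1/time), > 0.
    K
        Carrying capacity (individuals), integer >= 2.  Ignored by the
        exponential family but kept for truncation of the state space.
    alpha, beta, gamma
        Exponents of the generalized logistic law.  Each family fixes some
        of them (logistic: all 1; blumberg: beta=1; richards: gamma=1);
        passing a value inconsistent with the family raises ``ValueError``.
    d
        Per-capita death rate (1/time), >= 0.  Default 0 (pure birth).
    """

    family: str
    b: float = 1.0
    K: int = 100
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    d: float = 0.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not self.b > 0:
            raise ValueError("birth rate b must be > 0")
        if self.family != "exponential":
            if int(self.K) != self.K or self.K < 2:
                raise ValueError("carrying capacity K must be an integer >= 2")
            object.__setattr__(self, "K", int(self.K))
        if self.d < 0:
            raise ValueError("death rate d must be >= 0")
        fixed = _FAMILY_EXPONENTS[self.family]
        for name, val in fixed.items():
            given = getattr(self, name)
            if val is not None:
                if given is not None and not math.isclose(given, val):
                    raise ValueError(
                        f"{self.family} family fixes {name}={val}; got {given}")
                object.__setattr__(self, name, val)
            elif given is None:
                object.__setattr__(self, name, 1.0)  # free exponent default
        if self.family in ("blumberg",) and not self.gamma > 0:
            raise ValueError("blumberg exponent gamma must be > 0")
        if self.family == "richards" and not self.beta > 0:
            raise ValueError("richards exponent beta must be > 0")
        if self.family == "blumberg" and not self.alpha > 0:
            raise ValueError("blumberg exponent alpha must be > 0")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        """Flat mapping suitable for a YAML config block."""
        return {
            "family": self.family,
            "b": float(self.b),
            "K": int(self.K),
            "alpha": float(self.alpha),
            "beta": float(self.beta),
            "gamma": float(self.gamma),
            "d": float(self.d),
        }

    @classmethod
    def from_dict(cls, block: dict) -> "GrowthModel":
        known = {"family", "b", "K", "alpha", "beta", "gamma", "d"}
        extra = set(block) - known
        if extra:
            raise ValueError(f"unknown model keys: {sorted(extra)}")
        return cls(**block)


def _per_capita(model: GrowthModel, N) -> np.ndarray:
    """Per-capita factor g(N) with B(N) = b * N**alpha * g(N); g(0<N<K) > 0."""
    N = np.asarray(N, dtype=float)
    K = float(model.K)
    fam = model.family
    with np.errstate(divide="ignore", invalid="ignore"):
        if fam == "exponential":
            g = np.ones_like(N)
        elif fam == "logistic":
            g = 1.0 - N / K
        elif fam == "blumberg":
            g = (1.0 - N / K) ** model.gamma
        elif fam == "richards":
            g = 1.0 - (N / K) ** model.beta
        else:  # gompertz: b N log(K/N); g(0) := log(K/0) is irrelevant, B(0)=0
            g = np.log(K / np.where(N > 0, N, 1.0))
            g = np.where(N > 0, g, 0.0)
    return g


def population_birth_rate(model: GrowthModel, N) -> float | np.ndarray:
    """Total birth rate B(N) of the population at integer size N.

    Exponential family accepts any N >= 0; bounded families require
    0 <= N <= K and return exactly 0 at both boundaries.
    """
    arr = np.asarray(N, dtype=float)
    if np.any(arr < 0):
        raise ValueError("population size must be >= 0")
    if model.family != "exponential" and np.any(arr > model.K):
        raise ValueError(f"population size exceeds carrying capacity K={model.K}")
    B = model.b * arr**model.alpha * _per_capita(model, arr)
    B = np.where(arr == 0, 0.0, B)
    if model.family != "exponential":
        B = np.where(arr == model.K, 0.0, B)
    return float(B) if np.isscalar(N) or arr.ndim == 0 else B


def birth_rates(model: GrowthModel, N0: int, K: int | None = None) -> np.ndarray:
    """Ordered rates ``B(N0), ..., B(K-1)`` of the pure-birth chain.

    Stochastic solvers require alpha=1 (otherwise the jump process has no
    well-defined deterministic limit) and d=0.
    """
    if model.d > 0:
        raise ValueError("pure-birth rate sequence undefined for d > 0")
    if not math.isclose(model.alpha, 1.0):
        raise ValueError("stochastic solvers require alpha = 1")
    K = model.K if K is None else int(K)
    if not 1 <= N0 < K:
        raise ValueError("need 1 <= N0 < K")
    sizes = np.arange(N0, K)
    return np.asarray(population_birth_rate(model, sizes), dtype=float)


def inflection_size(model: GrowthModel) -> float:
    """Population size N* at which B(N) is maximal (deterministic inflection).

    N* = K * (1 + beta*gamma/alpha)**(-1/beta); the Gompertz (beta -> 0)
    limit is K * exp(-gamma/alpha).
    """
    if model.family == "exponential":
        raise ValueError("inflection size undefined for exponential growth")
    K, a, be, ga = float(model.K), model.alpha, model.beta, model.gamma
    if model.family == "gompertz":
        return K * math.exp(-ga / a)
    return K * (1.0 + be * ga / a) ** (-1.0 / be)


def deterministic_trajectory(model: GrowthModel, N0: float, times) -> np.ndarray:
    """Deterministic solution N(t) of dN/dt = B(N) from N(0) = N0.

    Closed forms are used for the exponential, logistic, Richards and
    Gompertz families; Blumberg (no closed form) is integrated with an
    adaptive stiff-capable solver at rtol 1e-10.
    """
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    K, b = float(model.K), model.b
    if model.family != "exponential" and not 1 <= N0 <= model.K:
        raise ValueError("need 1 <= N0 <= K")
    if model.family == "exponential":
        return N0 * np.exp(b * t)
    if model.family == "logistic":
        return K / (1.0 + (K / N0 - 1.0) * np.exp(-b * t))
    if model.family == "richards":
        be = model.beta
        return K / (1.0 + ((K / N0) ** be - 1.0) * np.exp(-be * b * t)) ** (1.0 / be)
    if model.family == "gompertz":
        return K * (N0 / K) ** np.exp(-b * t)
    # blumberg: numerical integration
    return _integrate_ode(model, N0, t, death=False)


def deterministic_birth_death_trajectory(model: GrowthModel, N0: float, times) -> np.ndarray:
    """Numerical solution of dN/dt = B(N) - d*N; equals
    :func:`deterministic_trajectory` when d = 0 (within tolerance)."""
    t = np.asarray(times, dtype=float)
    return _integrate_ode(model, N0, t, death=True)


def _integrate_ode(model: GrowthModel, N0: float, t: np.ndarray, death: bool) -> np.ndarray:
    d = model.d if death else 0.0

    def rhs(_t, y):
        N = min(max(y[0], 0.0), float(model.K)) if model.family != "exponential" else max(y[0], 0.0)
        return [population_birth_rate(model, N) - d * y[0]]

    if t.size == 0:
        return np.empty(0)
    t_span = (0.0, float(t[-1]) if t[-1] > 0 else 1e-12)
    sol = solve_ivp(rhs, t_span, [float(N0)], t_eval=np.maximum(t, 0.0),
                    method="LSODA", rtol=_RTOL, atol=_ATOL)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0]


def rapid_extinction_probability(model: GrowthModel, N0: int) -> float:
    """Probability of early extinction of the birth-death process.

    At the start of growth (N << K) the process is approximately a linear
    birth-death process with per-capita birth rate b (density independence),
    whose extinction probability from N0 individuals is (d/b)**N0.  The
    Gompertz family keeps a density-dependent initial per-capita rate
    b*log(K/N0), which replaces b.  Returns 1.0 when the death rate meets or
    exceeds the effective birth rate (subcritical).
    """
    if model.d == 0:
        return 0.0
    if model.family == "gompertz":
        b_eff = model.b * math.log(model.K / N0)
    else:
        b_eff = model.b
    if model.d >= b_eff:
        return 1.0
    return (model.d / b_eff) ** N0
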