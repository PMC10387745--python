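"""Moment hierarchy of the logistic pure-birth process and its closures.

For a pure-birth process with polynomial total birth rate B(N), the raw
moments obey d⟨f(N)⟩/dt = ⟨(f(N+1) - f(N)) B(N)⟩.  For the exponential
model (B = bN) the hierarchy is closed; for the logistic model
(B = bN(1 - N/K)) the equation for ⟨N^m⟩ involves ⟨N^{m+1}⟩, so the first
two moment equations

    d⟨N⟩/dt  = ⟨N⟩ - ⟨N²⟩/K
    d⟨N²⟩/dt = ⟨N⟩ + (2 - 1/K)⟨N²⟩ - (2/K)⟨N³⟩

(written in units of 1/b) must be closed by expressing the third moment in
terms of the first two.  The classical closures implemented here assume a
distributional family for the size distribution and match its first two
moments; the degenerate ``mean_field`` closure (⟨N²⟩ = ⟨N⟩²) recovers the
deterministic logistic equation.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .exact_solution import MomentTrajectory
from .growth_models import GrowthModel

__all__ = [
    "CLOSURES",
    "moment_rhs",
    "third_moment_closure",
    "closure_trajectory",
]

#: closures expressing ⟨N³⟩ as a function of (⟨N⟩, ⟨N²⟩); ``mean_field``
#: is handled separately (it closes the first equation alone).
CLOSURES = ("binomial", "lognormal", "sdm", "nasell_poisson", "new_poisson",
            "normal", "mean_field")

_RTOL = 1e-10
_ATOL = 1e-12


def moment_rhs(model: GrowthModel, m: int, moments: dict) -> float:
    """Exact time derivative of the raw moment ⟨N^m⟩ for polynomial rates.

    ``moments`` maps order -> value and must contain orders 1..m+deg(B)-1
    (exponential: up to m; logistic: up to m+1).  Only families with
    polynomial B(N) admit a finite moment expansion; others raise.
    """
    if m < 1:
        raise ValueError("moment order must be >= 1")
    if model.family == "exponential":
        # d<N^m>/dt = < ((N+1)^m - N^m) N > = sum_{j<m} C(m,j) <N^{j+1}>
        return float(sum(_comb(m, j) * moments[j + 1] for j in range(m)))
    if model.family == "logistic":
        # B(N) = N - N^2/K (b=1 units); ((N+1)^m - N^m)(N - N^2/K)
        K = float(model.K)
        total = 0.0
        for j in range(m):
            c = _comb(m, j)
            total += c * (moments[j + 1] - moments[j + 2] / K)
        return float(total)
    raise ValueError(
        f"moment equations close only for polynomial birth rates; "
        f"family {model.family!r} is unsupported")


def _comb(n, k):
    from math import comb
    return comb(n, k)


def third_moment_closure(closure: str, m1: float, m2: float) -> float:
    """⟨N³⟩ estimated from (⟨N⟩, ⟨N²⟩) under the named closure.

    Each closure assumes a two-parameter distribution family, matches its
    first two moments and reports that family's third moment.  With the
    central moments mu2 = m2 - m1² the raw third moment is
    mu3 + 3 m2 m1 - 2 m1³ where mu3 is the assumed third central moment:
    binomial mu3 = 2 mu2²/m1 - mu2; Poisson-based mu3 = m1 (Nåsell) or mu2
    (new-Poisson); normal mu3 = 0; lognormal and separable
    derivative-matching instead give m2³/m1³ directly.
    """
    if m1 <= 0:
        raise ValueError("mean must be positive")
    base = 3.0 * m2 * m1 - 2.0 * m1**3
    mu2 = m2 - m1 * m1
    if closure == "binomial":
        return 2.0 * mu2 * mu2 / m1 - mu2 + base
    if closure in ("lognormal", "sdm"):
        return m2**3 / m1**3
    if closure == "nasell_poisson":
        return m1 + base
    if closure == "new_poisson":
        return mu2 + base
    if closure == "normal":
        return base
    raise ValueError(f"unknown closure {closure!r}")


def closure_trajectory(model: GrowthModel, closure: str, N0: int, times) -> MomentTrajectory:
    """Integrate the closed two-moment system for the logistic model.

    Starts from the point-mass initial condition (⟨N⟩, ⟨N²⟩) = (N0, N0²).
    ``mean_field`` closes the first equation alone via ⟨N²⟩ = ⟨N⟩² and
    reproduces the deterministic logistic solution.  Rates b != 1 are
    handled by the time rescaling t -> b t.  If a closure drives the
    variance negative the integration continues, but the first violation
    time is recorded on the returned trajectory as ``invalid_from``.
    """
    if model.family != "logistic":
        raise ValueError("closure trajectories are defined for the logistic family")
    if closure not in CLOSURES:
        raise ValueError(f"unknown closure {closure!r}; options: {CLOSURES}")
    times = np.asarray(times, dtype=float)
    K = float(model.K)
    tau = model.b * times  # integrate in units of 1/b

    if closure == "mean_field":
        def rhs(_t, y):
            m1 = y[0]
            return [m1 - m1 * m1 / K]
        y0 = [float(N0)]
    else:
        def rhs(_t, y):
            m1, m2 = y
            m3 = third_moment_closure(closure, m1, m2)
            return [m1 - m2 / K,
                    m1 + (2.0 - 1.0 / K) * m2 - 2.0 / K * m3]
        y0 = [float(N0), float(N0) ** 2]

    t_max = float(tau[-1]) if tau.size and tau[-1] > 0 else 1e-12
    sol = solve_ivp(rhs, (0.0, t_max), y0, t_eval=tau, method="LSODA",
                    rtol=_RTOL, atol=_ATOL)
    if not sol.success:
        raise RuntimeError(f"closure integration failed: {sol.message}")
    if closure == "mean_field":
        m1 = sol.y[0]
        vals = {1: m1, 2: m1**2}
        invalid_from = None
    else:
        m1, m2 = sol.y
        vals = {1: m1, 2: m2}
        viol = m2 - m1**2 < -1e-9
        invalid_from = float(times[np.argmax(viol)]) if np.any(viol) else None
    traj = MomentTrajectory(times=times, values=vals)
    traj.invalid_from = invalid_from
    return traj
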