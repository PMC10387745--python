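"""Exact transient solution of the pure-birth master equation.

A bounded pure-birth process on sizes ``N0..K`` jumps from ``N`` to ``N+1``
at rate ``B(N)`` and is absorbed at the carrying capacity ``K``.  Its
occupation probabilities obey the master equation

    dP_N/dt = B(N-1) P_{N-1} - B(N) P_N,        N0 <= N <= K-1,

with ``P_K = 1 - sum_{N<K} P_N``.  Because the sizes are visited in a fixed
order, the hitting time of size ``N`` is a sum of independent exponential
waiting times with rates ``B(N0), ..., B(N-1)`` — a hypoexponential (phase
type) random variable — and the exact occupation probability is

    P_{N0,N}(t) = H_t(B_{N0}, ..., B_N) / B_N,

where ``H_t`` is the hypoexponential density.  Four routes to the same
distribution are provided and cross-checked:

* :func:`exact_distribution` — hypoexponential closed forms (Erlang /
  distinct-rate / partially degenerate cases), with an arbitrary-precision
  fallback when the alternating sums lose too many digits;
* :func:`spectral_distribution` — eigendecomposition of the bidiagonal
  generator, valid only when all rates are distinct;
* uniformization of the generator (numerically robust; the production
  default for long chains such as K = 100);
* :func:`master_equation_oracle` — direct stiff ODE integration, used as
  the independent ground truth in the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.special import gammaln

from .growth_models import GrowthModel, birth_rates

__all__ = [
    "DegenerateRatesError",
    "RateSequence",
    "SizeDistribution",
    "MomentTrajectory",
    "hypoexponential_pdf",
    "hypoexponential_cdf",
    "distribution_from_rates",
    "exact_distribution",
    "spectral_distribution",
    "master_equation_oracle",
    "distribution_moments",
    "relative_error",
]

#: relative tolerance under which two rates are treated as degenerate
GROUP_RTOL = 1e-9
#: estimated digits of cancellation beyond which the float closed forms
#: are abandoned for arbitrary precision
_CANCEL_GUARD = 1e6
#: number of rates above which ``method="auto"`` prefers uniformization
_AUTO_HYPOEXP_MAX = 40


class DegenerateRatesError(ValueError):
    """Raised when the spectral solution is requested for a rate sequence
    with repeated entries (degenerate eigenvalues)."""


# ---------------------------------------------------------------------------
# rate sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateSequence:
    """The ordered birth rates ``B(N0), ..., B(K-1)`` of a pure-birth chain.

    ``groups`` collects the unique rate values with their multiplicities
    (two rates are grouped when they differ by less than ``GROUP_RTOL``
    relative to the largest rate); grouping is permutation invariant.
    """

    N0: int
    K: int
    rates: tuple

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        if r.size != self.K - self.N0:
            raise ValueError("need exactly K - N0 rates")
        if r.size == 0:
            raise ValueError("empty rate sequence")
        if np.any(r <= 0):
            raise ValueError("all birth rates must be strictly positive")
        object.__setattr__(self, "rates", tuple(float(x) for x in r))

    @classmethod
    def from_model(cls, model: GrowthModel, N0: int) -> "RateSequence":
        return cls(N0=N0, K=model.K, rates=tuple(birth_rates(model, N0)))

    @property
    def groups(self) -> tuple[np.ndarray, np.ndarray]:
        """(unique rates, multiplicities), multiplicities summing to len(rates)."""
        return _group_rates(np.asarray(self.rates))

    @property
    def is_degenerate(self) -> bool:
        lam, mult = self.groups
        return bool(np.any(mult > 1))


def _group_rates(rates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    tol = GROUP_RTOL * float(np.max(rates))
    order = np.sort(np.asarray(rates, dtype=float))
    uniq, mult = [], []
    for r in order:
        if uniq and r - uniq[-1] <= tol:
            # keep the group representative stable: mean of members
            uniq[-1] = (uniq[-1] * mult[-1] + r) / (mult[-1] + 1)
            mult[-1] += 1
        else:
            uniq.append(r)
            mult.append(1)
    return np.asarray(uniq), np.asarray(mult, dtype=int)


# ---------------------------------------------------------------------------
# hypoexponential density
# ---------------------------------------------------------------------------

def _case3_coefficients(lam: np.ndarray, mult: np.ndarray):
    """Partial-fraction coefficients C[i][k] of the degenerate hypoexponential.

    C_{i,k} is the k-th derivative of f_i(s) = prod_{j != i} (s + lam_j)^(-n_j)
    at s = -lam_i, computed with the logarithmic-derivative recursion:
    derivatives of log f_i are elementary power sums, and
    f^{(k)} = sum_{p<k} C(k-1, p) f^{(p)} (log f)^{(k-p)}.
    """
    m = lam.size
    out = []
    for i in range(m):
        n_i = int(mult[i])
        diffs = lam[np.arange(m) != i] - lam[i]          # lam_j - lam_i
        n_j = mult[np.arange(m) != i].astype(float)
        # L[p] = p-th derivative of log f_i at s=-lam_i, p >= 1
        L = np.empty(n_i)  # L[p-1] holds order p
        for p in range(1, n_i + 1):
            L[p - 1] = -np.sum(n_j * (-1.0) ** (p - 1) * math.factorial(p - 1) / diffs**p)
        f = np.empty(n_i)
        with np.errstate(over="raise"):
            f[0] = np.prod(diffs ** (-n_j))
        for k in range(1, n_i):
            acc = 0.0
            for p in range(k):
                acc += math.comb(k - 1, p) * f[p] * L[k - 1 - p]
            f[k] = acc
        out.append(f)
    return out


def _hypoexp_terms_float(lam: np.ndarray, mult: np.ndarray, t: np.ndarray):
    """(values, max_term_magnitude) of the hypoexponential pdf at times t."""
    n = int(mult.sum())
    if lam.size == 1:
        # Case 1: Erlang(n, lam)
        lam0 = lam[0]
        logpdf = (n * math.log(lam0) - gammaln(n)
                  + (n - 1) * np.log(np.where(t > 0, t, 1.0)) - lam0 * t)
        pdf = np.where(t > 0, np.exp(logpdf), (lam0 if n == 1 else 0.0))
        return pdf, np.abs(pdf)
    if np.all(mult == 1):
        # Case 2: all distinct
        weights = np.empty(lam.size)
        for i in range(lam.size):
            others = lam[np.arange(lam.size) != i]
            weights[i] = lam[i] * np.prod(others / (others - lam[i]))
        terms = weights[None, :] * np.exp(-np.outer(t, lam))
        return terms.sum(axis=1), np.abs(terms).max(axis=1)
    # Case 3: partial degeneracy
    C = _case3_coefficients(lam, mult)
    pref = np.prod(lam**mult.astype(float))
    vals = np.zeros_like(t)
    peak = np.zeros_like(t)
    tt = np.where(t > 0, t, 1.0)
    for i in range(lam.size):
        n_i = int(mult[i])
        e = np.exp(-lam[i] * t)
        for k in range(n_i):
            pw = n_i - k - 1
            coef = pref * C[i][k] / (math.factorial(k) * math.factorial(pw))
            term = coef * np.where(t > 0, tt**pw, 1.0 if pw == 0 else 0.0) * e
            vals += term
            peak = np.maximum(peak, np.abs(term))
    return vals, peak


def _hypoexp_mpmath(lam: np.ndarray, mult: np.ndarray, t: np.ndarray, dps: int):
    """Arbitrary-precision evaluation of the Case 2/3 closed forms."""
    import mpmath as mp

    with mp.workdps(dps):
        lam_mp = [mp.mpf(x) for x in lam]
        out = np.empty(t.size)
        if np.all(mult == 1):
            w = []
            for i, li in enumerate(lam_mp):
                prod = mp.mpf(1)
                for j, lj in enumerate(lam_mp):
                    if j != i:
                        prod *= lj / (lj - li)
                w.append(li * prod)
            for k, tk in enumerate(t):
                s = mp.fsum(w[i] * mp.e**(-lam_mp[i] * mp.mpf(tk))
                            for i in range(len(lam_mp)))
                out[k] = float(s)
            return out
        # degenerate: derivatives of f_i via the same log-derivative recursion
        pref = mp.mpf(1)
        for li, ni in zip(lam_mp, mult):
            pref *= li ** int(ni)
        coeffs = []   # (i, power, coefficient)
        for i, li in enumerate(lam_mp):
            n_i = int(mult[i])
            diffs = [lam_mp[j] - li for j in range(len(lam_mp)) if j != i]
            n_j = [int(mult[j]) for j in range(len(lam_mp)) if j != i]
            L = [-mp.fsum(nj * (-1) ** (p - 1) * mp.factorial(p - 1) / dj**p
                          for nj, dj in zip(n_j, diffs)) for p in range(1, n_i + 1)]
            f = [mp.fprod(dj ** (-nj) for nj, dj in zip(n_j, diffs))]
            for k in range(1, n_i):
                f.append(mp.fsum(mp.binomial(k - 1, p) * f[p] * L[k - 1 - p]
                                 for p in range(k)))
            for k in range(n_i):
                pw = n_i - k - 1
                coeffs.append((i, pw, pref * f[k] / (mp.factorial(k) * mp.factorial(pw))))
        for kk, tk in enumerate(t):
            tmp = mp.mpf(tk)
            s = mp.fsum(c * (tmp**pw if (tmp > 0 or pw == 0) else 0) * mp.e**(-lam_mp[i] * tmp)
                        for i, pw, c in coeffs)
            out[kk] = float(s)
        return out


def hypoexponential_pdf(rates, t) -> float | np.ndarray:
    """Density of a sum of independent exponentials with the given rates.

    Dispatches among the Erlang (all rates equal), distinct-rate, and
    partially degenerate closed forms based on degeneracy grouping.  When
    the alternating sums of the float closed forms are estimated to cancel
    more than ~6 decimal digits, the evaluation is redone in arbitrary
    precision (mpmath) at a precision scaled to the estimated loss.
    """
    r = np.asarray(rates, dtype=float)
    if r.size == 0:
        raise ValueError("empty rate list")
    if np.any(r <= 0):
        raise ValueError("rates must be strictly positive")
    scalar = np.isscalar(t) or np.ndim(t) == 0
    tv = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tv < 0):
        raise ValueError("t must be >= 0")
    lam, mult = _group_rates(r)
    try:
        vals, peak = _hypoexp_terms_float(lam, mult, tv)
        with np.errstate(over="ignore"):
            loss = peak / np.maximum(np.abs(vals), np.finfo(float).tiny)
        bad = ~np.isfinite(vals) | ((peak > 1e-300) & (loss > _CANCEL_GUARD))
    except FloatingPointError:
        vals = np.full_like(tv, np.nan)
        peak = np.full_like(tv, 1e30)
        bad = np.ones_like(tv, dtype=bool)
    if np.any(bad):
        # digits needed ~ 16 + log10(estimated cancellation)
        est = float(np.max(np.where(np.isfinite(peak[bad]), peak[bad], 1e30)))
        dps = int(min(300, 30 + 1.2 * max(0.0, math.log10(max(est, 1.0)))))
        vals = vals.copy()
        vals[bad] = _hypoexp_mpmath(lam, mult, tv[bad], dps)
    vals = np.maximum(vals, 0.0)
    return float(vals[0]) if scalar else vals


def hypoexponential_cdf(rates, t) -> float | np.ndarray:
    """CDF of the hypoexponential hitting time, via the same closed forms
    applied to the integrated terms (used for the absorbing state)."""
    r = np.asarray(rates, dtype=float)
    scalar = np.isscalar(t) or np.ndim(t) == 0
    tv = np.atleast_1d(np.asarray(t, dtype=float))
    # integrate the pdf numerically is wasteful; use the survival expansion
    # via an auxiliary absorbing chain: CDF(t) = P(absorbed by t) computed
    # from uniformization of the linear chain with these rates.
    P = _uniformization(r, tv)
    out = P[:, -1]
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# full distributions
# ---------------------------------------------------------------------------

@dataclass
class SizeDistribution:
    """Time-indexed distribution P_{N0,N}(t) over sizes N0..K.

    ``probs[i, j]`` is the probability of size ``N0 + j`` at ``times[i]``.
    Rows sum to one; the absorbing mass ``P_{N0,K}`` is non-decreasing.
    """

    N0: int
    K: int
    times: np.ndarray
    probs: np.ndarray
    max_clamp: float = 0.0       # largest negative round-off clamped to 0
    max_rowsum_dev: float = 0.0  # worst |row sum - 1| before renormalization

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.N0, self.K + 1)

    def moment(self, m: int) -> np.ndarray:
        return self.probs @ (self.sizes.astype(float) ** m)

    def mean(self) -> np.ndarray:
        return self.moment(1)


def _finalize(N0, K, times, probs) -> SizeDistribution:
    probs = np.asarray(probs, dtype=float)
    clamp = float(max(0.0, -probs.min())) if probs.size else 0.0
    if clamp > 1e-9:
        raise RuntimeError(f"negative probability {-clamp:.3e} exceeds round-off budget")
    rowsum_dev = float(np.abs(probs.sum(axis=1) - 1.0).max()) if probs.size else 0.0
    probs = np.clip(probs, 0.0, 1.0)
    probs /= probs.sum(axis=1, keepdims=True)
    return SizeDistribution(N0=int(N0), K=int(K), times=np.asarray(times, float),
                            probs=probs, max_clamp=clamp, max_rowsum_dev=rowsum_dev)


def _uniformization(rates: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Transient probabilities of the linear absorbing chain with the given
    up-rates, by Poisson randomization of the embedded uniformized DTMC."""
    M = rates.size + 1
    lam_max = float(np.max(rates))
    t_max = float(np.max(times)) if times.size else 0.0
    a = lam_max * t_max
    if a == 0.0:
        P = np.zeros((times.size, M))
        P[:, 0] = 1.0
        return P
    kmax = int(stats.poisson.isf(1e-16, a)) + 5
    up = rates / lam_max
    stay = 1.0 - up
    V = np.empty((kmax + 1, M))
    v = np.zeros(M)
    v[0] = 1.0
    V[0] = v
    for k in range(1, kmax + 1):
        nxt = v.copy()
        nxt[:-1] = v[:-1] * stay
        nxt[1:] += v[:-1] * up
        v = nxt
        V[k] = v
    ks = np.arange(kmax + 1)
    W = stats.poisson.pmf(ks[None, :], (lam_max * times)[:, None])
    return W @ V


def distribution_from_rates(rates, N0: int, K: int, times,
                            method: str = "auto") -> SizeDistribution:
    """Exact size distribution of the pure-birth chain with explicit rates.

    method:
        ``hypoexp``        — Eq.-by-Eq. hypoexponential closed forms;
        ``uniformization`` — Poisson randomization of the generator;
        ``ode``            — stiff integration of the master equation;
        ``spectral``       — eigendecomposition (distinct rates only);
        ``auto``           — hypoexp for chains of <= 40 rates, else
                             uniformization.
    """
    r = np.asarray(rates, dtype=float)
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing")
    if method == "auto":
        method = "hypoexp" if r.size <= _AUTO_HYPOEXP_MAX else "uniformization"
    if method == "uniformization":
        probs = _uniformization(r, times)
        return _finalize(N0, K, times, probs)
    if method == "ode":
        probs = _master_equation_probs(r, times)
        return _finalize(N0, K, times, probs)
    if method == "spectral":
        probs = _spectral_probs(r, times)
        return _finalize(N0, K, times, probs)
    if method != "hypoexp":
        raise ValueError(f"unknown method {method!r}")
    M = r.size + 1
    probs = np.empty((times.size, M))
    for j in range(M - 1):
        probs[:, j] = hypoexponential_pdf(r[: j + 1], times) / r[j]
    probs[:, -1] = 1.0 - probs[:, :-1].sum(axis=1)
    return _finalize(N0, K, times, probs)


def exact_distribution(model: GrowthModel, N0: int, times,
                       method: str = "auto") -> SizeDistribution:
    """Exact transient size distribution of the pure-birth process.

    Requires a pure-birth model (d = 0) with alpha = 1.
    """
    if model.d > 0:
        raise ValueError("exact solution defined for pure-birth models only (d = 0)")
    seq = RateSequence.from_model(model, N0)
    return distribution_from_rates(seq.rates, N0, model.K, times, method=method)


def _spectral_probs(r: np.ndarray, times: np.ndarray) -> np.ndarray:
    lam, mult = _group_rates(r)
    if np.any(mult > 1):
        # report which chain states collide
        tol = GROUP_RTOL * float(np.max(r))
        idx = np.argsort(r, kind="stable")
        sorted_r = r[idx]
        pairs = [(int(idx[i]), int(idx[i + 1]))
                 for i in range(r.size - 1) if sorted_r[i + 1] - sorted_r[i] <= tol]
        raise DegenerateRatesError(
            f"degenerate birth rates; colliding state offsets (from N0): {pairs}")
    # identical algebra to the distinct-rate hypoexponential closed form,
    # so share its guarded (arbitrary-precision fallback) evaluation
    M = r.size + 1
    probs = np.empty((times.size, M))
    for j in range(M - 1):
        probs[:, j] = hypoexponential_pdf(r[: j + 1], times) / r[j]
    probs[:, -1] = 1.0 - probs[:, :-1].sum(axis=1)
    return probs


def spectral_distribution(model: GrowthModel, N0: int, times) -> SizeDistribution:
    """Spectral (eigendecomposition) solution of the master equation.

    The generator of the pure-birth chain is lower bidiagonal, so its
    eigenvalues are ``-B(N)``; the solution is a weighted superposition of
    exponentials.  Defined only when all rates are pairwise distinct —
    degenerate sequences (e.g. the logistic model's mirror symmetry
    B(N) = B(K-N)) raise :class:`DegenerateRatesError`.
    """
    if model.d > 0:
        raise ValueError("spectral solution defined for pure-birth models only")
    seq = RateSequence.from_model(model, N0)
    times = np.asarray(times, dtype=float)
    probs = _spectral_probs(np.asarray(seq.rates), times)
    return _finalize(N0, model.K, times, probs)


def _master_equation_probs(r: np.ndarray, times: np.ndarray) -> np.ndarray:
    M = r.size + 1
    rates_ext = np.concatenate([r, [0.0]])

    def rhs(_t, p):
        out = -rates_ext * p
        out[1:] += r * p[:-1]
        return out

    p0 = np.zeros(M)
    p0[0] = 1.0
    t_max = float(times[-1]) if times.size and times[-1] > 0 else 1e-12
    sol = solve_ivp(rhs, (0.0, t_max), p0, t_eval=times, method="LSODA",
                    rtol=1e-10, atol=1e-13)
    if not sol.success:
        raise RuntimeError(f"master-equation integration failed: {sol.message}")
    return sol.y.T


def master_equation_oracle(model: GrowthModel, N0: int, times) -> SizeDistribution:
    """Ground-truth distribution by direct stiff integration of the
    K - N0 + 1 coupled master equations (independent of the closed forms)."""
    if model.d > 0:
        raise ValueError("pure-birth oracle requires d = 0")
    seq = RateSequence.from_model(model, N0)
    times = np.asarray(times, dtype=float)
    probs = _master_equation_probs(np.asarray(seq.rates), times)
    return _finalize(N0, model.K, times, probs)


# ---------------------------------------------------------------------------
# moments and errors
# ---------------------------------------------------------------------------

@dataclass
class MomentTrajectory:
    """Moments ⟨N^m⟩(t) of a size distribution on a time grid."""

    times: np.ndarray
    values: dict   # order m -> array over times

    def __getitem__(self, m: int) -> np.ndarray:
        return self.values[m]


def distribution_moments(dist: SizeDistribution, orders=(1, 2)) -> MomentTrajectory:
    """Raw moments ⟨N^m⟩(t) = sum_N N^m P_{N0,N}(t) for each requested order."""
    vals = {int(m): dist.moment(int(m)) for m in orders}
    return MomentTrajectory(times=np.asarray(dist.times, float), values=vals)


def relative_error(deterministic, stochastic_mean) -> np.ndarray:
    """Relative error eta(t) = (N_det(t) - N_mean(t)) / N_mean(t) of a
    deterministic prediction against the exact (or simulated) mean."""
    det = np.asarray(deterministic, dtype=float)
    sto = np.asarray(stochastic_mean, dtype=float)
    if det.shape != sto.shape:
        raise ValueError("trajectories must share the same time grid")
    if np.any(sto <= 0):
        raise ZeroDivisionError("stochastic mean must be positive")
    return (det - sto) / sto
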