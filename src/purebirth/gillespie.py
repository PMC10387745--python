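"""Exact stochastic simulation (Gillespie) of the growth processes.

Single trajectories are simulated in pure Python with a seeded numpy
Generator and returned as :class:`Trajectory` objects.  Ensemble statistics
at the 10^5-replicate scale go through dedicated fast paths: the pure-birth
ensemble is fully vectorized (jump times are cumulative sums of independent
exponentials with fixed rates), while birth-death, two-strain community and
serial-passage ensembles use numba-compiled kernels.  Per-replicate seeds
are derived from the master seed through a numpy ``SeedSequence``, so
ensembles are reproducible and embarrassingly parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .growth_models import GrowthModel, birth_rates, population_birth_rate

__all__ = [
    "Trajectory",
    "simulate_pure_birth",
    "simulate_birth_death",
    "simulate_community",
    "simulate_serial_passage",
    "ensemble_mean",
    "pure_birth_ensemble_mean",
    "birth_death_extinction_fraction",
    "community_ensemble_means",
    "serial_passage_fixation_fraction",
]


@dataclass
class Trajectory:
    """Piecewise-constant sample path of a jump process.

    ``sizes[0]`` is the initial state; ``sizes[i]`` holds after
    ``jump_times[i-1]``.  For community runs ``mutants`` tracks the mutant
    count on the same grid.
    """

    jump_times: np.ndarray
    sizes: np.ndarray
    seed: int
    t_max: float
    mutants: np.ndarray | None = None

    def value_at(self, times, which: str = "sizes") -> np.ndarray:
        """State at each requested time (piecewise-constant, right-continuous)."""
        t = np.asarray(times, dtype=float)
        vals = self.sizes if which == "sizes" else self.mutants
        idx = np.searchsorted(self.jump_times, t, side="right")
        return vals[idx].astype(float)


def _per_capita_table(model: GrowthModel, K: int) -> np.ndarray:
    """g(N) = B(N)/(b N) for N = 0..K, with g(0) := 0 (no reproducers)."""
    N = np.arange(K + 1)
    B = np.asarray(population_birth_rate(model, N), dtype=float)
    g = np.zeros(K + 1)
    g[1:] = B[1:] / (model.b * N[1:])
    return g


def simulate_pure_birth(model: GrowthModel, N0: int, t_max: float, seed: int) -> Trajectory:
    """One pure-birth sample path: waiting time in state N is exponential
    with rate B(N); stops at ``t_max`` or on absorption at K."""
    if model.d > 0:
        raise ValueError("pure-birth simulation requires d = 0")
    rng = np.random.default_rng(seed)
    K = model.K
    times, sizes = [], [N0]
    t, N = 0.0, int(N0)
    while True:
        rate = population_birth_rate(model, N)
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t > t_max:
            break
        N += 1
        times.append(t)
        sizes.append(N)
        if N >= K:
            break
    return Trajectory(np.asarray(times), np.asarray(sizes), seed, t_max)


def simulate_birth_death(model: GrowthModel, N0: int, t_max: float, seed: int) -> Trajectory:
    """One birth-death sample path with total birth rate B(N) and total
    death rate d*N.  Only N = 0 is absorbing; at N = K births stop but
    deaths continue.  With d = 0 the path law (and the consumed random
    stream) coincides with :func:`simulate_pure_birth`."""
    rng = np.random.default_rng(seed)
    K = model.K if model.family != "exponential" else None
    times, sizes = [], [N0]
    t, N = 0.0, int(N0)
    while N > 0:
        rb = population_birth_rate(model, N) if (K is None or N <= K) else 0.0
        rd = model.d * N
        total = rb + rd
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        if rd > 0 and rng.random() * total >= rb:
            N -= 1
        else:
            N += 1
        times.append(t)
        sizes.append(N)
    return Trajectory(np.asarray(times), np.asarray(sizes), seed, t_max)


def simulate_community(model: GrowthModel, bW: float, bM: float, N0: int, n0: int,
                       t_max: float, seed: int) -> Trajectory:
    """One two-strain community path.  Births occur at total rate
    g(N)(bM n + bW (N - n)); each birth is a mutant with probability
    bM n / (bM n + bW (N - n))."""
    if not 0 <= n0 <= N0:
        raise ValueError("need 0 <= n0 <= N0")
    rng = np.random.default_rng(seed)
    K = model.K
    g = _per_capita_table(model, K)
    times, sizes, muts = [], [N0], [n0]
    t, N, n = 0.0, int(N0), int(n0)
    while N < K:
        rM = bM * g[N] * n
        rW = bW * g[N] * (N - n)
        total = rM + rW
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > t_max:
            break
        if rng.random() * total < rM:
            n += 1
        N += 1
        times.append(t)
        sizes.append(N)
        muts.append(n)
    return Trajectory(np.asarray(times), np.asarray(sizes), seed, t_max,
                      mutants=np.asarray(muts))


def simulate_serial_passage(model: GrowthModel, bW: float, bM: float, D: float,
                            tau: float, n0: int, seed: int,
                            max_cycles: int = 100_000) -> bool:
    """One serial-passage experiment: grow for ``tau``, then bottleneck by
    a binomial draw of N0 = D*K individuals; repeat until the mutant count
    hits 0 (loss) or N0 (fixation).  Returns True on fixation."""
    K = model.K
    N0 = D * K
    if abs(N0 - round(N0)) > 1e-9 or round(N0) < 2:
        raise ValueError("D*K must be an integer >= 2")
    N0 = int(round(N0))
    if not 0 <= n0 <= N0:
        raise ValueError("need 0 <= n0 <= N0")
    if n0 == 0:
        return False
    if n0 == N0:
        return True
    g = _per_capita_table(model, K)
    seeds = _spawn_seeds(seed, 1)
    res = _passage_kernel(g, float(bW), float(bM), K, N0, n0, float(tau),
                          seeds, max_cycles)
    return bool(res[0])


# ---------------------------------------------------------------------------
# ensemble statistics
# ---------------------------------------------------------------------------

def ensemble_mean(trajectories, times, which: str = "sizes"):
    """Mean and standard error of an ensemble of trajectories at grid times
    (piecewise-constant interpolation)."""
    t = np.asarray(times, dtype=float)
    vals = np.stack([tr.value_at(t, which=which) for tr in trajectories])
    mean = vals.mean(axis=0)
    n = vals.shape[0]
    se = vals.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, se


def pure_birth_ensemble_mean(model: GrowthModel, N0: int, times, n_reps: int,
                             seed: int):
    """Mean and standard error of the pure-birth size at grid times over
    ``n_reps`` replicates, vectorized through the hitting-time construction:
    the time of the j-th birth is the cumulative sum of exponentials with
    rates B(N0), ..., B(N0+j-1)."""
    rng = np.random.default_rng(seed)
    rates = birth_rates(model, N0)
    t = np.asarray(times, dtype=float)
    waits = rng.exponential(1.0 / rates, size=(n_reps, rates.size))
    hits = np.cumsum(waits, axis=1)
    mean = np.empty(t.size)
    se = np.empty(t.size)
    for i, ti in enumerate(t):
        sizes = N0 + (hits <= ti).sum(axis=1)
        mean[i] = sizes.mean()
        se[i] = sizes.std(ddof=1) / np.sqrt(n_reps)
    return mean, se


@njit(cache=True)
def _bd_extinct_kernel(B, d, N0, t_max, n_thresh, seeds):  # pragma: no cover
    n_ext = 0
    for i in range(seeds.size):
        np.random.seed(seeds[i])
        N = N0
        t = 0.0
        while True:
            rb = B[N]
            rd = d * N
            total = rb + rd
            if total <= 0.0:
                break
            t += np.random.exponential(1.0 / total)
            if t > t_max:
                break
            if np.random.random() * total < rb:
                N += 1
            else:
                N -= 1
            if N == 0:
                n_ext += 1
                break
            if N >= n_thresh:
                break  # escaped the rapid-extinction window
    return n_ext


def birth_death_extinction_fraction(model: GrowthModel, N0: int, n_reps: int,
                                    seed: int, t_max: float = 50.0,
                                    survival_threshold: int = 30) -> float:
    """Fraction of birth-death replicates that go extinct before growing.

    Rapid extinctions happen while the population is still small, so each
    replicate is stopped early once it reaches ``survival_threshold``
    individuals (counted as surviving)."""
    K = model.K
    B = np.zeros(K + 1)
    B[:K] = np.asarray(population_birth_rate(model, np.arange(K)), dtype=float)
    seeds = _spawn_seeds(seed, n_reps)
    n_ext = _bd_extinct_kernel(B, float(model.d), int(N0), float(t_max),
                               int(min(survival_threshold, K)), seeds)
    return n_ext / n_reps


@njit(cache=True)
def _community_kernel(g, bW, bM, K, N0, n0, times, seeds):  # pragma: no cover
    T = times.size
    sN = np.zeros(T)
    sn = np.zeros(T)
    sN2 = np.zeros(T)
    sn2 = np.zeros(T)
    for i in range(seeds.size):
        np.random.seed(seeds[i])
        t = 0.0
        N = N0
        n = n0
        ti = 0
        while ti < T:
            rM = bM * g[N] * n
            rW = bW * g[N] * (N - n)
            total = rM + rW
            if total <= 0.0:
                while ti < T:
                    sN[ti] += N
                    sn[ti] += n
                    sN2[ti] += N * N
                    sn2[ti] += n * n
                    ti += 1
                break
            t_next = t + np.random.exponential(1.0 / total)
            while ti < T and times[ti] < t_next:
                sN[ti] += N
                sn[ti] += n
                sN2[ti] += N * N
                sn2[ti] += n * n
                ti += 1
            t = t_next
            if np.random.random() * total < rM:
                n += 1
            N += 1
    return sN, sn, sN2, sn2


def community_ensemble_means(model: GrowthModel, bW: float, bM: float, N0: int,
                             n0: int, times, n_reps: int, seed: int):
    """Ensemble means (and standard errors) of total size N and mutant
    count n at grid times, over ``n_reps`` community replicates."""
    t = np.asarray(times, dtype=float)
    g = _per_capita_table(model, model.K)
    seeds = _spawn_seeds(seed, n_reps)
    sN, sn, sN2, sn2 = _community_kernel(g, float(bW), float(bM), int(model.K),
                                         int(N0), int(n0), t, seeds)
    meanN, meann = sN / n_reps, sn / n_reps
    varN = np.maximum(sN2 / n_reps - meanN**2, 0.0) * n_reps / (n_reps - 1)
    varn = np.maximum(sn2 / n_reps - meann**2, 0.0) * n_reps / (n_reps - 1)
    return meanN, meann, np.sqrt(varN / n_reps), np.sqrt(varn / n_reps)


@njit(cache=True)
def _passage_kernel(g, bW, bM, K, N0, n0, tau, seeds, max_cycles):  # pragma: no cover
    out = np.zeros(seeds.size, dtype=np.uint8)
    for i in range(seeds.size):
        np.random.seed(seeds[i])
        n = n0
        for _c in range(max_cycles):
            N = N0
            nn = n
            t = 0.0
            while N < K:
                rM = bM * g[N] * nn
                rW = bW * g[N] * (N - nn)
                total = rM + rW
                if total <= 0.0:
                    break
                t += np.random.exponential(1.0 / total)
                if t > tau:
                    break
                if np.random.random() * total < rM:
                    nn += 1
                N += 1
            n = np.random.binomial(N0, nn / N)
            if n == 0:
                break
            if n == N0:
                out[i] = 1
                break
    return out


def serial_passage_fixation_fraction(model: GrowthModel, bW: float, bM: float,
                                     D: float, tau: float, n0: int,
                                     n_reps: int, seed: int,
                                     max_cycles: int = 100_000):
    """Fixation frequency (and binomial SE) of the mutant strain over
    ``n_reps`` independent serial-passage experiments."""
    K = model.K
    N0 = D * K
    if abs(N0 - round(N0)) > 1e-9 or round(N0) < 2:
        raise ValueError("D*K must be an integer >= 2")
    N0 = int(round(N0))
    if not 0 <= n0 <= N0:
        raise ValueError("need 0 <= n0 <= N0")
    g = _per_capita_table(model, K)
    seeds = _spawn_seeds(seed, n_reps)
    out = _passage_kernel(g, float(bW), float(bM), int(K), N0, int(n0),
                          float(tau), seeds, int(max_cycles))
    p = out.mean()
    se = np.sqrt(p * (1 - p) / n_reps)
    return float(p), float(se)


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-replicate seeds derived from the master seed."""
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64)
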