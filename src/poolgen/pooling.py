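"""Mathematical-expectation (ME) pooled-screening design.

For a rare variant with per-individual carrier probability ``p`` among ``N``
samples, screening pools of ``n`` individuals and retesting only the members
of positive pools needs on average

    E[RT](n) = N/n + N * (1 - (1-p)^n)

PCR reactions: one reaction per pool plus ``n`` retests for each pool that
contains at least one carrier. Minimizing over the integer pool size gives
the ME design; at low carrier frequencies the optimum sits near 1/sqrt(p)
and the predicted reaction count is far below the ``N`` reactions of
one-by-one genotyping.

The module also provides pool assignment, a stochastic screening simulator
with optional pool-level false positives/negatives, carrier calling, and
savings accounting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MEDesign:
    """Optimal pooled-screening design for (N, p).

    Attributes
    ----------
    n_opt : optimal individuals per pool (NGn).
    expected_rt : expected reaction count at ``n_opt`` (real-valued).
    predicted_rt : ceiling of ``expected_rt`` (pRT, whole reactions).
    predicted_reduction : (N - predicted_rt) / N (pRR).
    """

    N: int
    p: float
    n_opt: int
    expected_rt: float
    predicted_rt: int
    predicted_reduction: float


@dataclass(frozen=True)
class PoolPlan:
    """Ordered partition of individual ids into pools; only the last pool may be short."""

    pools: tuple  # tuple of tuples of ids
    pool_size: int

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def sizes(self) -> List[int]:
        return [len(p) for p in self.pools]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pool_id": i, "individual_id": ind}
            for i, pool in enumerate(self.pools)
            for ind in pool
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PoolOutcome:
    """Result of one simulated pooled screen."""

    pool_positive: tuple  # observed positivity per pool
    calls: pd.Series  # individual id -> called genotype
    realized_rt: int
    reduction: float


def expected_reaction_times(N: int, p: float, n: int) -> float:
    """Expected PCR reaction count for pools of size ``n`` (continuous pool count).

    ``n = 1`` is individual testing and returns ``N`` exactly.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 < p < 1.0:
        raise ValueError(f"carrier frequency p must be in (0, 1), got {p}")
    if n < 1:
        raise ValueError("pool size n must be >= 1")
    if n > N:
        raise ValueError(f"pool size n={n} exceeds sample count N={N}")
    if n == 1:
        return float(N)
    return N / n + N * (1.0 - (1.0 - p) ** n)


def expected_realized_rt(N: int, p: float, n: int) -> float:
    """Exact expected reaction count for the integer pool layout.

    Uses ceil(N/n) pools with a short final pool; each pool of size ``k``
    contributes ``1 + k * (1 - (1-p)^k)`` expected reactions. Coincides with
    :func:`expected_reaction_times` whenever ``n`` divides ``N``.
    """
    if n == 1:
        return float(N)
    sizes = [n] * (N // n)
    if N % n:
        sizes.append(N % n)
    return sum(1.0 + k * (1.0 - (1.0 - p) ** k) for k in sizes)


def optimal_pool_size(N: int, p: float, n_max: Optional[int] = None) -> MEDesign:
    """Minimize the expected reaction count over integer pool sizes in [2, n_max].

    Ties are broken toward the larger pool size. Warns when ``p >= 0.5``
    (pooling then saves nothing: expected RT >= N for every pool size).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"carrier frequency p must be in (0, 1), got {p}")
    if n_max is None:
        n_max = N
    if n_max > N:
        raise ValueError(f"n_max={n_max} exceeds sample count N={N}")
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    if p >= 0.5:
        warnings.warn(
            "carrier frequency >= 0.5: pooled screening cannot beat individual testing",
            UserWarning,
            stacklevel=2,
        )
    ns = np.arange(2, n_max + 1)
    rts = N / ns + N * (1.0 - (1.0 - p) ** ns)
    # ties toward larger n: scan reversed, take the last index achieving the min
    best = int(ns[len(ns) - 1 - int(np.argmin(rts[::-1]))])
    expected = float(N / best + N * (1.0 - (1.0 - p) ** best))
    predicted = math.ceil(expected - 1e-9)
    return MEDesign(
        N=N,
        p=p,
        n_opt=best,
        expected_rt=expected,
        predicted_rt=predicted,
        predicted_reduction=(N - predicted) / N,
    )


def reaction_curve(N: int, p: float, n_max: int) -> pd.DataFrame:
    """Expected reaction count as a function of pool size (for plotting the design curve)."""
    rows = [{"n": n, "expected_rt": expected_reaction_times(N, p, n)} for n in range(1, n_max + 1)]
    return pd.DataFrame(rows)


def make_pools(
    ids: Sequence, n: int, shuffle: bool = False, seed: Optional[int] = None
) -> PoolPlan:
    """Partition ids into ceil(len(ids)/n) pools of size ``n`` (last may be short).

    Sequential chunking by default; ``shuffle`` permutes the ids first with a
    seeded RNG so repeated calls with the same seed give identical plans.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("cannot pool an empty id list")
    if n < 1:
        raise ValueError("pool size must be >= 1")
    if shuffle:
        rng = np.random.default_rng(seed)
        ids = [ids[i] for i in rng.permutation(len(ids))]
    pools = tuple(tuple(ids[i : i + n]) for i in range(0, len(ids), n))
    return PoolPlan(pools=pools, pool_size=n)


def run_pools(
    plan: PoolPlan,
    pop: pd.DataFrame,
    locus: str,
    mutant_allele: str,
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    seed: Optional[int] = None,
) -> PoolOutcome:
    """Simulate one pooled screen of a genotyped herd.

    A pool is truly positive iff it contains at least one carrier (an
    individual whose genotype includes the mutant allele). Observed
    positivity flips the truth with probability ``fp_rate``
    (negative -> positive) or ``fn_rate`` (positive -> negative), modelling
    pool-level PCR artifacts. Members of observed-positive pools are retested
    individually (error-free) and receive their true genotype; everyone in an
    observed-negative pool is called homozygous reference — so carriers in
    false-negative pools are miscalled, a leakage this simulator makes
    measurable.
    """
    if not 0.0 <= fp_rate <= 1.0 or not 0.0 <= fn_rate <= 1.0:
        raise ValueError("fp_rate and fn_rate must be in [0, 1]")
    if locus not in pop.columns:
        raise ValueError(f"locus {locus!r} not in population table")
    if mutant_allele not in ("I", "D"):
        raise ValueError("mutant_allele must be 'I' or 'D'")
    genotype = dict(zip(pop["id"], pop[locus]))
    plan_ids = [ind for pool in plan.pools for ind in pool]
    missing = set(plan_ids) - genotype.keys()
    if missing:
        raise ValueError(f"plan contains ids absent from the population: {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    ref_homo = "II" if mutant_allele == "D" else "DD"

    calls = {}
    observed = []
    realized = plan.n_pools
    flips = rng.random(plan.n_pools)
    for k, pool in enumerate(plan.pools):
        truth = any(mutant_allele in genotype[ind] for ind in pool)
        obs = (flips[k] >= fn_rate) if truth else (flips[k] < fp_rate)
        observed.append(obs)
        if obs:
            realized += len(pool)
            for ind in pool:
                calls[ind] = genotype[ind]
        else:
            for ind in pool:
                calls[ind] = ref_homo
    n_total = len(plan_ids)
    return PoolOutcome(
        pool_positive=tuple(observed),
        calls=pd.Series(calls, name=locus),
        realized_rt=realized,
        reduction=reduction_rate(realized, n_total),
    )


def reduction_rate(realized_rt: int, N: int) -> float:
    """Fraction of reactions saved relative to individual testing: (N - RT)/N.

    Negative when the screen cost more than one-by-one genotyping.
    """
    if N == 0:
        raise ValueError("N must be positive")
    if realized_rt < 0:
        raise ValueError("realized_rt must be >= 0")
    return (N - realized_rt) / N


def simulate_realized_rt(
    N: int,
    p: float,
    n: int,
    reps: int,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Vectorized Monte-Carlo of the realized reaction count, error-free pooling.

    Carriers are iid Bernoulli(p); pools are the integer layout of
    :func:`expected_realized_rt`. Returns the realized RT of each replicate,
    for checking the expectation formula against simulation.
    """
    if n < 1:
        raise ValueError("pool size must be >= 1")
    rng = np.random.default_rng(seed)
    carriers = rng.random((reps, N)) < p
    if n == 1:
        return np.full(reps, N)
    n_full = N // n
    rem = N % n
    full = carriers[:, : n_full * n].reshape(reps, n_full, n).any(axis=2)
    retests = full.sum(axis=1) * n
    n_pools = n_full
    if rem:
        last = carriers[:, n_full * n :].any(axis=1)
        retests = retests + last * rem
        n_pools += 1
    return n_pools + retests
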