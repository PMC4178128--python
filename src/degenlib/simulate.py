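"""Monte Carlo simulation of random clone picking.

Estimates, per discovery rank k, how many clones must be drawn between
the (k-1)-th and k-th new target variant (incremental) and in total up
to the k-th (cumulative), over many independent library screens.

Sampling is done at the discovery level: with missing-target mass q the
waiting time to the next discovery is Geometric(q) and the discovered
target is chosen proportionally to its probability among the missing
ones.  This is distribution-identical to clone-by-clone drawing (stop
codons and off-target draws are consumed inside the geometric waits)
and allows fully vectorized iteration batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .genetic_code import VariantDistribution
from .library_stats import expected_distinct

__all__ = [
    "SimulationConfig",
    "RankStats",
    "SimulationSummary",
    "FixedScreenResult",
    "simulate_screening",
    "simulate_fixed_screen",
]

# Iterations are processed in fixed-size blocks so memory stays bounded
# while the RNG stream (and therefore every output) is bit-reproducible.
_BLOCK = 65536


@dataclass(frozen=True)
class SimulationConfig:
    dist: VariantDistribution
    targets: FrozenSet[str]
    n_iterations: int = 1_000_000
    seed: int = 0
    record: str = "both"  # incremental | cumulative | both

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", frozenset(self.targets))
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.record not in ("incremental", "cumulative", "both"):
            raise ValueError(f"invalid record mode {self.record!r}")
        unreachable = sorted(
            t for t in self.targets if self.dist.p(t) == 0
        )
        if unreachable:
            raise ValueError(
                f"targets unreachable under the distribution: {unreachable}"
            )
        if not self.targets:
            raise ValueError("target set must be nonempty")


@dataclass(frozen=True)
class RankStats:
    """Mean/sd of clone counts at one discovery rank."""

    rank: int
    incremental_mean: float
    incremental_sd: float
    cumulative_mean: float
    cumulative_sd: float


@dataclass(frozen=True)
class SimulationSummary:
    per_rank: Tuple[RankStats, ...]
    n_iterations: int
    seed: int

    @property
    def full_collection_mean(self) -> float:
        return self.per_rank[-1].cumulative_mean

    @property
    def full_collection_sd(self) -> float:
        return self.per_rank[-1].cumulative_sd

    @property
    def full_collection_se(self) -> float:
        """Monte Carlo standard error of the full-collection mean."""
        return self.per_rank[-1].cumulative_sd / np.sqrt(self.n_iterations)


class _Moments:
    """Streaming count/mean/M2 accumulator (Chan parallel combination)."""

    def __init__(self, k: int) -> None:
        self.n = 0
        self.mean = np.zeros(k)
        self.m2 = np.zeros(k)

    def update(self, block: np.ndarray) -> None:
        n_b = block.shape[0]
        mean_b = block.mean(axis=0)
        m2_b = ((block - mean_b) ** 2).sum(axis=0)
        delta = mean_b - self.mean
        n_tot = self.n + n_b
        self.mean += delta * (n_b / n_tot)
        self.m2 += m2_b + delta**2 * (self.n * n_b / n_tot)
        self.n = n_tot

    def sd(self) -> np.ndarray:
        if self.n < 2:
            return np.zeros_like(self.mean)
        return np.sqrt(self.m2 / (self.n - 1))


def simulate_screening(config: SimulationConfig) -> SimulationSummary:
    """Run the clone-picking simulation and aggregate per-rank statistics."""
    targets = sorted(config.targets)
    p = np.array([float(config.dist.p(t)) for t in targets])
    k = len(targets)
    rng = np.random.default_rng(config.seed)

    inc = _Moments(k)
    cum = _Moments(k)

    remaining = config.n_iterations
    while remaining > 0:
        m = min(_BLOCK, remaining)
        remaining -= m

        missing = np.ones((m, k), dtype=bool)
        inc_block = np.empty((m, k))
        for rank in range(k):
            pm = np.where(missing, p, 0.0)
            cdf = np.cumsum(pm, axis=1)
            q = cdf[:, -1]
            # u in (0, q] so the first index with cdf >= u always has
            # positive missing mass (rng.random may return exactly 0).
            u = (1.0 - rng.random(m)) * q
            idx = np.minimum((cdf < u[:, None]).sum(axis=1), k - 1)
            inc_block[:, rank] = rng.geometric(q)
            missing[np.arange(m), idx] = False
        inc.update(inc_block)
        cum.update(np.cumsum(inc_block, axis=1))

    per_rank = tuple(
        RankStats(
            rank=r + 1,
            incremental_mean=float(inc.mean[r]),
            incremental_sd=float(inc.sd()[r]),
            cumulative_mean=float(cum.mean[r]),
            cumulative_sd=float(cum.sd()[r]),
        )
        for r in range(k)
    )
    return SimulationSummary(
        per_rank=per_rank, n_iterations=config.n_iterations, seed=config.seed
    )


@dataclass(frozen=True)
class FixedScreenResult:
    """Empirical distribution of distinct-target counts in a fixed screen."""

    n_clones: int
    n_iterations: int
    seed: int
    distinct_counts: Dict[int, int]  # distinct targets -> iterations
    mean_distinct: float
    sd_distinct: float
    compositions: Optional[np.ndarray] = None  # (n_samples, n_targets)
    target_order: Tuple[str, ...] = ()

    @property
    def se_distinct(self) -> float:
        return self.sd_distinct / np.sqrt(self.n_iterations)


def simulate_fixed_screen(
    dist: VariantDistribution,
    n_clones: int,
    n_iterations: int,
    seed: int,
    targets: Optional[FrozenSet[str]] = None,
    keep_compositions: int = 0,
) -> FixedScreenResult:
    """Draw n_clones i.i.d. clones per iteration; count distinct targets.

    The mean distinct count converges to
    :func:`~degenlib.library_stats.expected_distinct`.  Draws are over the
    full variant space; only target variants count toward distinctness.
    Up to ``keep_compositions`` per-variant count vectors are retained.
    """
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if targets is None:
        targets = dist.reachable_amino_acids
    t_sorted = sorted(targets)
    symbols = sorted(dist.reachable)
    pvec = np.array([float(dist.p(s)) for s in symbols])
    pvec = pvec / pvec.sum()  # guard rounding; exact fractions sum to 1
    t_idx = np.array([symbols.index(t) for t in t_sorted if t in symbols], dtype=int)

    rng = np.random.default_rng(seed)
    hist: Dict[int, int] = {}
    total = 0.0
    total_sq = 0.0
    kept: List[np.ndarray] = []

    remaining = n_iterations
    while remaining > 0:
        m = min(_BLOCK, remaining)
        remaining -= m
        counts = rng.multinomial(n_clones, pvec, size=m)
        distinct = (counts[:, t_idx] > 0).sum(axis=1) if len(t_idx) else np.zeros(m, int)
        vals, freq = np.unique(distinct, return_counts=True)
        for v, f in zip(vals, freq):
            hist[int(v)] = hist.get(int(v), 0) + int(f)
        total += float(distinct.sum())
        total_sq += float((distinct.astype(float) ** 2).sum())
        if len(kept) < keep_compositions:
            take = min(keep_compositions - len(kept), m)
            kept.extend(counts[i, t_idx] for i in range(take))

    mean = total / n_iterations
    var = max(total_sq / n_iterations - mean**2, 0.0)
    sd = float(np.sqrt(var * n_iterations / max(n_iterations - 1, 1)))
    return FixedScreenResult(
        n_clones=n_clones,
        n_iterations=n_iterations,
        seed=seed,
        distinct_counts=dict(sorted(hist.items())),
        mean_distinct=mean,
        sd_distinct=sd,
        compositions=np.array(kept) if kept else None,
        target_order=tuple(t_sorted),
    )
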