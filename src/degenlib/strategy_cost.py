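"""Cost model for library construction strategies.

Compares pure random screening, pure one-by-one site-directed
mutagenesis (SDM), and the hybrid strategy: screen n random clones,
then construct every still-missing target variant by SDM.  Hybrid cost
is the risk-neutral expectation

    cost(n) = n * cost_per_screened_clone
            + E[missing after n] * cost_per_sdm_variant

where unreachable targets always count as SDM work.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import numpy as np

from .genetic_code import DegenerateCodon, VariantDistribution
from .library_stats import (
    LibraryDesign,
    ObservedComposition,
    expected_missing,
    min_library_size,
)

__all__ = [
    "CostModel",
    "StrategyEvaluation",
    "evaluate_strategy",
    "optimal_switch_point",
    "realized_cost",
]

# Default unit costs: SDM variant = oligo synthesis + QuikChange reaction
# + DNA isolation + sequencing; screened clone = isolation + sequencing.
DEFAULT_SCREEN_COST = 20.0
DEFAULT_SDM_COST = 100.0


@dataclass(frozen=True)
class CostModel:
    cost_per_screened_clone: float = DEFAULT_SCREEN_COST
    cost_per_sdm_variant: float = DEFAULT_SDM_COST

    def __post_init__(self) -> None:
        if self.cost_per_screened_clone <= 0 or self.cost_per_sdm_variant <= 0:
            raise ValueError("unit costs must be strictly positive")


@dataclass(frozen=True)
class StrategyEvaluation:
    n_random: int
    expected_missing: float
    screening_cost: float
    sdm_cost: float

    @property
    def expected_total_cost(self) -> float:
        return self.screening_cost + self.sdm_cost


def evaluate_strategy(
    dist: VariantDistribution,
    targets: Iterable[str],
    cost: CostModel,
    n_random: int,
) -> StrategyEvaluation:
    """Expected cost of screening n_random clones then SDM-ing the rest."""
    if n_random < 0:
        raise ValueError("n_random must be >= 0")
    targets = sorted(set(targets))
    miss = expected_missing(dist, n_random, targets)
    return StrategyEvaluation(
        n_random=n_random,
        expected_missing=miss,
        screening_cost=n_random * cost.cost_per_screened_clone,
        sdm_cost=miss * cost.cost_per_sdm_variant,
    )


def _default_n_max(dist: VariantDistribution, targets: List[str]) -> int:
    """4x the 95% library size, or 1000 when some target is unreachable."""
    reachable = [t for t in targets if dist.p(t) > 0]
    if len(reachable) < len(targets) or not reachable:
        return 1000
    try:
        scheme = DegenerateCodon(dist.source)
    except ValueError:
        scheme = DegenerateCodon("NNN")  # placeholder; unused by the search
    design = LibraryDesign(scheme=scheme, targets=frozenset(reachable), threshold=0.95)
    return 4 * min_library_size(design, dist, method="product")


def optimal_switch_point(
    dist: VariantDistribution,
    targets: Iterable[str],
    cost: CostModel,
    n_max: Optional[int] = None,
) -> Tuple[int, List[StrategyEvaluation]]:
    """Cost-minimizing number of random clones before switching to SDM.

    Returns the argmin over n in [0, n_max] (ties broken toward smaller
    n) together with the full cost curve for reporting.
    """
    targets = sorted(set(targets))
    if n_max is None:
        n_max = _default_n_max(dist, targets)
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    curve = [evaluate_strategy(dist, targets, cost, n) for n in range(n_max + 1)]
    costs = np.array([ev.expected_total_cost for ev in curve])
    n_star = int(np.argmin(costs))  # argmin returns the first minimum
    return n_star, curve


def realized_cost(
    observed: ObservedComposition,
    remaining_sdm_variants: Iterable[str],
    cost: CostModel,
) -> float:
    """Actual cost of a finished screen plus its SDM completions."""
    remaining = set(remaining_sdm_variants)
    return (
        observed.n_clones * cost.cost_per_screened_clone
        + len(remaining) * cost.cost_per_sdm_variant
    )
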