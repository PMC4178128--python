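"""Analytic statistics for single-position randomized libraries.

Completeness probabilities, minimum screening sizes, expected
distinct/missing variant counts and coupon-collector waiting times for a
variant distribution induced by a degenerate codon.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Sequence, Tuple

import numpy as np

from .genetic_code import AMINO_ACIDS, STOP, DegenerateCodon, VariantDistribution

__all__ = [
    "LibraryDesign",
    "ObservedComposition",
    "EXACT_TARGET_CAP",
    "completeness_probability",
    "min_library_size",
    "expected_distinct",
    "expected_missing",
    "expected_collection_time",
    "probability_monotypic",
    "expected_counts",
    "size_report",
]

#: Largest target set handled by the exact inclusion-exclusion method
#: (2**22 signed terms); single-position libraries never exceed 21 variants.
EXACT_TARGET_CAP = 22


@dataclass(frozen=True)
class LibraryDesign:
    """A codon scheme, a target variant set, and a confidence threshold."""

    scheme: DegenerateCodon
    targets: FrozenSet[str] = field(default=frozenset())
    threshold: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0,1), got {self.threshold}")
        object.__setattr__(self, "targets", frozenset(self.targets))
        if not self.targets:
            raise ValueError("target set must be nonempty")


@dataclass(frozen=True)
class ObservedComposition:
    """Variant -> clone-count table from a sequenced screen."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be nonnegative")

    @property
    def n_clones(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct(self) -> FrozenSet[str]:
        return frozenset(v for v, c in self.counts.items() if c > 0)


def _target_probs(dist: VariantDistribution, targets: Iterable[str]) -> np.ndarray:
    syms = sorted(set(targets))
    return np.array([float(dist.p(s)) for s in syms], dtype=float)


def _subset_sums_signs(ps: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Probabilities summed over every subset of targets, with IE signs."""
    sums = np.zeros(1)
    signs = np.ones(1)
    for p in ps:
        sums = np.concatenate([sums, sums + p])
        signs = np.concatenate([signs, -signs])
    return sums, signs


def _pow_one_minus(s: np.ndarray, L: int) -> np.ndarray:
    """(1-s)^L via exp(L*log1p(-s)), safe against underflow and s == 1."""
    if L == 0:
        return np.ones_like(s)
    with np.errstate(divide="ignore"):
        out = np.exp(L * np.log1p(-np.minimum(s, 1.0)))
    return np.where(s >= 1.0, 0.0, out)


def completeness_probability(
    dist: VariantDistribution,
    L: int,
    targets: Iterable[str],
    method: str = "exact",
) -> float:
    """P(all targets present among L i.i.d. clones).

    ``exact`` evaluates the inclusion-exclusion sum
    sum_{S subset targets} (-1)^|S| (1 - sum_{i in S} p_i)^L;
    ``product`` the independence approximation
    prod_i (1 - (1-p_i)^L).  A target with zero probability forces 0.
    """
    if L < 0:
        raise ValueError("L must be >= 0")
    targets = sorted(set(targets))
    if not targets:
        return 1.0
    ps = _target_probs(dist, targets)
    if np.any(ps == 0.0):
        return 0.0
    if L == 0:
        return 0.0
    if method == "product":
        return float(np.prod(1.0 - _pow_one_minus(ps, L)))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    if len(targets) > EXACT_TARGET_CAP:
        raise ValueError(
            f"{len(targets)} targets exceed the exact-method cap of "
            f"{EXACT_TARGET_CAP}; use method='product'"
        )
    sums, signs = _subset_sums_signs(ps)
    val = float(np.sum(signs * _pow_one_minus(sums, L)))
    return min(max(val, 0.0), 1.0)


def min_library_size(
    design: LibraryDesign,
    dist: VariantDistribution,
    method: str = "exact",
) -> int:
    """Smallest L with completeness >= the design threshold.

    Found by doubling then binary search; completeness is nondecreasing
    in L.  Raises if any target is unreachable under the distribution.
    """
    targets = sorted(design.targets)
    unreachable = [t for t in targets if dist.p(t) == 0]
    if unreachable:
        raise ValueError(
            f"targets unreachable under the distribution: {unreachable}"
        )
    ps = _target_probs(dist, targets)
    theta = design.threshold

    if method == "exact":
        if len(targets) > EXACT_TARGET_CAP:
            raise ValueError(
                f"{len(targets)} targets exceed the exact-method cap of "
                f"{EXACT_TARGET_CAP}; use method='product'"
            )
        sums, signs = _subset_sums_signs(ps)

        def prob(L: int) -> float:
            if L == 0:
                return 0.0
            return float(np.sum(signs * _pow_one_minus(sums, L)))

    elif method == "product":

        def prob(L: int) -> float:
            return float(np.prod(1.0 - _pow_one_minus(ps, L)))

    else:
        raise ValueError(f"unknown method {method!r}")

    hi = 1
    while prob(hi) < theta:
        hi *= 2
        if hi > 10**9:  # pragma: no cover - pathological thresholds
            raise RuntimeError("library size search exceeded 1e9 clones")
    lo = hi // 2  # prob(lo) < theta (or lo == 0)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if prob(mid) >= theta:
            hi = mid
        else:
            lo = mid
    return hi


def expected_distinct(
    dist: VariantDistribution, L: int, targets: Iterable[str]
) -> float:
    """Expected number of distinct target variants among L clones."""
    if L < 0:
        raise ValueError("L must be >= 0")
    ps = _target_probs(dist, targets)
    return float(np.sum(1.0 - _pow_one_minus(ps, L)))


def expected_missing(
    dist: VariantDistribution, n: int, targets: Iterable[str]
) -> float:
    """Expected number of target variants absent after n clones."""
    if n < 0:
        raise ValueError("n must be >= 0")
    ps = _target_probs(dist, targets)
    return float(np.sum(_pow_one_minus(ps, n)))


def expected_collection_time(
    dist: VariantDistribution, targets: Iterable[str]
) -> float:
    """Expected clones drawn until every target has appeared at least once.

    Inclusion-exclusion for the unequal-probability coupon collector:
    sum over nonempty subsets S of (-1)^(|S|+1) / (sum_{i in S} p_i).
    Off-target draws (e.g. stop codons) consume clones automatically
    because the p_i are fractions of the whole codon space.
    """
    targets = sorted(set(targets))
    ps = _target_probs(dist, targets)
    unreachable = [t for t, p in zip(targets, ps) if p == 0.0]
    if unreachable:
        raise ValueError(f"targets unreachable under the distribution: {unreachable}")
    if len(targets) > EXACT_TARGET_CAP:
        raise ValueError(
            f"{len(targets)} targets exceed the exact-method cap of {EXACT_TARGET_CAP}"
        )
    sums, signs = _subset_sums_signs(ps)
    # skip the empty subset (index 0); signs[k] = (-1)^|S| so negate.
    with np.errstate(divide="ignore"):
        terms = -signs[1:] / sums[1:]
    return float(np.sum(terms))


def probability_monotypic(dist: VariantDistribution, variant: str, n: int) -> float:
    """Probability that all n clones carry the same given variant: p^n."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return float(dist.p(variant)) ** n


def expected_counts(
    n: int, dist: VariantDistribution, targets: Iterable[str]
) -> Dict[str, float]:
    """Expected per-variant clone counts in a screen of n clones: n * p_i."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return {t: n * float(dist.p(t)) for t in sorted(set(targets))}


def size_report(
    design: LibraryDesign,
    dist: VariantDistribution,
    method: str = "exact",
) -> Dict[str, object]:
    """L* report row: scheme, targets, threshold, method, L*, P(L*), P(L*-1)."""
    lstar = min_library_size(design, dist, method=method)
    return {
        "scheme": str(design.scheme),
        "targets": "".join(sorted(design.targets)),
        "n_targets": len(design.targets),
        "threshold": design.threshold,
        "method": method,
        "L_star": lstar,
        "P_at_L_star": completeness_probability(dist, lstar, design.targets, method),
        "P_below": completeness_probability(dist, lstar - 1, design.targets, method),
    }
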