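"""Quantifying alignment gain and characterizing permutations.

The central statistic is the alignment gain

    eta(P, a, b) = ||C_a - C_b||_F - ||P C_a P^T - C_b||_F ,

the drop in Frobenius distance between two subjects' connectomes achieved
by permuting subject ``a``'s regions with ``P``. Positive eta means the
permutation made the connectomes more similar; eta computed on a modality
not used when estimating ``P`` measures generalization of the permutation.

Significance of a collection of gains is assessed with a one-sided
Wilcoxon signed-rank test (gains stochastically greater than a symmetric
null) under Bonferroni control over the family of tested conditions.
Permutations are further characterized spatially: each moved label is
classified as a self (distance 0), local (distance 1) or remote
(distance >= 2) move by its shortest-path distance on the region
adjacency graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectomes import Connectome
from .solver import PermutationMatrix

__all__ = [
    "EtaRecord",
    "PermutationSpatialSummary",
    "WilcoxonReport",
    "eta",
    "wilcoxon_assess",
    "permutation_distances",
    "reference_variability",
    "permutation_agreement",
    "alignment_design_count",
    "hypothesis_count",
    "bonferroni_threshold",
]


def alignment_design_count(
    n_subjects: int = 600, n_alphas: int = 11, n_strategies: int = 3,
    n_training_sets: int = 2,
) -> int:
    """Total alignments in an all-to-all cohort design.

    Every subject is aligned to every other (ordered pairs, since moving
    and reference roles differ), for each value of the SC/FC mixing
    weight, each constraint strategy, and each training dataset.
    """
    ordered_pairs = n_subjects * (n_subjects - 1)
    return ordered_pairs * n_alphas * n_strategies * n_training_sets


def hypothesis_count(
    n_alphas: int = 11, n_strategies: int = 3, n_connectome_types: int = 4,
    n_training_sets: int = 2,
) -> int:
    """Number of tested (alpha, strategy, connectome type, training set) cells."""
    return n_alphas * n_strategies * n_connectome_types * n_training_sets


def bonferroni_threshold(family_alpha: float = 0.001, n_hypotheses: int = 264) -> float:
    """Per-test significance threshold under Bonferroni control."""
    if n_hypotheses < 1:
        raise ValueError("n_hypotheses must be >= 1")
    return family_alpha / n_hypotheses


@dataclass(frozen=True)
class EtaRecord:
    """One alignment-gain observation (tidy long-format row)."""

    eta: float
    modality: str
    moving: str
    reference: str
    alpha: float
    strategy: str
    in_training: bool


@dataclass(frozen=True)
class PermutationSpatialSummary:
    """Spatial classification of one permutation's moves.

    ``per_region_distance[k]`` is the adjacency-graph distance between
    label ``k``'s original and final positions. Counts partition the
    regions into self (d=0), local (d=1) and remote (d>=2, including
    unreachable) moves.
    """

    per_region_distance: np.ndarray
    self_count: int
    local_count: int
    remote_count: int
    mean_distance: float
    has_infinite_move: bool = False

    @property
    def counts(self) -> dict:
        return {
            "self": self.self_count,
            "local": self.local_count,
            "remote": self.remote_count,
        }


@dataclass(frozen=True)
class WilcoxonReport:
    """One-sided signed-rank test under Bonferroni control."""

    p_value: float
    statistic: float
    n_used: int
    n_hypotheses: int
    family_alpha: float
    corrected_threshold: float
    significant: bool
    significant_decrease: bool


def eta(P: PermutationMatrix, C_a, C_b) -> float:
    """Alignment gain: pre- minus post-permutation Frobenius distance.

    Positive iff permuting subject ``a``'s regions by ``P`` brought its
    connectome closer to subject ``b``'s. Connectome inputs must share the
    modality (comparing an SC distance with an FC distance is meaningless).
    """
    if isinstance(C_a, Connectome) and isinstance(C_b, Connectome):
        if C_a.modality != C_b.modality:
            raise ValueError(
                f"modality mismatch: {C_a.modality} vs {C_b.modality}"
            )
    A = C_a.values if isinstance(C_a, Connectome) else np.asarray(C_a, dtype=float)
    B = C_b.values if isinstance(C_b, Connectome) else np.asarray(C_b, dtype=float)
    if A.shape != B.shape or A.shape[0] != P.n:
        raise ValueError("connectomes and permutation must share N")
    before = np.linalg.norm(A - B)
    after = np.linalg.norm(P.apply(A) - B)
    return float(before - after)


def wilcoxon_assess(
    etas, n_hypotheses: int = 264, family_alpha: float = 0.001
) -> WilcoxonReport:
    """One-sided Wilcoxon signed-rank test on alignment gains.

    Tests whether the gains are stochastically greater than a distribution
    symmetric about zero. Exact null distribution for n <= 25 (after
    discarding exact zeros, Wilcoxon's original treatment), normal
    approximation with continuity correction above. The significance
    threshold is Bonferroni-corrected: ``family_alpha / n_hypotheses``.
    A significant decrease (the complementary one-sided test) is reported
    alongside.
    """
    x = np.asarray(etas, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("etas must be a non-empty 1-D collection")
    nonzero = x[x != 0]
    if nonzero.size == 0:
        raise ValueError("all gains are exactly zero: the signed-rank test is undefined")
    method = "exact" if nonzero.size <= 25 and np.unique(np.abs(nonzero)).size == nonzero.size else "approx"
    greater = stats.wilcoxon(x, zero_method="wilcox", alternative="greater",
                             method=method, correction=(method == "approx"))
    less = stats.wilcoxon(x, zero_method="wilcox", alternative="less",
                          method=method, correction=(method == "approx"))
    if n_hypotheses < 1:
        raise ValueError("n_hypotheses must be >= 1")
    threshold = family_alpha / n_hypotheses
    return WilcoxonReport(
        p_value=float(greater.pvalue),
        statistic=float(greater.statistic),
        n_used=int(nonzero.size),
        n_hypotheses=n_hypotheses,
        family_alpha=family_alpha,
        corrected_threshold=threshold,
        significant=bool(greater.pvalue < threshold),
        significant_decrease=bool(less.pvalue < threshold),
    )


def permutation_distances(
    P: PermutationMatrix, dist: np.ndarray
) -> PermutationSpatialSummary:
    """Classify each label's move by adjacency-graph distance.

    ``dist`` is the all-pairs shortest-path matrix from
    :func:`~connalign.constraints.region_graph_distances`. Label ``k``'s
    distance is measured between its original position and the position it
    ends up at. An unreachable move (infinite distance) counts as remote
    and is flagged.
    """
    dist = np.asarray(dist, dtype=float)
    n = P.n
    if dist.shape != (n, n):
        raise ValueError("distance matrix size does not match permutation")
    # label l sits at position k with mapping[k] = l, i.e. position sigma(l)=k
    sigma = P.inverse().mapping
    d = dist[np.arange(n), sigma]
    self_count = int(np.sum(d == 0))
    local_count = int(np.sum(d == 1))
    remote_count = int(n - self_count - local_count)
    finite = d[np.isfinite(d)]
    return PermutationSpatialSummary(
        per_region_distance=d,
        self_count=self_count,
        local_count=local_count,
        remote_count=remote_count,
        mean_distance=float(finite.mean()) if finite.size else float("nan"),
        has_infinite_move=bool(np.any(~np.isfinite(d))),
    )


def reference_variability(records, ddof: int = 0):
    """Mean alignment gain per reference subject, and its spread.

    Some subjects are systematically better references than others; the
    standard deviation of per-reference mean gains across references
    quantifies how much the choice of reference matters. ``ddof=0``
    (population denominator) by default; pass ``ddof=1`` for the sample
    convention.

    ``records`` is an iterable of :class:`EtaRecord` or of
    ``(reference_id, eta)`` pairs. Returns ``(means, sd)`` where ``means``
    maps reference id to its mean gain.
    """
    groups: dict[str, list[float]] = {}
    for rec in records:
        if isinstance(rec, EtaRecord):
            ref, val = rec.reference, rec.eta
        else:
            ref, val = rec
        groups.setdefault(ref, []).append(float(val))
    if len(groups) < 2:
        raise ValueError("need at least two reference subjects")
    means = {ref: float(np.mean(v)) for ref, v in groups.items()}
    sd = float(np.std(list(means.values()), ddof=ddof))
    return means, sd


def permutation_agreement(P1: PermutationMatrix, P2: PermutationMatrix) -> dict:
    """Fraction of labels placed identically by two permutations.

    ``overall`` counts all labels; ``restricted`` counts only labels moved
    by at least one of the two permutations (defined as 1.0 when both
    permutations are the identity, where no label moves at all).
    """
    if P1.n != P2.n:
        raise ValueError("permutations must share N")
    s1 = P1.inverse().mapping
    s2 = P2.inverse().mapping
    same = s1 == s2
    idx = np.arange(P1.n)
    moved = (s1 != idx) | (s2 != idx)
    overall = float(np.mean(same))
    restricted = float(np.mean(same[moved])) if moved.any() else 1.0
    return {
        "overall": overall,
        "restricted": restricted,
        "n_moved_union": int(moved.sum()),
    }
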