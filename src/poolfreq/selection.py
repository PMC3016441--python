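"""Informative-SNP selection by greedy max–min pairwise difference.

The regression is best conditioned when every pair of haplotypes disagrees
at a large fraction of the SNPs used.  The *mean* pairwise difference over a
SNP subset S is fixed by the per-SNP allele frequencies alone:

    mean_diff(S) = sum_{m in S} c_m (h - c_m) / ( C(h,2) * |S| ),

where c_m is the number of haplotypes carrying the coded-1 allele at SNP m
and h the number of haplotypes.  Its maximum over one SNP column,
max_k k(h-k)/C(h,2), is attained at allele frequency 1/2 (k = h/2), giving
an upper bound of h/(2(h-1)) for even h and (h+1)/(2h) for odd h.

But a high mean does not prevent one *pair* of haplotypes from being nearly
identical on S, which is the actual collinearity risk, so the selection
criterion is the smallest pairwise difference.  Selection is a greedy local
search with random restarts: repeatedly find the worst pair, swap out a
selected SNP where that pair agrees for an outside candidate where it
differs, and keep the swap only if no pair drops below the previous global
minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .panel import HaplotypePanel

__all__ = [
    "SNPSelection",
    "pairwise_difference",
    "mean_pairwise_difference",
    "theoretical_max_mean_difference",
    "candidate_filter",
    "select_informative_snps",
]


@dataclass
class SNPSelection:
    """Result of an informative-SNP search.

    ``trace`` records the global minimum pairwise difference after each
    accepted swap of the winning restart (starting from its initial random
    subset); it is non-decreasing by construction of the acceptance rule.
    """

    selected_indices: np.ndarray
    min_pairwise_difference: float
    mean_pairwise_difference: float
    iterations_used: int
    restarts_used: int
    target_min: float
    converged: bool
    trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=np.int64)
        if len(np.unique(self.selected_indices)) != len(self.selected_indices):
            raise ValueError("selected SNP indices must be unique")


def pairwise_difference(panel: HaplotypePanel, i: int, j: int, subset) -> float:
    """Fraction of SNPs in ``subset`` where haplotypes i and j differ."""
    if i == j:
        raise ValueError("need two distinct haplotypes")
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("subset must be nonempty")
    return float(np.mean(panel.matrix[i, subset] != panel.matrix[j, subset]))


def _pair_diff_counts(matrix: np.ndarray) -> np.ndarray:
    """h x h matrix of counts of columns where each haplotype pair differs."""
    A = matrix.astype(np.int64)
    n = A.shape[1]
    same = A @ A.T + (1 - A) @ (1 - A).T
    return n - same


def mean_pairwise_difference(
    panel: HaplotypePanel, subset=None, method: str = "closed_form"
) -> float:
    """Average pairwise difference over all h(h-1)/2 haplotype pairs.

    ``method="closed_form"`` uses the allele-frequency identity above;
    ``method="enumeration"`` averages :func:`pairwise_difference` over every
    pair.  The two agree to floating-point precision — the enumeration route
    exists so that agreement can be asserted.
    """
    h = panel.n_haplotypes
    if h < 2:
        raise ValueError("need at least two haplotypes")
    subset = np.arange(panel.n_loci) if subset is None else np.asarray(subset)
    if subset.size == 0:
        raise ValueError("subset must be nonempty")
    n_pairs = h * (h - 1) // 2
    if method == "closed_form":
        c = panel.matrix[:, subset].sum(axis=0).astype(np.int64)
        return float((c * (h - c)).sum() / (n_pairs * subset.size))
    if method == "enumeration":
        total = 0.0
        for i in range(h):
            for j in range(i + 1, h):
                total += pairwise_difference(panel, i, j, subset)
        return total / n_pairs
    raise ValueError(f"unknown method {method!r}")


def theoretical_max_mean_difference(h: int) -> float:
    """Largest achievable mean pairwise difference for h haplotypes.

    Per SNP the number of differing pairs is k(h-k) for allele count k, so
    the best single column gives max_k k(h-k)/C(h,2); any panel whose every
    SNP attains the max reaches it overall.  For odd h allele frequency 1/2
    is unattainable and the max is taken over feasible integer counts.
    """
    if h < 2:
        raise ValueError("need at least two haplotypes")
    n_pairs = h * (h - 1) // 2
    return max(k * (h - k) for k in range(h + 1)) / n_pairs


def candidate_filter(
    panel: HaplotypePanel, maf_low: float = 0.4, maf_high: float = 0.6
) -> np.ndarray:
    """Indices of SNPs whose coded-1 allele frequency lies in [maf_low, maf_high].

    Bounds are inclusive; the default 40%–60% window keeps SNPs present in
    roughly half the haplotypes, where a single column distinguishes the
    most pairs.
    """
    if maf_low > maf_high:
        raise ValueError("maf_low must not exceed maf_high")
    f = panel.allele_frequencies()
    return np.flatnonzero((f >= maf_low) & (f <= maf_high))


def select_informative_snps(
    panel: HaplotypePanel,
    candidates,
    n: int,
    target_min: float = 0.45,
    max_iterations: int = 10_000,
    restarts: int = 20,
    seed: int = 0,
) -> SNPSelection:
    """Greedy max–min selection of ``n`` SNPs from ``candidates``.

    Each restart starts from a seeded random n-subset and iterates: find the
    haplotype pair with the smallest pairwise difference on the current
    subset (ties broken by the lexicographically first pair); propose
    removing a uniformly random selected SNP where that pair agrees and
    adding a uniformly random outside candidate where it differs; accept the
    swap only if no pair's difference drops below the previous global
    minimum (the worst pair's own difference strictly increases by
    construction).  Every proposal, accepted or not, counts as one
    iteration.  A restart stops on reaching ``target_min`` or the iteration
    cap; restarts stop early once one converges.  Across restarts the
    selection with the largest achieved minimum wins (ties: larger mean,
    then first found).
    """
    candidates = np.asarray(sorted(set(np.asarray(candidates, dtype=np.int64).tolist())))
    h = panel.n_haplotypes
    if h < 2:
        raise ValueError("need at least two haplotypes")
    if n < 1 or n > candidates.size:
        raise ValueError(f"cannot select {n} SNPs from {candidates.size} candidates")
    if target_min > theoretical_max_mean_difference(h):
        warnings.warn(
            f"target_min {target_min} exceeds the theoretical maximum mean "
            f"pairwise difference for h={h}; the target may be unreachable",
            stacklevel=2,
        )

    M = panel.matrix
    iu = np.triu_indices(h, k=1)
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(restarts)

    best: tuple[float, float] | None = None
    best_sel: np.ndarray | None = None
    best_iters = 0
    best_trace: list[float] = []
    best_converged = False
    restarts_used = 0

    for child in child_seeds:
        restarts_used += 1
        rng = np.random.default_rng(child)
        sel = rng.choice(candidates, size=n, replace=False)
        in_sel = np.zeros(panel.n_loci, dtype=bool)
        in_sel[sel] = True
        D = _pair_diff_counts(M[:, sel])
        min_count = int(D[iu].min())
        trace = [min_count / n]
        iterations = 0
        converged = min_count / n >= target_min

        while not converged and iterations < max_iterations:
            iterations += 1
            # lexicographically first worst pair
            flat = int(np.argmin(D[iu]))
            wi, wj = int(iu[0][flat]), int(iu[1][flat])
            sel_arr = np.flatnonzero(in_sel)
            agree_sel = sel_arr[M[wi, sel_arr] == M[wj, sel_arr]]
            outside = candidates[~in_sel[candidates]]
            diff_out = outside[M[wi, outside] != M[wj, outside]]
            if agree_sel.size == 0 or diff_out.size == 0:
                break  # worst pair cannot be improved by any swap
            s = int(rng.choice(agree_sel))
            c = int(rng.choice(diff_out))
            neq_c = (M[:, c][:, None] != M[:, c][None, :]).astype(np.int64)
            neq_s = (M[:, s][:, None] != M[:, s][None, :]).astype(np.int64)
            newD = D + neq_c - neq_s
            new_min = int(newD[iu].min())
            if new_min >= min_count:  # no pair falls below the previous minimum
                D = newD
                in_sel[s] = False
                in_sel[c] = True
                min_count = new_min
                trace.append(min_count / n)
                converged = min_count / n >= target_min

        achieved_min = min_count / n
        sel_final = np.flatnonzero(in_sel)
        achieved_mean = mean_pairwise_difference(panel, sel_final)
        key = (achieved_min, achieved_mean)
        if best is None or key > best:
            best = key
            best_sel = sel_final
            best_iters = iterations
            best_trace = trace
            best_converged = converged
        if converged:
            break

    assert best_sel is not None
    # recompute scores from scratch on the winning subset
    sub = panel.restrict(best_sel)
    counts = _pair_diff_counts(sub.matrix)
    final_min = float(counts[iu].min() / n)
    final_mean = mean_pairwise_difference(panel, best_sel)
    return SNPSelection(
        selected_indices=best_sel,
        min_pairwise_difference=final_min,
        mean_pairwise_difference=final_mean,
        iterations_used=best_iters,
        restarts_used=restarts_used,
        target_min=target_min,
        converged=best_converged,
        trace=best_trace,
    )
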