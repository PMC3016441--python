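"""Frequency inference by unconstrained least squares, and its QC.

The model: at each informative SNP m, the pooled allele frequency Y_m is
(up to sampling noise) the sum of the frequencies of the haplotypes that
carry the coded-1 allele there,

    Y = b_1 X_1 + ... + b_h X_h,

with X_i the 0/1 allele vector of haplotype i and b_i its frequency in the
pool.  There is no intercept and there are no constraints: b must in truth
be nonnegative and sum to one, but those constraints are deliberately NOT
imposed — how far the raw ordinary-least-squares solution drifts from them
is the quality-control signal for systematic coverage bias (copy-number
variation, library duplication, mapping artefacts).  Forcing the solution
onto the simplex would destroy that alarm.

The 0/1 coding also defuses the usual collinearity pathology: an allele
coded 0 contributes nothing to the sum, so near-complementary haplotypes
such as (0,0,0,1) and (1,1,1,0) cannot trade coefficient mass against each
other the way correlated regressors normally do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .panel import HaplotypePanel, PooledObservation

__all__ = [
    "FrequencyEstimate",
    "QCFlag",
    "QCReport",
    "infer_frequencies",
    "mean_absolute_error",
    "qc_check",
]


@dataclass
class FrequencyEstimate:
    """Raw OLS haplotype-frequency estimates plus QC ingredients.

    ``b_hat`` is the untouched least-squares solution — never clipped to
    [0, 1] and never renormalized.  Use :meth:`normalized` for a clearly
    labelled derived view.
    """

    haplotype_ids: list[str]
    b_hat: np.ndarray
    residual_norm: float  # root-mean-square regression residual
    n_snps_used: int
    rank: int
    rank_deficient: bool = False

    def __post_init__(self) -> None:
        self.b_hat = np.asarray(self.b_hat, dtype=float)
        if len(self.b_hat) != len(self.haplotype_ids):
            raise ValueError("one coefficient per haplotype required")

    @property
    def sum_b(self) -> float:
        return float(self.b_hat.sum())

    @property
    def negative_mass(self) -> float:
        """Sum of |b_hat_i| over negative coefficients (>= 0)."""
        return float(-self.b_hat[self.b_hat < 0].sum()) + 0.0

    def normalized(self) -> np.ndarray:
        """Derived view: negatives clipped to 0, rescaled to sum 1.

        This is NOT the estimate the QC diagnostics are computed from; it is
        a convenience projection onto the simplex for downstream reporting.
        """
        clipped = np.clip(self.b_hat, 0.0, None)
        total = clipped.sum()
        if total <= 0:
            raise ValueError("cannot normalize: no positive coefficient mass")
        return clipped / total


class QCFlag(str, Enum):
    PASS = "pass"
    WARN = "warn"
    FAIL = "fail"


@dataclass
class QCReport:
    sum_deviation: float  # |sum(b_hat) - 1|
    negative_mass: float
    flag: QCFlag
    thresholds_used: tuple[float, float]  # (sum_deviation_warn, negative_mass_warn)


def infer_frequencies(panel: HaplotypePanel, obs: PooledObservation) -> FrequencyEstimate:
    """Estimate haplotype frequencies by unconstrained, intercept-free OLS.

    ``obs`` must cover a subset of the panel's loci under the same allele
    coding; the design matrix is the panel restricted to the observed loci.
    When the design is rank deficient the minimum-norm solution is returned
    and ``rank_deficient`` is set (with a warning) rather than failing.
    """
    panel_index = {(l.chromosome, l.position): m for m, l in enumerate(panel.loci)}
    cols = []
    for locus in obs.loci:
        key = (locus.chromosome, locus.position)
        if key not in panel_index:
            raise ValueError(f"observed locus {key[0]}:{key[1]} is not in the panel")
        m = panel_index[key]
        if panel.coding_map[m] not in (locus.allele_a, locus.allele_b):
            raise ValueError(
                f"allele coding mismatch at {key[0]}:{key[1]}: panel codes "
                f"{panel.coding_map[m]!r} as 1"
            )
        cols.append(m)
    n_used = len(cols)
    h = panel.n_haplotypes
    if n_used < h:
        raise ValueError(
            f"need at least as many SNPs as haplotypes ({h}); got {n_used}"
        )
    X = panel.matrix[:, cols].T.astype(float)  # (n_used, h)
    y = obs.frequencies
    b_hat, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b_hat
    rank_deficient = bool(rank < h)
    if rank_deficient:
        warnings.warn(
            f"design matrix is rank deficient (rank {rank} < {h} haplotypes); "
            "returning the minimum-norm solution",
            stacklevel=2,
        )
    return FrequencyEstimate(
        haplotype_ids=list(panel.haplotype_ids),
        b_hat=b_hat,
        residual_norm=float(np.sqrt(np.mean(resid**2))),
        n_snps_used=n_used,
        rank=int(rank),
        rank_deficient=rank_deficient,
    )


def mean_absolute_error(b_true, b_hat) -> float:
    """Mean absolute difference between aligned frequency vectors: (1/h) sum |b̂_i - b_i|."""
    b_true = np.asarray(b_true, dtype=float)
    b_hat = np.asarray(b_hat, dtype=float)
    if b_true.shape != b_hat.shape:
        raise ValueError("frequency vectors must have equal length")
    return float(np.mean(np.abs(b_hat - b_true)))


def qc_check(
    est: FrequencyEstimate,
    sum_deviation_warn: float = 0.05,
    negative_mass_warn: float = 0.05,
) -> QCReport:
    """Constraint-based quality control of a raw estimate.

    True frequencies are nonnegative and sum to one; the unconstrained
    estimate should *approximately* satisfy both.  One threshold breached →
    warn; both → fail.  Defaults (0.05, 0.05) are loose enough not to flag
    ordinary sampling noise at the ~1–2% error levels of well-behaved pools.
    """
    sum_dev = abs(est.sum_b - 1.0)
    neg = est.negative_mass
    breaches = (sum_dev >= sum_deviation_warn) + (neg >= negative_mass_warn)
    flag = (QCFlag.PASS, QCFlag.WARN, QCFlag.FAIL)[breaches]
    return QCReport(
        sum_deviation=sum_dev,
        negative_mass=neg,
        flag=flag,
        thresholds_used=(sum_deviation_warn, negative_mass_warn),
    )
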