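"""Synthetic panels, pooled-read simulation, and the replicate protocol.

The simulator reproduces the statistical structure assumed by the frequency
regression: a pool of h known haplotypes mixed at frequencies b, sequenced
so that each SNP's coverage is an independent draw with a chosen mean and
standard deviation, and each read at a SNP originates from haplotype i with
probability b_i.  Read-level detail (read length, linkage between adjacent
SNPs carried on one read) is deliberately collapsed to per-SNP multinomial
sampling: per-SNP independence is the model's working assumption and it is
what makes uneven coverage act as exchangeable sampling noise.

An experiment run draws fresh random frequencies per replicate, simulates
the pool on the selected SNPs, infers frequencies, and averages the mean
absolute error across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import HaplotypePanel, Locus, PooledObservation, pooled_frequencies
from .regression import (
    FrequencyEstimate,
    QCReport,
    infer_frequencies,
    mean_absolute_error,
    qc_check,
)
from .selection import SNPSelection

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "synthetic_panel",
    "random_frequencies",
    "simulate_coverage",
    "simulate_pool",
    "run_experiment",
]


@dataclass
class SimulationConfig:
    n_haplotypes: int
    n_snps_selected: int
    mean_coverage: float  # per-SNP mean coverage of the pool (x)
    coverage_sd: float
    n_replicates: int = 30
    seed: int = 0
    frequency_model: str = "uniform_simplex"  # or "user_supplied"
    user_frequencies: np.ndarray | None = None
    coverage_family: str = "normal"
    error_rate: float = 0.0  # per-read allele misread probability

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.coverage_sd < 0:
            raise ValueError("coverage_sd must be nonnegative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.frequency_model not in ("uniform_simplex", "user_supplied"):
            raise ValueError(f"unknown frequency_model {self.frequency_model!r}")
        if self.frequency_model == "user_supplied":
            if self.user_frequencies is None:
                raise ValueError("user_supplied frequency model needs user_frequencies")
            self.user_frequencies = np.asarray(self.user_frequencies, dtype=float)


@dataclass
class SimulationResult:
    per_replicate_errors: list[float]
    config: SimulationConfig
    per_replicate_qc: list[QCReport] = field(default_factory=list)
    per_replicate_estimates: list[FrequencyEstimate] = field(default_factory=list)

    @property
    def mean_error(self) -> float:
        return float(np.mean(self.per_replicate_errors))


def synthetic_panel(
    h: int,
    n_candidates: int,
    maf_low: float = 0.4,
    maf_high: float = 0.6,
    seed: int = 0,
    chromosome: str = "1",
) -> HaplotypePanel:
    """Random bi-allelic panel with per-SNP allele frequencies in a window.

    For each SNP independently a target frequency f is drawn uniform in
    [maf_low, maf_high] and the coded-1 allele is assigned to round(f*h)
    haplotypes chosen uniformly at random; draws whose rounded count would
    be 0 or h are redrawn so every SNP stays polymorphic.  Loci are placed
    at consecutive positions on one chromosome with alleles A (coded 1)
    and T.
    """
    if h < 2:
        raise ValueError("need at least two haplotypes")
    if n_candidates < 1:
        raise ValueError("need at least one SNP")
    if not (0 < maf_low <= maf_high < 1):
        raise ValueError("need 0 < maf_low <= maf_high < 1")
    rng = np.random.default_rng(seed)
    matrix = np.zeros((h, n_candidates), dtype=np.int8)
    for m in range(n_candidates):
        while True:
            k = round(rng.uniform(maf_low, maf_high) * h)
            if 0 < k < h:
                break
        carriers = rng.choice(h, size=k, replace=False)
        matrix[carriers, m] = 1
    loci = [Locus(chromosome, pos + 1, "A", "T") for pos in range(n_candidates)]
    return HaplotypePanel(
        haplotype_ids=[f"hap{i + 1}" for i in range(h)],
        loci=loci,
        matrix=matrix,
        coding_map=["A"] * n_candidates,
        coding_seed=None,
    )


def random_frequencies(h: int, seed) -> np.ndarray:
    """Flat-simplex (symmetric Dirichlet, concentration 1) frequency draw."""
    if h < 1:
        raise ValueError("need at least one haplotype")
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.ones(h))


def simulate_coverage(
    n: int,
    mean_coverage: float,
    coverage_sd: float,
    seed,
    family: str = "normal",
) -> np.ndarray:
    """Independent per-SNP integer coverages achieving the given mean and SD.

    Draws come from a symmetric bell-shaped distribution (normal), rounded
    to the nearest integer and truncated below at 1; ``coverage_sd = 0``
    gives every SNP exactly ``round(mean_coverage)``.  Rounding adds
    quantization variance (~1/12), so the underlying normal is drawn with
    sd sqrt(max(sd^2 - 1/12, 0)) so that the *realized* integer coverages
    achieve the requested SD; SDs below the quantization floor (~0.29) are
    not exactly attainable with integer coverages.
    """
    if mean_coverage < 1:
        raise ValueError("mean_coverage must be >= 1")
    if family != "normal":
        raise ValueError(f"unknown coverage family {family!r}")
    if coverage_sd == 0:
        return np.full(n, round(mean_coverage), dtype=np.int64)
    rng = np.random.default_rng(seed)
    inner_sd = float(np.sqrt(max(coverage_sd**2 - 1 / 12, 0.0)))
    draws = np.rint(rng.normal(mean_coverage, inner_sd, size=n)).astype(np.int64)
    return np.maximum(draws, 1)


def simulate_pool(
    panel: HaplotypePanel,
    b_true,
    coverages,
    seed,
    error_rate: float = 0.0,
) -> PooledObservation:
    """Simulate pooled per-SNP allele counts from a haplotype mixture.

    At each SNP, every read independently originates from haplotype i with
    probability b_true_i; the coded-1 count is the number of reads whose
    source haplotype carries code 1 there.  ``error_rate`` optionally flips
    each read's observed allele independently (default 0).
    """
    b_true = np.asarray(b_true, dtype=float)
    if len(b_true) != panel.n_haplotypes:
        raise ValueError("b_true length must equal the number of haplotypes")
    if abs(b_true.sum() - 1.0) > 1e-9 or (b_true < -1e-12).any():
        raise ValueError("b_true must lie on the simplex")
    coverages = np.asarray(coverages, dtype=np.int64)
    if len(coverages) != panel.n_loci or (coverages < 1).any():
        raise ValueError("coverages must align with panel SNPs and be >= 1")
    rng = np.random.default_rng(seed)
    # reads-per-haplotype at every SNP: (n_snps, h) multinomial draws
    reads = rng.multinomial(coverages, b_true)
    count1 = np.einsum("mh,hm->m", reads, panel.matrix.astype(np.int64))
    if error_rate > 0:
        kept = rng.binomial(count1, 1.0 - error_rate)
        flipped_in = rng.binomial(coverages - count1, error_rate)
        count1 = kept + flipped_in
    return pooled_frequencies(panel.loci, count1, coverages)


def run_experiment(
    panel: HaplotypePanel,
    selection: SNPSelection,
    config: SimulationConfig,
) -> SimulationResult:
    """Replicate protocol: random frequencies x simulated pool x inference.

    Per replicate: draw b_true (flat simplex unless user-supplied), simulate
    per-SNP coverage and pooled counts on the selected SNPs, infer
    frequencies by OLS, and record the mean absolute error and QC report.
    All randomness derives from ``config.seed`` via spawned child streams,
    so identical configs give identical results.
    """
    sub = panel.restrict(selection.selected_indices)
    n = sub.n_loci
    errors: list[float] = []
    qcs: list[QCReport] = []
    ests: list[FrequencyEstimate] = []
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    for child in children:
        freq_seed, cov_seed, pool_seed = child.spawn(3)
        if config.frequency_model == "uniform_simplex":
            b_true = random_frequencies(config.n_haplotypes, freq_seed)
        else:
            b_true = config.user_frequencies
        coverages = simulate_coverage(
            n, config.mean_coverage, config.coverage_sd, cov_seed,
            family=config.coverage_family,
        )
        obs = simulate_pool(sub, b_true, coverages, pool_seed, config.error_rate)
        est = infer_frequencies(sub, obs)
        errors.append(mean_absolute_error(b_true, est.b_hat))
        qcs.append(qc_check(est))
        ests.append(est)
    return SimulationResult(
        per_replicate_errors=errors,
        config=config,
        per_replicate_qc=qcs,
        per_replicate_estimates=ests,
    )
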