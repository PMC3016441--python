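"""Haplotype panels and pooled observations.

A haplotype panel is the set of *known* haplotypes over a list of bi-allelic
SNP loci, stored as an h x n matrix of 0/1 allele codes.  A pooled
observation holds, for each SNP, the read count supporting the allele coded
1 together with the total coverage; the derived per-SNP pooled allele
frequency is the dependent variable of the frequency regression.

Allele coding is deliberately *random* per locus (neither major nor minor
allele): coding by the observed major allele would bias the observed pooled
frequency upward at every locus, because the "major" call is itself made
from the noisy pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Locus",
    "RawPanel",
    "HaplotypePanel",
    "PooledObservation",
    "code_alleles",
    "pooled_frequencies",
]


@dataclass(frozen=True, order=True)
class Locus:
    """A bi-allelic SNP locus. ``position`` is 1-based, as in VCF."""

    chromosome: str
    position: int
    allele_a: str = field(compare=False, default="A")
    allele_b: str = field(compare=False, default="T")

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(
                f"locus {self.chromosome}:{self.position} is not bi-allelic: "
                f"both alleles are {self.allele_a!r}"
            )


def _check_loci(loci: list[Locus]) -> None:
    keys = [(l.chromosome, l.position) for l in loci]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate loci in panel")
    if keys != sorted(keys):
        raise ValueError("loci must be sorted by chromosome then position")


@dataclass
class RawPanel:
    """Haplotypes with per-locus allele *strings*, prior to 0/1 coding.

    ``alleles`` is an h x n array of allele strings; row i gives haplotype
    i's allele at every locus.
    """

    haplotype_ids: list[str]
    loci: list[Locus]
    alleles: np.ndarray  # dtype object/str, shape (h, n)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=object)
        h, n = self.alleles.shape
        if h != len(self.haplotype_ids):
            raise ValueError("allele matrix rows do not match haplotype_ids")
        if n != len(self.loci):
            raise ValueError("allele matrix columns do not match loci")
        if h < 1 or n < 1:
            raise ValueError("panel needs at least one haplotype and one locus")
        _check_loci(self.loci)
        for m, locus in enumerate(self.loci):
            observed = set(self.alleles[:, m])
            allowed = {locus.allele_a, locus.allele_b}
            if not observed <= allowed:
                raise ValueError(
                    f"haplotype carries allele outside {allowed} at "
                    f"{locus.chromosome}:{locus.position}"
                )

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]


@dataclass
class HaplotypePanel:
    """Coded haplotype panel: h x n matrix over {0, 1}.

    ``coding_map[m]`` is the allele string coded 1 at locus m; ``coding_seed``
    records the seed of the random coding (None when the panel was built
    directly in coded form, e.g. by the simulator).
    """

    haplotype_ids: list[str]
    loci: list[Locus]
    matrix: np.ndarray  # shape (h, n), values in {0, 1}
    coding_map: list[str]
    coding_seed: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        h, n = self.matrix.shape
        if h != len(self.haplotype_ids) or n != len(self.loci):
            raise ValueError("matrix shape does not match haplotype_ids/loci")
        if h < 1 or n < 1:
            raise ValueError("panel needs at least one haplotype and one locus")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        if len(self.coding_map) != n:
            raise ValueError("coding_map must cover every locus")
        _check_loci(self.loci)
        for m, locus in enumerate(self.loci):
            if self.coding_map[m] not in (locus.allele_a, locus.allele_b):
                raise ValueError(
                    f"coding_map[{m}] = {self.coding_map[m]!r} is not an allele of "
                    f"{locus.chromosome}:{locus.position}"
                )

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_loci(self) -> int:
        return self.matrix.shape[1]

    def allele_frequencies(self, subset=None) -> np.ndarray:
        """Per-SNP frequency of the coded-1 allele among the haplotypes."""
        cols = self.matrix if subset is None else self.matrix[:, np.asarray(subset)]
        return cols.mean(axis=0)

    def restrict(self, snp_indices) -> "HaplotypePanel":
        """Panel restricted to a subset of SNP columns (kept in locus order)."""
        idx = np.sort(np.asarray(snp_indices))
        return HaplotypePanel(
            haplotype_ids=list(self.haplotype_ids),
            loci=[self.loci[m] for m in idx],
            matrix=self.matrix[:, idx],
            coding_map=[self.coding_map[m] for m in idx],
            coding_seed=self.coding_seed,
        )


def code_alleles(raw_panel: RawPanel, seed: int) -> HaplotypePanel:
    """Randomly code one allele per locus as 1.

    RNG protocol (fixed so the coding is replayable): a single
    ``numpy.random.default_rng(seed)`` generator draws
    ``rng.integers(0, 2, size=n)`` — one fair draw per locus, in locus sort
    order; draw 0 codes ``allele_a`` as 1, draw 1 codes ``allele_b`` as 1.
    The coding is independent of allele frequency by construction.
    """
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 2, size=raw_panel.n_loci)
    coding_map = [
        locus.allele_a if d == 0 else locus.allele_b
        for locus, d in zip(raw_panel.loci, draws)
    ]
    matrix = np.empty((raw_panel.n_haplotypes, raw_panel.n_loci), dtype=np.int8)
    for m, coded1 in enumerate(coding_map):
        matrix[:, m] = raw_panel.alleles[:, m] == coded1
    return HaplotypePanel(
        haplotype_ids=list(raw_panel.haplotype_ids),
        loci=list(raw_panel.loci),
        matrix=matrix,
        coding_map=coding_map,
        coding_seed=seed,
    )


@dataclass
class PooledObservation:
    """Per-SNP pooled counts of the coded-1 allele and total coverage.

    ``frequencies`` is exactly ``count_coded1 / coverage``.  SNPs with zero
    coverage are never stored: :func:`pooled_frequencies` drops them and
    lists them in ``dropped_loci``.
    """

    loci: list[Locus]
    count_coded1: np.ndarray
    coverage: np.ndarray
    dropped_loci: list[Locus] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.count_coded1 = np.asarray(self.count_coded1, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if not (len(self.loci) == len(self.count_coded1) == len(self.coverage)):
            raise ValueError("loci, counts and coverage must be aligned")
        if (self.coverage < 1).any():
            bad = int(np.argmax(self.coverage < 1))
            raise ValueError(
                f"zero/negative coverage at {self.loci[bad].chromosome}:"
                f"{self.loci[bad].position}; drop such SNPs before construction"
            )
        if (self.count_coded1 < 0).any() or (self.count_coded1 > self.coverage).any():
            bad = int(np.argmax((self.count_coded1 < 0) | (self.count_coded1 > self.coverage)))
            raise ValueError(
                f"count exceeds coverage at {self.loci[bad].chromosome}:"
                f"{self.loci[bad].position}"
            )

    @property
    def frequencies(self) -> np.ndarray:
        return self.count_coded1 / self.coverage

    @property
    def n_snps(self) -> int:
        return len(self.loci)


def pooled_frequencies(loci, count_coded1, coverage) -> PooledObservation:
    """Build a :class:`PooledObservation`, dropping zero-coverage SNPs.

    Dropped loci are reported on the returned observation's
    ``dropped_loci``; counts exceeding coverage are rejected outright.
    """
    count_coded1 = np.asarray(count_coded1, dtype=np.int64)
    coverage = np.asarray(coverage, dtype=np.int64)
    loci = list(loci)
    if not (len(loci) == len(count_coded1) == len(coverage)):
        raise ValueError("loci, counts and coverage must be aligned")
    over = count_coded1 > coverage
    if over.any():
        bad = loci[int(np.argmax(over))]
        raise ValueError(f"count exceeds coverage at {bad.chromosome}:{bad.position}")
    keep = coverage >= 1
    dropped = [l for l, k in zip(loci, keep) if not k]
    return PooledObservation(
        loci=[l for l, k in zip(loci, keep) if k],
        count_coded1=count_coded1[keep],
        coverage=coverage[keep],
        dropped_loci=dropped,
    )
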