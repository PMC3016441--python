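import numpy as np
import pytest

from poolfreq import HaplotypePanel, Locus, RawPanel


@pytest.fixture
def panel_from_matrix():
    """Factory: build a coded panel directly from a 0/1 matrix.

    Loci are consecutive positions on chromosome "1" with alleles A/T and
    allele A coded 1.
    """

    def make(matrix, chromosome="1"):
        matrix = np.asarray(matrix, dtype=np.int8)
        h, n = matrix.shape
        return HaplotypePanel(
            haplotype_ids=[f"hap{i + 1}" for i in range(h)],
            loci=[Locus(chromosome, m + 1, "A", "T") for m in range(n)],
            matrix=matrix,
            coding_map=["A"] * n,
        )

    return make


@pytest.fixture
def raw_two_hap():
    """Two haplotypes over four A/T loci, carrying complementary alleles."""
    loci = [Locus("1", p, "A", "T") for p in (10, 20, 30, 40)]
    alleles = np.array(
        [["A", "T", "A", "T"], ["T", "A", "T", "A"]], dtype=object
    )
    return RawPanel(["h1", "h2"], loci, alleles)
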