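"""Infer haplotype frequencies from a pooled sample.

Builds a tiny panel of two known haplotypes, mixes them 30:70 into a
simulated pool sequenced at 50x per SNP, and recovers the mixing
proportions by unconstrained least squares.  The QC block reports how far
the raw estimate drifts from the sum-to-one and nonnegativity constraints —
the built-in alarm for systematic coverage bias.
"""

import numpy as np

from poolfreq import (
    HaplotypePanel,
    Locus,
    infer_frequencies,
    qc_check,
    simulate_pool,
)

panel = HaplotypePanel(
    haplotype_ids=["strainA", "strainB"],
    loci=[Locus("1", p, "A", "T") for p in (100, 200, 300, 400)],
    matrix=np.array([[1, 0, 1, 0], [0, 1, 1, 0]]),
    coding_map=["A"] * 4,
)

obs = simulate_pool(panel, b_true=[0.3, 0.7], coverages=[50] * 4, seed=1)
est = infer_frequencies(panel, obs)
qc = qc_check(est)

print("pooled frequencies per SNP:", obs.frequencies)
for hid, b in zip(est.haplotype_ids, est.b_hat):
    print(f"{hid}: estimated frequency {b:.3f}")
print(f"QC: flag={qc.flag.value}, |sum-1|={qc.sum_deviation:.4f}, "
      f"negative mass={qc.negative_mass:.4f}")
# The estimates approximate the true 0.30/0.70 mix; at 50x per SNP the
# binomial sampling noise keeps them within a few percent, and the QC
# deviations stay well below the 0.05 warning thresholds.
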