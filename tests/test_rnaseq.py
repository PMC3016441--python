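"""Gene-model segmentation, terminal trimming, and isoform inference."""

import numpy as np
import pytest

from poolfreq import (
    GeneModel,
    Isoform,
    SegmentCoverage,
    detect_trivial,
    infer_isoform_frequencies,
    run_rnaseq_experiment,
    segment_gene_model,
    simulate_rnaseq,
    synthetic_gene_models,
    trim_terminal_segments,
)
from poolfreq.regression import mean_absolute_error


def _gene(exons_by_isoform, gene_id="g1"):
    isoforms = [Isoform(f"{gene_id}.i{k + 1}", ex) for k, ex in enumerate(exons_by_isoform)]
    return GeneModel(gene_id, "1", "+", isoforms)


def _signature_oracle(gene):
    """Per-base membership signatures merged into runs (brute force)."""
    union = sorted(
        {b for iso in gene.isoforms for s, e in iso.exons for b in range(s, e)}
    )
    segs, members = [], []
    prev_sig, start = None, None
    prev_base = None
    for base in union:
        sig = tuple(
            int(any(s <= base < e for s, e in iso.exons)) for iso in gene.isoforms
        )
        if sig != prev_sig or (prev_base is not None and base != prev_base + 1):
            if prev_sig is not None:
                segs.append((start, prev_base + 1))
                members.append(prev_sig)
            prev_sig, start = sig, base
        prev_base = base
    segs.append((start, prev_base + 1))
    members.append(prev_sig)
    return segs, np.array(members).T


class TestSegmentation:
    def test_shared_exon_with_longer_terminus(self):
        # exon 100-200 in A; 100-210 in B -> shared [100,200) + B-only [200,210)
        seg = segment_gene_model(_gene([[(100, 200)], [(100, 210)]]))
        assert seg.segments == [(100, 200), (200, 210)]
        assert seg.membership.tolist() == [[1, 0], [1, 1]]

    def test_single_isoform_nothing_to_split(self):
        seg = segment_gene_model(_gene([[(0, 100), (200, 300)]]))
        assert seg.segments == [(0, 100), (200, 300)]
        assert seg.membership.tolist() == [[1, 1]]

    def test_matches_per_base_signature_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            k = int(rng.integers(2, 5))
            isoforms = []
            for _i in range(k):
                n_ex = int(rng.integers(1, 4))
                cuts = np.sort(rng.choice(np.arange(1, 1000), size=2 * n_ex, replace=False))
                exons = [(int(cuts[2 * x]), int(cuts[2 * x + 1])) for x in range(n_ex)]
                isoforms.append(exons)
            gene = _gene(isoforms)
            seg = segment_gene_model(gene)
            o_segs, o_members = _signature_oracle(gene)
            # oracle merges adjacent equal-signature runs; segmentation may
            # only split at exon boundaries, which always change a signature
            # for non-abutting exons (Isoform merges abutting ones)
            assert seg.segments == o_segs
            assert np.array_equal(seg.membership, o_members)

    def test_idempotent_and_length_conserving(self):
        gene = _gene([[(0, 500), (700, 1200)], [(0, 600), (700, 1000)]])
        seg = segment_gene_model(gene)
        # project each isoform onto its own segments and segment again
        regene = _gene(
            [
                [s for s, keep in zip(seg.segments, row) if keep]
                for row in seg.membership
            ]
        )
        reseg = segment_gene_model(regene)
        assert reseg.segments == seg.segments
        assert np.array_equal(reseg.membership, seg.membership)
        union = {b for iso in gene.isoforms for s, e in iso.exons for b in range(s, e)}
        assert sum(e - s for s, e in seg.segments) == len(union)

    def test_rejects_empty_isoform(self):
        with pytest.raises(ValueError, match="no exons"):
            Isoform("x", [])


class TestTrimming:
    def test_boundary_of_five_read_lengths(self):
        # 76 bp reads: a 380 bp terminal segment is trimmed, 381 bp is kept
        for first_len, expect_trim in ((380, True), (381, False)):
            gene = _gene([[(0, first_len), (1000, 4000)]])
            seg = trim_terminal_segments(segment_gene_model(gene), 76)
            assert (0 in seg.trimmed_segments) is expect_trim

    def test_long_segments_unchanged(self):
        gene = _gene([[(0, 10_000), (20_000, 30_000)]])
        seg = trim_terminal_segments(segment_gene_model(gene), 76)
        assert seg.trimmed_segments == []

    def test_both_short_termini_trimmed_gene_trivial(self):
        gene = _gene([[(0, 100), (500, 600)], [(0, 100)]])
        seg = trim_terminal_segments(segment_gene_model(gene), 76)
        assert seg.trimmed_segments == [0, 1]
        assert seg.trivial

    def test_pseudo_exon_counts_as_terminal(self):
        # the B-only terminal pseudo-exon [4000,4200) is short and trimmed
        gene = _gene([[(0, 1000), (2000, 4000)], [(0, 1000), (2000, 4200)]])
        seg = trim_terminal_segments(segment_gene_model(gene), 76)
        assert seg.segments[-1] == (4000, 4200)
        assert len(seg.segments) - 1 in seg.trimmed_segments
        assert 0 not in seg.trimmed_segments


class TestTrivialDetection:
    def test_identical_retained_rows_are_trivial(self):
        gene = _gene([[(0, 1000)], [(0, 1000)]])
        seg = segment_gene_model(gene)
        assert detect_trivial(seg)

    def test_distinct_full_rank_rows_not_trivial(self):
        gene = _gene([[(0, 1000)], [(2000, 3000)]])
        seg = segment_gene_model(gene)
        assert seg.membership.tolist() in ([[1, 0], [0, 1]], [[0, 1], [1, 0]])
        assert not detect_trivial(seg)

    def test_duplicate_rows_among_three_isoforms(self):
        gene = _gene(
            [
                [(0, 1000), (2000, 3000)],
                [(0, 1000), (4000, 5000)],
                [(0, 1000), (2000, 3000)],
            ]
        )
        seg = segment_gene_model(gene)
        assert detect_trivial(seg)
        # elimination oracle: duplicate rows mean rank < isoform count
        assert np.linalg.matrix_rank(seg.membership.astype(float)) == 2


class TestInferIsoformFrequencies:
    def test_single_isoform(self):
        gene = _gene([[(0, 1000)]])
        seg = segment_gene_model(gene)
        cov = SegmentCoverage("g1", seg.retained_segments, [42.0], 76)
        est = infer_isoform_frequencies(seg, cov)
        assert est.frequencies == pytest.approx([1.0])

    def test_worked_two_isoform_gene(self):
        # membership A=(1,0), B=(1,1); depths (C, 0.7C) -> frequencies (0.3, 0.7)
        gene = _gene([[(100, 200)], [(100, 210)]])
        seg = segment_gene_model(gene)
        C = 50.0
        cov = SegmentCoverage("g1", seg.retained_segments, [C, 0.7 * C], 76)
        est = infer_isoform_frequencies(seg, cov)
        assert est.frequencies == pytest.approx([0.3, 0.7], abs=1e-12)
        assert est.a_hat == pytest.approx([0.3 * C, 0.7 * C], abs=1e-9)

    def test_scale_invariance(self):
        gene = _gene([[(100, 200)], [(100, 210)]])
        seg = segment_gene_model(gene)
        f = []
        for scale in (1.0, 17.5):
            cov = SegmentCoverage("g1", seg.retained_segments,
                                  np.array([50.0, 35.0]) * scale, 76)
            f.append(infer_isoform_frequencies(seg, cov).frequencies)
        assert f[0] == pytest.approx(f[1], abs=1e-12)

    def test_noiseless_exact_recovery_random_models(self):
        rng = np.random.default_rng(31)
        genes = synthetic_gene_models(5, 3, seed=17)
        for gene in genes:
            seg = trim_terminal_segments(segment_gene_model(gene), 76)
            b = rng.dirichlet(np.ones(3))
            depths = seg.retained_membership.T.astype(float) @ (b * 100.0)
            cov = SegmentCoverage(gene.gene_id, seg.retained_segments, depths, 76)
            est = infer_isoform_frequencies(seg, cov)
            assert np.abs(est.frequencies - b).max() < 1e-10

    def test_trivial_model_rejected(self):
        gene = _gene([[(0, 1000)], [(0, 1000)]])
        seg = segment_gene_model(gene)
        cov = SegmentCoverage("g1", seg.retained_segments, [10.0], 76)
        with pytest.raises(ValueError, match="trivial"):
            infer_isoform_frequencies(seg, cov)


class TestSimulateRnaseq:
    def test_interior_depth_and_terminal_falloff_single_isoform(self):
        gene = _gene([[(0, 5000)]])
        cov = simulate_rnaseq(gene, [1.0], total_coverage=200.0, read_length=76, seed=3)
        # interior mean depth ~ total_coverage; the terminal ramp over one
        # read length lowers the single-segment mean by ~(rl-1)/L
        assert cov.depths[0] == pytest.approx(200.0 * (1 - 75 / 5000), rel=0.02)

    def test_absent_isoform_segments_have_zero_depth(self):
        gene = _gene([[(0, 1000)], [(0, 1000), (2000, 3000)]])
        cov = simulate_rnaseq(gene, [1.0, 0.0], 50.0, 76, seed=4)
        depths = dict(zip(cov.segments, cov.depths))
        assert depths[(2000, 3000)] == 0.0
        assert depths[(0, 1000)] > 0

    def test_deterministic_under_fixed_seed(self):
        gene = _gene([[(0, 2000)], [(0, 2000), (3000, 4000)]])
        a = simulate_rnaseq(gene, [0.5, 0.5], 50.0, 76, seed=5)
        b = simulate_rnaseq(gene, [0.5, 0.5], 50.0, 76, seed=5)
        assert np.array_equal(a.depths, b.depths)

    def test_transcript_shorter_than_read_rejected(self):
        gene = _gene([[(0, 50)]])
        with pytest.raises(ValueError, match="shorter than the read"):
            simulate_rnaseq(gene, [1.0], 50.0, 76, seed=0)


class TestRnaSeqExperiment:
    def test_all_trivial_genes_yield_empty_result(self):
        genes = [_gene([[(0, 1000)], [(0, 1000)]], gene_id=f"g{k}") for k in range(3)]
        res = run_rnaseq_experiment(genes, 50.0, 76, 2, seed=0)
        assert res.mean_error_by_isoform_count == {}
        assert res.trivial_gene_ids == ["g0", "g1", "g2"]
        assert res.n_trivial_excluded == 3

    def test_two_isoform_genes_high_coverage(self):
        genes = synthetic_gene_models(5, 2, seed=23)
        res = run_rnaseq_experiment(genes, 100.0, 76, 10, seed=1)
        assert res.mean_error_by_isoform_count[2] < 0.02

    def test_error_decreases_with_coverage(self):
        genes = synthetic_gene_models(8, 3, seed=29)
        errs = [
            run_rnaseq_experiment(genes, cov, 76, 15, seed=2).mean_error_by_isoform_count[3]
            for cov in (10.0, 100.0)
        ]
        assert errs[1] < errs[0]

    def test_inference_close_to_truth_single_case(self):
        genes = synthetic_gene_models(1, 3, seed=41)
        gene = genes[0]
        seg = trim_terminal_segments(segment_gene_model(gene), 76)
        b = np.array([0.2, 0.3, 0.5])
        cov = simulate_rnaseq(gene, b, 500.0, 76, seed=6, seg=seg)
        est = infer_isoform_frequencies(seg, cov)
        assert mean_absolute_error(b, est.frequencies) < 0.03
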