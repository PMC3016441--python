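"""Readers and writers: panels and pool counts (VCF/TSV), gene models
(GFF3/GTF), estimates (TSV + JSON QC), and run provenance.

Conventions: VCF positions are 1-based (kept as-is for SNP loci); genomic
intervals for gene models are converted to 0-based half-open at this
boundary and nowhere else.  Nothing is filtered silently — every dropped
record is counted in the returned ingest report.  Numbers in TSV output are
written with 6 significant digits; JSON carries full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import metadata

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, Locus, PooledObservation, RawPanel, pooled_frequencies
from .regression import FrequencyEstimate, QCReport
from .rnaseq import GeneModel, Isoform, SegmentCoverage

__all__ = [
    "IngestReport",
    "read_panel",
    "write_panel",
    "read_pool_counts",
    "write_pool_counts",
    "write_estimate",
    "read_gene_models",
    "read_segment_coverage",
    "write_segment_coverage",
    "provenance",
]

_PANEL_META_COLS = ["chromosome", "position", "allele_a", "allele_b"]


@dataclass
class IngestReport:
    """Accounting of records read vs dropped, by reason."""

    n_records: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    dropped_loci: list[tuple[str, int]] = field(default_factory=list)

    def drop(self, reason: str, locus: tuple[str, int] | None = None) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1
        if locus is not None:
            self.dropped_loci.append(locus)

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    p = str(path).lower()
    if p.endswith((".vcf", ".vcf.gz")):
        return "vcf"
    return "tsv"


# --------------------------------------------------------------------------
# haplotype panels


def write_panel(panel: HaplotypePanel, path: str) -> None:
    """TSV panel with the coding preserved (``coded1`` column, 0/1 entries)."""
    with open(path, "w") as fh:
        if panel.coding_seed is not None:
            fh.write(f"#coding_seed={panel.coding_seed}\n")
        cols = _PANEL_META_COLS + ["coded1"] + list(panel.haplotype_ids)
        fh.write("\t".join(cols) + "\n")
        for m, locus in enumerate(panel.loci):
            row = [
                locus.chromosome,
                str(locus.position),
                locus.allele_a,
                locus.allele_b,
                panel.coding_map[m],
            ] + [str(int(v)) for v in panel.matrix[:, m]]
            fh.write("\t".join(row) + "\n")


def _read_panel_tsv(path: str) -> tuple[RawPanel | HaplotypePanel, IngestReport]:
    coding_seed = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#coding_seed="):
            coding_seed = int(first.split("=", 1)[1])
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    report = IngestReport(n_records=len(df))
    missing = [c for c in _PANEL_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"panel TSV missing columns {missing}")
    coded = "coded1" in df.columns
    hap_ids = [c for c in df.columns if c not in _PANEL_META_COLS + ["coded1"]]
    if not hap_ids:
        raise ValueError("panel TSV has no haplotype columns")
    rows = []
    for ln, rec in enumerate(df.itertuples(index=False), start=2):
        rec = rec._asdict()
        try:
            locus = Locus(
                str(rec["chromosome"]), int(rec["position"]),
                str(rec["allele_a"]), str(rec["allele_b"]),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed panel record at line {ln}: {exc}") from exc
        rows.append((locus, rec))
    rows.sort(key=lambda t: t[0])
    loci = [t[0] for t in rows]
    if coded:
        coding_map = []
        matrix = np.zeros((len(hap_ids), len(loci)), dtype=np.int8)
        for m, (locus, rec) in enumerate(rows):
            coding_map.append(str(rec["coded1"]))
            for i, hid in enumerate(hap_ids):
                matrix[i, m] = int(rec[hid])
        panel = HaplotypePanel(hap_ids, loci, matrix, coding_map, coding_seed)
        return panel, report
    alleles = np.empty((len(hap_ids), len(loci)), dtype=object)
    for m, (locus, rec) in enumerate(rows):
        for i, hid in enumerate(hap_ids):
            v = str(rec[hid])
            if v == "0":
                v = locus.allele_a
            elif v == "1":
                v = locus.allele_b
            alleles[i, m] = v
    return RawPanel(hap_ids, loci, alleles), report


def _read_panel_vcf(path: str) -> tuple[RawPanel, IngestReport]:
    import pysam

    report = IngestReport()
    loci: list[Locus] = []
    cols: list[list[str]] = []
    with pysam.VariantFile(path) as vf:
        hap_ids = list(vf.header.samples)
        if not hap_ids:
            raise ValueError("panel VCF has no sample columns")
        for rec in vf:
            report.n_records += 1
            where = (rec.chrom, rec.pos)
            alts = rec.alts or ()
            if len(alts) != 1:
                report.drop("multiallelic_or_monomorphic", where)
                continue
            if len(rec.ref) != 1 or len(alts[0]) != 1:
                report.drop("non_snp", where)
                continue
            alleles_here = []
            ok = True
            for sample in hap_ids:
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    report.drop("missing_genotype", where)
                    ok = False
                    break
                if len(set(gt)) != 1:
                    report.drop("heterozygous", where)
                    ok = False
                    break
                alleles_here.append(rec.alleles[gt[0]])
            if ok:
                loci.append(Locus(rec.chrom, rec.pos, rec.ref, alts[0]))
                cols.append(alleles_here)
    if not loci:
        raise ValueError("no usable bi-allelic SNP records in panel VCF")
    idx = sorted(range(len(loci)), key=lambda m: (loci[m].chromosome, loci[m].position))
    loci = [loci[m] for m in idx]
    alleles = np.array([cols[m] for m in idx], dtype=object).T
    return RawPanel(hap_ids, loci, alleles), report


def read_panel(path: str, fmt: str | None = None):
    """Read a haplotype panel from TSV or VCF.

    Returns ``(panel, report)``.  TSV files written by :func:`write_panel`
    (with a ``coded1`` column) come back as a fully coded
    :class:`HaplotypePanel`; anything else comes back as a :class:`RawPanel`
    awaiting :func:`~poolfreq.panel.code_alleles`.
    """
    fmt = _detect_format(path, fmt)
    if fmt == "tsv":
        return _read_panel_tsv(path)
    if fmt == "vcf":
        return _read_panel_vcf(path)
    raise ValueError(f"unknown panel format {fmt!r}")


# --------------------------------------------------------------------------
# pooled counts


def write_pool_counts(obs: PooledObservation, panel: HaplotypePanel, path: str) -> None:
    """TSV with one row per (locus, allele): chromosome, position, allele, count."""
    index = {(l.chromosome, l.position): m for m, l in enumerate(panel.loci)}
    with open(path, "w") as fh:
        fh.write("chromosome\tposition\tallele\tcount\n")
        for k, locus in enumerate(obs.loci):
            m = index[(locus.chromosome, locus.position)]
            coded1 = panel.coding_map[m]
            other = locus.allele_b if coded1 == locus.allele_a else locus.allele_a
            c1 = int(obs.count_coded1[k])
            c0 = int(obs.coverage[k]) - c1
            fh.write(f"{locus.chromosome}\t{locus.position}\t{coded1}\t{c1}\n")
            fh.write(f"{locus.chromosome}\t{locus.position}\t{other}\t{c0}\n")


def _read_pool_tsv(path: str, panel: HaplotypePanel):
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    need = ["chromosome", "position", "allele", "count"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"pool TSV missing columns {missing}")
    by_locus: dict[tuple[str, int], dict[str, int]] = {}
    for rec in df.itertuples(index=False):
        key = (str(rec.chromosome), int(rec.position))
        by_locus.setdefault(key, {})
        by_locus[key][str(rec.allele)] = by_locus[key].get(str(rec.allele), 0) + int(rec.count)
    return by_locus


def _read_pool_vcf(path: str, panel: HaplotypePanel):
    import pysam

    by_locus: dict[tuple[str, int], dict[str, int]] = {}
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise ValueError("pool VCF must have exactly one (pooled) sample")
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                continue
            ad = rec.samples[samples[0]].get("AD")
            if ad is None:
                raise ValueError(f"no AD field at {rec.chrom}:{rec.pos}")
            by_locus[(rec.chrom, rec.pos)] = {rec.ref: int(ad[0]), alts[0]: int(ad[1])}
    return by_locus


def read_pool_counts(path: str, panel: HaplotypePanel, fmt: str | None = None):
    """Read pooled allele counts and orient them to the panel's coding.

    Counts keyed by allele string are re-oriented through the panel's
    coding_map; an allele string not matching the panel's two alleles at a
    locus is a hard error.  Returns ``(PooledObservation, IngestReport)``;
    the observation is restricted to loci present in both panel and file,
    with unmatched file loci counted in the report and zero-coverage SNPs
    dropped (listed on the observation).
    """
    fmt = _detect_format(path, fmt)
    by_locus = _read_pool_tsv(path, panel) if fmt == "tsv" else _read_pool_vcf(path, panel)
    report = IngestReport(n_records=len(by_locus))
    loci, count1, coverage = [], [], []
    panel_index = {(l.chromosome, l.position): m for m, l in enumerate(panel.loci)}
    for key, counts in by_locus.items():
        if key not in panel_index:
            report.drop("not_in_panel", key)
            continue
        m = panel_index[key]
        locus = panel.loci[m]
        allowed = {locus.allele_a, locus.allele_b}
        extra = set(counts) - allowed
        if extra:
            raise ValueError(
                f"allele(s) {sorted(extra)} at {key[0]}:{key[1]} do not match "
                f"panel alleles {sorted(allowed)}"
            )
        c1 = counts.get(panel.coding_map[m], 0)
        total = sum(counts.values())
        loci.append(locus)
        count1.append(c1)
        coverage.append(total)
    if not loci:
        raise ValueError("no pool loci matched the panel")
    order = sorted(range(len(loci)), key=lambda k: (loci[k].chromosome, loci[k].position))
    obs = pooled_frequencies(
        [loci[k] for k in order],
        [count1[k] for k in order],
        [coverage[k] for k in order],
    )
    for dropped in obs.dropped_loci:
        report.drop("zero_coverage", (dropped.chromosome, dropped.position))
    return obs, report


# --------------------------------------------------------------------------
# estimates, coverage tables, provenance


def write_estimate(
    est: FrequencyEstimate,
    qc: QCReport,
    tsv_path: str,
    json_path: str,
    config: dict | None = None,
) -> None:
    """Estimate TSV (haplotype_id, b_hat; 6 significant digits) + QC JSON."""
    with open(tsv_path, "w") as fh:
        fh.write("haplotype_id\tb_hat\n")
        for hid, b in zip(est.haplotype_ids, est.b_hat):
            fh.write(f"{hid}\t{b:.6g}\n")
    block = {
        "sum_b": est.sum_b,
        "negative_mass": est.negative_mass,
        "residual_norm": est.residual_norm,
        "n_snps_used": est.n_snps_used,
        "rank": est.rank,
        "rank_deficient": est.rank_deficient,
        "qc_flag": qc.flag.value,
        "sum_deviation": qc.sum_deviation,
        "thresholds_used": list(qc.thresholds_used),
        "provenance": provenance(config or {}),
    }
    with open(json_path, "w") as fh:
        json.dump(block, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_segment_coverage(covs: list[SegmentCoverage], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsegment_start\tsegment_end\tmean_depth\tread_length\n")
        for cov in covs:
            for (s, e), d in zip(cov.segments, cov.depths):
                fh.write(f"{cov.gene_id}\t{s}\t{e}\t{d:.6g}\t{cov.read_length}\n")


def read_segment_coverage(path: str) -> list[SegmentCoverage]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for gid, grp in df.groupby("gene_id", sort=False):
        out.append(
            SegmentCoverage(
                gene_id=str(gid),
                segments=[(int(s), int(e)) for s, e in zip(grp.segment_start, grp.segment_end)],
                depths=grp.mean_depth.to_numpy(dtype=float),
                read_length=int(grp.read_length.iloc[0]),
            )
        )
    return out


def read_gene_models(path: str) -> list[GeneModel]:
    """Gene models from GFF3/GTF (gene / mRNA|transcript / exon features).

    1-based closed coordinates are converted to 0-based half-open here.
    """
    import gffutils

    is_gtf = str(path).lower().endswith((".gtf", ".gtf.gz"))
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=not is_gtf,
        disable_infer_transcripts=not is_gtf,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        isoforms = []
        for tx in db.children(gene, level=1):
            if tx.featuretype not in ("mRNA", "transcript"):
                continue
            exons = [
                (ex.start - 1, ex.end)
                for ex in db.children(tx, featuretype="exon", order_by="start")
            ]
            if exons:
                isoforms.append(Isoform(tx.id, exons))
        if isoforms:
            genes.append(GeneModel(gene.id, gene.seqid, gene.strand, isoforms))
    if not genes:
        raise ValueError(f"no gene models found in {path}")
    return genes


def provenance(config: dict) -> dict:
    """Run provenance block: the config echo plus the package version."""
    try:
        version = metadata.version("poolfreq")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    return {"package": "poolfreq", "version": version, "config": config}
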