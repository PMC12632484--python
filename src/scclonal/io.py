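"""Readers and writers for the pipeline's on-disk interchange formats.

CN matrices travel as matrix-market files with a side BED of bins and a
barcode list; phased SNPs as VCF (written and read with pysam); allele
counts as long-format TSV; ST counts as matrix-market plus a spot table
and a gene-position BED; LOH and mirrored segments as BED-like TSV.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd
import pysam
from scipy import io as spio
from scipy import sparse

from .containers import (AlleleCounts, CellCNMatrix, LOHSegmentSet,
                         PhasedSNPTable, STSpotMatrix)


def _ensure_dir(path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    return path


# ---------------------------------------------------------------------------
# CN matrix


def write_cn_matrix(matrix: CellCNMatrix, outdir: str | os.PathLike) -> None:
    out = _ensure_dir(Path(outdir))
    spio.mmwrite(out / "cn.mtx", sparse.csr_matrix(matrix.cn))
    spio.mmwrite(out / "quality.mtx",
                 sparse.csr_matrix(matrix.quality.astype(np.float32)))
    bins = matrix.bins[["chrom", "start", "end", "mappability"]]
    bins.to_csv(out / "bins.bed", sep="\t", header=False, index=False)
    pd.Series(matrix.barcodes).to_csv(out / "barcodes.tsv", sep="\t",
                                      header=False, index=False)
    if matrix.mask.any():
        spio.mmwrite(out / "mask.mtx",
                     sparse.csr_matrix(matrix.mask.astype(np.int8)))


def read_cn_matrix(indir: str | os.PathLike) -> CellCNMatrix:
    ind = Path(indir)
    cn = np.asarray(spio.mmread(ind / "cn.mtx").todense())
    quality = np.asarray(spio.mmread(ind / "quality.mtx").todense())
    bins = pd.read_csv(ind / "bins.bed", sep="\t", header=None,
                       names=["chrom", "start", "end", "mappability"])
    barcodes = pd.read_csv(ind / "barcodes.tsv", sep="\t",
                           header=None)[0].tolist()
    mask = None
    if (ind / "mask.mtx").exists():
        mask = np.asarray(spio.mmread(ind / "mask.mtx").todense()) > 0
    return CellCNMatrix(pd.Index(barcodes), bins, cn.astype(np.int16),
                        quality, mask)


# ---------------------------------------------------------------------------
# phased SNPs (VCF) and allele counts


def write_phased_vcf(snps: PhasedSNPTable, path: str | os.PathLike,
                     contig_lengths: Dict[str, int]) -> None:
    """Phased heterozygous SNPs as a single-sample VCF (GT 0|1 / 1|0)."""
    header = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        header.contigs.add(contig, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("germline")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, row in snps.snps.iterrows():
            rec = vcf.new_record(contig=row["chrom"], start=int(row["pos"]),
                                 alleles=(row["ref"], row["alt"]),
                                 id=row["snp_id"])
            # hap A carries REF when the ALT allele is on haplotype B
            gt = (0, 1) if row["hap_b_is_alt"] else (1, 0)
            rec.samples["germline"]["GT"] = gt
            rec.samples["germline"].phased = True
            vcf.write(rec)


def read_phased_vcf(path: str | os.PathLike) -> PhasedSNPTable:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0]
        for rec in vcf:
            gt = rec.samples[sample]["GT"]
            rows.append({"snp_id": rec.id or f"{rec.contig}:{rec.pos}",
                         "chrom": rec.contig, "pos": rec.start,
                         "ref": rec.ref, "alt": rec.alts[0],
                         "hap_b_is_alt": gt == (0, 1)})
    return PhasedSNPTable(pd.DataFrame(rows))


def write_allele_counts(alleles: AlleleCounts, path: str | os.PathLike
                        ) -> None:
    """Long-format TSV: barcode, snp_id, ref_count, alt_count."""
    alt = alleles.alt_reads()
    ref = alleles.ref_reads()
    cells, snps = np.nonzero(alt + ref)
    ids = alleles.snps.snps["snp_id"].to_numpy()
    df = pd.DataFrame({"barcode": alleles.barcodes.to_numpy()[cells],
                       "snp_id": ids[snps],
                       "ref_count": ref[cells, snps],
                       "alt_count": alt[cells, snps]})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# spatial


def write_st(st: STSpotMatrix, outdir: str | os.PathLike) -> None:
    out = _ensure_dir(Path(outdir))
    spio.mmwrite(out / "counts.mtx", sparse.csr_matrix(st.counts))
    st.spots.reset_index().to_csv(out / "spots.tsv", sep="\t", index=False)
    genes = st.genes.reset_index()
    genes["end"] = genes["start"] + 1
    genes[["chrom", "start", "end", "gene"]].to_csv(
        out / "genes.bed", sep="\t", header=False, index=False)


def read_st(indir: str | os.PathLike) -> STSpotMatrix:
    ind = Path(indir)
    counts = np.asarray(spio.mmread(ind / "counts.mtx").todense())
    spots = pd.read_csv(ind / "spots.tsv", sep="\t").set_index("barcode")
    genes = pd.read_csv(ind / "genes.bed", sep="\t", header=None,
                        names=["chrom", "start", "end", "gene"]
                        ).set_index("gene")[["chrom", "start"]]
    return STSpotMatrix(spots, genes, counts.astype(np.int32))


# ---------------------------------------------------------------------------
# segment tables


def write_segments_bed(segments: pd.DataFrame, path: str | os.PathLike
                       ) -> None:
    """BED-like TSV with chrom/start/end first, extra columns after."""
    cols = ["chrom", "start", "end"] + [c for c in segments.columns
                                        if c not in
                                        ("chrom", "start", "end")]
    segments[cols].to_csv(path, sep="\t", index=False)


def write_loh(loh: LOHSegmentSet, path: str | os.PathLike) -> None:
    write_segments_bed(loh.segments, path)
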