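"""In-memory containers shared across pipeline stages.

The central object is :class:`CellCNMatrix`: integer copy-number calls per
(barcode, 20 kb bin) with a parallel per-call quality matrix, a boolean
mask of removed calls, and a bin table (chrom, start, end, mappability)
in 0-based half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

BIN_COLUMNS = ["chrom", "start", "end", "mappability"]


@dataclass
class CellCNMatrix:
    """Integer CN calls per cell barcode over ordered genome bins."""

    barcodes: pd.Index
    bins: pd.DataFrame                 # chrom, start, end, mappability
    cn: np.ndarray                     # (n_cells, n_bins) int
    quality: np.ndarray                # (n_cells, n_bins) float
    mask: Optional[np.ndarray] = None  # True where the call was removed

    def __post_init__(self) -> None:
        self.barcodes = pd.Index(self.barcodes)
        n, m = self.cn.shape
        if len(self.barcodes) != n:
            raise ValueError("barcode count does not match cn rows")
        if len(self.bins) != m:
            raise ValueError("bin count does not match cn columns")
        if self.quality.shape != (n, m):
            raise ValueError("quality shape mismatch")
        if self.mask is None:
            self.mask = np.zeros((n, m), dtype=bool)
        if self.mask.shape != (n, m):
            raise ValueError("mask shape mismatch")
        mp = self.bins["mappability"].to_numpy()
        if ((mp < 0) | (mp > 1)).any():
            raise ValueError("mappability must lie in [0, 1]")
        if (self.cn[~self.mask] < 0).any():
            raise ValueError("unmasked CN calls must be >= 0")

    @property
    def n_cells(self) -> int:
        return self.cn.shape[0]

    @property
    def n_bins(self) -> int:
        return self.cn.shape[1]

    def copy(self) -> "CellCNMatrix":
        return CellCNMatrix(self.barcodes.copy(), self.bins.copy(),
                            self.cn.copy(), self.quality.copy(),
                            self.mask.copy())

    def subset_cells(self, keep: Sequence[str]) -> "CellCNMatrix":
        idx = self.barcodes.get_indexer(pd.Index(keep))
        if (idx < 0).any():
            missing = [b for b, i in zip(keep, idx) if i < 0]
            raise KeyError(f"barcodes not present: {missing[:5]}")
        return CellCNMatrix(pd.Index(keep), self.bins,
                            self.cn[idx], self.quality[idx], self.mask[idx])


@dataclass
class AggregatedCNMatrix:
    """Mean ploidy per cell over coarse (default 10 Mb) windows.

    ``values`` holds NaN where every fine call in the window was masked.
    """

    barcodes: pd.Index
    coarse_bins: pd.DataFrame          # chrom, start, end
    values: np.ndarray                 # (n_cells, n_windows) float, NaN=missing

    def __post_init__(self) -> None:
        self.barcodes = pd.Index(self.barcodes)
        if self.values.shape != (len(self.barcodes), len(self.coarse_bins)):
            raise ValueError("values shape mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def subset_cells(self, keep: Sequence[str]) -> "AggregatedCNMatrix":
        idx = self.barcodes.get_indexer(pd.Index(keep))
        if (idx < 0).any():
            raise KeyError("unknown barcodes in subset")
        return AggregatedCNMatrix(pd.Index(keep), self.coarse_bins,
                                  self.values[idx])


@dataclass
class CloneProfile:
    """Per-cluster representative CN profile over coarse bins."""

    cluster: str
    mean: np.ndarray                   # mean ploidy per coarse bin
    rounded: np.ndarray                # rounded-integer variant
    sd: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("profile needs >= 1 cell")
        if np.nanmin(self.sd) < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class ClusterAssignment:
    """Two-level (cluster.subcluster) labels for retained barcodes."""

    labels: pd.DataFrame               # index barcode; cluster, subcluster
    scores: pd.DataFrame               # k, aic, bic (+ level column)

    def __post_init__(self) -> None:
        need = {"cluster", "subcluster"}
        if not need.issubset(self.labels.columns):
            raise ValueError("labels must have cluster and subcluster columns")

    @property
    def barcodes(self) -> pd.Index:
        return self.labels.index

    def full_label(self) -> pd.Series:
        return (self.labels["cluster"].astype(str) + "."
                + self.labels["subcluster"].astype(str))

    def cells_of(self, cluster: str) -> pd.Index:
        return self.labels.index[self.labels["cluster"].astype(str)
                                 == str(cluster)]


@dataclass
class DoubletProfile:
    """Expected coarse-bin CN of a synthetic doublet profile."""

    kind: str                          # diploid_tumor | tumor_tumor
    sources: tuple
    expected: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("diploid_tumor", "tumor_tumor"):
            raise ValueError(f"unknown doublet kind {self.kind!r}")


@dataclass
class HaplotypeCN:
    """Integer (A, B) copy allocation per (cell, coarse bin).

    ``a + b`` equals the rounded total CN wherever the split is defined;
    unknown splits (zero allele depth) are marked -1 in both matrices.
    """

    barcodes: pd.Index
    coarse_bins: pd.DataFrame
    a: np.ndarray                      # (n_cells, n_bins) int
    b: np.ndarray

    def __post_init__(self) -> None:
        if self.a.shape != self.b.shape:
            raise ValueError("a/b shape mismatch")

    @property
    def known(self) -> np.ndarray:
        return (self.a >= 0) & (self.b >= 0)

    @property
    def total(self) -> np.ndarray:
        t = self.a + self.b
        t[~self.known] = -1
        return t


LOH_CLASSES = ("hemizygous", "copy_neutral", "amplified")


def classify_loh(retained_copies: int) -> str:
    """LOH class from the copy count of the retained haplotype."""
    if retained_copies <= 0:
        raise ValueError("LOH requires >= 1 retained copy")
    if retained_copies == 1:
        return "hemizygous"
    if retained_copies == 2:
        return "copy_neutral"
    return "amplified"


@dataclass
class LOHSegmentSet:
    """Per-cluster LOH segments with class labels.

    ``segments`` columns: cluster, chrom, start, end, lost_haplotype
    (A|B), retained_copies, loh_class.
    """

    segments: pd.DataFrame

    COLUMNS = ["cluster", "chrom", "start", "end", "lost_haplotype",
               "retained_copies", "loh_class"]

    def __post_init__(self) -> None:
        if self.segments.empty:
            self.segments = pd.DataFrame(columns=self.COLUMNS)
        missing = set(self.COLUMNS) - set(self.segments.columns)
        if missing:
            raise ValueError(f"missing LOH columns: {missing}")

    def for_cluster(self, cluster: str) -> pd.DataFrame:
        seg = self.segments
        return seg[seg["cluster"].astype(str) == str(cluster)]


@dataclass
class PhasedSNPTable:
    """Phased heterozygous autosomal SNPs.

    ``snps`` columns: snp_id, chrom, pos (0-based), ref, alt, hap_b_is_alt
    (True when the ALT allele sits on haplotype B, i.e. GT ``0|1``).
    """

    snps: pd.DataFrame

    COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "hap_b_is_alt"]

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.snps.columns)
        if missing:
            raise ValueError(f"missing SNP columns: {missing}")


@dataclass
class STSpotMatrix:
    """Spot x gene raw counts with array coordinates and gene positions."""

    spots: pd.DataFrame                # index barcode; x, y
    genes: pd.DataFrame                # index gene id; chrom, start
    counts: np.ndarray                 # (n_spots, n_genes)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.spots), len(self.genes)):
            raise ValueError("counts shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")


@dataclass
class STCNProfile:
    """Inferred CN profile of one ST tumor subgroup."""

    subgroup: str
    gene_index: pd.Index
    smoothed: np.ndarray               # mean smoothed relative expression
    states: np.ndarray                 # -1 loss / 0 neutral / +1 gain per gene
    spots: pd.Index

    def __post_init__(self) -> None:
        if not set(np.unique(self.states)).issubset({-1, 0, 1}):
            raise ValueError("states must be in {-1, 0, 1}")


@dataclass
class AlleleCounts:
    """Per-cell haplotype-resolved read counts at phased SNPs.

    ``a_reads``/``b_reads`` count reads supporting the A/B haplotype per
    (cell, SNP). REF/ALT counts follow from ``hap_b_is_alt`` in the SNP
    table. ``bin_reads`` are total per-cell read counts in coarse
    (default 10 Mb) genomic bins, used for read-depth ratios.
    """

    barcodes: pd.Index
    snps: PhasedSNPTable
    a_reads: np.ndarray                # (n_cells, n_snps)
    b_reads: np.ndarray
    bin_reads: Optional[np.ndarray] = None   # (n_cells, n_coarse_bins)

    def __post_init__(self) -> None:
        self.barcodes = pd.Index(self.barcodes)
        shape = (len(self.barcodes), len(self.snps.snps))
        if self.a_reads.shape != shape or self.b_reads.shape != shape:
            raise ValueError("allele count shape mismatch")

    def alt_reads(self) -> np.ndarray:
        flip = self.snps.snps["hap_b_is_alt"].to_numpy()
        return np.where(flip, self.b_reads, self.a_reads)

    def ref_reads(self) -> np.ndarray:
        flip = self.snps.snps["hap_b_is_alt"].to_numpy()
        return np.where(flip, self.a_reads, self.b_reads)

    def subset_cells(self, keep: Sequence[str]) -> "AlleleCounts":
        idx = self.barcodes.get_indexer(pd.Index(keep))
        if (idx < 0).any():
            raise KeyError("unknown barcodes in subset")
        br = None if self.bin_reads is None else self.bin_reads[idx]
        return AlleleCounts(pd.Index(keep), self.snps,
                            self.a_reads[idx], self.b_reads[idx], br)


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the synthetic data."""

    cells: pd.DataFrame                # index barcode; class, clone,
    #                                    subclone, wgd, source_a, source_b,
    #                                    ploidy_confident
    true_cn: np.ndarray                # (n_cells, n_bins) total CN
    clone_hap_a: dict                  # profile key -> (n_bins,) int
    clone_hap_b: dict
    loh_truth: pd.DataFrame            # clone, chrom, start, end, class,
    #                                    lost_haplotype
    variant_truth: pd.DataFrame        # variant_id, chrom, pos, haplotype,
    #                                    carrier clones, reverted_in
    pseudo_gain_bins: dict = field(default_factory=dict)
    spot_truth: Optional[pd.DataFrame] = None
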