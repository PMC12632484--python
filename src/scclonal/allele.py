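"""Haplotype-specific copy number, LOH and mirrored allelic imbalance.

Read-depth ratios (RDR) over 10 Mb bins and phased B-allele frequencies
(BAF) over 50 kb bins summarise per-cell allelic state. Conditional on
the rounded total CN of a bin, the integer haplotype split (a, b) with
a + b = total is chosen by maximising the binomial likelihood of the
observed B-haplotype reads with success probability b/(a+b)
(error-adjusted at monoallelic splits, ties broken toward balance).
Cluster consensus splits define LOH segments — any region lacking one
haplotype, classed hemizygous / copy-neutral / amplified by the
retained copy count — and mirrored allelic-imbalance segments between
cluster pairs (equal totals, swapped major haplotype).
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import (AlleleCounts, HaplotypeCN, LOHSegmentSet,
                         PhasedSNPTable, classify_loh)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# RDR / BAF


def compute_rdr(bin_reads: np.ndarray, barcodes: pd.Index,
                reference_cells: Sequence[str]) -> np.ndarray:
    """Read-depth ratio per (cell, bin) against a pooled diploid reference.

    RDR = (cell bin count / cell total) / (pooled reference bin count /
    reference total). Bins with zero pooled reference coverage are NaN.
    Scale-invariant: doubling a cell's counts leaves its RDR unchanged.
    """
    ref_idx = barcodes.get_indexer(pd.Index(reference_cells))
    if len(ref_idx) == 0 or (ref_idx < 0).any():
        raise ValueError("reference cell set empty or unknown")
    pooled = bin_reads[ref_idx].sum(axis=0).astype(float)
    ref_frac = pooled / pooled.sum()
    cell_tot = bin_reads.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cell_frac = bin_reads / np.maximum(cell_tot, 1)
        rdr = cell_frac / ref_frac[None, :]
    rdr[:, ref_frac <= 0] = np.nan
    return rdr


def _bin_key(chrom: np.ndarray, pos: np.ndarray, bin_size: int
             ) -> pd.DataFrame:
    return pd.DataFrame({"chrom": chrom, "bin_start": (pos // bin_size)
                         * bin_size})


def compute_baf(alleles: AlleleCounts, bin_size: int = 50_000
                ) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Phased BAF per (cell, genomic bin).

    BAF = B-haplotype reads / total reads, summed over the bin's SNPs.
    Returns (bin table, baf matrix, depth matrix); bins without covered
    SNPs are NaN for that cell.
    """
    snps = alleles.snps.snps
    key = _bin_key(snps["chrom"].to_numpy(), snps["pos"].to_numpy(),
                   bin_size)
    groups = key.groupby(["chrom", "bin_start"], sort=True).indices
    bins = pd.DataFrame([{"chrom": c, "start": s, "end": s + bin_size}
                         for (c, s) in groups])
    n_cells = len(alleles.barcodes)
    baf = np.full((n_cells, len(groups)), np.nan)
    depth = np.zeros((n_cells, len(groups)), dtype=np.int64)
    for j, (kk, idx) in enumerate(groups.items()):
        b = alleles.b_reads[:, idx].sum(axis=1)
        t = b + alleles.a_reads[:, idx].sum(axis=1)
        depth[:, j] = t
        with np.errstate(divide="ignore", invalid="ignore"):
            baf[:, j] = np.where(t > 0, b / np.maximum(t, 1), np.nan)
    return bins, baf, depth


def cluster_baf_blocks(alleles: AlleleCounts, cluster_cells: Sequence[str],
                       block_size: int = 100_000) -> pd.DataFrame:
    """Cluster-pooled BAF in genomic blocks (default 100 kb).

    Reads are pooled across the cluster's cells within each block
    before the ratio is computed, smoothing single-cell noise; the
    pooled value equals the read-weighted mean of per-cell BAFs.
    """
    sub = alleles.subset_cells(cluster_cells)
    snps = sub.snps.snps
    key = _bin_key(snps["chrom"].to_numpy(), snps["pos"].to_numpy(),
                   block_size)
    b_tot = sub.b_reads.sum(axis=0)
    t_tot = b_tot + sub.a_reads.sum(axis=0)
    df = key.assign(b=b_tot, t=t_tot).groupby(
        ["chrom", "bin_start"], sort=True, as_index=False).sum()
    df = df[df["t"] > 0]
    df["baf"] = df["b"] / df["t"]
    df = df.rename(columns={"bin_start": "start", "t": "depth"})
    df["end"] = df["start"] + block_size
    return df[["chrom", "start", "end", "baf", "depth", "b"]].reset_index(
        drop=True)


# ---------------------------------------------------------------------------
# haplotype-specific CN


def _binom_split_loglik(total: int, b_reads: int, depth: int,
                        error_floor: float) -> np.ndarray:
    """Log-likelihood of each split b = 0..total given observed B reads."""
    bs = np.arange(total + 1)
    p = bs / total if total > 0 else np.array([0.5])
    p = np.clip(p, error_floor, 1 - error_floor)
    # log C(depth, b_reads) is constant across splits; drop it
    return b_reads * np.log(p) + (depth - b_reads) * np.log1p(-p)


def call_haplotype_cn(total_cn: np.ndarray, b_reads: np.ndarray,
                      depth: np.ndarray, error_floor: float = 0.01
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """ML integer haplotype split per (cell, bin) given total CN.

    For each entry chooses (a, b) with a + b = total maximising the
    binomial likelihood of ``b_reads`` out of ``depth`` at success
    probability b/total, clipped to [error_floor, 1 - error_floor].
    Ties break toward the balanced split. Entries with zero depth or
    negative total are unknown (-1, -1); total 0 yields (0, 0).
    """
    total_cn = np.asarray(total_cn)
    a_out = np.full(total_cn.shape, -1, dtype=np.int16)
    b_out = np.full(total_cn.shape, -1, dtype=np.int16)
    max_t = int(total_cn.max()) if total_cn.size else 0
    for t in range(0, max_t + 1):
        sel = total_cn == t
        if not sel.any():
            continue
        if t == 0:
            a_out[sel], b_out[sel] = 0, 0
            continue
        d = depth[sel].astype(np.int64)
        br = b_reads[sel].astype(np.int64)
        bs = np.arange(t + 1)
        p = np.clip(bs / t, error_floor, 1 - error_floor)
        ll = (br[:, None] * np.log(p)[None, :]
              + (d - br)[:, None] * np.log1p(-p)[None, :])
        # stable tie-break toward balance: subtract a tiny penalty
        # growing with |a - b|
        ll = ll - 1e-9 * np.abs(t - 2 * bs)[None, :]
        best_b = bs[np.argmax(ll, axis=1)]
        a_sel = (t - best_b).astype(np.int16)
        b_sel = best_b.astype(np.int16)
        known = d > 0
        rows = np.flatnonzero(sel.ravel())
        flat_a, flat_b = a_out.ravel(), b_out.ravel()
        flat_a[rows[known]] = a_sel[known]
        flat_b[rows[known]] = b_sel[known]
    return a_out, b_out


def haplotype_cn_matrix(agg_values: np.ndarray, barcodes: pd.Index,
                        coarse_bins: pd.DataFrame, alleles: AlleleCounts,
                        error_floor: float = 0.01) -> HaplotypeCN:
    """Per-cell haplotype CN over coarse bins from aggregated total CN.

    SNP reads are pooled per coarse bin per cell; totals are the
    rounded aggregated mean ploidy.
    """
    snps = alleles.snps.snps
    sub_idx = alleles.barcodes.get_indexer(barcodes)
    if (sub_idx < 0).any():
        raise ValueError("allele counts missing for some barcodes")
    b_bin = np.zeros((len(barcodes), len(coarse_bins)), dtype=np.int64)
    d_bin = np.zeros_like(b_bin)
    starts = coarse_bins["start"].to_numpy()
    chroms = coarse_bins["chrom"].to_numpy()
    lookup = {(c, s): j for j, (c, s) in enumerate(zip(chroms, starts))}
    size = int(coarse_bins["end"].iloc[0] - coarse_bins["start"].iloc[0])
    snp_bin = [lookup.get((c, (p // size) * size), -1)
               for c, p in zip(snps["chrom"], snps["pos"])]
    snp_bin = np.asarray(snp_bin)
    for j in range(len(coarse_bins)):
        cols = snp_bin == j
        if not cols.any():
            continue
        b_bin[:, j] = alleles.b_reads[sub_idx][:, cols].sum(axis=1)
        d_bin[:, j] = b_bin[:, j] \
            + alleles.a_reads[sub_idx][:, cols].sum(axis=1)
    total = np.where(np.isfinite(agg_values),
                     np.round(agg_values).astype(int), -1)
    total = np.maximum(total, -1)
    a, b = call_haplotype_cn(np.where(total < 0, 0, total), b_bin, d_bin,
                             error_floor)
    a[total < 0] = -1
    b[total < 0] = -1
    return HaplotypeCN(barcodes, coarse_bins, a, b)


def cluster_consensus(hap: HaplotypeCN, cluster_cells: Sequence[str]
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Per-cluster modal (a, b) split per coarse bin."""
    idx = hap.barcodes.get_indexer(pd.Index(cluster_cells))
    if (idx < 0).any():
        raise ValueError("unknown barcodes in cluster")
    a_out = np.full(hap.a.shape[1], -1, dtype=int)
    b_out = np.full(hap.a.shape[1], -1, dtype=int)
    for j in range(hap.a.shape[1]):
        av, bv = hap.a[idx, j], hap.b[idx, j]
        ok = (av >= 0) & (bv >= 0)
        if not ok.any():
            continue
        pairs, counts = np.unique(np.stack([av[ok], bv[ok]]), axis=1,
                                  return_counts=True)
        best = np.argmax(counts)
        a_out[j], b_out[j] = int(pairs[0, best]), int(pairs[1, best])
    return a_out, b_out


# ---------------------------------------------------------------------------
# LOH segmentation


def infer_loh(consensus: Dict[str, Tuple[np.ndarray, np.ndarray]],
              coarse_bins: pd.DataFrame) -> LOHSegmentSet:
    """Merge consecutive LOH bins of each cluster consensus into segments.

    A bin is LOH when min(a, b) = 0 with a + b > 0; consecutive
    same-chromosome bins with the same lost haplotype and retained copy
    count merge into one segment classed hemizygous (1 retained copy),
    copy-neutral (2) or amplified (>= 3).
    """
    chroms = coarse_bins["chrom"].to_numpy()
    rows = []
    for cluster, (a, b) in consensus.items():
        j = 0
        n = len(a)
        while j < n:
            known = a[j] >= 0 and b[j] >= 0
            is_loh = known and min(a[j], b[j]) == 0 and (a[j] + b[j]) > 0
            if not is_loh:
                j += 1
                continue
            lost = "A" if a[j] == 0 else "B"
            retained = int(max(a[j], b[j]))
            k = j
            while (k + 1 < n and chroms[k + 1] == chroms[j]
                   and a[k + 1] >= 0 and b[k + 1] >= 0
                   and min(a[k + 1], b[k + 1]) == 0
                   and (a[k + 1] + b[k + 1]) > 0
                   and ("A" if a[k + 1] == 0 else "B") == lost
                   and int(max(a[k + 1], b[k + 1])) == retained):
                k += 1
            rows.append({"cluster": cluster, "chrom": chroms[j],
                         "start": int(coarse_bins["start"].iloc[j]),
                         "end": int(coarse_bins["end"].iloc[k]),
                         "lost_haplotype": lost,
                         "retained_copies": retained,
                         "loh_class": classify_loh(retained)})
            j = k + 1
    return LOHSegmentSet(pd.DataFrame(rows))


def detect_mirrored_imbalance(cons_i: Tuple[np.ndarray, np.ndarray],
                              cons_j: Tuple[np.ndarray, np.ndarray],
                              coarse_bins: pd.DataFrame) -> pd.DataFrame:
    """Maximal segments where two consensuses swap an unbalanced split.

    Reports runs of bins where cluster i carries (a, b) and cluster j
    carries (b, a) with a != b; totals are equal by construction.
    """
    ai, bi = cons_i
    aj, bj = cons_j
    known = (ai >= 0) & (bi >= 0) & (aj >= 0) & (bj >= 0)
    hit = known & (ai == bj) & (bi == aj) & (ai != bi)
    chroms = coarse_bins["chrom"].to_numpy()
    rows = []
    j = 0
    n = len(hit)
    while j < n:
        if not hit[j]:
            j += 1
            continue
        k = j
        while (k + 1 < n and hit[k + 1] and chroms[k + 1] == chroms[j]
               and ai[k + 1] == ai[j] and bi[k + 1] == bi[j]):
            k += 1
        rows.append({"chrom": chroms[j],
                     "start": int(coarse_bins["start"].iloc[j]),
                     "end": int(coarse_bins["end"].iloc[k]),
                     "split_i": f"{ai[j]},{bi[j]}",
                     "split_j": f"{aj[j]},{bj[j]}",
                     "total": int(ai[j] + bi[j])})
        j = k + 1
    return pd.DataFrame(rows,
                        columns=["chrom", "start", "end", "split_i",
                                 "split_j", "total"])


# ---------------------------------------------------------------------------
# driver reversion


def detect_reversion_by_loh(variant: pd.Series,
                            cluster_vafs: Dict[str, Tuple[float, int]],
                            loh: LOHSegmentSet,
                            min_carrier_vaf: float = 0.1,
                            max_reverted_vaf: float = 0.02) -> pd.DataFrame:
    """Flag clusters where LOH removed the variant-bearing haplotype.

    ``variant`` needs chrom, pos, haplotype (A/B or empty if unphased);
    ``cluster_vafs`` maps cluster -> (pseudobulk VAF, depth). A cluster
    is flagged as a reversion when (1) it has an LOH segment spanning
    the site with the variant's haplotype lost, (2) its VAF is ~0, and
    (3) some other cluster carries the variant (VAF above threshold).
    An unphased variant yields status ``inconclusive``.
    """
    hap = variant.get("haplotype", "")
    rows = []
    carriers = [c for c, (v, d) in cluster_vafs.items()
                if d > 0 and v >= min_carrier_vaf]
    for cluster, (vaf, depth) in cluster_vafs.items():
        seg = loh.for_cluster(cluster)
        over = seg[(seg["chrom"] == variant["chrom"])
                   & (seg["start"] <= variant["pos"])
                   & (seg["end"] > variant["pos"])]
        if over.empty:
            status = "no_loh"
        elif not hap:
            status = "inconclusive"
        elif (over["lost_haplotype"] == hap).any():
            others = [c for c in carriers if c != cluster]
            if depth > 0 and vaf <= max_reverted_vaf and others:
                status = "reversion"
            else:
                status = "loh_lost_haplotype"
        else:
            # LOH retained the variant-bearing haplotype
            status = "loh_retained_mutant"
        rows.append({"cluster": cluster, "vaf": vaf, "depth": depth,
                     "status": status})
    return pd.DataFrame(rows)
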