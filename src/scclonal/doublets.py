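"""Doublet-profile construction and removal of doublets and artifacts.

Doublet reference profiles are built from the baseline (pre-WGD) tumor
cluster profiles: a diploid-tumor profile is each baseline plus 2 at
every bin, and a tumor-tumor profile is the element-wise sum of each
unordered baseline pair. Cells matching a doublet profile more closely
than any singlet clone profile are removed. A second filter removes
copy-number overfit artifacts: non-diploid cells lacking any 10 Mb
window with an odd modal copy number.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .containers import (AggregatedCNMatrix, CellCNMatrix, CloneProfile,
                         DoubletProfile)

logger = logging.getLogger(__name__)


def build_doublet_profiles(profiles: Dict[str, CloneProfile],
                           kinds: Dict[str, str]) -> List[DoubletProfile]:
    """Doublet reference profiles from baseline (pre-WGD) tumor clusters.

    One ``diploid_tumor`` profile per baseline (baseline + 2 everywhere)
    and one ``tumor_tumor`` profile per unordered baseline pair; with
    two baselines this yields exactly 3 profiles.
    """
    baselines = [cl for cl, kind in kinds.items() if kind == "tumor_baseline"]
    if not baselines:
        raise ValueError("no baseline (pre-WGD) tumor profile identified")
    out = []
    for cl in baselines:
        out.append(DoubletProfile("diploid_tumor", (cl,),
                                  profiles[cl].mean + 2.0))
    for i, a in enumerate(baselines):
        for b in baselines[i + 1:]:
            out.append(DoubletProfile("tumor_tumor", (a, b),
                                      profiles[a].mean + profiles[b].mean))
    return out


def _mad_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Mean absolute deviation over bins finite in both vectors."""
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.any():
        return np.inf
    return float(np.abs(x[ok] - y[ok]).mean())


def doublet_like_clusters(profiles: Dict[str, CloneProfile],
                          kinds: Dict[str, str],
                          doublet_profiles: Sequence[DoubletProfile],
                          threshold: float = 0.35) -> Set[str]:
    """Clusters whose own profile matches a doublet profile.

    Such clusters (typically small clusters formed entirely of barcode
    collisions) are excluded from the singlet reference set; their
    sources are ignored when testing them against ``tumor_tumor``
    profiles built from themselves. Diploid and WGD clusters are exempt:
    a WGD profile is arithmetically indistinguishable from a tumor-tumor
    collision of two subclones of the same clone, and genuine WGD
    populations are retained.
    """
    flagged = set()
    for cl, pr in profiles.items():
        kind = kinds.get(cl, "")
        if kind == "diploid" or kind.startswith("wgd"):
            continue
        for dp in doublet_profiles:
            if cl in map(str, dp.sources):
                continue
            if _mad_distance(pr.mean, dp.expected) < threshold:
                flagged.add(cl)
                logger.info("cluster %s matches %s doublet profile of %s",
                            cl, dp.kind, dp.sources)
                break
    return flagged


def match_doublets(agg: AggregatedCNMatrix,
                   doublet_profiles: Sequence[DoubletProfile],
                   singlet_profiles: Dict[str, CloneProfile],
                   threshold: float = 0.35
                   ) -> Tuple[Set[str], pd.DataFrame]:
    """Barcodes removed as doublets, with per-barcode reasons.

    A cell is removed when its mean-absolute-deviation distance to some
    doublet profile is below ``threshold`` AND smaller than its distance
    to every singlet clone profile. Lowering the threshold never removes
    more cells.
    """
    removed = set()
    log_rows = []
    singlets = {cl: pr.mean for cl, pr in singlet_profiles.items()}
    for i, bc in enumerate(agg.barcodes):
        v = agg.values[i]
        d_single = min(_mad_distance(v, p) for p in singlets.values())
        best, best_d = None, np.inf
        for dp in doublet_profiles:
            d = _mad_distance(v, dp.expected)
            if d < best_d:
                best, best_d = dp, d
        if best_d < threshold and best_d < d_single:
            removed.add(bc)
            log_rows.append({"barcode": bc, "reason": best.kind,
                             "sources": "+".join(map(str, best.sources)),
                             "distance": best_d,
                             "singlet_distance": d_single})
    return removed, pd.DataFrame(log_rows)


def odd_region_filter(matrix: CellCNMatrix, labels: pd.Series,
                      kinds: Dict[str, str], window_bp: int = 10_000_000,
                      exempt_diploid: bool = True
                      ) -> Tuple[Set[str], pd.DataFrame]:
    """Remove cells with no 10 Mb window of odd modal copy number.

    A genuine aneuploid genome contains odd-CN stretches; a profile that
    is even everywhere is the signature of copy-number overfitting (for
    example a diploid genome called at twice its real ploidy). Cells of
    the diploid cluster are exempt by default: an all-2 genome contains
    no odd window but is genuine.
    """
    bins = matrix.bins
    chroms = bins["chrom"].to_numpy()
    starts = bins["start"].to_numpy()
    win_of = np.zeros(len(bins), dtype=int)
    wid = -1
    prev = None
    for i in range(len(bins)):
        key = (chroms[i], starts[i] // window_bp)
        if key != prev:
            wid += 1
            prev = key
        win_of[i] = wid
    n_win = wid + 1

    removed = set()
    log_rows = []
    diploid_clusters = {cl for cl, kind in kinds.items()
                        if kind == "diploid"} if exempt_diploid else set()
    for bc, cl in labels.items():
        if str(cl) in diploid_clusters:
            continue
        i = matrix.barcodes.get_loc(bc)
        cn = matrix.cn[i]
        ok = ~matrix.mask[i]
        has_odd = False
        for w in range(n_win):
            sel = (win_of == w) & ok
            if not sel.any():
                continue
            vals, counts = np.unique(cn[sel], return_counts=True)
            if vals[np.argmax(counts)] % 2 == 1:
                has_odd = True
                break
        if not has_odd:
            removed.add(bc)
            log_rows.append({"barcode": bc, "reason": "no-odd-region",
                             "cluster": str(cl)})
    return removed, pd.DataFrame(log_rows)


def remove_doublets_and_artifacts(matrix: CellCNMatrix,
                                  agg: AggregatedCNMatrix,
                                  labels: pd.Series,
                                  profiles: Dict[str, CloneProfile],
                                  kinds: Dict[str, str],
                                  threshold: float = 0.35,
                                  exempt_diploid: bool = True
                                  ) -> Tuple[Set[str], pd.DataFrame]:
    """Full stage: doublet matching plus the odd-region artifact filter."""
    dps = build_doublet_profiles(profiles, kinds)
    suspect = doublet_like_clusters(profiles, kinds, dps, threshold)
    singlets = {cl: pr for cl, pr in profiles.items() if cl not in suspect}
    removed_d, log_d = match_doublets(agg, dps, singlets, threshold)
    removed_o, log_o = odd_region_filter(matrix, labels, kinds,
                                         exempt_diploid=exempt_diploid)
    log = pd.concat([log_d, log_o], ignore_index=True)
    logger.info("removed %d doublets, %d no-odd-region artifacts",
                len(removed_d), len(removed_o - removed_d))
    return removed_d | removed_o, log
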