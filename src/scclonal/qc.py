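"""Cell- and call-level quality control for single-cell CN matrices.

Cells are dropped when their DIMAPD-style bin-to-bin variation score is
an upper-tail outlier of a Gaussian fitted to the per-cell score
distribution (p < alpha, default 0.1), or when the upstream ploidy
confidence is low. Individual calls are masked at quality < 15 and in
bins with mappability < 0.90.

The DIMAPD statistic here is the mean absolute difference between
consecutive unmasked bin calls, normalized by the cell's mean CN: a
scale-free member of the MAPD family. (The median variant is
uninformative on integer call matrices, where most consecutive
differences are exactly zero.)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CellCNMatrix

logger = logging.getLogger(__name__)


class UndefinedScoreError(ValueError):
    """Raised when a cell has fewer than 2 usable bins."""


@dataclass
class CellQCRecord:
    barcode: str
    dimapd: float
    ploidy_confident: bool = True
    mean_ploidy: float = float("nan")

    def __post_init__(self) -> None:
        if self.dimapd < 0:
            raise ValueError("dimapd must be >= 0")


def compute_dimapd(matrix: CellCNMatrix, barcode: str) -> float:
    """Bin-to-bin variation score of one cell.

    Mean |CN[i+1] - CN[i]| over consecutive unmasked same-chromosome bin
    pairs, divided by the cell's mean CN. Deterministic; 0 for a
    constant profile, 1.0 for 1,3,1,3,... (mean CN 2).
    """
    i = matrix.barcodes.get_loc(barcode)
    return float(_dimapd_rows(matrix, [i])[0])


def _dimapd_rows(matrix: CellCNMatrix, rows: Sequence[int]) -> np.ndarray:
    chrom = matrix.bins["chrom"].to_numpy()
    same_chrom = chrom[1:] == chrom[:-1]
    cn = matrix.cn[rows].astype(np.float32)
    unmasked = ~matrix.mask[rows]
    pair_ok = unmasked[:, 1:] & unmasked[:, :-1] & same_chrom[None, :]
    diffs = np.abs(np.diff(cn, axis=1))
    n_pairs = pair_ok.sum(axis=1)
    n_bins = unmasked.sum(axis=1)
    if (n_pairs < 1).any() or (n_bins < 2).any():
        raise UndefinedScoreError(
            "fewer than 2 consecutive unmasked bins; DIMAPD undefined")
    mean_cn = (cn * unmasked).sum(axis=1) / n_bins
    mean_diff = (diffs * pair_ok).sum(axis=1) / n_pairs
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(mean_cn > 0, mean_diff / np.maximum(mean_cn, 1e-12),
                         0.0)
    return score


def compute_qc_records(matrix: CellCNMatrix,
                       ploidy_confident: Sequence[bool] | None = None
                       ) -> List[CellQCRecord]:
    """DIMAPD + mean ploidy for every cell.

    ``ploidy_confident`` is an upstream per-cell metric; when absent all
    cells are treated as confident (with a logged warning).
    """
    if ploidy_confident is None:
        logger.warning("no ploidy-confidence column supplied; treating all "
                       "cells as confident")
        ploidy_confident = [True] * matrix.n_cells
    scores = _dimapd_rows(matrix, np.arange(matrix.n_cells))
    unmasked = ~matrix.mask
    mean_ploidy = ((matrix.cn * unmasked).sum(axis=1)
                   / np.maximum(unmasked.sum(axis=1), 1))
    return [CellQCRecord(bc, float(s), bool(p), float(mp))
            for bc, s, p, mp in zip(matrix.barcodes, scores,
                                    ploidy_confident, mean_ploidy)]


def flag_noisy_cells(qc: Iterable[CellQCRecord], alpha: float = 0.1,
                     robust: bool = False) -> Set[str]:
    """Barcodes failing the DIMAPD Gaussian tail test or ploidy confidence.

    A Gaussian is fitted to the DIMAPD scores of all cells; cells whose
    upper-tail p-value is below ``alpha`` are flagged, as are cells with
    ``ploidy_confident`` False regardless of score. The default moment
    (mean/sd) fit lets the noisy tail inflate the fitted scale, so that
    only gross outliers — replicating, degraded or otherwise noisy
    cells, typically many sigma out — are removed while the clean bulk
    is untouched. ``robust=True`` switches to a median / 1.4826*MAD fit.
    """
    qc = list(qc)
    if len(qc) < 10:
        raise ValueError("need >= 10 cells to fit the score distribution")
    scores = np.array([r.dimapd for r in qc])
    if robust:
        loc = float(np.median(scores))
        scale = 1.4826 * float(np.median(np.abs(scores - loc)))
    else:
        loc, scale = float(scores.mean()), float(scores.std(ddof=1))
    flagged = {r.barcode for r in qc if not r.ploidy_confident}
    if scale <= 0 or not np.isfinite(scale):
        logger.warning("degenerate DIMAPD distribution (zero variance); "
                       "no score-based flags")
        return flagged
    threshold = loc + stats.norm.ppf(1 - alpha) * scale
    logger.info("DIMAPD threshold %.4f (loc %.4f scale %.4f alpha %.2f)",
                threshold, loc, scale, alpha)
    p = stats.norm.sf(scores, loc=loc, scale=scale)
    flagged |= {r.barcode for r, pv in zip(qc, p) if pv < alpha}
    return flagged


def filter_calls(matrix: CellCNMatrix, min_quality: float = 15.0,
                 min_mappability: float = 0.90) -> CellCNMatrix:
    """Mask low-quality calls and low-mappability bins.

    Masks accumulate (a call already masked stays masked); CN values are
    never altered. Idempotent at fixed thresholds and monotone in both.
    """
    if min_quality < 0 or min_mappability < 0:
        raise ValueError("thresholds must be >= 0")
    out = matrix.copy()
    out.mask |= matrix.quality < min_quality
    low_bins = matrix.bins["mappability"].to_numpy() < min_mappability
    out.mask |= low_bins[None, :]
    return out


def assemble_clean_matrix(matrix: CellCNMatrix, flagged: Set[str]
                          ) -> tuple[CellCNMatrix, dict]:
    """Drop flagged barcodes; report bookkeeping counts."""
    keep = [b for b in matrix.barcodes if b not in flagged]
    if not keep:
        raise ValueError("all cells flagged; empty output matrix")
    clean = matrix.subset_cells(keep)
    report = {"cells_in": matrix.n_cells, "cells_out": clean.n_cells,
              "cells_flagged": matrix.n_cells - clean.n_cells,
              "calls_masked": int(clean.mask.sum())}
    logger.info("QC kept %d/%d cells; %d calls masked", clean.n_cells,
                matrix.n_cells, report["calls_masked"])
    return clean, report


def run_qc(matrix: CellCNMatrix,
           ploidy_confident: Sequence[bool] | None = None,
           alpha: float = 0.1, min_quality: float = 15.0,
           min_mappability: float = 0.90
           ) -> tuple[CellCNMatrix, Set[str], dict]:
    """Full QC stage: call filtering, noisy-cell flagging, assembly."""
    filtered = filter_calls(matrix, min_quality, min_mappability)
    records = compute_qc_records(filtered, ploidy_confident)
    flagged = flag_noisy_cells(records, alpha=alpha)
    clean, report = assemble_clean_matrix(filtered, flagged)
    report["alpha"] = alpha
    report["min_quality"] = min_quality
    report["min_mappability"] = min_mappability
    return clean, flagged, report
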