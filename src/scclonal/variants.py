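"""Cluster-level somatic-variant summaries and pseudo-diploid detection.

Variant support is summarised per cluster as pseudobulk VAF (alt and
ref reads summed over the cluster's cells) and per cell as a
three-state genotype (mutant / wildtype-covered / no-coverage) that is
honest about droplet-scale sparsity. Pseudo-diploid cells — near
diploid cells in the diploid cluster carrying sparse low-level gains at
sites also altered in a malignant clone — are detected by correlating
each cell's CN deviation vector with the clone deviation profiles.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import AggregatedCNMatrix, CloneProfile


def pseudobulk_vaf(alt: np.ndarray, depth: np.ndarray, barcodes: pd.Index,
                   cluster_cells: Sequence[str], variant_idx: int
                   ) -> Tuple[float, int]:
    """Cluster pseudobulk VAF and total depth at one variant site.

    Sums alt and total reads over the cluster's cells; zero depth gives
    VAF NaN (missing, not 0). The pooled VAF equals the read-weighted
    mean of per-cell VAFs.
    """
    idx = barcodes.get_indexer(pd.Index(cluster_cells))
    if len(idx) == 0 or (idx < 0).any():
        raise ValueError("cluster empty or contains unknown barcodes")
    a = int(alt[idx, variant_idx].sum())
    d = int(depth[idx, variant_idx].sum())
    return (a / d if d > 0 else float("nan")), d


def cluster_vaf_table(variants: pd.DataFrame, alt: np.ndarray,
                      depth: np.ndarray, barcodes: pd.Index,
                      clusters: Dict[str, Sequence[str]]) -> pd.DataFrame:
    """Pseudobulk VAF of every variant in every cluster."""
    rows = []
    for j, (_, var) in enumerate(variants.iterrows()):
        for cl, cells in clusters.items():
            vaf, d = pseudobulk_vaf(alt, depth, barcodes, cells, j)
            rows.append({"variant_id": var["variant_id"], "cluster": cl,
                         "vaf": vaf, "depth": d,
                         "alt_reads": int(round(vaf * d)) if d else 0})
    return pd.DataFrame(rows)


def per_cell_genotype(alt: np.ndarray, depth: np.ndarray,
                      variant_idx: int, min_alt: int = 2) -> np.ndarray:
    """Per-cell genotype status at one site.

    ``mutant`` with alt >= min_alt; ``wildtype-covered`` with
    alt < min_alt but total >= min_alt; otherwise ``no-coverage``
    (droplet coverage is too sparse to call either way).
    """
    a = alt[:, variant_idx]
    d = depth[:, variant_idx]
    out = np.where(a >= min_alt, "mutant",
                   np.where(d >= min_alt, "wildtype-covered",
                            "no-coverage"))
    return out


# ---------------------------------------------------------------------------
# pseudo-diploid detection


def pseudo_diploid_score(cell_values: np.ndarray,
                         clone_profiles: Dict[str, CloneProfile],
                         deviation_cutoff: float = 0.5) -> dict:
    """Concordance of a near-diploid cell's CN deviations with each clone.

    The deviation vector is (rounded coarse CN - 2). The score against
    each clone is the Pearson correlation of deviation vectors; the
    overlap fraction is the share of the cell's gained bins lying in
    clone-gained bins. Cells with no deviating bins score NaN.
    """
    dev = np.round(cell_values) - 2.0
    dev = np.where(np.isfinite(cell_values), dev, 0.0)
    n_aberrant = int((np.abs(dev) >= deviation_cutoff).sum())
    out = {"n_aberrant_bins": n_aberrant, "scores": {}, "overlap": {}}
    cell_gained = np.flatnonzero(dev >= deviation_cutoff)
    for cl, pr in clone_profiles.items():
        clone_dev = pr.rounded - 2.0
        if n_aberrant == 0 or np.allclose(clone_dev, 0):
            out["scores"][cl] = float("nan")
            out["overlap"][cl] = float("nan")
            continue
        sd_c, sd_p = dev.std(), clone_dev.std()
        if sd_c == 0 or sd_p == 0:
            out["scores"][cl] = float("nan")
        else:
            out["scores"][cl] = float(np.corrcoef(dev, clone_dev)[0, 1])
        clone_gained = set(np.flatnonzero(clone_dev > 0))
        out["overlap"][cl] = (
            float(np.mean([g in clone_gained for g in cell_gained]))
            if len(cell_gained) else float("nan"))
    return out


def pseudo_diploid_reports(agg: AggregatedCNMatrix,
                           diploid_cells: Sequence[str],
                           clone_profiles: Dict[str, CloneProfile]
                           ) -> pd.DataFrame:
    """Score every diploid-cluster cell against every clone profile."""
    idx = agg.barcodes.get_indexer(pd.Index(diploid_cells))
    if (idx < 0).any():
        raise ValueError("unknown barcodes among diploid cells")
    rows = []
    for bc, i in zip(diploid_cells, idx):
        res = pseudo_diploid_score(agg.values[i], clone_profiles)
        scores = res["scores"]
        valid = {c: s for c, s in scores.items() if np.isfinite(s)}
        best = max(valid, key=valid.get) if valid else ""
        rows.append({"barcode": bc,
                     "n_aberrant_bins": res["n_aberrant_bins"],
                     "best_clone": best,
                     "score": valid.get(best, float("nan")),
                     "overlap_fraction": res["overlap"].get(
                         best, float("nan")) if best else float("nan")})
    return pd.DataFrame(rows).set_index("barcode")


def classify_pseudo_diploid(reports: pd.DataFrame, threshold: float = 0.15,
                            min_aberrant_bins: int = 3) -> set:
    """Barcodes classified pseudo-diploid.

    Positive when the best clone-concordance score exceeds ``threshold``
    and at least ``min_aberrant_bins`` coarse bins deviate from CN 2.
    Cells with undefined scores are negative. Order-invariant.
    """
    ok = (reports["score"].fillna(-np.inf) > threshold) \
        & (reports["n_aberrant_bins"] >= min_aberrant_bins)
    return set(reports.index[ok])
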