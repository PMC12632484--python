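"""Maximum-likelihood clustering of aggregated CN profiles.

Cells are aggregated to mean ploidy in 10 Mb windows (500 consecutive
20 kb bins), then clustered with centroid (k-means) partitions for every
k up to ``k_max``. Each solution is scored with a spherical-Gaussian
log-likelihood evaluated at a fixed, data-wide variance scale (the k=1
residual variance); AIC selects k, with BIC reported alongside. Fixing
the variance scale makes the information criteria compare how much of
the total variance each partition explains, which gives a sharp elbow
at the number of well-separated CN profiles and is insensitive to the
(tiny) within-clone call noise; under this scoring BIC's heavier
penalty leaves rare subpopulations unsplit (underclustering) while AIC
resolves them.

A second round of the same procedure inside each cluster yields dotted
``cluster.subcluster`` labels. DAPC (PCA followed by LDA on cluster
labels), within-cluster pairwise distances and the per-bin mean-vs-sd
regression quantify cluster relationships and intra-cluster diversity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .containers import (AggregatedCNMatrix, CellCNMatrix, CloneProfile,
                         ClusterAssignment)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# aggregation


def aggregate_bins(matrix: CellCNMatrix, bins_per_window: int = 500
                   ) -> AggregatedCNMatrix:
    """Mean ploidy over windows of consecutive same-chromosome fine bins.

    Masked calls are excluded from the window mean; a window whose calls
    are all masked is NaN. 500 bins of 20 kb span 10 Mb.
    """
    if bins_per_window < 1:
        raise ValueError("bins_per_window must be >= 1")
    bins = matrix.bins
    chroms = bins["chrom"].to_numpy()
    # window id: consecutive runs within each chromosome
    window_id = np.empty(len(bins), dtype=int)
    wid = 0
    rows = []
    i = 0
    while i < len(bins):
        chrom = chroms[i]
        j = i
        while j < len(bins) and chroms[j] == chrom and j - i < bins_per_window:
            j += 1
        window_id[i:j] = wid
        rows.append((chrom, int(bins["start"].iloc[i]),
                     int(bins["end"].iloc[j - 1])))
        wid += 1
        i = j
    coarse = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    cn = matrix.cn.astype(np.float64)
    ok = (~matrix.mask).astype(np.float64)
    n_win = wid
    sums = np.zeros((matrix.n_cells, n_win))
    cnts = np.zeros((matrix.n_cells, n_win))
    # column-block accumulation (windows are contiguous column ranges)
    starts = np.flatnonzero(np.r_[True, window_id[1:] != window_id[:-1]])
    ends = np.r_[starts[1:], len(window_id)]
    for w, (s, e) in enumerate(zip(starts, ends)):
        sums[:, w] = (cn[:, s:e] * ok[:, s:e]).sum(axis=1)
        cnts[:, w] = ok[:, s:e].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return AggregatedCNMatrix(matrix.barcodes, coarse, values)


def _dense(agg: AggregatedCNMatrix) -> np.ndarray:
    """Aggregated values with missing windows imputed to the column mean."""
    x = agg.values.copy()
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 2.0)
    nan_r, nan_c = np.nonzero(~np.isfinite(x))
    x[nan_r, nan_c] = col_mean[nan_c]
    return x


# ---------------------------------------------------------------------------
# ML clustering with AIC/BIC model selection


@dataclass
class ClusterScores:
    """Per-k model scores and labels from :func:`ml_cluster`."""

    scores: pd.DataFrame               # k, aic, bic, loglik, rss
    labels: Dict[int, np.ndarray]      # k -> label vector
    n_pcs: int
    sigma2: float


def ml_cluster(agg: AggregatedCNMatrix, k_max: int = 20, seed: int = 0,
               n_restarts: int = 10, n_pcs: Optional[int] = None
               ) -> ClusterScores:
    """Centroid clustering for k = 1..k_max with likelihood scoring.

    The data are centered and projected onto principal components
    (all components by default; ``n_pcs`` may truncate). For each k the
    best of ``n_restarts`` k-means runs is kept and scored with the
    spherical-Gaussian log-likelihood at the fixed k=1 variance scale;
    AIC = -2 lnL + 2p and BIC = -2 lnL + p ln n with p = k*d + 1.
    """
    x = _dense(agg)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need >= 2 cells to cluster")
    k_max = min(k_max, n)
    d_max = min(n - 1, x.shape[1])
    if n_pcs is not None:
        d_max = min(d_max, n_pcs)
    pca = PCA(n_components=d_max, random_state=seed)
    z = pca.fit_transform(x)
    n, d = z.shape

    # fixed data-wide variance scale from the k=1 model
    rss1 = float(((z - z.mean(axis=0)) ** 2).sum())
    sigma2 = max(rss1 / (n * d), 1e-12)

    rows = []
    labels: Dict[int, np.ndarray] = {}
    for k in range(1, k_max + 1):
        if k == 1:
            lab = np.zeros(n, dtype=int)
            rss = rss1
        else:
            km = KMeans(n_clusters=k, n_init=n_restarts,
                        random_state=seed + k).fit(z)
            lab = km.labels_
            rss = float(km.inertia_)
        loglik = -0.5 * (rss / sigma2 + n * d * np.log(2 * np.pi * sigma2))
        p = k * d + 1
        rows.append({"k": k, "aic": -2 * loglik + 2 * p,
                     "bic": -2 * loglik + p * np.log(n),
                     "loglik": loglik, "rss": rss})
        labels[k] = lab
    return ClusterScores(pd.DataFrame(rows), labels, d, sigma2)


def select_k(scores: pd.DataFrame, criterion: str = "aic") -> int:
    """Arg-min of the information criterion; ties broken toward smaller k."""
    s = scores.dropna(subset=[criterion]).sort_values("k")
    if s.empty:
        raise ValueError("no finite scores")
    best = s.loc[s[criterion].idxmin(), "k"]  # idxmin returns first minimum
    logger.info("selected k=%d by %s", int(best), criterion)
    return int(best)


def _relabel_by_ploidy(agg_values: np.ndarray, labels: np.ndarray
                       ) -> np.ndarray:
    """Renumber clusters 1..k by ascending mean ploidy (diploid first)."""
    ids = np.unique(labels)
    ploidy = [np.nanmean(agg_values[labels == i]) for i in ids]
    order = ids[np.argsort(ploidy)]
    mapping = {old: new + 1 for new, old in enumerate(order)}
    return np.array([mapping[l] for l in labels])


def cluster_cells(agg: AggregatedCNMatrix, k_max: int = 20, seed: int = 0,
                  n_restarts: int = 10, n_pcs: Optional[int] = None
                  ) -> Tuple[pd.Series, ClusterScores]:
    """One clustering round: fit, select k by AIC, relabel by ploidy."""
    cs = ml_cluster(agg, k_max=k_max, seed=seed, n_restarts=n_restarts,
                    n_pcs=n_pcs)
    k = select_k(cs.scores)
    labels = _relabel_by_ploidy(agg.values, cs.labels[k])
    return pd.Series(labels, index=agg.barcodes, name="cluster"), cs


def subcluster(agg: AggregatedCNMatrix, clusters: pd.Series,
               k_max: int = 20, seed: int = 0, n_restarts: int = 10,
               min_size: int = 5, n_pcs: Optional[int] = None
               ) -> ClusterAssignment:
    """Second clustering round within each cluster; dotted labels."""
    labels = pd.DataFrame(index=agg.barcodes)
    labels["cluster"] = clusters.astype(int)
    labels["subcluster"] = 1
    all_scores = []
    for cl in sorted(clusters.unique()):
        cells = clusters.index[clusters == cl]
        if len(cells) < max(min_size, 2):
            continue
        sub_agg = agg.subset_cells(cells)
        sub_k_max = min(k_max, len(cells))
        cs = ml_cluster(sub_agg, k_max=sub_k_max, seed=seed,
                        n_restarts=n_restarts, n_pcs=n_pcs)
        k = select_k(cs.scores)
        sub = _relabel_by_ploidy(sub_agg.values, cs.labels[k])
        labels.loc[cells, "subcluster"] = sub
        sc = cs.scores.copy()
        sc.insert(0, "level", f"cluster_{cl}")
        all_scores.append(sc)
    scores = (pd.concat(all_scores, ignore_index=True) if all_scores
              else pd.DataFrame(columns=["level", "k", "aic", "bic"]))
    return ClusterAssignment(labels, scores)


# ---------------------------------------------------------------------------
# cluster profiles and classification


def clone_profiles(agg: AggregatedCNMatrix, labels: pd.Series
                   ) -> Dict[str, CloneProfile]:
    """Representative coarse-bin CN per cluster (mean, rounded, sd)."""
    out = {}
    for cl in sorted(labels.unique()):
        cells = labels.index[labels == cl]
        idx = agg.barcodes.get_indexer(cells)
        vals = agg.values[idx]
        mean = np.nanmean(vals, axis=0)
        sd = np.nanstd(vals, axis=0)
        out[str(cl)] = CloneProfile(str(cl), mean, np.round(mean), sd,
                                    len(cells))
    return out


def classify_clusters(profiles: Dict[str, CloneProfile],
                      diploid_min_frac: float = 0.9,
                      wgd_cosine: float = 0.9) -> Dict[str, str]:
    """Label clusters diploid / wgd / tumor_baseline.

    diploid: modal rounded CN 2 over >= 90% of bins. WGD: mean ploidy
    about twice another cluster's and matching CN deviations after
    doubling (cosine similarity of profile-minus-flat deviations >= 0.9).
    Everything else is a tumor baseline.
    """
    kinds = {}
    for cl, pr in profiles.items():
        frac2 = float(np.mean(pr.rounded == 2))
        kinds[cl] = "diploid" if frac2 >= diploid_min_frac else None
    for cl, pr in profiles.items():
        if kinds[cl] is not None:
            continue
        for other, opr in profiles.items():
            if other == cl:
                continue
            ratio = np.nanmean(pr.mean) / max(np.nanmean(opr.mean), 1e-9)
            if not 1.7 <= ratio <= 2.3:
                continue
            dev_w = pr.mean - np.nanmean(pr.mean)
            dev_2c = 2 * opr.mean - np.nanmean(2 * opr.mean)
            na, nb = np.linalg.norm(dev_w), np.linalg.norm(dev_2c)
            if na < 1e-9 and nb < 1e-9:
                cos = 1.0          # two flat profiles; doubled-flat case
            elif na < 1e-9 or nb < 1e-9:
                cos = 0.0
            else:
                cos = float(dev_w @ dev_2c / (na * nb))
            if cos >= wgd_cosine:
                kinds[cl] = f"wgd_of_{other}"
                break
    for cl in kinds:
        if kinds[cl] is None:
            kinds[cl] = "tumor_baseline"
    return kinds


# ---------------------------------------------------------------------------
# diversity statistics


def dapc(agg: AggregatedCNMatrix, labels: pd.Series, n_pcs: int = 10,
         n_df: int = 2) -> Tuple[pd.DataFrame, np.ndarray]:
    """Discriminant analysis of principal components.

    PCA projection followed by LDA on cluster labels; returns the first
    ``n_df`` discriminant coordinates per cell and the loadings (PC
    space -> DF space).
    """
    if labels.nunique() < 2:
        raise ValueError("DAPC requires >= 2 clusters")
    x = _dense(agg)
    idx = agg.barcodes.get_indexer(labels.index)
    x = x[idx]
    n_pcs = min(n_pcs, x.shape[0] - 1, x.shape[1])
    z = PCA(n_components=n_pcs, random_state=0).fit_transform(x)
    n_df = min(n_df, labels.nunique() - 1)
    lda = LinearDiscriminantAnalysis(n_components=n_df)
    coords = lda.fit_transform(z, labels.to_numpy())
    df = pd.DataFrame(coords, index=labels.index,
                      columns=[f"DF{i + 1}" for i in range(coords.shape[1])])
    return df, lda.scalings_[:, :n_df]


def intra_cluster_distances(agg: AggregatedCNMatrix, labels: pd.Series
                            ) -> Dict[str, np.ndarray]:
    """All unique within-cluster pairwise Euclidean distances.

    Computed on coarse-bin mean-ploidy vectors; windows missing in
    either member of a pair are excluded pairwise (with rescaling to
    the shared-window count so distances stay comparable).
    """
    out = {}
    for cl in sorted(labels.unique()):
        cells = labels.index[labels == cl]
        if len(cells) < 2:
            continue
        idx = agg.barcodes.get_indexer(cells)
        vals = agg.values[idx]
        if np.isfinite(vals).all():
            out[str(cl)] = pdist(vals)
            continue
        m = len(cells)
        dists = []
        for i in range(m):
            for j in range(i + 1, m):
                ok = np.isfinite(vals[i]) & np.isfinite(vals[j])
                if not ok.any():
                    continue
                d2 = ((vals[i, ok] - vals[j, ok]) ** 2).sum()
                dists.append(np.sqrt(d2 * vals.shape[1] / ok.sum()))
        out[str(cl)] = np.array(dists)
    return out


def mean_sd_regression(agg: AggregatedCNMatrix, labels: pd.Series,
                       cluster) -> dict:
    """OLS of per-bin within-cluster sd on per-bin mean copy number."""
    cells = labels.index[labels.astype(str) == str(cluster)]
    if len(cells) < 3:
        raise ValueError("cluster must have >= 3 cells")
    idx = agg.barcodes.get_indexer(cells)
    vals = agg.values[idx]
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=1)
    ok = np.isfinite(mean) & np.isfinite(sd)
    if ok.sum() < 3:
        raise ValueError("need >= 3 usable bins")
    xm = sm.add_constant(mean[ok])
    fit = sm.OLS(sd[ok], xm).fit()
    ci = fit.conf_int()
    return {"slope": float(fit.params[1]), "intercept": float(fit.params[0]),
            "slope_ci": (float(ci[1][0]), float(ci[1][1])),
            "slope_p": float(fit.pvalues[1]), "r2": float(fit.rsquared),
            "n_bins": int(ok.sum())}
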