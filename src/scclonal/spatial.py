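"""Expression-inferred CN from spatial transcriptomics and clone matching.

Spots are split into tumor and reference by a purity score built from
stromal and immune signature enrichment (single-sample, rank-based).
Tumor-spot expression relative to the reference baseline is smoothed
along the genome, partitioned into subgroups by Leiden community
detection, and decoded with a 3-state (loss / neutral / gain)
Gaussian-emission HMM. Subgroup profiles are matched to scDNA clone
profiles by correlation over 10 Mb bins; positional gene-set enrichment
assigns spots to clones where transcript counts are too sparse for CN
inference. ssGSEA-style scores and Seurat-style cell-cycle phase calls
support program-level comparisons between clone territories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy import stats

from .containers import CloneProfile, STCNProfile, STSpotMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization


def normalize_counts(st: STSpotMatrix, target: float = 10_000.0
                     ) -> Tuple[np.ndarray, pd.Index]:
    """Library-size scaling to a fixed depth target followed by log1p.

    The fixed target (counts-per-10k convention) makes the output
    invariant to any global rescaling of raw counts: two spots with
    proportional counts normalize identically. Deterministic;
    zero-depth spots are dropped with a warning. Returns (normalized
    matrix, retained spot index).
    """
    depth = st.counts.sum(axis=1).astype(float)
    keep = depth > 0
    if not keep.all():
        logger.warning("dropping %d zero-depth spots", int((~keep).sum()))
    if not keep.any():
        raise ValueError("no spots with nonzero depth")
    counts = st.counts[keep].astype(float)
    depth = depth[keep]
    scaled = counts * (target / depth)[:, None]
    return np.log1p(scaled), st.spots.index[keep]


# ---------------------------------------------------------------------------
# single-sample enrichment


def ssgsea_score(expression: np.ndarray, in_set: np.ndarray,
                 weight: float = 0.25) -> np.ndarray:
    """Single-sample enrichment score(s) of one gene set.

    ``expression``: (n_spots, n_genes) or (n_genes,); ``in_set``:
    boolean mask over genes. Genes are ranked by expression per spot;
    the score is the integrated difference between the weighted in-set
    ECDF and the uniform out-set ECDF, scaled by the gene count so it
    lies in (-1, 1). With weight 0 the statistic is rank-symmetric:
    reversing the ranking negates it.
    """
    x = np.atleast_2d(np.asarray(expression, dtype=float))
    n_spots, n_genes = x.shape
    m = int(in_set.sum())
    if m == 0 or m == n_genes:
        raise ValueError("gene set is empty (or all genes) on this panel")
    order = np.argsort(-x, axis=1, kind="stable")
    in_sorted = in_set[order]                     # (n_spots, n_genes)
    if weight == 0:
        w = np.ones_like(x)
    else:
        w = np.abs(np.take_along_axis(x, order, axis=1)) ** weight
    w_in = np.where(in_sorted, w, 0.0)
    denom = w_in.sum(axis=1, keepdims=True)
    denom[denom == 0] = 1.0
    p_in = np.cumsum(w_in, axis=1) / denom
    p_out = np.cumsum(~in_sorted, axis=1) / float(n_genes - m)
    es = (p_in - p_out).sum(axis=1) / n_genes
    return es if expression.ndim > 1 else float(es[0])


def _set_mask(genes: pd.Index, gene_set: Sequence[str]) -> np.ndarray:
    mask = genes.isin(gene_set)
    missing = [g for g in gene_set if g not in genes]
    if not mask.any():
        raise ValueError(f"no gene-set members on panel; missing {missing[:5]}")
    return mask


# ---------------------------------------------------------------------------
# purity


def purity_score(norm: np.ndarray, genes: pd.Index,
                 stromal_signature: Sequence[str],
                 immune_signature: Sequence[str],
                 threshold: float = 0.7, steepness: float = 15.0,
                 center: float = 0.15) -> pd.DataFrame:
    """Tumor-purity score per spot and the tumor/reference split.

    The stromal and immune single-sample enrichment scores are averaged
    and mapped monotonically to [0, 1] (1 = pure tumor) by a logistic
    in the combined score; the map's steepness is calibrated on
    synthetic mixtures so that pure stromal spots fall below and pure
    tumor spots above the 0.7 protocol cut. Spots exactly at the
    threshold are assigned to the reference side. Rank-based scores
    make the ordering invariant to monotone renormalization.
    """
    if len(stromal_signature) == 0 or len(immune_signature) == 0:
        raise ValueError("signatures must be nonempty")
    s_mask = _set_mask(genes, stromal_signature)
    i_mask = _set_mask(genes, immune_signature)
    # weight 0: purely rank-based, hence invariant under any monotone
    # renormalization of expression
    s = ssgsea_score(norm, s_mask, weight=0.0)
    i = ssgsea_score(norm, i_mask, weight=0.0)
    combined = (np.asarray(s) + np.asarray(i)) / 2.0
    # logistic calibrated on synthetic mixtures: pure-tumor spots score
    # well below `center`, stroma-dominated spots well above it
    purity = 1.0 / (1.0 + np.exp(steepness * (combined - center)))
    return pd.DataFrame({"stromal_score": s, "immune_score": i,
                         "purity": purity,
                         "is_tumor": purity > threshold})


# ---------------------------------------------------------------------------
# relative expression, smoothing, HMM


def _genome_order(genes: pd.DataFrame) -> np.ndarray:
    return np.lexsort((genes["start"].to_numpy(),
                       genes["chrom"].to_numpy()))


def smooth_profiles(rel: np.ndarray, chroms: np.ndarray, window: int
                    ) -> np.ndarray:
    """Centered moving average along the gene order, per chromosome."""
    out = np.empty_like(rel)
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        w = min(window, len(cols))
        out[:, cols] = uniform_filter1d(rel[:, cols], size=max(w, 1),
                                        axis=1, mode="nearest")
    return out


def viterbi_decode(obs: np.ndarray, means: np.ndarray, var: float,
                   stay_prob: float) -> np.ndarray:
    """Most probable state path of a Gaussian-emission chain.

    Uniform initial distribution; off-diagonal transitions share
    (1 - stay_prob) equally. Returns state indices.
    """
    n_states = len(means)
    n = len(obs)
    log_emit = (-0.5 * (obs[:, None] - means[None, :]) ** 2 / var
                - 0.5 * np.log(2 * np.pi * var))
    log_trans = np.full((n_states, n_states),
                        np.log((1 - stay_prob) / (n_states - 1)))
    np.fill_diagonal(log_trans, np.log(stay_prob))
    delta = np.full((n, n_states), -np.inf)
    psi = np.zeros((n, n_states), dtype=int)
    delta[0] = -np.log(n_states) + log_emit[0]
    for t in range(1, n):
        cand = delta[t - 1][:, None] + log_trans
        psi[t] = np.argmax(cand, axis=0)
        delta[t] = cand[psi[t], np.arange(n_states)] + log_emit[t]
    states = np.empty(n, dtype=int)
    states[-1] = int(np.argmax(delta[-1]))
    for t in range(n - 2, -1, -1):
        states[t] = psi[t + 1, states[t + 1]]
    return states


@dataclass
class STInference:
    """Output of :func:`infer_cn_profiles`."""

    profiles: List[STCNProfile]
    spot_subgroup: pd.Series            # tumor spot -> subgroup label
    gene_order: pd.Index                # genome-ordered gene ids
    gene_table: pd.DataFrame            # chrom, start (genome-ordered)
    smoothed: np.ndarray                # (n_tumor_spots, n_genes)


def infer_cn_profiles(norm: np.ndarray, spots: pd.Index,
                      genes: pd.DataFrame, tumor_spots: Sequence[str],
                      reference_spots: Sequence[str],
                      window: int = 101, resolution: float = 0.5,
                      n_neighbors: int = 15, state_shift: float = 0.2,
                      stay_prob: float = 1 - 1e-4, seed: int = 0
                      ) -> STInference:
    """Infer loss/neutral/gain profiles for tumor-spot subgroups.

    Relative expression = normalized value minus the reference-spot
    mean per gene, clipped at 3 reference sd; a centered moving average
    over ``window`` genes (per chromosome, genome order) smooths it.
    Tumor spots are partitioned by Leiden community detection on a kNN
    graph of smoothed profiles, and each subgroup's mean profile is
    decoded chromosome-by-chromosome with a 3-state Gaussian HMM whose
    state means sit at -shift/0/+shift and whose variance comes from
    the reference spots' smoothed profiles.
    """
    if len(tumor_spots) == 0 or len(reference_spots) == 0:
        raise ValueError("tumor and reference spot sets must be nonempty")
    if len(reference_spots) < 10:
        logger.warning("reference set has %d (<10) spots; baseline noisy",
                       len(reference_spots))
    order = _genome_order(genes)
    gene_order = genes.index[order]
    chroms = genes["chrom"].to_numpy()[order]

    spot_pos = {b: k for k, b in enumerate(spots)}
    t_idx = np.array([spot_pos[b] for b in tumor_spots])
    r_idx = np.array([spot_pos[b] for b in reference_spots])
    x = norm[:, order]
    ref_mean = x[r_idx].mean(axis=0)
    ref_sd = x[r_idx].std(axis=0)
    rel = x - ref_mean[None, :]
    lim = 3.0 * np.maximum(ref_sd, 1e-6)
    rel = np.clip(rel, -lim[None, :], lim[None, :])

    smooth_all = smooth_profiles(rel, chroms, window)
    # re-subtract the reference baseline after smoothing (cancels
    # gene-level noise skew), then median-center each smoothed profile
    # (cancels compositional/library offsets; the median window is
    # copy-neutral in mostly-unaltered genomes)
    smooth_all = smooth_all - smooth_all[r_idx].mean(axis=0)[None, :]
    smooth_all = smooth_all - np.median(smooth_all, axis=1, keepdims=True)
    smooth_t = smooth_all[t_idx]
    smooth_r = smooth_all[r_idx]
    hmm_var = max(float(smooth_r.var()), 1e-6)

    sub = _leiden_subgroups(smooth_t, n_neighbors, resolution, seed)
    spot_subgroup = pd.Series(sub, index=pd.Index(tumor_spots),
                              name="subgroup")

    means = np.array([-state_shift, 0.0, state_shift])
    profiles = []
    for g in sorted(set(sub)):
        members = spot_subgroup.index[spot_subgroup == g]
        prof = smooth_t[np.asarray(spot_subgroup == g)].mean(axis=0)
        states = np.empty(len(prof), dtype=int)
        for chrom in pd.unique(chroms):
            cols = np.flatnonzero(chroms == chrom)
            states[cols] = viterbi_decode(prof[cols], means, hmm_var,
                                          stay_prob)
        profiles.append(STCNProfile(str(g), gene_order, prof,
                                    states - 1, members))
    gene_table = genes.iloc[order][["chrom", "start"]]
    return STInference(profiles, spot_subgroup, gene_order, gene_table,
                       smooth_t)


def _leiden_subgroups(x: np.ndarray, n_neighbors: int, resolution: float,
                      seed: int) -> np.ndarray:
    """Leiden community labels on a kNN graph of profile vectors."""
    import anndata as ad
    import scanpy as sc
    adata = ad.AnnData(x.astype(np.float32))
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, x.shape[0] - 1),
                    use_rep="X", random_state=seed)
    sc.tl.leiden(adata, resolution=resolution, key_added="leiden",
                 random_state=seed, flavor="igraph", n_iterations=2,
                 directed=False)
    return adata.obs["leiden"].to_numpy().astype(str)


# ---------------------------------------------------------------------------
# matching to scDNA clones


def aggregate_to_bins(values: np.ndarray, gene_table: pd.DataFrame,
                      coarse_bins: pd.DataFrame) -> np.ndarray:
    """Mean of per-gene values within each coarse genomic bin (NaN when
    a bin has no genes)."""
    chroms = gene_table["chrom"].to_numpy()
    starts = gene_table["start"].to_numpy()
    out = np.full(len(coarse_bins), np.nan)
    for j, row in coarse_bins.iterrows():
        sel = (chroms == row["chrom"]) & (starts >= row["start"]) \
            & (starts < row["end"])
        if sel.any():
            out[j] = values[sel].mean()
    return out


def match_st_to_scdna(inference: STInference,
                      clone_profiles: Dict[str, CloneProfile],
                      coarse_bins: pd.DataFrame, margin: float = 0.1
                      ) -> pd.DataFrame:
    """Correlate each ST subgroup's profile with scDNA clone profiles.

    Subgroup smoothed profiles are aggregated to 10 Mb bins and
    Pearson-correlated with each clone's CN deviation profile
    (mean - 2). The best clone is assigned when its correlation exceeds
    the runner-up by ``margin``, else the subgroup is ``ambiguous``.
    """
    rows = []
    for prof in inference.profiles:
        binned = aggregate_to_bins(prof.smoothed, inference.gene_table,
                                   coarse_bins)
        ok = np.isfinite(binned)
        if not ok.any():
            raise ValueError("no overlapping bins between ST genes and "
                             "CN bins")
        cors = {}
        for cl, cp in clone_profiles.items():
            dev = cp.mean - 2.0
            if np.std(dev[ok]) < 1e-12 or np.std(binned[ok]) < 1e-12:
                cors[cl] = float("nan")
            else:
                cors[cl] = float(np.corrcoef(binned[ok], dev[ok])[0, 1])
        ranked = sorted((v, k) for k, v in cors.items()
                        if np.isfinite(v))[::-1]
        if not ranked:
            assigned = "ambiguous"
        elif len(ranked) == 1 or ranked[0][0] - ranked[1][0] > margin:
            assigned = ranked[0][1]
        else:
            assigned = "ambiguous"
        row = {"subgroup": prof.subgroup, "assigned": assigned,
               "n_spots": len(prof.spots)}
        row.update({f"cor_{k}": v for k, v in cors.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# positional gene-set enrichment


def positional_gene_sets(genes: pd.DataFrame,
                         clone_regions: Dict[str, pd.DataFrame],
                         min_genes: int = 10) -> Dict[str, list]:
    """Gene sets from clone-private gained regions (chrom, start, end)."""
    out = {}
    chroms = genes["chrom"].to_numpy()
    starts = genes["start"].to_numpy()
    for clone, regions in clone_regions.items():
        members: list = []
        for _, r in regions.iterrows():
            sel = (chroms == r["chrom"]) & (starts >= r["start"]) \
                & (starts < r["end"])
            members.extend(genes.index[sel])
        if len(members) < min_genes:
            logger.warning("clone %s positional set has %d (<%d) genes; "
                           "excluded", clone, len(members), min_genes)
            continue
        out[clone] = sorted(set(members))
    return out


def positional_enrichment(norm: np.ndarray, spots: pd.Index,
                          genes: pd.Index, gene_sets: Dict[str, list],
                          n_permutations: int = 200, alpha: float = 0.05,
                          seed: int = 0, weight: float = 0.25
                          ) -> pd.DataFrame:
    """Assign spots to clones by positional single-sample enrichment.

    For two clone gene sets the per-spot score difference is tested
    against a permutation null (random same-size sets, normal
    approximation), two-sided, Bonferroni-adjusted across spots; spots
    that are not significant stay unassigned. Swapping the two sets
    swaps the assignments exactly.
    """
    if len(gene_sets) != 2:
        raise ValueError("positional assignment expects exactly 2 sets")
    (name_a, set_a), (name_b, set_b) = sorted(gene_sets.items())
    mask_a = _set_mask(genes, set_a)
    mask_b = _set_mask(genes, set_b)
    diff = ssgsea_score(norm, mask_a, weight) \
        - ssgsea_score(norm, mask_b, weight)

    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, norm.shape[0]))
    for p in range(n_permutations):
        ra = np.zeros(len(genes), dtype=bool)
        ra[rng.choice(len(genes), mask_a.sum(), replace=False)] = True
        rb = np.zeros(len(genes), dtype=bool)
        rb[rng.choice(len(genes), mask_b.sum(), replace=False)] = True
        null[p] = ssgsea_score(norm, ra, weight) \
            - ssgsea_score(norm, rb, weight)
    mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
    z = (diff - mu) / np.maximum(sd, 1e-12)
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = np.minimum(p_raw * len(p_raw), 1.0)
    assigned = np.where(p_adj < alpha,
                        np.where(diff > 0, name_a, name_b), "unassigned")
    return pd.DataFrame({"score_diff": diff, "z": z, "p": p_raw,
                         "p_bonferroni": p_adj, "assigned": assigned},
                        index=spots)


# ---------------------------------------------------------------------------
# cell cycle


def cell_cycle_score(norm: np.ndarray, spots: pd.Index, genes: pd.Index,
                     s_genes: Sequence[str], g2m_genes: Sequence[str],
                     n_bins: int = 24, n_ctrl: int = 50, seed: int = 0,
                     min_score: float = 0.1) -> pd.DataFrame:
    """Gene-set cell-cycle phase scores with expression-matched controls.

    Per phase, score = mean expression of phase genes minus the mean of
    control genes drawn from bins of similar average expression; phase
    is the arg-max score when it exceeds ``min_score`` (a margin on the
    log-normalized scale that keeps pure noise from leaving G1), else
    G1.
    """
    if len(s_genes) == 0 or len(g2m_genes) == 0:
        raise ValueError("phase gene lists must be nonempty")
    avg = norm.mean(axis=0)
    if len(genes) < n_bins * 2:
        raise ValueError("too few genes for control binning")
    bins = pd.qcut(pd.Series(avg, index=genes), q=n_bins, labels=False,
                   duplicates="drop")
    rng = np.random.default_rng(seed)
    scores = {}
    for phase, members in (("S", s_genes), ("G2M", g2m_genes)):
        mask = _set_mask(genes, members)
        ctrl = np.zeros(len(genes), dtype=bool)
        for b in np.unique(bins[mask]):
            pool = np.flatnonzero((bins == b) & ~mask)
            if len(pool) == 0:
                continue
            take = min(n_ctrl, len(pool))
            ctrl[rng.choice(pool, take, replace=False)] = True
        if not ctrl.any():
            raise ValueError("no control genes available")
        scores[phase] = norm[:, mask].mean(axis=1) \
            - norm[:, ctrl].mean(axis=1)
    df = pd.DataFrame(scores, index=spots)
    best = df.to_numpy().argmax(axis=1)
    positive = df.to_numpy().max(axis=1) > min_score
    df["phase"] = np.where(positive, df.columns.to_numpy()[best], "G1")
    return df
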