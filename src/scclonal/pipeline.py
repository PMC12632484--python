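"""End-to-end orchestration: simulate -> QC -> cluster -> doublets ->
haplotype/LOH -> variants & pseudo-diploids -> phylogeny -> spatial.

``run_pipeline`` executes every stage under one :class:`RunConfig`,
writes optional artifacts (labels, LOH BED, Newick tree, report JSON)
and returns a machine-readable report including a truth-comparison
block measured against the generator's planted ground truth.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import allele, clustering, doublets, phylo, qc, spatial, variants
from .config import RunConfig
from .simulate import SimBundle, make_coarse_bins, simulate

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _majority_truth(cells: pd.Index, truth: pd.DataFrame) -> str:
    lab = truth.loc[cells, "profile"].where(
        truth.loc[cells, "profile"] != "", truth.loc[cells, "class"])
    return lab.value_counts().idxmax()


def run_pipeline(config: Optional[RunConfig] = None,
                 outdir: Optional[str] = None,
                 bundle: Optional[SimBundle] = None) -> dict:
    """Run the full analysis on synthetic data; return the run report."""
    config = config or RunConfig()
    report: dict = {"provenance": config.provenance(), "stages": {}}
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # ---- simulate -------------------------------------------------------
    stage = "simulate"
    try:
        if bundle is None:
            bundle = simulate(config.sim)
        truth = bundle.truth
        report["stages"][stage] = {
            "n_cells": int(bundle.matrix.n_cells),
            "n_bins": int(bundle.matrix.n_bins),
            "n_spots": int(bundle.st.counts.shape[0]),
            "class_counts": truth.cells["class"].value_counts().to_dict(),
        }
    except Exception as exc:                      # pragma: no cover
        raise StageError(stage, exc) from exc

    # ---- qc ---------------------------------------------------------------
    stage = "qc"
    try:
        clean, flagged, qc_report = qc.run_qc(
            bundle.matrix, truth.cells["ploidy_confident"].to_numpy(),
            alpha=config.alpha, min_quality=config.min_quality,
            min_mappability=config.min_mappability)
        report["stages"][stage] = qc_report
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- first-round clustering -----------------------------------------
    stage = "clustering"
    try:
        agg = clustering.aggregate_bins(clean, config.bins_per_window)
        labels1, scores1 = clustering.cluster_cells(
            agg, k_max=config.k_max, seed=config.seed,
            n_restarts=config.n_restarts)
        profiles1 = clustering.clone_profiles(agg, labels1)
        kinds1 = clustering.classify_clusters(profiles1)
        report["stages"][stage] = {
            "k_round1": int(labels1.nunique()),
            "k_round1_bic": int(clustering.select_k(scores1.scores, "bic")),
            "cluster_kinds_round1": kinds1,
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- doublet & artifact removal --------------------------------------
    stage = "doublets"
    try:
        removed, removal_log = doublets.remove_doublets_and_artifacts(
            clean, agg, labels1, profiles1, kinds1,
            threshold=config.doublet_threshold,
            exempt_diploid=config.odd_region_exempt_diploid)
        keep = [b for b in clean.barcodes if b not in removed]
        final_matrix = clean.subset_cells(keep)
        report["stages"][stage] = {
            "n_removed": len(removed),
            "reasons": (removal_log["reason"].value_counts().to_dict()
                        if len(removal_log) else {}),
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- final clustering and subclustering -------------------------------
    stage = "final_clustering"
    try:
        agg_f = clustering.aggregate_bins(final_matrix,
                                          config.bins_per_window)
        labels, scores = clustering.cluster_cells(
            agg_f, k_max=config.k_max, seed=config.seed,
            n_restarts=config.n_restarts)
        assignment = clustering.subcluster(
            agg_f, labels, k_max=config.k_max, seed=config.seed,
            n_restarts=config.n_restarts,
            min_size=config.min_subcluster_size)
        profiles = clustering.clone_profiles(agg_f, labels)
        kinds = clustering.classify_clusters(profiles)
        sizes = labels.value_counts().sort_index()
        report["stages"][stage] = {
            "k_final": int(labels.nunique()),
            "cluster_sizes": {str(k): int(v) for k, v in sizes.items()},
            "cluster_kinds": kinds,
            "n_subclusters": int(assignment.full_label().nunique()),
        }
        if out:
            assignment.labels.assign(
                label=assignment.full_label()).to_csv(out / "clusters.tsv",
                                                      sep="\t")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    diploid_clusters = [c for c, k in kinds.items() if k == "diploid"]
    baseline_clusters = [c for c, k in kinds.items()
                         if k == "tumor_baseline"]

    # ---- haplotype CN and LOH ---------------------------------------------
    stage = "allele_loh"
    try:
        hap = allele.haplotype_cn_matrix(
            agg_f.values, agg_f.barcodes, agg_f.coarse_bins, bundle.alleles,
            error_floor=config.error_floor)
        consensus = {}
        for cl in sorted(labels.unique()):
            cells = labels.index[labels == cl]
            consensus[str(cl)] = allele.cluster_consensus(hap, cells)
        loh = allele.infer_loh(consensus, agg_f.coarse_bins)
        mirrored = []
        cl_list = sorted(consensus)
        for i, a in enumerate(cl_list):
            for b in cl_list[i + 1:]:
                seg = allele.detect_mirrored_imbalance(
                    consensus[a], consensus[b], agg_f.coarse_bins)
                if len(seg):
                    seg.insert(0, "cluster_i", a)
                    seg.insert(1, "cluster_j", b)
                    mirrored.append(seg)
        mirrored = (pd.concat(mirrored, ignore_index=True) if mirrored
                    else pd.DataFrame())
        rdr = allele.compute_rdr(
            bundle.alleles.bin_reads,
            bundle.alleles.barcodes,
            list(labels.index[labels.astype(str).isin(diploid_clusters)])
            or list(labels.index))
        report["stages"][stage] = {
            "n_loh_segments": int(len(loh.segments)),
            "loh_classes": (loh.segments["loh_class"].value_counts()
                            .to_dict() if len(loh.segments) else {}),
            "n_mirrored_segments": int(len(mirrored)),
            "rdr_mean_diploid": float(np.nanmean(rdr[
                bundle.alleles.barcodes.get_indexer(
                    labels.index[labels.astype(str).isin(
                        diploid_clusters)])])) if diploid_clusters else None,
        }
        if out:
            from .io import write_loh, write_segments_bed
            write_loh(loh, out / "loh_segments.bed")
            if len(mirrored):
                write_segments_bed(mirrored, out / "mirrored_segments.bed")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- variants and pseudo-diploid --------------------------------------
    stage = "variants"
    try:
        clusters_cells = {str(cl): list(labels.index[labels == cl])
                          for cl in sorted(labels.unique())}
        vaf_table = variants.cluster_vaf_table(
            bundle.variants, bundle.variant_alt, bundle.variant_depth,
            bundle.alleles.barcodes, clusters_cells)
        reversions = []
        for j, (_, var) in enumerate(bundle.variants.iterrows()):
            cvafs = {cl: variants.pseudobulk_vaf(
                bundle.variant_alt, bundle.variant_depth,
                bundle.alleles.barcodes, cells, j)
                for cl, cells in clusters_cells.items()}
            cvafs = {cl: (v if np.isfinite(v) else 0.0, d)
                     for cl, (v, d) in cvafs.items()}
            rev = allele.detect_reversion_by_loh(var, cvafs, loh)
            hit = rev[rev["status"] == "reversion"]
            for _, r in hit.iterrows():
                reversions.append({"variant_id": var["variant_id"],
                                   "cluster": r["cluster"],
                                   "vaf": float(r["vaf"])})
        dip_cells = [b for cl in diploid_clusters
                     for b in clusters_cells[cl]]
        tumor_profiles = {cl: profiles[cl] for cl in baseline_clusters}
        if dip_cells and tumor_profiles:
            reports_pd = variants.pseudo_diploid_reports(
                agg_f, dip_cells, tumor_profiles)
            pseudo_set = variants.classify_pseudo_diploid(
                reports_pd, threshold=config.pseudo_score_threshold,
                min_aberrant_bins=config.min_aberrant_bins)
        else:
            reports_pd, pseudo_set = pd.DataFrame(), set()
        report["stages"][stage] = {
            "n_variants": int(len(bundle.variants)),
            "reversions": reversions,
            "n_pseudo_diploid": len(pseudo_set),
        }
        if out:
            vaf_table.to_csv(out / "cluster_vafs.tsv", sep="\t",
                             index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- phylogeny ---------------------------------------------------------
    stage = "phylogeny"
    try:
        full = assignment.full_label()
        vec = phylo.subcluster_vectors(final_matrix, full)
        tree_newick = None
        if len(vec) >= 3:
            dm = phylo.cn_distance_matrix(vec)
            tree = phylo.build_me_tree(dm)
            outgroup = (f"{diploid_clusters[0]}.1" if diploid_clusters
                        else str(vec.index[0]))
            rooted = phylo.root_at_outgroup(tree, outgroup)
            tree_newick = phylo.to_newick(rooted)
            if out:
                (out / "subclusters.nwk").write_text(tree_newick)
        report["stages"][stage] = {
            "n_taxa": int(len(vec)),
            "outgroup": (f"{diploid_clusters[0]}.1"
                         if diploid_clusters else None),
            "newick": tree_newick,
        }
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- spatial concordance ----------------------------------------------
    stage = "spatial"
    try:
        norm, kept = spatial.normalize_counts(bundle.st)
        pur = spatial.purity_score(
            norm, bundle.st.genes.index, bundle.signatures["stromal"],
            bundle.signatures["immune"], threshold=config.purity_threshold)
        tumor_spots = list(kept[pur["is_tumor"].to_numpy()])
        ref_spots = list(kept[~pur["is_tumor"].to_numpy()])
        inference = spatial.infer_cn_profiles(
            norm, kept, bundle.st.genes, tumor_spots, ref_spots,
            window=config.smoothing_window,
            resolution=config.leiden_resolution,
            n_neighbors=config.knn_neighbors,
            state_shift=config.hmm_state_shift,
            stay_prob=config.hmm_stay_prob, seed=config.seed)
        coarse = make_coarse_bins(config.sim)
        # match at the clone level: baseline clusters with near-identical
        # deviation profiles (subclones of one clone) are pooled first
        st_profiles = _group_baselines(profiles, baseline_clusters) \
            or profiles
        match = spatial.match_st_to_scdna(inference, st_profiles, coarse,
                                          margin=config.match_margin)
        report["stages"][stage] = {
            "n_tumor_spots": len(tumor_spots),
            "n_reference_spots": len(ref_spots),
            "n_subgroups": len(inference.profiles),
            "matches": match.drop(columns=[c for c in match.columns
                                           if c.startswith("cor_")])
            .to_dict("records"),
        }
        if out:
            match.to_csv(out / "st_matches.tsv", sep="\t", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ---- truth comparison ---------------------------------------------------
    report["truth_comparison"] = _truth_block(
        bundle, truth, flagged, removed, labels, assignment, loh, mirrored,
        pseudo_set, reversions, inference, match, kinds)

    report_json = json.dumps(report, indent=2, sort_keys=True, default=str)
    if out:
        (out / "report.json").write_text(report_json)
    return report


def _group_baselines(profiles, baseline_clusters, cor_threshold: float = 0.9
                     ) -> dict:
    """Pool baseline clusters with near-identical deviation profiles.

    Subclones of one clone differ in a couple of bins; their deviation
    profiles correlate almost perfectly and are merged (cell-count
    weighted) into one clone-level profile named "a+b".
    """
    from .containers import CloneProfile
    groups: list = []
    for cl in baseline_clusters:
        dev = profiles[cl].mean - 2.0
        placed = False
        for grp in groups:
            ref = profiles[grp[0]].mean - 2.0
            if np.std(dev) > 0 and np.std(ref) > 0 and \
                    float(np.corrcoef(dev, ref)[0, 1]) >= cor_threshold:
                grp.append(cl)
                placed = True
                break
        if not placed:
            groups.append([cl])
    out = {}
    for grp in groups:
        w = np.array([profiles[c].n_cells for c in grp], dtype=float)
        mean = np.average([profiles[c].mean for c in grp], axis=0,
                          weights=w)
        name = "+".join(grp)
        out[name] = CloneProfile(name, mean, np.round(mean),
                                 np.zeros_like(mean), int(w.sum()))
    return out


def _cluster_to_truth(labels: pd.Series, truth_cells: pd.DataFrame
                      ) -> Dict[str, str]:
    return {str(cl): _majority_truth(labels.index[labels == cl],
                                     truth_cells)
            for cl in sorted(labels.unique())}


def _truth_block(bundle, truth, flagged, removed, labels, assignment,
                 loh, mirrored, pseudo_set, reversions, inference, match,
                 kinds) -> dict:
    """Recovery metrics against the planted ground truth."""
    cells = truth.cells
    block: dict = {}

    bad = cells.index[cells["class"].isin(["noisy", "degraded"])]
    block["noisy_degraded_removal"] = float(
        np.mean([b in flagged for b in bad])) if len(bad) else None
    clean_sing = cells.index[cells["class"].isin(
        ["diploid", "clone", "wgd", "pseudo_diploid"])
        & cells["ploidy_confident"]]
    block["clean_cell_loss"] = float(
        np.mean([b in flagged for b in clean_sing]))

    dbl = [b for b in cells.index[cells["class"] == "doublet"]
           if b not in flagged]
    block["doublet_sensitivity"] = float(
        np.mean([b in removed for b in dbl])) if dbl else None
    art = [b for b in cells.index[cells["class"] == "artifact"]
           if b not in flagged]
    block["artifact_removal"] = float(
        np.mean([b in removed for b in art])) if art else None
    singl = [b for b in cells.index[cells["class"].isin(
        ["diploid", "clone", "wgd", "pseudo_diploid"])] if b not in flagged]
    block["doublet_fpr"] = float(np.mean([b in removed for b in singl]))

    # cluster purity: every final cluster maps to one dominant truth group
    mapping = _cluster_to_truth(labels, cells)
    purities = []
    for cl in sorted(labels.unique()):
        members = labels.index[labels == cl]
        lab = cells.loc[members, "profile"].where(
            cells.loc[members, "profile"] != "",
            cells.loc[members, "class"])
        purities.append(float((lab == mapping[str(cl)]).mean()))
    block["cluster_purity_min"] = min(purities)
    block["cluster_to_truth"] = mapping

    # LOH recovery per truth clone profile (Jaccard over coarse bins)
    cb = loh.segments
    lt = truth.loh_truth
    jac = {}
    coarse = None
    from .simulate import make_coarse_bins
    coarse = make_coarse_bins(bundle.config)
    for cl, key in mapping.items():
        if key not in set(lt.get("profile", [])):
            continue
        want = set(lt[lt["profile"] == key]["coarse_bin"])
        seg = cb[cb["cluster"].astype(str) == cl] if len(cb) else cb
        got = set()
        for _, s in seg.iterrows():
            sel = ((coarse["chrom"] == s["chrom"])
                   & (coarse["start"] >= s["start"])
                   & (coarse["start"] < s["end"]))
            got |= set(np.flatnonzero(sel))
        if want | got:
            jac[cl] = len(want & got) / len(want | got)
    block["loh_jaccard"] = jac
    block["loh_jaccard_min"] = min(jac.values()) if jac else None

    block["n_mirrored_segments"] = int(len(mirrored))

    truep = set(cells.index[cells["class"] == "pseudo_diploid"])
    truep &= set(labels.index)
    if truep:
        block["pseudo_sensitivity"] = len(pseudo_set & truep) / len(truep)
    dip_true = set(cells.index[cells["class"] == "diploid"]) \
        & set(labels.index)
    block["pseudo_fpr"] = (len(pseudo_set - truep) / len(dip_true)
                           if dip_true else None)

    # reversion: flagged only in clusters mapping to the planted clone
    rev_truth = truth.variant_truth
    planted = rev_truth[rev_truth["kind"] == "driver_reverted"]
    if len(planted):
        rev_clusters = {r["cluster"] for r in reversions
                        if r["variant_id"] == planted.iloc[0]["variant_id"]}
        expected = {cl for cl, key in mapping.items()
                    if key.startswith("clone1") or key == "wgd1"}
        block["reversion_flagged_clusters"] = sorted(rev_clusters)
        block["reversion_correct"] = bool(
            rev_clusters and rev_clusters <= expected)

    # ST: spot-level clone assignment accuracy
    amap = dict(zip(match["subgroup"], match["assigned"]))
    assigned = inference.spot_subgroup.map(amap)
    spot_truth = truth.spot_truth.loc[assigned.index]

    def _clone_name(label: str) -> str:
        first = str(label).split("+")[0]
        key = mapping.get(first, "")
        return f"clone{key[5]}" if key.startswith("clone") else str(label)

    pred = assigned.map(_clone_name)
    ok = pred == spot_truth["region"]
    block["st_spot_accuracy"] = float(ok.mean())
    cors = []
    for _, row in match.iterrows():
        cc = [v for k, v in row.items() if k.startswith("cor_")
              and np.isfinite(v)]
        if cc and row["n_spots"] >= 50:
            cors.append(max(cc))
    block["st_profile_correlation_min"] = min(cors) if cors else None
    return block
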