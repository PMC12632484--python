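"""Synthetic droplet scDNA-seq and Visium-like data with planted truth.

The generator emulates the structure of a multi-clonal ovarian-carcinoma
study: integer CN calls in 20 kb bins per cell barcode (with per-call
quality and bin mappability), phased heterozygous SNPs with per-cell
haplotype read counts, per-cell alt/ref counts at candidate somatic
sites, and a spot x gene count matrix with spatially contiguous clone
territories and stromal contamination.

Planted structure (default two-clone scenario):

* trunk events shared by all tumor clones, including one copy-neutral
  LOH segment (2,0);
* a mirrored allelic-imbalance segment — clone 0 carries (1,2) where
  clone 1 carries (2,1), both with total CN 3;
* a clone-1-private copy-neutral LOH that removes the haplotype bearing
  a trunk driver variant (driver reversion: the descendant clone keeps
  only the wild-type allele);
* subclonal WGD of clone 1 (2x the parent profile plus a post-WGD
  gain), doublets (element-wise sums of two source cells), noisy and
  degraded cells, all-even "overfit" artifact cells, and pseudo-diploid
  cells whose sparse gains preferentially hit clone-gained bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .config import BIN_SIZE, COARSE_BINS, COARSE_SIZE, SimConfig
from .containers import (AlleleCounts, CellCNMatrix, PhasedSNPTable,
                         SimTruth, STSpotMatrix, classify_loh)

DIPLOID = "diploid"
ARTIFACT = "artifact"

# stable per-operation rng streams derived from the config seed
_STREAM = {"profiles": 1, "cells": 2, "alleles": 3, "variants": 4, "st": 5}


def _rng(config: SimConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], config.seed])


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genome layout helpers


def make_bins(config: SimConfig, mappability: Optional[np.ndarray] = None
              ) -> pd.DataFrame:
    """Fine-bin table (0-based half-open, sorted by chrom then start)."""
    chroms = np.repeat([f"chr{i + 1}" for i in range(config.n_chromosomes)],
                       config.bins_per_chromosome)
    start = np.tile(np.arange(config.bins_per_chromosome) * BIN_SIZE,
                    config.n_chromosomes)
    if mappability is None:
        mappability = np.ones(config.n_bins)
    return pd.DataFrame({"chrom": chroms, "start": start,
                         "end": start + BIN_SIZE,
                         "mappability": mappability})


def make_coarse_bins(config: SimConfig) -> pd.DataFrame:
    cpc = config.coarse_per_chromosome
    chrom_len = config.bins_per_chromosome * BIN_SIZE
    rows = []
    for c in range(config.n_chromosomes):
        for w in range(cpc):
            s = w * COARSE_SIZE
            rows.append((f"chr{c + 1}", s, min(s + COARSE_SIZE, chrom_len)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _coarse_to_fine(config: SimConfig, coarse_idx: int) -> slice:
    cpc = config.coarse_per_chromosome
    chrom, within = divmod(coarse_idx, cpc)
    base = chrom * config.bins_per_chromosome
    lo = within * COARSE_BINS
    hi = min(lo + COARSE_BINS, config.bins_per_chromosome)
    return slice(base + lo, base + hi)


def _segment_slice(config: SimConfig, chrom: int, c_lo: int, c_hi: int
                   ) -> slice:
    """Fine-bin slice for coarse bins [c_lo, c_hi) of one chromosome."""
    cpc = config.coarse_per_chromosome
    first = _coarse_to_fine(config, chrom * cpc + c_lo)
    last = _coarse_to_fine(config, chrom * cpc + c_hi - 1)
    return slice(first.start, last.stop)


def aggregate_profile(config: SimConfig, fine: np.ndarray) -> np.ndarray:
    """Mean of a fine-bin vector over coarse windows."""
    out = np.empty(config.n_coarse_bins)
    for c in range(config.n_coarse_bins):
        out[c] = fine[_coarse_to_fine(config, c)].mean()
    return out


# ---------------------------------------------------------------------------
# clone profiles


@dataclass
class ClonePanel:
    """Haplotype-resolved CN profiles of every planted cell population."""

    config: SimConfig
    hap_a: Dict[str, np.ndarray]
    hap_b: Dict[str, np.ndarray]
    events: pd.DataFrame
    loh_truth: pd.DataFrame
    mirrored_truth: pd.DataFrame
    special: dict = field(default_factory=dict)

    def total(self, key: str) -> np.ndarray:
        return self.hap_a[key] + self.hap_b[key]

    def base_key(self, clone: int) -> str:
        return f"clone{clone}.1"

    def clone_keys(self, clone: int) -> list:
        n_sub = self.config.subclones_per_clone[clone]
        keys = [f"clone{clone}.{s + 1}" for s in range(n_sub)]
        if self.config.wgd_fraction_per_clone[clone] > 0:
            keys.append(f"wgd{clone}")
        return keys

    def gained_coarse_bins(self, clone: int) -> np.ndarray:
        """Coarse bins where the clone's baseline total CN exceeds 2."""
        coarse = aggregate_profile(self.config, self.total(self.base_key(clone)))
        return np.flatnonzero(np.round(coarse) > 2)


def _apply_event(hap_a: np.ndarray, hap_b: np.ndarray, sl: slice,
                 hap: str, delta: int) -> None:
    target = hap_a if hap == "A" else hap_b
    if delta < 0 and target[sl].min() + delta < 0:
        raise SimulationError(
            "planted deletion would drive a haplotype copy number below 0")
    target[sl] += delta


def simulate_clone_profiles(config: SimConfig) -> ClonePanel:
    """Generate haplotype CN profiles by descent from a diploid ancestor.

    Trunk events appear in every clone; each clone then receives its
    private planted and random segmental events, subclone variants add
    one further gain each, and WGD profiles are 2x the parent baseline
    plus one post-WGD gain (so WGD cells retain an odd-CN region).
    """
    if config.n_clones < 1:
        raise SimulationError("n_clones must be >= 1")
    rng = _rng(config, "profiles")
    nb = config.n_bins
    cpc = config.coarse_per_chromosome
    events = []

    def record(scope, chrom, c_lo, c_hi, hap, delta, kind):
        events.append({"scope": scope, "chrom": f"chr{chrom + 1}",
                       "coarse_lo": c_lo, "coarse_hi": c_hi, "hap": hap,
                       "delta": delta, "kind": kind})

    ancestor_a = np.ones(nb, dtype=np.int8)
    ancestor_b = np.ones(nb, dtype=np.int8)
    blocked = set()
    special: dict = {}

    if config.plant_special_events:
        if config.n_chromosomes < 6:
            raise SimulationError(
                "planted special events require >= 6 chromosomes")
        # trunk: gain, hemizygous loss, copy-neutral LOH
        planted_trunk = [(0, 0, 3, "A", +1, "trunk_gain"),
                         (1, 0, 2, "B", -1, "trunk_hemizygous_loss"),
                         (4, 0, cpc, "A", +1, "trunk_cnloh"),
                         (4, 0, cpc, "B", -1, "trunk_cnloh")]
        for chrom, lo, hi, hap, delta, kind in planted_trunk:
            _apply_event(ancestor_a, ancestor_b,
                         _segment_slice(config, chrom, lo, hi), hap, delta)
            record("trunk", chrom, lo, hi, hap, delta, kind)
            blocked.update(chrom * cpc + c for c in range(lo, hi))
        special["trunk_cnloh"] = {"chrom": "chr5", "coarse": (0, cpc),
                                  "lost_haplotype": "B"}

    hap_a = {DIPLOID: np.ones(nb, dtype=np.int8)}
    hap_b = {DIPLOID: np.ones(nb, dtype=np.int8)}
    clone_a = [ancestor_a.copy() for _ in range(config.n_clones)]
    clone_b = [ancestor_b.copy() for _ in range(config.n_clones)]

    if config.plant_special_events and config.n_clones >= 2:
        # clone 0 private gain; mirrored segment on chr6; clone 1
        # private CN-LOH (the driver-reversion region) and gain
        plan = [(0, 3, 0, 3, "B", +1, "private_gain"),
                (0, 5, 0, 2, "B", +1, "mirrored"),
                (1, 5, 0, 2, "A", +1, "mirrored"),
                (1, 2, 0, 3, "A", +1, "reversion_cnloh"),
                (1, 2, 0, 3, "B", -1, "reversion_cnloh"),
                (1, 3, 4, 6, "A", +1, "private_gain")]
        for clone, chrom, lo, hi, hap, delta, kind in plan:
            _apply_event(clone_a[clone], clone_b[clone],
                         _segment_slice(config, chrom, lo, hi), hap, delta)
            record(f"clone{clone}", chrom, lo, hi, hap, delta, kind)
            blocked.update(chrom * cpc + c for c in range(lo, hi))
        special["mirrored"] = {"chrom": "chr6", "coarse": (0, 2)}
        special["reversion"] = {"chrom": "chr3", "coarse": (0, 3),
                                "clone": 1, "lost_haplotype": "B"}

    # random private events per clone, avoiding planted regions
    for clone in range(config.n_clones):
        for _ in range(config.n_random_events):
            for _try in range(50):
                chrom = int(rng.integers(config.n_chromosomes))
                length = int(rng.integers(1, 5))
                lo = int(rng.integers(0, max(1, cpc - length + 1)))
                hi = min(lo + length, cpc)
                cells = {chrom * cpc + c for c in range(lo, hi)}
                if cells & blocked:
                    continue
                hap = "A" if rng.random() < 0.5 else "B"
                delta = +1 if rng.random() < 0.7 else -1
                sl = _segment_slice(config, chrom, lo, hi)
                try:
                    _apply_event(clone_a[clone], clone_b[clone], sl, hap,
                                 delta)
                except SimulationError:
                    continue
                record(f"clone{clone}", chrom, lo, hi, hap, delta, "random")
                blocked.update(cells)
                break

    # subclones: one private gain each beyond the first
    for clone in range(config.n_clones):
        hap_a[f"clone{clone}.1"] = clone_a[clone].copy()
        hap_b[f"clone{clone}.1"] = clone_b[clone].copy()
        for sub in range(1, config.subclones_per_clone[clone]):
            sa, sb = clone_a[clone].copy(), clone_b[clone].copy()
            for _try in range(50):
                chrom = int(rng.integers(config.n_chromosomes))
                lo = int(rng.integers(0, cpc - 1))
                hi = lo + 2
                cells = {chrom * cpc + c for c in range(lo, hi)}
                if cells & blocked:
                    continue
                sl = _segment_slice(config, chrom, lo, hi)
                hap = "A" if rng.random() < 0.5 else "B"
                _apply_event(sa, sb, sl, hap, +1)
                record(f"clone{clone}.{sub + 1}", chrom, lo, hi, hap, +1,
                       "subclone_gain")
                blocked.update(cells)
                break
            hap_a[f"clone{clone}.{sub + 1}"] = sa
            hap_b[f"clone{clone}.{sub + 1}"] = sb

    # WGD: 2x parent baseline, then one post-WGD gain (odd-CN region)
    for clone in range(config.n_clones):
        if config.wgd_fraction_per_clone[clone] > 0:
            wa = (2 * clone_a[clone]).astype(np.int8)
            wb = (2 * clone_b[clone]).astype(np.int8)
            chrom, lo, hi = 0, cpc - 2, cpc
            _apply_event(wa, wb, _segment_slice(config, chrom, lo, hi),
                         "A", +1)
            record(f"wgd{clone}", chrom, lo, hi, "A", +1, "post_wgd_gain")
            hap_a[f"wgd{clone}"] = wa
            hap_b[f"wgd{clone}"] = wb

    hap_a[ARTIFACT] = np.full(nb, 2, dtype=np.int8)
    hap_b[ARTIFACT] = np.full(nb, 2, dtype=np.int8)

    panel = ClonePanel(config, hap_a, hap_b, pd.DataFrame(events),
                       pd.DataFrame(), pd.DataFrame(), special)
    panel.loh_truth = _scan_loh_truth(panel)
    panel.mirrored_truth = _scan_mirrored_truth(panel)
    return panel


def _scan_loh_truth(panel: ClonePanel) -> pd.DataFrame:
    """LOH truth by direct scan of the emitted haplotype profiles."""
    config = panel.config
    coarse = make_coarse_bins(config)
    rows = []
    for key in panel.hap_a:
        if key in (DIPLOID, ARTIFACT):
            continue
        a = aggregate_profile(config, panel.hap_a[key]).round().astype(int)
        b = aggregate_profile(config, panel.hap_b[key]).round().astype(int)
        loh = ((a == 0) | (b == 0)) & ((a + b) > 0)
        for c in np.flatnonzero(loh):
            lost = "A" if a[c] == 0 else "B"
            retained = int(max(a[c], b[c]))
            rows.append({"profile": key, "chrom": coarse.loc[c, "chrom"],
                         "start": int(coarse.loc[c, "start"]),
                         "end": int(coarse.loc[c, "end"]),
                         "coarse_bin": int(c), "lost_haplotype": lost,
                         "loh_class": classify_loh(retained)})
    return pd.DataFrame(rows)


def _scan_mirrored_truth(panel: ClonePanel) -> pd.DataFrame:
    config = panel.config
    if config.n_clones < 2:
        return pd.DataFrame()
    coarse = make_coarse_bins(config)
    rows = []
    for i in range(config.n_clones):
        for j in range(i + 1, config.n_clones):
            ai = aggregate_profile(config, panel.hap_a[panel.base_key(i)])
            bi = aggregate_profile(config, panel.hap_b[panel.base_key(i)])
            aj = aggregate_profile(config, panel.hap_a[panel.base_key(j)])
            bj = aggregate_profile(config, panel.hap_b[panel.base_key(j)])
            ai, bi = ai.round().astype(int), bi.round().astype(int)
            aj, bj = aj.round().astype(int), bj.round().astype(int)
            hit = (ai == bj) & (bi == aj) & (ai != bi)
            for c in np.flatnonzero(hit):
                rows.append({"clone_i": i, "clone_j": j,
                             "chrom": coarse.loc[c, "chrom"],
                             "start": int(coarse.loc[c, "start"]),
                             "end": int(coarse.loc[c, "end"]),
                             "coarse_bin": int(c)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cells


def _allocate(n: int, fractions) -> np.ndarray:
    """Largest-remainder integer allocation of n across fractions."""
    fr = np.asarray(fractions, dtype=float)
    raw = fr * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def _noise_rate(rng: np.random.Generator, true_cn: np.ndarray,
                rate: np.ndarray) -> np.ndarray:
    """Integer call noise: +/-1 flips with probability rate * cn/2."""
    p = np.minimum(rate * true_cn / 2.0, 1.0)
    flip = rng.random(true_cn.shape) < p
    sign = rng.integers(0, 2, size=true_cn.shape) * 2 - 1
    return np.maximum(true_cn + flip * sign, 0)


def simulate_cells(config: SimConfig, panel: ClonePanel
                   ) -> Tuple[CellCNMatrix, SimTruth]:
    """Emit the observed CN-call matrix plus the planted per-cell truth."""
    rng = _rng(config, "cells")
    n, nb = config.n_cells, config.n_bins

    counts = {
        DIPLOID: round(config.diploid_fraction * n),
        "noisy": round(config.noisy_cell_rate * n),
        "degraded": round(config.degraded_cell_rate * n),
        "doublet": round(config.doublet_rate * n),
        ARTIFACT: round(config.artifact_even_rate * n),
        "pseudo_diploid": round(config.pseudo_diploid_rate * n),
    }
    n_tumor = n - sum(counts.values())
    if n_tumor < config.n_clones:
        raise SimulationError("config leaves too few tumor cells")
    clone_n = _allocate(n_tumor, config.clone_fractions)

    records = []
    profile_of = []        # per-cell profile key ("" for composites)

    def add(klass, profile, clone=-1, subclone=0):
        records.append({"class": klass, "clone": clone, "subclone": subclone,
                        "profile": profile, "source_a": "", "source_b": ""})
        profile_of.append(profile)

    for _ in range(counts[DIPLOID]):
        add(DIPLOID, DIPLOID)
    for clone in range(config.n_clones):
        n_wgd = round(config.wgd_fraction_per_clone[clone] * clone_n[clone])
        n_base = clone_n[clone] - n_wgd
        sub_n = _allocate(n_base, [1.0 / config.subclones_per_clone[clone]]
                          * config.subclones_per_clone[clone])
        for sub, ns in enumerate(sub_n):
            for _ in range(ns):
                add("clone", f"clone{clone}.{sub + 1}", clone, sub + 1)
        for _ in range(n_wgd):
            add("wgd", f"wgd{clone}", clone, 1)
    base_pool = [r["profile"] for r in records]      # singlet truth pool
    # doublet sources: the collision classes the removal stage models
    # (diploid-tumor and tumor-tumor baseline pairs)
    doublet_pool = [i for i, r in enumerate(records)
                    if r["class"] in (DIPLOID, "clone")]
    for _ in range(counts["noisy"]):
        add("noisy", base_pool[int(rng.integers(len(base_pool)))])
    for _ in range(counts["degraded"]):
        add("degraded", base_pool[int(rng.integers(len(base_pool)))])
    for _ in range(counts[ARTIFACT]):
        add(ARTIFACT, ARTIFACT)
    for _ in range(counts["pseudo_diploid"]):
        add("pseudo_diploid", "")
    for _ in range(counts["doublet"]):
        # collisions of the modeled classes only: diploid-tumor, or
        # tumor-tumor across DISTINCT clones (a same-clone pair is CN-
        # indistinguishable from a WGD cell by construction)
        while True:
            i, j = rng.choice(doublet_pool, size=2, replace=False)
            ci, cj = records[i]["clone"], records[j]["clone"]
            if ci == cj:          # same clone, or diploid-diploid (-1,-1)
                continue
            break
        records.append({"class": "doublet", "clone": -1, "subclone": 0,
                        "profile": "", "source_a": f"cell_{i:04d}",
                        "source_b": f"cell_{j:04d}"})
        profile_of.append("")

    barcodes = pd.Index([f"cell_{i:04d}" for i in range(len(records))])
    cells = pd.DataFrame(records, index=barcodes)
    cells["ploidy_confident"] = rng.random(len(cells)) \
        >= config.low_ploidy_confidence_rate

    # true CN
    true_cn = np.zeros((len(cells), nb), dtype=np.int16)
    for i, key in enumerate(profile_of):
        if key:
            true_cn[i] = panel.total(key)

    # pseudo-diploid cells: diploid plus 2-3 sparse gains preferentially
    # at the designated clone's gained coarse bins
    gains_per_clone = [len(panel.gained_coarse_bins(c))
                       for c in range(config.n_clones)]
    designated = int(np.argmax(gains_per_clone))
    clone_gained = panel.gained_coarse_bins(designated)
    pseudo_gain_bins = {}
    pseudo_rows = np.flatnonzero((cells["class"] == "pseudo_diploid").values)
    for i in pseudo_rows:
        true_cn[i] = 2
        n_seg = int(rng.integers(2, 4))
        chosen = []
        for _ in range(n_seg):
            length = int(rng.integers(1, 4))
            on_target = (rng.random() < config.pseudo_gain_overlap
                         and len(clone_gained) > 0)
            start = (int(rng.choice(clone_gained)) if on_target
                     else int(rng.integers(config.n_coarse_bins)))
            seg = [c for c in range(start, min(start + length,
                                               config.n_coarse_bins))]
            chosen.extend(seg)
        chosen = sorted(set(chosen))
        for c in chosen:
            true_cn[i, _coarse_to_fine(config, c)] += 1
        pseudo_gain_bins[barcodes[i]] = np.array(chosen, dtype=int)

    # degraded cells: random segmental dropout of 30-70% of the genome
    lo_f, hi_f = config.degraded_dropout_range
    for i in np.flatnonzero((cells["class"] == "degraded").values):
        frac = rng.uniform(lo_f, hi_f)
        drop = rng.random(config.n_coarse_bins) < frac
        for c in np.flatnonzero(drop):
            true_cn[i, _coarse_to_fine(config, c)] = int(rng.integers(0, 2))

    # doublets: exact element-wise sum of the two source cells' true CN
    for i in np.flatnonzero((cells["class"] == "doublet").values):
        ia = barcodes.get_loc(cells.iloc[i]["source_a"])
        ib = barcodes.get_loc(cells.iloc[i]["source_b"])
        true_cn[i] = true_cn[ia] + true_cn[ib]

    # observed CN = true CN + integer call noise (chunked for memory);
    # degraded cells produce noisy calls too, not just dropout
    observed = np.empty_like(true_cn)
    noisy_mask = cells["class"].isin(["noisy", "degraded"]).values
    for lo in range(0, len(cells), 200):
        hi = min(lo + 200, len(cells))
        rate = np.where(noisy_mask[lo:hi, None],
                        config.noisy_cell_noise_rate, config.cn_noise_rate)
        observed[lo:hi] = _noise_rate(rng, true_cn[lo:hi], rate)

    # per-call quality and per-bin mappability
    quality = np.empty((len(cells), nb), dtype=np.float32)
    for lo in range(0, len(cells), 200):
        hi = min(lo + 200, len(cells))
        low = rng.random((hi - lo, nb)) < config.low_quality_fraction
        q_hi = rng.uniform(15, 61, size=(hi - lo, nb))
        q_lo = rng.uniform(0, 15, size=(hi - lo, nb))
        quality[lo:hi] = np.where(low, q_lo, q_hi)
    low_map = rng.random(nb) < config.low_mappability_fraction
    mappability = np.where(low_map, rng.uniform(0.5, 0.90, size=nb),
                           rng.uniform(0.95, 1.0, size=nb))

    matrix = CellCNMatrix(barcodes, make_bins(config, mappability),
                          observed.astype(np.int16), quality)
    truth = SimTruth(cells=cells, true_cn=true_cn,
                     clone_hap_a=panel.hap_a, clone_hap_b=panel.hap_b,
                     loh_truth=panel.loh_truth,
                     variant_truth=pd.DataFrame(),
                     pseudo_gain_bins=pseudo_gain_bins)
    return matrix, truth


# ---------------------------------------------------------------------------
# allele counts


def _cell_hap_profiles(config: SimConfig, panel: ClonePanel, truth: SimTruth,
                       fine_idx: np.ndarray
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """True (A, B) copies per cell at the given fine-bin positions."""
    cells = truth.cells
    n = len(cells)
    a = np.zeros((n, len(fine_idx)), dtype=np.int16)
    b = np.zeros((n, len(fine_idx)), dtype=np.int16)
    barcodes = cells.index
    for i, (bc, row) in enumerate(cells.iterrows()):
        key = row["profile"]
        if key:
            a[i] = panel.hap_a[key][fine_idx]
            b[i] = panel.hap_b[key][fine_idx]
        elif row["class"] == "pseudo_diploid":
            a[i] = 1
            b[i] = 1
            gained = truth.pseudo_gain_bins.get(bc, [])
            cpc = config.coarse_per_chromosome
            coarse_of = fine_idx // config.bins_per_chromosome \
                * cpc + (fine_idx % config.bins_per_chromosome) // COARSE_BINS
            for c in gained:
                a[i, coarse_of == c] += 1
    # doublets after singlets so sources are filled
    for i, (bc, row) in enumerate(cells.iterrows()):
        if row["class"] == "doublet":
            ia = barcodes.get_loc(row["source_a"])
            ib = barcodes.get_loc(row["source_b"])
            a[i] = a[ia] + a[ib]
            b[i] = b[ia] + b[ib]
    return a, b


def simulate_allele_counts(config: SimConfig, panel: ClonePanel,
                           truth: SimTruth) -> AlleleCounts:
    """Phased SNPs plus per-cell haplotype read counts and RDR bin reads.

    B-haplotype reads are binomial with success probability B/(A+B),
    error-adjusted; total SNP depth is Poisson with mean proportional to
    local total CN. Bins with A+B=0 emit zero-depth SNPs.
    """
    rng = _rng(config, "alleles")
    genome_mb = config.n_bins * BIN_SIZE / 1e6
    n_snps = max(1, round(genome_mb * config.snp_density))
    pos = np.sort(rng.choice(config.n_bins * BIN_SIZE, size=n_snps,
                             replace=False))
    chrom_len = config.bins_per_chromosome * BIN_SIZE
    chrom_idx = pos // chrom_len
    snp_pos = pos % chrom_len
    fine_idx = pos // BIN_SIZE

    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=n_snps)
    alt_i = (ref_i + rng.integers(1, 4, size=n_snps)) % 4
    snps = pd.DataFrame({
        "snp_id": [f"snp_{i:05d}" for i in range(n_snps)],
        "chrom": [f"chr{c + 1}" for c in chrom_idx],
        "pos": snp_pos,
        "ref": bases[ref_i], "alt": bases[alt_i],
        "hap_b_is_alt": rng.random(n_snps) < 0.5,
    })

    a_cop, b_cop = _cell_hap_profiles(config, panel, truth, fine_idx)
    tot = a_cop + b_cop
    lam = config.snp_depth_mean * tot / 2.0
    depth = rng.poisson(lam).astype(np.int32)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_b = np.where(tot > 0, b_cop / np.maximum(tot, 1), 0.0)
    e = config.sequencing_error
    p_b = p_b * (1 - e) + (1 - p_b) * e
    b_reads = rng.binomial(depth, p_b).astype(np.int32)
    a_reads = depth - b_reads

    # RDR input: per-cell read counts in coarse bins, scaled by true CN
    coarse_cn = np.empty((len(truth.cells), config.n_coarse_bins))
    for c in range(config.n_coarse_bins):
        coarse_cn[:, c] = truth.true_cn[:, _coarse_to_fine(config, c)].mean(1)
    size_factor = rng.lognormal(0.0, 0.1, size=len(truth.cells))[:, None]
    lam_bins = (config.reads_per_cell_mean / config.n_coarse_bins
                * coarse_cn / 2.0 * size_factor)
    bin_reads = rng.poisson(lam_bins).astype(np.int32)

    return AlleleCounts(truth.cells.index, PhasedSNPTable(snps),
                        a_reads, b_reads, bin_reads)


# ---------------------------------------------------------------------------
# somatic variants


def simulate_variants(config: SimConfig, panel: ClonePanel, truth: SimTruth
                      ) -> Tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Plant somatic variants and emit per-cell alt/ref counts.

    Returns ``(variant_table, alt_reads, total_reads)``. Trunk variants
    are ancestral to every tumor clone; each clone receives private
    variants; one trunk variant sits inside the trunk copy-neutral LOH
    on the retained haplotype (pseudobulk VAF 1); and, when special
    events are planted, a trunk driver lies on the haplotype that clone
    1 later loses by LOH (driver reversion: alt reads vanish there).
    Pseudo-diploid cells carry the first trunk variant, mirroring their
    shared ancestry with the malignant population.
    """
    rng = _rng(config, "variants")
    cpc = config.coarse_per_chromosome
    bases = ["A", "C", "G", "T"]
    rows = []

    special_bins = set()
    if config.plant_special_events:
        for chrom, rng_c in ((2, range(0, 3)), (4, range(0, cpc))):
            special_bins.update(chrom * cpc + c for c in rng_c)

    # candidate somatic sites must be observable: trunk variants sit in
    # regions still (1,1) in every clone (comparable VAF across clones),
    # private variants on a haplotype the carrier clone retains
    base_a = [panel.hap_a[panel.base_key(c)] for c in range(config.n_clones)]
    base_b = [panel.hap_b[panel.base_key(c)] for c in range(config.n_clones)]
    all_het = np.ones(config.n_bins, dtype=bool)
    for a, b in zip(base_a, base_b):
        all_het &= (a == 1) & (b == 1)

    def random_site(hap: str, clones) -> Tuple[int, int]:
        while True:
            c = int(rng.integers(config.n_coarse_bins))
            if c in special_bins:
                continue
            sl = _coarse_to_fine(config, c)
            fine = int(rng.integers(sl.start, sl.stop))
            if len(clones) > 1:
                if not all_het[fine]:
                    continue
            else:
                cl = clones[0]
                cop = base_a[cl][fine] if hap == "A" else base_b[cl][fine]
                if cop < 1:
                    continue
            offset = int(rng.integers(BIN_SIZE))
            return fine, offset

    def add(vid, fine, offset, hap, kind, clones):
        chrom_i, within = divmod(fine, config.bins_per_chromosome)
        ref = bases[int(rng.integers(4))]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
        rows.append({"variant_id": vid, "chrom": f"chr{chrom_i + 1}",
                     "pos": within * BIN_SIZE + offset, "ref": ref,
                     "alt": alt, "haplotype": hap, "kind": kind,
                     "fine_bin": fine,
                     "carrier_clones": ",".join(map(str, clones))})

    all_clones = list(range(config.n_clones))
    for t in range(config.n_trunk_variants):
        hap = "A" if rng.random() < 0.5 else "B"
        fine, off = random_site(hap, all_clones)
        add(f"trunk_{t}", fine, off, hap, "trunk", all_clones)
    if config.plant_special_events:
        # VAF-1 variant: trunk CN-LOH (chr5) retains haplotype A
        sl = _segment_slice(config, 4, 1, 2)
        add("trunk_loh_retained", int((sl.start + sl.stop) // 2), 100, "A",
            "trunk_loh_retained", all_clones)
        if config.n_clones >= 2:
            # driver on haplotype B inside clone 1's chr3 CN-LOH region
            sl = _segment_slice(config, 2, 1, 2)
            add("driver", int((sl.start + sl.stop) // 2), 200, "B",
                "driver_reverted", all_clones)
    for clone in range(config.n_clones):
        for v in range(config.n_private_variants):
            hap = "A" if rng.random() < 0.5 else "B"
            fine, off = random_site(hap, [clone])
            add(f"private{clone}_{v}", fine, off, hap, f"private_{clone}",
                [clone])
    table = pd.DataFrame(rows)
    truth.variant_truth = table

    fine_idx = table["fine_bin"].to_numpy()
    a_cop, b_cop = _cell_hap_profiles(config, panel, truth, fine_idx)
    tot = a_cop + b_cop

    # per-cell copies of the variant-bearing haplotype, zeroed for
    # non-carrier lineages
    hap_is_a = (table["haplotype"] == "A").to_numpy()
    var_cop = np.where(hap_is_a[None, :], a_cop, b_cop).astype(float)
    cells = truth.cells
    carrier = np.zeros((len(cells), len(table)), dtype=bool)
    carrier_sets = [set(map(int, s.split(","))) if s else set()
                    for s in table["carrier_clones"]]
    clone_of = cells["clone"].to_numpy()
    klass = cells["class"].to_numpy()
    for j, cl_set in enumerate(carrier_sets):
        carrier[:, j] = [c in cl_set for c in clone_of]
        if table.iloc[j]["variant_id"] == "trunk_0":
            carrier[klass == "pseudo_diploid", j] = True
    # noisy/degraded cells inherit carrier status from their base profile
    for i in np.flatnonzero(np.isin(klass, ["noisy", "degraded"])):
        key = cells.iloc[i]["profile"]
        if key.startswith(("clone", "wgd")):
            cl = int(key.replace("wgd", "clone").split(".")[0][5:])
            carrier[i] = [cl in s for s in carrier_sets]
    # doublets carry what their sources carry (copy-weighted)
    var_cop_eff = np.where(carrier, var_cop, 0.0)
    for i in np.flatnonzero(klass == "doublet"):
        ia = cells.index.get_loc(cells.iloc[i]["source_a"])
        ib = cells.index.get_loc(cells.iloc[i]["source_b"])
        var_cop_eff[i] = var_cop_eff[ia] + var_cop_eff[ib]

    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(tot > 0, var_cop_eff / np.maximum(tot, 1), 0.0)
    e = config.sequencing_error
    vaf = vaf * (1 - e) + (1 - vaf) * e
    depth = rng.poisson(config.variant_depth_mean * np.maximum(tot, 0) / 2.0)
    alt = rng.binomial(depth, vaf)
    return table, alt.astype(np.int32), depth.astype(np.int32)


# ---------------------------------------------------------------------------
# spatial transcriptomics


def simulate_st_spots(config: SimConfig, panel: ClonePanel
                      ) -> Tuple[STSpotMatrix, pd.DataFrame,
                                 Dict[str, list]]:
    """Visium-like spot x gene counts with planted clone territories.

    Expression follows copy-number dosage: the tumor fraction of a spot
    contributes gene means scaled by local clone CN / 2; the stromal
    fraction contributes a flat diploid baseline with elevated stromal
    and immune signature genes. Clone territories are contiguous,
    disjoint rectangles. Returns (matrix, spot_truth, signatures).
    """
    rng = _rng(config, "st")
    genome_mb = config.n_bins * BIN_SIZE / 1e6
    n_genes = max(10, round(genome_mb * config.st_genes_per_mb))
    chrom_len = config.bins_per_chromosome * BIN_SIZE
    pos = np.sort(rng.choice(config.n_bins * BIN_SIZE, size=n_genes,
                             replace=False))
    gene_ids = [f"gene_{i:05d}" for i in range(n_genes)]

    n_sig = config.st_signature_genes
    sig_pos = rng.choice(config.n_bins * BIN_SIZE, size=2 * n_sig,
                         replace=False)
    stromal_ids = [f"stromal_{i:03d}" for i in range(n_sig)]
    immune_ids = [f"immune_{i:03d}" for i in range(n_sig)]

    all_ids = gene_ids + stromal_ids + immune_ids
    all_pos = np.concatenate([pos, sig_pos])
    genes = pd.DataFrame({"chrom": [f"chr{p // chrom_len + 1}"
                                    for p in all_pos],
                          "start": all_pos % chrom_len},
                         index=pd.Index(all_ids, name="gene"))

    # baseline means; signature genes low in tumor, high in their niche
    base = rng.lognormal(math.log(config.st_mean_counts_per_gene), 0.6,
                         size=len(all_ids))
    tumor_factor = np.ones(len(all_ids))
    stromal_factor = np.ones(len(all_ids))
    sl_str = slice(n_genes, n_genes + n_sig)
    sl_imm = slice(n_genes + n_sig, None)
    tumor_factor[sl_str] = tumor_factor[sl_imm] = 0.1
    stromal_factor[sl_str] = stromal_factor[sl_imm] = 5.0

    fine_idx = np.minimum(all_pos // BIN_SIZE, config.n_bins - 1)
    clone_dosage = np.ones((config.n_clones, len(all_ids)))
    for clone in range(config.n_clones):
        clone_dosage[clone] = panel.total(panel.base_key(clone))[fine_idx] / 2.0

    # grid with a stromal ring around a central tumor rectangle
    side = math.ceil(math.sqrt(config.st_n_spots))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    xs, ys = xs.ravel()[:config.st_n_spots], ys.ravel()[:config.st_n_spots]
    inner = math.sqrt(1.0 - config.st_stromal_fraction)
    lo, hi = (1 - inner) / 2 * side, (1 + inner) / 2 * side
    in_tumor = (xs >= lo) & (xs < hi) & (ys >= lo) & (ys < hi)
    frac_x = np.clip((xs - lo) / max(hi - lo, 1e-9), 0, 1)
    cum = np.cumsum(config.clone_fractions)
    clone_of_spot = np.searchsorted(cum, frac_x, side="right")
    clone_of_spot = np.minimum(clone_of_spot, config.n_clones - 1)
    clone_of_spot = np.where(in_tumor, clone_of_spot, -1)

    w_t = np.where(in_tumor, config.st_tumor_purity, 0.0)
    mean = np.empty((config.st_n_spots, len(all_ids)))
    for s in range(config.st_n_spots):
        c = clone_of_spot[s]
        dosage = clone_dosage[c] if c >= 0 else np.ones(len(all_ids))
        mean[s] = base * (w_t[s] * tumor_factor * dosage
                          + (1 - w_t[s]) * stromal_factor)
    counts = rng.poisson(mean).astype(np.int32)

    spot_ids = pd.Index([f"spot_{i:04d}" for i in range(config.st_n_spots)],
                        name="barcode")
    spots = pd.DataFrame({"x": xs, "y": ys}, index=spot_ids)
    region = np.where(clone_of_spot >= 0,
                      [f"clone{c}" for c in clone_of_spot], "stroma")
    spot_truth = pd.DataFrame({"region": region, "tumor_weight": w_t,
                               "clone": clone_of_spot}, index=spot_ids)
    signatures = {"stromal": stromal_ids, "immune": immune_ids}
    return STSpotMatrix(spots, genes, counts), spot_truth, signatures


# ---------------------------------------------------------------------------
# one-call bundle


@dataclass
class SimBundle:
    config: SimConfig
    panel: ClonePanel
    matrix: CellCNMatrix
    truth: SimTruth
    alleles: AlleleCounts
    variants: pd.DataFrame
    variant_alt: np.ndarray
    variant_depth: np.ndarray
    st: STSpotMatrix
    spot_truth: pd.DataFrame
    signatures: Dict[str, list]


def simulate(config: Optional[SimConfig] = None) -> SimBundle:
    """Run every generator stage under one config (one seed)."""
    config = config or SimConfig()
    panel = simulate_clone_profiles(config)
    matrix, truth = simulate_cells(config, panel)
    alleles = simulate_allele_counts(config, panel, truth)
    variants, alt, depth = simulate_variants(config, panel, truth)
    st, spot_truth, signatures = simulate_st_spots(config, panel)
    truth.spot_truth = spot_truth
    return SimBundle(config, panel, matrix, truth, alleles, variants, alt,
                     depth, st, spot_truth, signatures)
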