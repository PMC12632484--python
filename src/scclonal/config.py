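"""Configuration objects for the simulator and the pipeline.

All randomness in the package flows from the single ``seed`` field of the
relevant config; stages derive child generators via
:func:`numpy.random.default_rng` spawning so that a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

BIN_SIZE = 20_000          # fine CN-call bin width (bp)
COARSE_BINS = 500          # fine bins per aggregation window (10 Mb)
COARSE_SIZE = BIN_SIZE * COARSE_BINS


def _check_prop(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SimConfig:
    """Parameters of the synthetic scDNA-seq + Visium study.

    The defaults define the study conditions every downstream default and
    test refers to: a diploid admixture, two tumor clones sharing trunk
    events, subclonal WGD of the later clone, doublets, replication-noisy
    and degraded (apoptotic-like) cells, pseudo-diploid cells, and a
    spatially organised two-clone Visium section with stromal
    contamination.
    """

    # genome
    n_chromosomes: int = 12
    bins_per_chromosome: int = 3000        # 20 kb bins -> 60 Mb chromosomes

    # cell composition
    n_cells: int = 1000
    n_clones: int = 2
    clone_fractions: Sequence[float] = (0.30, 0.70)   # of tumor cells
    diploid_fraction: float = 0.18
    wgd_fraction_per_clone: Sequence[float] = (0.0, 0.40)
    subclones_per_clone: Sequence[int] = (1, 2)
    doublet_rate: float = 0.03
    noisy_cell_rate: float = 0.05
    degraded_cell_rate: float = 0.03
    artifact_even_rate: float = 0.01       # all-even "overfit" cells
    pseudo_diploid_rate: float = 0.01

    # CN call noise model: per-bin perturbation probability scales with
    # local copy number (rate * cn/2), perturbations are +/-1 calls
    cn_noise_rate: float = 0.02
    noisy_cell_noise_rate: float = 0.45
    degraded_dropout_range: Sequence[float] = (0.3, 0.7)
    pseudo_gain_overlap: float = 0.9       # fraction of pseudo-diploid gains
    #                                        placed at clone-gained bins
    low_quality_fraction: float = 0.05     # per-call quality < 15
    low_mappability_fraction: float = 0.03  # bins with mappability < 0.90
    low_ploidy_confidence_rate: float = 0.01

    # allele / variant model
    reads_per_cell_mean: int = 150_000
    snp_density: float = 1.0               # heterozygous SNPs per Mb
    snp_depth_mean: float = 12.0           # reads per SNP per cell
    sequencing_error: float = 0.001
    n_trunk_variants: int = 5
    n_private_variants: int = 3            # per clone
    variant_depth_mean: float = 2.0        # reads per cell per variant site
    n_random_events: int = 2               # extra private CNAs per clone

    # spatial transcriptomics
    st_n_spots: int = 2000
    st_stromal_fraction: float = 0.30
    st_genes_per_mb: float = 2.0
    st_mean_counts_per_gene: float = 6.0
    st_signature_genes: int = 30           # per signature (stromal, immune)
    st_tumor_purity: float = 0.85          # tumor fraction in tumor spots

    plant_special_events: bool = True      # mirrored segment, CN-LOH, reversion
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("diploid_fraction", "doublet_rate", "noisy_cell_rate",
                     "degraded_cell_rate", "artifact_even_rate",
                     "pseudo_diploid_rate", "cn_noise_rate",
                     "noisy_cell_noise_rate", "pseudo_gain_overlap",
                     "low_quality_fraction", "low_mappability_fraction",
                     "low_ploidy_confidence_rate", "sequencing_error",
                     "st_stromal_fraction", "st_tumor_purity"):
            _check_prop(name, getattr(self, name))
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if len(self.clone_fractions) != self.n_clones:
            raise ValueError("clone_fractions length must equal n_clones")
        if abs(sum(self.clone_fractions) - 1.0) > 1e-9:
            raise ValueError("clone_fractions must sum to 1")
        for f in self.clone_fractions:
            _check_prop("clone_fractions", f)
        if len(self.wgd_fraction_per_clone) != self.n_clones:
            raise ValueError("wgd_fraction_per_clone length must equal n_clones")
        for f in self.wgd_fraction_per_clone:
            _check_prop("wgd_fraction_per_clone", f)
        if len(self.subclones_per_clone) != self.n_clones:
            raise ValueError("subclones_per_clone length must equal n_clones")
        total = (self.diploid_fraction + self.doublet_rate
                 + self.noisy_cell_rate + self.degraded_cell_rate
                 + self.artifact_even_rate + self.pseudo_diploid_rate)
        if total >= 1.0:
            raise ValueError("non-tumor cell fractions sum to >= 1")

    @property
    def n_bins(self) -> int:
        return self.n_chromosomes * self.bins_per_chromosome

    @property
    def coarse_per_chromosome(self) -> int:
        return -(-self.bins_per_chromosome // COARSE_BINS)

    @property
    def n_coarse_bins(self) -> int:
        return self.n_chromosomes * self.coarse_per_chromosome

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Threshold defaults follow the source protocol where it states them
    (call quality 15, mappability 0.90, noisy-cell alpha 0.1, 500-bin
    aggregation windows, k_max 20, 50 kb BAF bins, 100 kb pooled-BAF
    blocks, 10 Mb RDR bins, ST purity cut 0.7); the remaining defaults are
    this package's own calibration choices and are flagged ``choice`` in
    the provenance block that :func:`scclonal.pipeline.run_pipeline`
    emits.
    """

    sim: SimConfig = field(default_factory=SimConfig)

    # qc
    alpha: float = 0.1
    min_quality: float = 15.0
    min_mappability: float = 0.90

    # clustering
    bins_per_window: int = COARSE_BINS
    k_max: int = 20
    n_restarts: int = 10
    min_subcluster_size: int = 5

    # doublets / artifacts
    doublet_threshold: float = 0.35
    odd_region_exempt_diploid: bool = True

    # allele / LOH
    baf_bin_size: int = 50_000
    baf_block_size: int = 100_000
    rdr_bin_size: int = 10_000_000
    error_floor: float = 0.01

    # variants / pseudo-diploid
    min_alt_reads: int = 2
    pseudo_score_threshold: float = 0.15
    min_aberrant_bins: int = 3

    # spatial
    purity_threshold: float = 0.7
    smoothing_window: int = 21
    hmm_state_shift: float = 0.2
    hmm_stay_prob: float = 1.0 - 1e-4
    leiden_resolution: float = 0.5
    knn_neighbors: int = 15
    match_margin: float = 0.1

    seed: int = 0

    # which defaults are stated by the source protocol (for provenance)
    PAPER_DEFAULTS = ("alpha", "min_quality", "min_mappability",
                      "bins_per_window", "k_max", "baf_bin_size",
                      "baf_block_size", "rdr_bin_size", "purity_threshold")

    def provenance(self) -> dict:
        out = {}
        for key, val in asdict(self).items():
            if key == "sim":
                continue
            out[key] = {"value": val,
                        "origin": "protocol" if key in self.PAPER_DEFAULTS
                        else "choice"}
        return out
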