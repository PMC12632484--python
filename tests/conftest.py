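import numpy as np
import pandas as pd
import pytest

from scclonal.config import RunConfig, SimConfig
from scclonal.containers import CellCNMatrix
from scclonal import simulate as sim


def make_matrix(cn, quality=None, mappability=None, chroms=None,
                mask=None):
    """Small CellCNMatrix builder for unit tests (20 kb bins, chr1)."""
    cn = np.asarray(cn, dtype=np.int16)
    n, m = cn.shape
    if quality is None:
        quality = np.full((n, m), 30.0)
    if mappability is None:
        mappability = np.ones(m)
    if chroms is None:
        chroms = ["chr1"] * m
    start = []
    pos = {}
    for c in chroms:
        pos.setdefault(c, 0)
        start.append(pos[c] * 20_000)
        pos[c] += 1
    bins = pd.DataFrame({"chrom": chroms, "start": start,
                         "end": [s + 20_000 for s in start],
                         "mappability": mappability})
    barcodes = pd.Index([f"c{i}" for i in range(n)])
    return CellCNMatrix(barcodes, bins, cn,
                        np.asarray(quality, dtype=float), mask)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale study: 6 chromosomes, 300 cells, 600 spots."""
    return SimConfig(seed=11, n_chromosomes=6, n_cells=300, st_n_spots=600)


@pytest.fixture(scope="session")
def small_bundle(small_cfg):
    return sim.simulate(small_cfg)


@pytest.fixture(scope="session")
def default_report():
    """One full-pipeline run at the default (~1000-cell) scale."""
    from scclonal.pipeline import run_pipeline
    return run_pipeline(RunConfig(seed=1))
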