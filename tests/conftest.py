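import logging

import numpy as np
import pytest

from tribestamp.calling import APOBEC, Thresholds
from tribestamp.countmatrix import matrix_from_rows
from tribestamp.simulate import SimulationParams, simulate_experiment

logging.getLogger("tribestamp").setLevel(logging.ERROR)


def make_matrix(rows, **kwargs):
    """rows: list of (contig, position, (A, C, G, T))."""
    return matrix_from_rows(rows, **kwargs)


def random_matrix(rng, n_positions, contigs=("chr1", "chr2"), max_cov=200):
    """A random count matrix with plenty of boundary-adjacent rows."""
    rows = []
    per = n_positions // len(contigs)
    for contig in contigs:
        positions = np.sort(rng.choice(np.arange(1, per * 10), size=per,
                                       replace=False))
        cov = rng.integers(0, max_cov, size=per)
        for pos, c in zip(positions, cov):
            if c == 0:
                counts = np.zeros(4, dtype=int)
            else:
                # skew toward one dominant base so control criteria trigger
                major = rng.integers(0, 4)
                p = np.full(4, 0.05)
                p[major] = 0.85
                counts = rng.multinomial(int(c), p)
            rows.append((contig, int(pos), tuple(int(x) for x in counts)))
    return make_matrix(rows)


@pytest.fixture(scope="session")
def default_thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def adar_experiment():
    """Moderate-size ADAR simulation shared across tests (seed 7)."""
    params = SimulationParams(n_transcripts=60, n_truth_sites=120,
                              n_background_sites=30)
    return params, simulate_experiment(params, 7)


@pytest.fixture(scope="session")
def apobec_jitter_experiment():
    """APOBEC-style simulation with inter-replicate jitter (seed 11)."""
    params = SimulationParams(enzyme=APOBEC, rep_jitter_bp=80,
                              n_transcripts=80, n_truth_sites=150,
                              n_background_sites=0)
    return params, simulate_experiment(params, 11)
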