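"""Shared fixtures: synthetic benchmarks and trained models.

The heavier artefacts (encoded matrices, feature selection, trained
ensembles) are session-scoped so the training cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from methsemble import encode, learn, select, simdata

# fixed study conditions for the recovery experiments
TRAIN_SEED, TEST_SEED = 11, 12
N_TRAIN, N_TEST = 2000, 500
SCAN_SEED_A, SCAN_SEED_B = 21, 22
N_SCAN_TRAIN = 400


@pytest.fixture(scope="session")
def strong_benchmarks():
    """Separation-1 train (2000/2000) and test (500/500) window sets."""
    train = simdata.generate_benchmark(N_TRAIN, N_TRAIN, 1.0, seed=TRAIN_SEED)
    test = simdata.generate_benchmark(N_TEST, N_TEST, 1.0, seed=TEST_SEED)
    return train, test


@pytest.fixture(scope="session")
def strong_matrices(strong_benchmarks):
    train, test = strong_benchmarks
    return (encode.encode_matrix(train.windows),
            encode.encode_matrix(test.windows))


@pytest.fixture(scope="session")
def strong_selection(strong_benchmarks, strong_matrices):
    train, _ = strong_benchmarks
    Xtr, _ = strong_matrices
    return select.hybrid_select(Xtr, train.labels, top_n=40, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def strong_model(strong_benchmarks, strong_matrices, strong_selection):
    train, _ = strong_benchmarks
    Xtr, _ = strong_matrices
    return learn.train_ensemble(Xtr, train.labels,
                                strong_selection.selected,
                                species_tag="rice", seed=TRAIN_SEED)


def build_scan_model(seed: int, species: str, n: int = N_SCAN_TRAIN):
    """Full pipeline (generate -> encode -> select -> train) at desk scale."""
    bench = simdata.generate_benchmark(n, n, 1.0, seed=seed)
    X = encode.encode_matrix(bench.windows)
    sel = select.hybrid_select(X, bench.labels, top_n=40, seed=seed)
    return learn.train_ensemble(X, bench.labels, sel.selected,
                                species_tag=species, seed=seed)


@pytest.fixture(scope="session")
def scan_model_pair():
    """Two independently trained 'species' models for intersection scans."""
    return (build_scan_model(SCAN_SEED_A, "rice"),
            build_scan_model(SCAN_SEED_B, "arabidopsis"))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
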