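"""Shared fixtures: synthetic corpora at the benchmark study conditions."""

import numpy as np
import pytest

import m5csub as m


BENCH_SEED = 7


@pytest.fixture(scope="session")
def planted_benchmark():
    """500 windows/class, planting rate 0.9: the signal-recovery conditions."""
    corpus = m.simulate_corpus(m.SimConfig(seed=BENCH_SEED))
    pos, neg = m.make_labeled_windows(corpus)
    windows = [w.sequence for w in pos + neg]
    labels = np.array([w.label for w in pos + neg])
    return corpus, windows, labels


@pytest.fixture(scope="session")
def null_benchmark():
    """Same conditions with planting rate 0: labels carry no signal."""
    corpus = m.simulate_corpus(m.SimConfig(seed=BENCH_SEED, planting_rate=0.0))
    pos, neg = m.make_labeled_windows(corpus)
    windows = [w.sequence for w in pos + neg]
    labels = np.array([w.label for w in pos + neg])
    return corpus, windows, labels


@pytest.fixture(scope="session")
def small_corpus():
    """A small corpus exercising every pipeline stage, incl. IVT decoys."""
    return m.simulate_corpus(
        m.SimConfig(n_transcripts=20, n_pos=150, n_unbound=40, n_ivt=10, seed=3)
    )


@pytest.fixture(scope="session")
def pc_table():
    return m.PCTable.default()
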