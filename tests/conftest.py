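import numpy as np
import pytest

from hfovar.datatypes import EpochRateMatrix


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def rank1_matrix(w, h):
    """Noiseless one-source rate matrix as an EpochRateMatrix."""
    w = np.asarray(w, dtype=float)
    h = np.asarray(h, dtype=float)
    R = np.outer(w, h)
    return EpochRateMatrix(
        R=R,
        epoch_start=np.arange(len(h)) * 600.0,
        analyzed_min=np.full(len(h), 10.0),
        channel_labels=[f"ch{i:02d}" for i in range(len(w))],
    )


def block_rank_k(K, n_ch=9, n_ep=60):
    """Noiseless rank-K matrix from K disjoint channel/epoch blocks.

    Disjoint supports make every factor pair's Spearman correlation
    negative, satisfying the construction requirement of the K-selection
    benchmark.
    """
    W = np.zeros((n_ch, K))
    H = np.zeros((K, n_ep))
    chs = np.array_split(np.arange(n_ch), K)
    eps_ = np.array_split(np.arange(n_ep), K)
    for k in range(K):
        W[chs[k], k] = np.linspace(1.0, 0.5, len(chs[k]))
        H[k, eps_[k]] = 2.0 + np.sin(np.arange(len(eps_[k])))
    return W @ H
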