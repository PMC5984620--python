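"""Blind source separation and categorization of HFO-rate variability.

The channel-by-epoch rate matrix R is factorized as R = W x H by
non-negative matrix factorization: W holds each channel's membership weight
in each source (group of channels with a common temporal evolution) and H
the effective HFO rate of each source per 10-min epoch. The number of
sources K is selected by starting at min(n_channels, n_epochs, 12) and
decrementing whenever any pair of sources is redundant, i.e. the Spearman
correlation between two rows of H (time) or two columns of W (space)
exceeds 0.30.

Each recording is then placed in one of four variability categories:

a. one source, consistently active: at least 40% of epochs above the mean
   effective rate and at most 5% of epochs with zero HFOs;
b. one source that comes and goes (fails the consistency rule);
c. multiple sources with independent temporal evolution (K > 1);
d. too few HFOs to categorize: every channel below 0.5 HFOs/min in every
   epoch (decided without running NMF).

Because NMF is stochastic, the categorization is repeated 10 times from
different random initializations and the modal label wins; ties go to the
more complex category (c > b > a).

The module exposes both the individual operations and a statsmodels-style
pair :class:`RateVariabilityModel` / :class:`VariabilityResults`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import EpochRateMatrix

__all__ = [
    "CategorizerParams",
    "SourceModel",
    "CategoryResult",
    "nmf_decompose",
    "select_k",
    "classify_once",
    "classify",
    "source_channels",
    "RateVariabilityModel",
    "VariabilityResults",
]

#: complexity order used for tie-breaks (most complex first)
COMPLEXITY = ("c", "b", "a", "d")

_SEED_MOD = 2**31


@dataclass(frozen=True)
class CategorizerParams:
    """Thresholds of the categorization algorithm.

    ``k_cap`` bounds the initial source count; ``corr_threshold`` is the
    Spearman redundancy threshold of the K-selection loop;
    ``consistency_frac`` and ``zero_frac`` define the category-(a)
    consistency rule; ``min_rate`` (HFOs/min) defines category (d);
    ``n_rep`` is the number of repeated categorizations voted over.
    """

    k_cap: int = 12
    corr_threshold: float = 0.30
    consistency_frac: float = 0.40
    zero_frac: float = 0.05
    min_rate: float = 0.5
    n_rep: int = 10
    zero_tol: float = 1e-12     # NMF rarely emits exact zeros
    max_iter: int = 500
    tol: float = 1e-6

    def __post_init__(self) -> None:
        for name in ("corr_threshold", "consistency_frac", "zero_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.k_cap < 1:
            raise ValueError("k_cap must be >= 1")


@dataclass
class SourceModel:
    """One NMF factorization R ~ W x H with the rate-scaling convention.

    A single global scale factor is moved from W into H so that the mean
    over epochs of the summed effective source rate equals the mean entry
    of W x H; H is therefore in HFOs/min.
    """

    K: int
    W: np.ndarray
    H: np.ndarray
    seed: int
    reconstruction_error: float

    def __post_init__(self) -> None:
        if np.any(self.W < 0) or np.any(self.H < 0):
            raise ValueError("NMF factors must be non-negative")


@dataclass
class CategoryResult:
    """Final variability label with the per-repetition votes."""

    label: str
    votes: list[str]
    K_per_rep: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in {"a", "b", "c", "d"}:
            raise ValueError(f"unknown category {self.label!r}")
        if self.label != _modal_label(self.votes):
            raise ValueError("label must be the modal vote (complexity tie-break)")


def _modal_label(votes) -> str:
    counts = Counter(votes)
    best = max(counts.values())
    # ties resolved toward greater complexity
    for lab in COMPLEXITY:
        if counts.get(lab, 0) == best:
            return lab
    raise ValueError("empty vote list")


def _as_matrix(R) -> np.ndarray:
    if isinstance(R, EpochRateMatrix):
        return R.R
    return np.asarray(R, dtype=float)


# ---------------------------------------------------------------------------
# operations

def _mu_loop_py(X, W, H, max_iter, tol):
    eps = 1e-10
    err0 = np.linalg.norm(X - W @ H)
    prev = err0
    for it in range(max_iter):
        H *= (W.T @ X) / np.maximum(W.T @ W @ H, eps)
        W *= (X @ H.T) / np.maximum(W @ (H @ H.T), eps)
        if (it + 1) % 10 == 0:
            err = np.linalg.norm(X - W @ H)
            if err0 > 0 and (prev - err) / err0 < tol:
                break
            prev = err
    return W, H

try:  # jit the inner loop when numba is available; identical arithmetic
    from numba import njit

    _mu_loop = njit(cache=True)(_mu_loop_py)
except ImportError:  # pragma: no cover
    _mu_loop = _mu_loop_py


def _nmf_mu(X: np.ndarray, K: int, seed: int, max_iter: int,
            tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Frobenius-loss NMF by multiplicative updates.

    Uniform-random initialization scaled to the data magnitude; convergence
    checked every 10 iterations against ``tol`` times the initial error
    (relative decrease). A zero data column drives the matching H entries
    to exact zero in the first update.
    """
    rng = np.random.default_rng(seed)
    avg = np.sqrt(X.mean() / K)
    W = avg * (rng.random((X.shape[0], K)) + 1e-3)
    H = avg * (rng.random((K, X.shape[1])) + 1e-3)
    return _mu_loop(np.ascontiguousarray(X), W, H, max_iter, tol)


def nmf_decompose(R, K: int, seed: int = 0,
                  params: CategorizerParams | None = None) -> SourceModel:
    """Seeded NMF of the rate matrix with Frobenius loss.

    Multiplicative updates from a uniform-random initialization, at most
    ``params.max_iter`` iterations, relative tolerance ``params.tol``.
    """
    params = params or CategorizerParams()
    X = _as_matrix(R)
    if np.any(X < 0):
        raise ValueError("rate matrix must be non-negative")
    if not np.any(X > 0):
        raise ValueError("all-zero rate matrix has no source structure")
    if K > min(X.shape):
        raise ValueError("K cannot exceed min(n_channels, n_epochs)")
    W, H = _nmf_mu(X, K, int(seed) % _SEED_MOD, params.max_iter, params.tol)
    # move a global scale from W into H: mean summed effective rate per
    # epoch equals the mean entry of W x H
    approx = W @ H
    h_epoch = H.sum(axis=0).mean()
    if h_epoch > 0:
        s = approx.mean() / h_epoch
        H = H * s
        W = W / s
    err = np.linalg.norm(X - approx) / max(np.linalg.norm(X), 1e-300)
    return SourceModel(K=K, W=W, H=H, seed=int(seed) % _SEED_MOD,
                       reconstruction_error=float(err))


def _max_pairwise_spearman(M: np.ndarray) -> float:
    """Largest signed Spearman correlation over row pairs of ``M``.

    Computed as the Pearson correlation of midranks (identical to the
    tie-corrected Spearman statistic). A degenerate (constant) factor makes
    the correlation undefined; such a pair is reported as +inf so the
    caller treats the factorization as redundant and reduces K.
    """
    if M.shape[0] < 2:
        return -np.inf
    ranks = stats.rankdata(M, axis=1)
    if np.any(ranks.std(axis=1) == 0):
        return np.inf
    C = np.corrcoef(ranks)
    iu = np.triu_indices_from(C, k=1)
    return float(C[iu].max())


def select_k(R, params: CategorizerParams | None = None,
             seed: int = 0) -> SourceModel:
    """Decrementing-K source-count selection.

    K starts at min(n_epochs, n_channels, k_cap). After each fit, if any
    pairwise Spearman correlation among rows of H or among columns of W
    exceeds the threshold, K is decremented and the fit repeated (from a
    fresh initialization, seed offset by K); the loop stops when no pair is
    redundant or K = 1.
    """
    params = params or CategorizerParams()
    X = _as_matrix(R)
    K = min(X.shape[0], X.shape[1], params.k_cap)
    while True:
        model = nmf_decompose(X, K, seed=(int(seed) + K) % _SEED_MOD,
                              params=params)
        if K == 1:
            return model
        worst = max(_max_pairwise_spearman(model.H),
                    _max_pairwise_spearman(model.W.T))
        if worst <= params.corr_threshold:
            return model
        K -= 1


def _consistency_label(h: np.ndarray, params: CategorizerParams) -> str:
    """Apply the category-(a) consistency rule to a single source's rates."""
    frac_above = float(np.mean(h > h.mean()))
    frac_zero = float(np.mean(h <= params.zero_tol))
    if frac_above >= params.consistency_frac and frac_zero <= params.zero_frac:
        return "a"
    return "b"


def is_category_d(R, params: CategorizerParams | None = None) -> bool:
    """Deterministic, NMF-free check: every channel < 0.5 HFOs/min always."""
    params = params or CategorizerParams()
    return bool(np.all(_as_matrix(R) < params.min_rate))


def classify_once(R, params: CategorizerParams | None = None,
                  seed: int = 0) -> tuple[str, SourceModel | None]:
    """One categorization pass; returns ``(label, fitted model or None)``."""
    params = params or CategorizerParams()
    if is_category_d(R, params):
        return "d", None
    model = select_k(R, params, seed=seed)
    if model.K > 1:
        return "c", model
    return _consistency_label(model.H[0], params), model


def classify(R, params: CategorizerParams | None = None,
             seed: int = 0) -> CategoryResult:
    """Repeated categorization with a majority vote.

    ``n_rep`` independent passes are run from distinct seeds derived from
    ``seed``; the final label is the modal vote with ties broken toward the
    more complex category. Category (d) is deterministic and short-circuits
    the vote.
    """
    params = params or CategorizerParams()
    if is_category_d(R, params):
        return CategoryResult("d", ["d"] * params.n_rep, [0] * params.n_rep)
    votes, ks = [], []
    for rep in range(params.n_rep):
        label, model = classify_once(R, params,
                                     seed=(int(seed) * 1009 + rep) % _SEED_MOD)
        votes.append(label)
        ks.append(model.K if model is not None else 0)
    return CategoryResult(_modal_label(votes), votes, ks)


def source_channels(model: SourceModel, frac: float = 0.5) -> list[list[int]]:
    """Channels most involved with each source.

    For source k, the channels whose weight reaches ``frac`` of the source's
    maximum weight. An all-zero column yields an empty set.
    """
    out = []
    for k in range(model.K):
        col = model.W[:, k]
        m = col.max()
        if m <= 0:
            out.append([])
        else:
            out.append(np.flatnonzero(col >= frac * m).tolist())
    return out


# ---------------------------------------------------------------------------
# model / results surface

class RateVariabilityModel:
    """Spatiotemporal-variability model of a channel-by-epoch HFO-rate matrix.

    Parameters
    ----------
    rates : EpochRateMatrix, DataFrame or ndarray (channels x epochs)
    params : CategorizerParams, optional

    Examples
    --------
    >>> model = RateVariabilityModel(rate_matrix)
    >>> res = model.fit(seed=7)
    >>> res.label
    'c'
    """

    def __init__(self, rates, params: CategorizerParams | None = None):
        self.params = params or CategorizerParams()
        if isinstance(rates, EpochRateMatrix):
            self.data = rates
            self.endog = rates.R
            self.channel_labels = list(rates.channel_labels)
        elif isinstance(rates, pd.DataFrame):
            self.data = None
            self.endog = rates.to_numpy(dtype=float)
            self.channel_labels = [str(c) for c in rates.index]
        else:
            self.data = None
            self.endog = np.asarray(rates, dtype=float)
            self.channel_labels = [f"ch{i:02d}" for i in range(self.endog.shape[0])]
        if self.endog.ndim != 2:
            raise ValueError("rates must be 2-D (channels x epochs)")
        if np.any(self.endog < 0):
            raise ValueError("rates must be non-negative")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       params: CategorizerParams | None = None):
        """Build from a DataFrame with channels in rows, epochs in columns."""
        return cls(df, params=params)

    def fit(self, seed: int = 0) -> "VariabilityResults":
        """Run the repeated categorization and keep a representative fit."""
        result = classify(self.endog, self.params, seed=seed)
        model = None
        if result.label != "d":
            # refit the representative pass: first repetition that voted
            # with the majority
            rep = result.votes.index(result.label)
            _, model = classify_once(self.endog, self.params,
                                     seed=(int(seed) * 1009 + rep) % _SEED_MOD)
        return VariabilityResults(self, result, model, seed)


class VariabilityResults:
    """Fitted categorization: label, votes, and the representative factors."""

    def __init__(self, model: RateVariabilityModel, category: CategoryResult,
                 source_model: SourceModel | None, seed: int):
        self.model = model
        self.category = category
        self.source_model = source_model
        self.seed = seed

    @property
    def label(self) -> str:
        return self.category.label

    @property
    def votes(self) -> list[str]:
        return self.category.votes

    @property
    def K(self) -> int:
        return self.source_model.K if self.source_model is not None else 0

    @property
    def W(self) -> np.ndarray | None:
        return None if self.source_model is None else self.source_model.W

    @property
    def H(self) -> np.ndarray | None:
        return None if self.source_model is None else self.source_model.H

    def source_channels(self, frac: float = 0.5):
        if self.source_model is None:
            return []
        return source_channels(self.source_model, frac=frac)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        names = {
            "a": "one consistent source",
            "b": "one intermittent source",
            "c": "multiple independent sources",
            "d": "too few HFOs",
        }
        n_ch, n_ep = self.model.endog.shape
        lines = [
            "HFO-rate variability categorization",
            "=" * 51,
            f"channels: {n_ch:>5d}    epochs: {n_ep:>5d}",
            f"category: {self.label}  ({names[self.label]})",
            f"votes:    {''.join(self.votes)}   (n_rep={len(self.votes)})",
            f"K per repetition: {self.category.K_per_rep}",
        ]
        if self.source_model is not None:
            sm = self.source_model
            lines.append(f"representative fit: K={sm.K}, "
                         f"rel. reconstruction error={sm.reconstruction_error:.3g}")
            labels = self.model.channel_labels
            for k, chans in enumerate(self.source_channels()):
                named = ", ".join(labels[c] for c in chans)
                rate = sm.H[k].mean()
                lines.append(f"  source {k + 1}: mean {rate:5.2f} HFOs/min; "
                             f"channels: {named}")
        lines.append("=" * 51)
        return "\n".join(lines)

    def plot_sources(self, axes=None):
        """Heatmap of W (channels x sources) and traces of H (sources x time)."""
        import matplotlib.pyplot as plt
        if self.source_model is None:
            raise ValueError("category d has no fitted sources")
        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 4),
                                   gridspec_kw={"width_ratios": [1, 3]})
        ax_w, ax_h = axes
        ax_w.imshow(self.source_model.W, aspect="auto", cmap="viridis")
        ax_w.set_xlabel("source")
        ax_w.set_ylabel("channel")
        for k in range(self.K):
            ax_h.plot(self.source_model.H[k], label=f"source {k + 1}")
        ax_h.set_xlabel("epoch")
        ax_h.set_ylabel("effective rate (HFOs/min)")
        ax_h.legend(frameon=False)
        return axes
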