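"""HFO-rate asymmetry between the seizure onset zone and the rest.

The asymmetry A = (mean rate inside SOZ - mean rate outside) /
(mean inside + mean outside) behaves like a correlation: +1 when all HFOs
are inside the SOZ, -1 when all are outside, 0 when the mean rates are
equal. It is only computed when at least one channel in the tested scope
exceeds 0.5 HFOs/min, since lower rates are unlikely to reflect epileptic
activity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AsymmetryResult",
    "rate_asymmetry",
    "asymmetry_distributions",
    "asymmetry_tests",
    "max_channel_analysis",
    "MIN_RATE_HFO_PER_MIN",
]

MIN_RATE_HFO_PER_MIN = 0.5


@dataclass(frozen=True)
class AsymmetryResult:
    """One asymmetry value, or an exclusion with its reason."""

    value: float | None
    scope: str = "epoch"            # "epoch" | "subject"
    excluded: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.value is not None and not -1.0 - 1e-12 <= self.value <= 1.0 + 1e-12:
            raise ValueError("asymmetry must lie in [-1, 1]")


def rate_asymmetry(rates, soz_mask, scope: str = "epoch") -> AsymmetryResult:
    """Asymmetry of per-channel rates with respect to the SOZ mask.

    Excluded (value ``None``) when no channel exceeds 0.5 HFOs/min or when
    both means are zero.
    """
    rates = np.asarray(rates, dtype=float)
    soz_mask = np.asarray(soz_mask, dtype=bool)
    if rates.ndim != 1 or rates.shape != soz_mask.shape:
        raise ValueError("rates and soz_mask must be matching 1-D arrays")
    if not soz_mask.any() or soz_mask.all():
        raise ValueError("SOZ mask needs >= 1 channel inside and outside")
    if rates.max(initial=0.0) <= MIN_RATE_HFO_PER_MIN:
        return AsymmetryResult(None, scope, True,
                               f"no channel above {MIN_RATE_HFO_PER_MIN} HFOs/min")
    mean_in = rates[soz_mask].mean()
    mean_out = rates[~soz_mask].mean()
    denom = mean_in + mean_out
    if denom == 0.0:
        return AsymmetryResult(None, scope, True, "zero mean rates")
    return AsymmetryResult((mean_in - mean_out) / denom, scope)


def asymmetry_distributions(rate_matrix, soz_mask=None):
    """Per-epoch asymmetries and the per-subject (time-averaged) asymmetry.

    The per-subject value uses rates averaged over all analyzed epochs,
    weighted by each epoch's analyzed minutes; exclusions are applied per
    value. Returns ``(list of per-epoch AsymmetryResult, subject AsymmetryResult)``.
    """
    mask = soz_mask if soz_mask is not None else rate_matrix.soz_mask
    if mask is None:
        raise ValueError("no SOZ mask available")
    per_epoch = [rate_asymmetry(rate_matrix.R[:, t], mask, scope="epoch")
                 for t in range(rate_matrix.n_epochs)]
    subject = rate_asymmetry(rate_matrix.time_average(), mask, scope="subject")
    return per_epoch, subject


def asymmetry_tests(values_a, values_b):
    """Nonparametric tests on asymmetry distributions.

    For each set, a right-tailed one-sample Wilcoxon signed-rank test of
    "median > 0"; between the sets, a two-sided Wilcoxon rank-sum test.
    Returns ``(p_median_a, p_median_b, p_between)``. Degenerate all-zero
    sets give p = 1.
    """
    a = _defined(values_a)
    b = _defined(values_b)
    if len(a) < 5 or len(b) < 5:
        raise ValueError("need >= 5 defined values per set")
    return (_signed_rank_right(a), _signed_rank_right(b),
            float(stats.ranksums(a, b).pvalue))

def _defined(values) -> np.ndarray:
    out = []
    for v in values:
        if isinstance(v, AsymmetryResult):
            if v.value is not None:
                out.append(v.value)
        elif v is not None and np.isfinite(v):
            out.append(float(v))
    return np.asarray(out, dtype=float)

def _signed_rank_right(x: np.ndarray) -> float:
    if np.all(x == 0):
        return 1.0
    return float(stats.wilcoxon(x, alternative="greater").pvalue)


def max_channel_analysis(rate_matrix):
    """Stability of the single highest-rate channel over epochs.

    For every epoch with any nonzero rate, find the channel with the
    maximum rate (ties go to the lowest channel index). Returns a dict with
    the per-epoch argmax (-1 for all-zero epochs), the percentage of epochs
    each channel is the maximum, and the percentage of epochs whose maximum
    channel falls in the SOZ / resected volume (when masks are known).
    """
    R = rate_matrix.R
    nz = R.max(axis=0) > 0
    argmax = np.where(nz, R.argmax(axis=0), -1)
    n_used = int(nz.sum())
    pct = {}
    for c, label in enumerate(rate_matrix.channel_labels):
        hits = int(np.sum(argmax[nz] == c))
        pct[label] = 100.0 * hits / n_used if n_used else 0.0
    out = {"argmax_channel": argmax, "pct_epochs_max": pct,
           "n_epochs_used": n_used}
    for name, mask in (("soz", rate_matrix.soz_mask),
                       ("rv", rate_matrix.rv_mask)):
        if mask is not None and n_used:
            inside = np.sum(mask[argmax[nz]])
            out[f"pct_max_in_{name}"] = 100.0 * float(inside) / n_used
        elif mask is not None:
            out[f"pct_max_in_{name}"] = 0.0
    return out
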