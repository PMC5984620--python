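"""Night-to-night consistency and stopping-time analysis of categorization.

Two clinically motivated questions: does the variability category obtained
from a standard 1-3 AM window change from night to night, and, if the
recording had been stopped at hour h, what category would all data up to h
have produced? During stretches without new data the most recent
determination is carried forward.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .datatypes import AnnotationSet, EpochRateMatrix, HFOEvent
from .epoching import compute_rates, nrem_segments, select_interictal, EPOCH_S
from .variability import CategorizerParams, CategoryResult, classify

__all__ = [
    "nightly_categories",
    "cumulative_category",
    "stabilization_summary",
    "cohort_stabilization",
]

DAY_S = 86400.0
NIGHT_WINDOW_S = (3600.0, 3 * 3600.0)       # 01:00-03:00 local clock


def nightly_categories(
    events: Sequence[HFOEvent],
    annotations: AnnotationSet,
    channel_labels: Sequence[str],
    record_duration_s: float,
    rec_start_clock_s: float = 0.0,
    window_s: tuple[float, float] = NIGHT_WINDOW_S,
    params: CategorizerParams | None = None,
    seed: int = 0,
) -> tuple[list[CategoryResult], int]:
    """Categorize each night's 1-3 AM data independently.

    ``rec_start_clock_s`` is the clock time (seconds after midnight) of
    recording start; event and annotation times are recording-relative.
    Nights with no analyzed time are skipped. Returns the per-night results
    and the number of distinct labels.
    """
    params = params or CategorizerParams()
    segments_all, redactions = _analysis_segments(annotations, record_duration_s)

    results: list[CategoryResult] = []
    n_nights = int(math.ceil((rec_start_clock_s + record_duration_s) / DAY_S))
    for night in range(n_nights + 1):
        lo = night * DAY_S + window_s[0] - rec_start_clock_s
        hi = night * DAY_S + window_s[1] - rec_start_clock_s
        win = [(max(lo, 0.0), min(hi, record_duration_s))]
        if win[0][1] <= win[0][0]:
            continue
        segs = _intersect(segments_all, win)
        if not segs:
            continue
        mat = compute_rates(events, segs, redactions,
                            channel_labels=channel_labels)
        if mat.n_epochs == 0:
            continue
        results.append(classify(mat, params, seed=seed))
    labels = {r.label for r in results}
    return results, len(labels)


def _analysis_segments(annotations: AnnotationSet, duration_s: float):
    """Interictal analysis segments: NREM bouts when stages exist, else the
    whole record; seizure margins removed either way."""
    if annotations.sleep_stages:
        segments, redactions = nrem_segments(annotations)
    else:
        segments, redactions = [(0.0, duration_s)], []
    segments = select_interictal(segments, annotations.seizures)
    return segments, redactions


def _intersect(a, b):
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if e > s:
                out.append((s, e))
    return out


def cumulative_category(
    rate_matrix: EpochRateMatrix,
    stop_hours: Sequence[float] | None = None,
    params: CategorizerParams | None = None,
    seed: int = 0,
) -> list[tuple[float, str | None]]:
    """Category as a function of the stopping hour.

    For each stopping hour h, all epochs starting before h are classified;
    hours before the first epoch are undefined (``None``); when no new epoch
    was added since the previous grid point the previous label is carried
    forward. The default grid is every integer hour from the first to the
    last epoch.
    """
    params = params or CategorizerParams()
    starts = rate_matrix.epoch_start
    if stop_hours is None:
        first = math.floor(starts.min() / 3600.0) + 1
        last = math.ceil((starts.max() + EPOCH_S) / 3600.0)
        stop_hours = list(range(first, last + 1))
    stop_hours = list(stop_hours)
    if not stop_hours:
        raise ValueError("stopping-hour grid is empty")

    out: list[tuple[float, str | None]] = []
    prev_n = -1
    prev_label: str | None = None
    for h in stop_hours:
        mask = starts < h * 3600.0
        n = int(mask.sum())
        if n == 0:
            label = None
        elif n == prev_n:
            label = prev_label          # no new data: carry forward
        else:
            label = classify(rate_matrix.select_epochs(mask),
                             params, seed=seed).label
        out.append((float(h), label))
        prev_n, prev_label = n, label
    return out


def stabilization_summary(
    labels_per_hour: Sequence[tuple[float, str | None]],
) -> float:
    """Hour of the last change in categorization (0 if it never changes).

    A "change at hour h" means the label at h differs from the label at the
    previous defined grid point; undefined leading hours are ignored.
    """
    last_change = 0.0
    prev: str | None = None
    for h, lab in labels_per_hour:
        if lab is None:
            continue
        if prev is not None and lab != prev:
            last_change = h
        prev = lab
    if prev is None:
        raise ValueError("no defined labels")
    return last_change


def cohort_stabilization(
    hours_to_last_change: Sequence[float],
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Cohort median time-to-last-change with a bootstrap 95% CI."""
    x = np.asarray(hours_to_last_change, dtype=float)
    if x.size == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    meds = np.median(rng.choice(x, size=(n_boot, x.size), replace=True), axis=1)
    lo, hi = np.percentile(meds, [2.5, 97.5])
    return {"median_h": float(np.median(x)), "ci95_h": (float(lo), float(hi)),
            "n": int(x.size)}
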