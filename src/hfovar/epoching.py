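"""Interictal NREM segmentation and channel-by-epoch rate matrices.

Analysis time is restricted to NREM sleep (stages 2-4) more than 30 minutes
away from any seizure. Microarousals shorter than one minute stay inside a
NREM bout but their time (and any events during them) is redacted; longer
arousals split the bout. Each segment is tiled into consecutive 10-minute
epochs anchored at the segment start; rates are event counts divided by the
analyzed minutes of the epoch.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datatypes import (AnnotationSet, EpochRateMatrix, HFOEvent, NREM_STAGES,
                        STAGE_LABELS, merge_intervals, overlap_length,
                        subtract_intervals)

__all__ = [
    "select_interictal",
    "nrem_segments",
    "compute_rates",
    "order_channels_for_display",
]

logger = logging.getLogger(__name__)

SEIZURE_MARGIN_S = 30.0 * 60.0
MICROAROUSAL_MAX_S = 60.0
EPOCH_S = 600.0


def select_interictal(
    intervals: Iterable[tuple[float, float]],
    seizures: Iterable[tuple[float, float]] | Iterable[tuple[float, float, str]],
    margin_min: float = 30.0,
) -> list[tuple[float, float]]:
    """Remove time within ``margin_min`` of any seizure's start or end.

    Overlapping seizure records are unioned. The margin is closed: data at
    exactly 30 minutes from a seizure boundary is not interictal ("more
    than" 30 minutes is required).
    """
    margin = margin_min * 60.0
    padded = [(s - margin, e + margin) for s, e, *_ in seizures]
    return subtract_intervals(intervals, padded)


def nrem_segments(
    annotations: AnnotationSet,
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Contiguous NREM (stage 2-4) bouts and their microarousal redactions.

    Interruptions shorter than one minute are kept inside the bout and
    returned as redaction intervals; interruptions of one minute or longer
    split the bout. Returns ``(segments, redactions)``.
    """
    stages = sorted(annotations.sleep_stages)
    for _, _, st in stages:
        if st not in STAGE_LABELS:
            raise ValueError(f"unknown sleep stage {st!r}")
    nrem = merge_intervals((s, e) for s, e, st in stages if st in NREM_STAGES)
    non_nrem = merge_intervals((s, e) for s, e, st in stages
                               if st not in NREM_STAGES)

    segments: list[tuple[float, float]] = []
    redactions: list[tuple[float, float]] = []
    for s, e in nrem:
        # a strictly-sub-minute gap to the previous NREM bout is a microarousal
        if segments:
            ps, pe = segments[-1]
            gap = s - pe
            if 0 <= gap < MICROAROUSAL_MAX_S and _covered(pe, s, non_nrem):
                segments[-1] = (ps, e)
                if gap > 0:
                    redactions.append((pe, s))
                continue
        segments.append((s, e))
    return segments, redactions

def _covered(s: float, e: float, intervals: list[tuple[float, float]]) -> bool:
    """True when [s, e] lies inside annotated (non-NREM) time, i.e. is a
    scored arousal rather than a gap in the record."""
    if e <= s:
        return True
    return not subtract_intervals([(s, e)], intervals)


def compute_rates(
    events: Sequence[HFOEvent],
    segments: Iterable[tuple[float, float]],
    redactions: Iterable[tuple[float, float]] = (),
    epoch_min: float = 10.0,
    channel_labels: Sequence[str] | None = None,
    soz_mask=None,
    rv_mask=None,
) -> EpochRateMatrix:
    """Tile segments into epochs and convert events to HFOs/min.

    Each segment is cut into consecutive ``epoch_min``-minute epochs from its
    start; a final partial epoch is kept when it retains analyzed time.
    Redacted time is subtracted from the analyzed minutes and events starting
    inside a redaction are not counted. Epochs with no analyzed time are
    dropped with a log entry.
    """
    epoch_s = epoch_min * 60.0
    redactions = merge_intervals(redactions)
    if channel_labels is None:
        channel_labels = sorted({ev.channel for ev in events})
    ch_index = {c: i for i, c in enumerate(channel_labels)}

    starts, ends, analyzed = [], [], []
    for seg_s, seg_e in merge_intervals(segments):
        t = seg_s
        while t < seg_e - 1e-9:
            end = min(t + epoch_s, seg_e)
            red = sum(overlap_length((t, end), r) for r in redactions)
            mins = (end - t - red) / 60.0
            if mins <= 1e-12:
                logger.info("epoch at %.1f s fully redacted; dropped", t)
            else:
                starts.append(t)
                ends.append(end)
                analyzed.append(mins)
            t = end
    starts_a = np.asarray(starts)
    ends_a = np.asarray(ends)
    analyzed_a = np.asarray(analyzed)

    counts = np.zeros((len(channel_labels), len(starts)), dtype=float)
    for ev in events:
        if ev.channel not in ch_index:
            continue
        if any(r[0] <= ev.start_s < r[1] for r in redactions):
            continue
        # assign by event start time
        idx = np.searchsorted(starts_a, ev.start_s, side="right") - 1
        if idx >= 0 and ev.start_s < ends_a[idx]:
            counts[ch_index[ev.channel], idx] += 1

    R = counts / analyzed_a[None, :] if len(starts) else counts
    return EpochRateMatrix(R=R, epoch_start=starts_a, analyzed_min=analyzed_a,
                           channel_labels=channel_labels,
                           soz_mask=soz_mask, rv_mask=rv_mask)


def order_channels_for_display(
    R: np.ndarray,
    soz_mask: np.ndarray | None = None,
    rv_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Channel permutation for rate heatmaps.

    Channels are grouped by SOZ/RV membership first; within each group they
    are arranged by optimal-leaf-ordered hierarchical clustering on the
    correlation distance between rate profiles, so channels with similar
    temporal dynamics end up adjacent. Returns a permutation of channel
    indices; the matrix itself is untouched.
    """
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    if n < 2:
        return np.arange(n)
    member = np.zeros(n, dtype=bool)
    if soz_mask is not None:
        member |= np.asarray(soz_mask, dtype=bool)
    if rv_mask is not None:
        member |= np.asarray(rv_mask, dtype=bool)

    order: list[int] = []
    for group in (np.flatnonzero(member), np.flatnonzero(~member)):
        if len(group) == 0:
            continue
        if len(group) == 1:
            order.extend(group.tolist())
            continue
        sub = R[group]
        order.extend(group[_leaf_order(sub)].tolist())
    return np.asarray(order)

def _leaf_order(X: np.ndarray) -> np.ndarray:
    # correlation distance; constant profiles get distance 1 to everything
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    D = 1.0 - np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    condensed = squareform(D, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    Z = hierarchy.optimal_leaf_ordering(Z, condensed)
    return np.asarray(hierarchy.leaves_list(Z))
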