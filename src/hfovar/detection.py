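"""Automated HFO detection with artifact redaction (the "qHFO" scheme).

The detection chain is: decimate to a common sampling rate, apply a common
average reference, run an energy-threshold oscillation detector per channel
(zero-phase 80-500 Hz bandpass, rectification, short sliding RMS, events
where the envelope exceeds the background mean by 5 SD with at least 6
supra-threshold peaks), detect artifacts (broadband fast transients,
non-focal events appearing simultaneously on most channels, and data-quality
gaps), and finally drop every candidate oscillation that overlaps an
applicable artifact interval. A fast-ripple variant uses a 200-500 Hz band
and is otherwise identical.

Detection is fully deterministic: the same signal block always yields the
same event list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .datatypes import ArtifactInterval, HFOEvent, SignalBlock, merge_intervals

__all__ = [
    "DetectorParams",
    "decimate_to_target",
    "common_average_reference",
    "staba_detect",
    "detect_artifacts",
    "qhfo",
    "BANDS",
]

logger = logging.getLogger(__name__)

#: named analysis bands: (low Hz, high Hz, band tag, detector tag)
BANDS = {
    "ripple": (80.0, 500.0, "ripple80_500", "qHFO"),
    "fr": (200.0, 500.0, "fr200_500", "qHFO-FR"),
}


@dataclass(frozen=True)
class DetectorParams:
    """Tunable thresholds of the oscillation detector.

    Defaults follow the standard RMS-detector conventions: a 3 ms RMS
    window, a 5 SD envelope threshold over the background, at least 6
    rectified-signal peaks above 3 SD, 6 ms minimum duration and a 10 ms
    merge gap. Background statistics are taken over ``background_window``
    seconds (the containing analysis window) with detected events excluded
    on a second pass.
    """

    band_low: float = 80.0
    band_high: float = 500.0
    rms_window_ms: float = 3.0
    threshold_sd: float = 5.0
    min_peaks: int = 6
    peak_threshold_sd: float = 3.0
    min_duration_ms: float = 6.0
    merge_gap_ms: float = 10.0
    background_window_s: float = 600.0

    def __post_init__(self) -> None:
        if not self.band_low < self.band_high:
            raise ValueError("band_low must be below band_high")
        if self.min_peaks < 1:
            raise ValueError("min_peaks must be >= 1")


# ---------------------------------------------------------------------------
# preprocessing

def decimate_to_target(block: SignalBlock, target_fs: float = 5000.0) -> SignalBlock:
    """Anti-aliased decimation to ``target_fs``.

    Only integer decimation factors are applied; a block whose rate is not an
    integer multiple of the target (e.g. 4096 Hz clinical recordings) passes
    through unchanged with a log note.
    """
    ratio = block.fs / target_fs
    q = int(round(ratio))
    if q < 1 or abs(ratio - q) > 1e-9:
        logger.info("fs %.0f Hz is not an integer multiple of %.0f Hz; "
                    "using data as acquired", block.fs, target_fs)
        return block
    if q == 1:
        return block
    out = block.samples
    # scipy recommends staged decimation for large factors
    for stage in _decimation_stages(q):
        out = sps.decimate(out, stage, ftype="fir", zero_phase=True, axis=0)
    return SignalBlock(out, target_fs, block.channel_labels, block.start_time)

def _decimation_stages(q: int) -> list[int]:
    stages = []
    while q > 13:
        for d in (8, 7, 6, 5, 4, 3, 2):
            if q % d == 0:
                stages.append(d)
                q //= d
                break
        else:  # prime > 13: single stage anyway
            break
    stages.append(q)
    return stages

def common_average_reference(block: SignalBlock) -> SignalBlock:
    """Subtract the instantaneous across-channel mean from every channel."""
    if block.n_channels < 2:
        raise ValueError("common average reference requires >= 2 channels")
    ref = block.samples.mean(axis=1, keepdims=True)
    return block.copy_with(samples=block.samples - ref)


# ---------------------------------------------------------------------------
# filtering helpers

def _fir_bandpass(fs: float, low: float, high: float) -> np.ndarray:
    """Linear-phase FIR bandpass; transition width 10% of the band edge."""
    nyq = fs / 2.0
    if high > nyq:
        raise ValueError(f"band edge {high} Hz above Nyquist {nyq} Hz")
    trans = 0.1 * low
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1  # Hamming design rule, odd
    hi = min(high, nyq * 0.99)
    return sps.firwin(numtaps, [low, hi], pass_zero=False, fs=fs)

def _fir_highpass(fs: float, low: float) -> np.ndarray:
    trans = 0.1 * low
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1
    return sps.firwin(numtaps, low, pass_zero=False, fs=fs)

def _zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # symmetric (linear-phase) kernel + centered convolution == zero phase
    return sps.fftconvolve(x, taps, mode="same")

def _sliding_rms(x: np.ndarray, fs: float, window_ms: float) -> np.ndarray:
    n = max(1, int(round(window_ms * 1e-3 * fs)))
    kernel = np.full(n, 1.0 / n)
    return np.sqrt(np.maximum(sps.fftconvolve(x * x, kernel, mode="same"), 0.0))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Index runs [i, j) where mask is True."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


# ---------------------------------------------------------------------------
# oscillation detector

def staba_detect(
    x: np.ndarray,
    fs: float,
    params: DetectorParams | None = None,
    start_time: float = 0.0,
    channel: str = "",
    band_tag: str = "ripple80_500",
    detector_tag: str = "qHFO",
) -> list[HFOEvent]:
    """RMS-threshold oscillation detector on one channel.

    Pipeline: zero-phase bandpass, rectify, sliding RMS, threshold at the
    background mean + ``threshold_sd`` SD, keep runs longer than
    ``min_duration_ms``, merge runs closer than ``merge_gap_ms``, and require
    at least ``min_peaks`` rectified-signal local maxima above the background
    mean + ``peak_threshold_sd`` SD. Background statistics exclude detected
    event samples on a second pass.
    """
    params = params or DetectorParams()
    if params.band_high > fs / 2:
        raise ValueError("detection band extends above Nyquist")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("staba_detect operates on a single channel")

    taps = _fir_bandpass(fs, params.band_low, params.band_high)
    bp = _zero_phase(x, taps)
    rect = np.abs(bp)
    rms = _sliding_rms(bp, fs, params.rms_window_ms)

    intervals = _detect_pass(rect, rms, fs, params, exclude=None)
    if intervals:
        # recompute background excluding event samples, then redetect
        excl = np.zeros(len(x), dtype=bool)
        for i, j in intervals:
            excl[i:j] = True
        intervals = _detect_pass(rect, rms, fs, params, exclude=excl)

    events = []
    for i, j in intervals:
        events.append(HFOEvent(channel=channel,
                               start_s=start_time + i / fs,
                               end_s=start_time + j / fs,
                               band=band_tag, detector=detector_tag))
    return events

def _detect_pass(rect, rms, fs, params, exclude):
    bg = slice(0, min(len(rms), int(round(params.background_window_s * fs))))
    keep = np.ones(len(rms), dtype=bool)
    if exclude is not None:
        keep = ~exclude
    bg_rms = rms[bg][keep[bg]]
    bg_rect = rect[bg][keep[bg]]
    if bg_rms.size == 0:
        return []
    thr_rms = bg_rms.mean() + params.threshold_sd * bg_rms.std()
    thr_peak = bg_rect.mean() + params.peak_threshold_sd * bg_rect.std()

    min_len = int(round(params.min_duration_ms * 1e-3 * fs))
    gap_len = int(round(params.merge_gap_ms * 1e-3 * fs))

    runs = [(i, j) for i, j in _runs(rms > thr_rms) if j - i >= min_len]
    merged: list[tuple[int, int]] = []
    for i, j in runs:
        if merged and i - merged[-1][1] < gap_len:
            merged[-1] = (merged[-1][0], j)
        else:
            merged.append((i, j))

    out = []
    for i, j in merged:
        seg = rect[i:j]
        peaks, _ = sps.find_peaks(seg, height=thr_peak)
        if len(peaks) >= params.min_peaks:
            out.append((i, j))
    return out


# ---------------------------------------------------------------------------
# artifact detection

@dataclass(frozen=True)
class ArtifactParams:
    """Thresholds of the artifact detectors.

    The fast-transient detector looks for broadband power above the HFO band
    (``transient_band_low`` to Nyquist) exceeding its own 5 SD threshold; it
    is skipped (with a warning) when the sampling rate cannot support that
    band. Non-focal events are times when candidate oscillations are active
    simultaneously on more than ``non_focal_frac`` of all channels.
    Flatline/NaN runs of at least ``flat_min_s`` become data-quality gaps.
    """

    transient_band_low: float = 850.0
    transient_threshold_sd: float = 5.0
    transient_pad_s: float = 0.1       # guards bandpass ringing around the spike
    transient_min_s: float = 0.001
    non_focal_frac: float = 0.5
    flat_min_s: float = 0.5


def detect_artifacts(
    block: SignalBlock,
    candidates: dict[str, list[HFOEvent]] | None = None,
    params: ArtifactParams | None = None,
) -> list[ArtifactInterval]:
    """Find fast transients, non-focal events and data-quality gaps."""
    params = params or ArtifactParams()
    out: list[ArtifactInterval] = []
    out.extend(_data_quality_intervals(block, params))
    out.extend(_fast_transient_intervals(block, params))
    if candidates:
        out.extend(_non_focal_intervals(block, candidates, params))
    return sorted(out, key=lambda a: (a.start_s, a.end_s))

def _data_quality_intervals(block, params):
    out = []
    min_len = int(round(params.flat_min_s * block.fs))
    for c, label in enumerate(block.channel_labels):
        x = block.samples[:, c]
        bad = np.isnan(x)
        flat = np.zeros(len(x), dtype=bool)
        if len(x) > 1:
            flat[1:] = np.diff(x) == 0.0
            flat[:-1] |= flat[1:]
        for mask in (bad, flat):
            for i, j in _runs(mask):
                if j - i >= min_len or mask is bad and j > i:
                    out.append(ArtifactInterval(
                        start_s=block.start_time + i / block.fs,
                        end_s=block.start_time + j / block.fs,
                        kind="data_quality", channels=frozenset({label})))
    return out

def _fast_transient_intervals(block, params):
    nyq = block.fs / 2.0
    if nyq <= params.transient_band_low:
        warnings.warn(
            f"sampling rate {block.fs:.0f} Hz cannot support the "
            f"{params.transient_band_low:.0f} Hz fast-transient band; skipping",
            RuntimeWarning, stacklevel=3)
        return []
    taps = _fir_highpass(block.fs, params.transient_band_low)
    min_len = max(1, int(round(params.transient_min_s * block.fs)))
    out = []
    for c, label in enumerate(block.channel_labels):
        x = np.nan_to_num(block.samples[:, c])
        hp = _zero_phase(x, taps)
        env = _sliding_rms(hp, block.fs, 3.0)
        thr = env.mean() + params.transient_threshold_sd * env.std()
        ivs = [(i / block.fs - params.transient_pad_s,
                j / block.fs + params.transient_pad_s)
               for i, j in _runs(env > thr) if j - i >= min_len]
        for s, e in merge_intervals(ivs):
            out.append(ArtifactInterval(
                start_s=block.start_time + max(s, 0.0),
                end_s=block.start_time + min(e, block.duration_s),
                kind="fast_transient", channels=frozenset({label})))
    return out

def _non_focal_intervals(block, candidates, params):
    # sweep line over candidate event boundaries, counting active channels
    points: list[tuple[float, int]] = []
    for evs in candidates.values():
        for ev in evs:
            points.append((ev.start_s, +1))
            points.append((ev.end_s, -1))
    if not points:
        return []
    points.sort()
    need = params.non_focal_frac * block.n_channels
    out, active, open_at = [], 0, None
    for t, d in points:
        active += d
        if active > need and open_at is None:
            open_at = t
        elif active <= need and open_at is not None:
            if t > open_at:
                out.append(ArtifactInterval(start_s=open_at, end_s=t,
                                            kind="non_focal", channels=None))
            open_at = None
    return out


# ---------------------------------------------------------------------------
# full scheme

def qhfo(
    block: SignalBlock,
    band: str = "ripple",
    params: DetectorParams | None = None,
    artifact_params: ArtifactParams | None = None,
    return_artifacts: bool = False,
):
    """Artifact-redacted HFO detection on a preprocessed (decimated) block.

    Applies the common average reference, runs the oscillation detector on
    every channel, detects artifacts, and drops each candidate that overlaps
    an applicable artifact interval. Channel-specific artifacts redact only
    their own channel; non-focal artifacts redact all channels.
    """
    low, high, band_tag, det_tag = BANDS[band]
    params = params or DetectorParams()
    params = replace(params, band_low=low, band_high=high)

    car = common_average_reference(block)
    candidates: dict[str, list[HFOEvent]] = {}
    for c, label in enumerate(car.channel_labels):
        x = np.nan_to_num(car.samples[:, c])
        candidates[label] = staba_detect(
            x, car.fs, params, start_time=car.start_time,
            channel=label, band_tag=band_tag, detector_tag=det_tag)

    # artifacts are sought on the signal as acquired: a transient common to
    # all channels would cancel under the average reference and escape
    artifacts = detect_artifacts(block, candidates, artifact_params)
    events = redact_events(
        [ev for evs in candidates.values() for ev in evs], artifacts)
    events.sort(key=lambda e: (e.start_s, e.channel))
    if return_artifacts:
        return events, artifacts
    return events


def redact_events(events: list[HFOEvent],
                  artifacts: list[ArtifactInterval]) -> list[HFOEvent]:
    """Drop every event with positive-length overlap with an applicable artifact."""
    out = []
    for ev in events:
        hit = any(a.applies_to(ev.channel)
                  and min(ev.end_s, a.end_s) > max(ev.start_s, a.start_s)
                  for a in artifacts)
        if not hit:
            out.append(ev)
    return out
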