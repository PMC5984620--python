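"""Core containers for multichannel iEEG analysis.

The objects here are deliberately small: a signal block (samples + sampling
rate + labels), detected oscillation events, artifact intervals, clinical
annotations (sleep stages, seizures, channel masks) and the channel-by-epoch
rate matrix that every downstream statistic consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalBlock",
    "HFOEvent",
    "ArtifactInterval",
    "AnnotationSet",
    "EpochRateMatrix",
    "merge_intervals",
    "subtract_intervals",
    "overlap_length",
]

NREM_STAGES = frozenset({"N2", "N3", "N4"})
STAGE_LABELS = frozenset({"W", "R", "N1", "N2", "N3", "N4"})


# ---------------------------------------------------------------------------
# interval arithmetic (half-open-ish real intervals; zero-length ignored)

def merge_intervals(intervals: Iterable[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of possibly-overlapping (start, end) intervals, sorted."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[float, float]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out

def subtract_intervals(
    base: Iterable[tuple[float, float]],
    remove: Iterable[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Set difference ``base \\ remove`` on real intervals."""
    removed = merge_intervals(remove)
    out: list[tuple[float, float]] = []
    for s, e in merge_intervals(base):
        cur = s
        for rs, re_ in removed:
            if re_ <= cur or rs >= e:
                continue
            if rs > cur:
                out.append((cur, rs))
            cur = max(cur, re_)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out

def overlap_length(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


# ---------------------------------------------------------------------------

@dataclass
class SignalBlock:
    """A multichannel iEEG segment.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : sequence of str
    start_time : float
        Absolute start time in seconds (recording clock).
    """

    samples: np.ndarray
    fs: float
    channel_labels: Sequence[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (time x channel)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[1]:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Absolute sample times in seconds."""
        return self.start_time + np.arange(self.n_samples) / self.fs

    def copy_with(self, **kw) -> "SignalBlock":
        return replace(self, **kw)


@dataclass(frozen=True)
class HFOEvent:
    """One detected high-frequency oscillation."""

    channel: str
    start_s: float
    end_s: float
    band: str = "ripple80_500"      # or "fr200_500"
    detector: str = "qHFO"          # or "qHFO-FR"

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("event must have positive duration")

    @property
    def interval(self) -> tuple[float, float]:
        return (self.start_s, self.end_s)


@dataclass(frozen=True)
class ArtifactInterval:
    """A redaction interval: fast transient, non-focal event or bad data.

    ``channels=None`` means the artifact applies to every channel.
    """

    start_s: float
    end_s: float
    kind: str                        # fast_transient | non_focal | data_quality
    channels: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError("artifact must have positive duration")
        if self.kind not in {"fast_transient", "non_focal", "data_quality"}:
            raise ValueError(f"unknown artifact kind {self.kind!r}")

    def applies_to(self, channel: str) -> bool:
        return self.channels is None or channel in self.channels

    @property
    def interval(self) -> tuple[float, float]:
        return (self.start_s, self.end_s)


@dataclass
class AnnotationSet:
    """Sleep stages, seizure times and channel masks for one recording.

    Stage intervals use labels W, R, N1..N4; seizures carry a free-text type
    label. ``soz_mask`` / ``rv_mask`` are boolean per-channel vectors marking
    the clinically determined seizure onset zone and the resected volume.
    """

    sleep_stages: list[tuple[float, float, str]] = field(default_factory=list)
    seizures: list[tuple[float, float, str]] = field(default_factory=list)
    soz_mask: np.ndarray | None = None
    rv_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        for s, e, stage in self.sleep_stages:
            if e < s:
                raise ValueError("negative-length stage interval")
            if stage not in STAGE_LABELS:
                raise ValueError(f"unknown sleep stage {stage!r}")
        for s, e, _ in self.seizures:
            if e < s:
                raise ValueError("negative-length seizure interval")
        if self.soz_mask is not None:
            self.soz_mask = np.asarray(self.soz_mask, dtype=bool)
        if self.rv_mask is not None:
            self.rv_mask = np.asarray(self.rv_mask, dtype=bool)


@dataclass
class EpochRateMatrix:
    """HFO rates per channel per 10-min epoch.

    ``R[c, t]`` is in HFOs/min, already normalized by the analyzed minutes of
    epoch ``t`` (which can be < 10 when microarousals were redacted).
    """

    R: np.ndarray
    epoch_start: np.ndarray
    analyzed_min: np.ndarray
    channel_labels: Sequence[str]
    soz_mask: np.ndarray | None = None
    rv_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.epoch_start = np.asarray(self.epoch_start, dtype=float)
        self.analyzed_min = np.asarray(self.analyzed_min, dtype=float)
        self.channel_labels = list(self.channel_labels)
        if self.R.ndim != 2:
            raise ValueError("R must be 2-D (channels x epochs)")
        if self.R.shape != (len(self.channel_labels), len(self.epoch_start)):
            raise ValueError("R shape inconsistent with labels/epochs")
        if len(self.analyzed_min) != self.R.shape[1]:
            raise ValueError("analyzed_min length must match epoch count")
        if np.any(self.R < 0):
            raise ValueError("rates must be non-negative")
        if np.any(np.diff(self.epoch_start) < 0):
            raise ValueError("epochs must be time-ordered")
        if np.any(self.analyzed_min <= 0) or np.any(self.analyzed_min > 10 + 1e-9):
            raise ValueError("analyzed_min must lie in (0, 10]")
        for m in (self.soz_mask, self.rv_mask):
            if m is not None and len(m) != self.R.shape[0]:
                raise ValueError("channel mask length mismatch")
        if self.soz_mask is not None:
            self.soz_mask = np.asarray(self.soz_mask, dtype=bool)
        if self.rv_mask is not None:
            self.rv_mask = np.asarray(self.rv_mask, dtype=bool)

    @property
    def n_channels(self) -> int:
        return self.R.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.R.shape[1]

    def time_average(self, weight_by_analyzed: bool = True) -> np.ndarray:
        """Mean rate per channel over epochs.

        Weighting by analyzed minutes makes the average an unbiased overall
        rate (total events / total analyzed time) when partial epochs exist.
        """
        if weight_by_analyzed:
            w = self.analyzed_min / self.analyzed_min.sum()
            return self.R @ w
        return self.R.mean(axis=1)

    def select_epochs(self, mask: np.ndarray) -> "EpochRateMatrix":
        mask = np.asarray(mask, dtype=bool)
        return EpochRateMatrix(
            R=self.R[:, mask],
            epoch_start=self.epoch_start[mask],
            analyzed_min=self.analyzed_min[mask],
            channel_labels=self.channel_labels,
            soz_mask=self.soz_mask,
            rv_mask=self.rv_mask,
        )

    def to_frame(self) -> pd.DataFrame:
        """Rates as a DataFrame: channels in rows, epoch start seconds as columns."""
        return pd.DataFrame(self.R, index=self.channel_labels,
                            columns=self.epoch_start)
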