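"""Readers and writers for the pipeline's text formats.

Events travel as CSV (``channel,start_s,end_s,band,detector``), rate
matrices as CSV with epoch start seconds in the header row, annotations as
``start_s,end_s,label`` CSV with the label vocabulary
{W,R,N1..N4,seizure:<type>}, masks as channel lists, and configs as YAML.
EDF recordings are read through mne when available; synthetic signals are
exported as CSV matrices with a YAML sidecar carrying fs/labels/start.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import AnnotationSet, EpochRateMatrix, HFOEvent, SignalBlock

__all__ = [
    "read_events_csv", "write_events_csv",
    "read_rates_csv", "write_rates_csv",
    "read_annotations_csv", "read_mask_csv",
    "read_edf", "read_signal_csv", "write_signal_csv",
    "load_config", "write_json",
]


def write_events_csv(events, path) -> None:
    df = pd.DataFrame(
        [(e.channel, e.start_s, e.end_s, e.band, e.detector) for e in events],
        columns=["channel", "start_s", "end_s", "band", "detector"])
    df.to_csv(path, index=False)

def read_events_csv(path) -> list[HFOEvent]:
    df = pd.read_csv(path)
    return [HFOEvent(channel=str(r.channel), start_s=float(r.start_s),
                     end_s=float(r.end_s), band=str(r.band),
                     detector=str(r.detector))
            for r in df.itertuples()]


def write_rates_csv(mat: EpochRateMatrix, path) -> None:
    df = pd.DataFrame(mat.R, index=mat.channel_labels,
                      columns=[f"{t:.1f}" for t in mat.epoch_start])
    df.index.name = "channel"
    df.loc["__analyzed_min__"] = mat.analyzed_min
    df.to_csv(path)

def read_rates_csv(path) -> EpochRateMatrix:
    df = pd.read_csv(path, index_col=0)
    analyzed = df.loc["__analyzed_min__"].to_numpy(dtype=float)
    df = df.drop(index="__analyzed_min__")
    return EpochRateMatrix(
        R=df.to_numpy(dtype=float),
        epoch_start=np.asarray([float(c) for c in df.columns]),
        analyzed_min=analyzed,
        channel_labels=[str(i) for i in df.index])


def read_annotations_csv(path, soz=None, rv=None) -> AnnotationSet:
    df = pd.read_csv(path)
    stages, seizures = [], []
    for r in df.itertuples():
        label = str(r.label)
        if label.startswith("seizure"):
            sz_type = label.split(":", 1)[1] if ":" in label else ""
            seizures.append((float(r.start_s), float(r.end_s), sz_type))
        else:
            stages.append((float(r.start_s), float(r.end_s), label))
    return AnnotationSet(sleep_stages=stages, seizures=seizures,
                         soz_mask=soz, rv_mask=rv)

def read_mask_csv(path, channel_labels) -> np.ndarray:
    """Boolean mask from a file listing one member channel per line."""
    members = {line.strip() for line in Path(path).read_text().splitlines()
               if line.strip()}
    return np.array([c in members for c in channel_labels], dtype=bool)


def read_edf(path) -> SignalBlock:
    """Read an EDF recording (requires mne)."""
    import mne
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return SignalBlock(raw.get_data().T * 1e6, float(raw.info["sfreq"]),
                       list(raw.ch_names), start_time=0.0)

def write_signal_csv(block: SignalBlock, path) -> None:
    path = Path(path)
    pd.DataFrame(block.samples, columns=block.channel_labels).to_csv(
        path, index=False)
    sidecar = {"fs": block.fs, "start_time": block.start_time,
               "channel_labels": list(block.channel_labels)}
    path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(sidecar))

def read_signal_csv(path) -> SignalBlock:
    path = Path(path)
    meta = yaml.safe_load(path.with_suffix(".meta.yaml").read_text())
    df = pd.read_csv(path)
    return SignalBlock(df.to_numpy(dtype=float), float(meta["fs"]),
                       meta["channel_labels"],
                       start_time=float(meta.get("start_time", 0.0)))


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")

def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
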