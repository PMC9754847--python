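"""State labeling and epoch extraction from annotated continuous EEG.

The preictal state (the positive class) is the 30-minute window before a
seizure onset. The seizure itself and the 2 hours after its end (postictal
recovery) are excluded from modeling; the remaining time is interictal
baseline (the negative class). When two seizures are separated by less than
2 hours, only the first is retained and the second's span is excluded.

Retained state intervals are tiled with nonoverlapping 60-second epochs and
each epoch is reduced to one averaged value per channel per second, giving a
p x q (electrodes x seconds) matrix per epoch.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import Recording, SeizureAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "StateIntervals",
    "Epoch",
    "EpochSet",
    "label_states",
    "extract_epochs",
    "save_epoch_set",
    "load_epoch_set",
]

MANIFEST_COLUMNS = ["patient_id", "epoch_index", "label", "origin_sec", "truncated_preictal"]


@dataclass
class StateIntervals:
    """Disjoint timeline intervals per state, plus tagged exclusions."""

    preictal: list[tuple[float, float]] = field(default_factory=list)
    interictal: list[tuple[float, float]] = field(default_factory=list)
    #: (start, end, reason) with reason in {"ictal", "postictal", "short-gap-seizure"}
    excluded: list[tuple[float, float, str]] = field(default_factory=list)
    #: preictal intervals shortened below the full horizon by a collision
    truncated_preictal: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class Epoch:
    """One 60-second per-second-averaged EEG segment with its state label."""

    data: np.ndarray          # (p electrodes, q seconds)
    label: int                # 1 preictal, 0 interictal
    patient_id: str = ""
    epoch_index: int = 0
    origin_sec: float = 0.0
    truncated_preictal: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (electrodes x seconds)")
        if not np.isfinite(self.data).all():
            raise ValueError("epoch data contains non-finite values")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (interictal) or 1 (preictal)")


@dataclass
class EpochSet:
    """A collection of epochs sharing p and q."""

    epochs: list[Epoch]

    def __post_init__(self) -> None:
        shapes = {e.data.shape for e in self.epochs}
        if len(shapes) > 1:
            raise ValueError(f"epochs have mixed shapes: {shapes}")

    @property
    def n1(self) -> int:
        """Number of preictal epochs."""
        return sum(e.label == 1 for e in self.epochs)

    @property
    def n2(self) -> int:
        """Number of interictal epochs."""
        return sum(e.label == 0 for e in self.epochs)

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self) -> Iterable[Epoch]:
        return iter(self.epochs)

    @property
    def shape(self) -> tuple[int, int]:
        if not self.epochs:
            raise ValueError("empty epoch set has no shape")
        return self.epochs[0].data.shape


def label_states(
    ann: SeizureAnnotation,
    rec_start_sec: float,
    rec_end_sec: float,
    preictal_minutes: float = 30.0,
    postictal_hours: float = 2.0,
) -> StateIntervals:
    """Partition a recording's timeline into preictal/interictal/excluded.

    Rules, applied greedily left-to-right over seizures sorted by onset:

    * a seizure whose onset falls less than ``postictal_hours`` after the
      previous *retained* seizure's offset is dropped entirely; its ictal
      span is excluded with reason ``short-gap-seizure``;
    * each retained seizure contributes a preictal window
      ``[onset - preictal_minutes*60, onset)`` clipped to the recording and
      to the end of any preceding exclusion, an ictal exclusion
      ``[onset, offset)`` and a postictal exclusion
      ``[offset, offset + postictal_hours*3600)``;
    * whatever timeline remains is interictal.
    """
    if rec_end_sec <= rec_start_sec:
        raise ValueError("recording end must exceed its start")
    horizon = preictal_minutes * 60.0
    gap = postictal_hours * 3600.0

    out = StateIntervals()
    frontier = rec_start_sec          # end of the last assigned interval
    last_retained_offset: float | None = None

    def exclude(start: float, end: float, reason: str) -> None:
        nonlocal frontier
        start = max(start, frontier)
        end = min(end, rec_end_sec)
        if end > start:
            out.excluded.append((start, end, reason))
            frontier = end

    for onset, offset in ann.events:
        if last_retained_offset is not None and onset - last_retained_offset < gap:
            logger.info("dropping seizure at %s: onset < %s s after previous offset",
                        onset, gap)
            exclude(onset, offset, "short-gap-seizure")
            continue
        pre_start = max(onset - horizon, rec_start_sec, frontier)
        if onset > pre_start:
            out.preictal.append((pre_start, onset))
            if onset - pre_start < horizon - 1e-9:
                out.truncated_preictal.append((pre_start, onset))
                logger.info("preictal window before onset %s truncated to %.0f s",
                            onset, onset - pre_start)
            frontier = onset
        exclude(onset, offset, "ictal")
        exclude(offset, offset + gap, "postictal")
        last_retained_offset = offset

    # interictal = complement of everything assigned
    assigned = sorted(
        [(a, b) for a, b in out.preictal] + [(a, b, ) for a, b, _ in out.excluded]
    )
    cursor = rec_start_sec
    for a, b in assigned:
        if a > cursor:
            out.interictal.append((cursor, a))
        cursor = max(cursor, b)
    if rec_end_sec > cursor:
        out.interictal.append((cursor, rec_end_sec))
    return out


def extract_epochs(
    rec: Recording,
    intervals: StateIntervals,
    epoch_seconds: int = 60,
    patient_id: str = "",
) -> EpochSet:
    """Tile state intervals with nonoverlapping epochs, averaging per second.

    Each interval is tiled left-to-right with ``epoch_seconds``-long windows;
    a partial trailing window is discarded. Within a window, every
    consecutive 1-s block of ``fs`` samples is averaged per channel, so an
    epoch is a p x ``epoch_seconds`` matrix.
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("per-second averaging requires an integer sampling rate")
    fs = int(round(fs))

    truncated = set(intervals.truncated_preictal)
    epochs: list[Epoch] = []
    idx = 0
    for label, ivals in ((1, intervals.preictal), (0, intervals.interictal)):
        for start, end in ivals:
            n_ep = int(np.floor((end - start) / epoch_seconds))
            if n_ep == 0:
                logger.info("interval [%s, %s) shorter than %d s: no epochs",
                            start, end, epoch_seconds)
                continue
            for k in range(n_ep):
                origin = start + k * epoch_seconds
                s0 = int(round((origin - rec.start_time_sec) * fs))
                s1 = s0 + epoch_seconds * fs
                if s0 < 0 or s1 > rec.n_samples:
                    logger.warning("epoch at %s s falls outside recorded samples; skipped",
                                   origin)
                    continue
                block = rec.signals[:, s0:s1]
                data = block.reshape(rec.n_channels, epoch_seconds, fs).mean(axis=2)
                epochs.append(Epoch(
                    data=data, label=label, patient_id=patient_id,
                    epoch_index=idx, origin_sec=origin,
                    truncated_preictal=(label == 1 and (start, end) in truncated),
                ))
                idx += 1
    return EpochSet(epochs=epochs)


def save_epoch_set(eset: EpochSet, directory: str | Path) -> Path:
    """Serialize epochs as per-epoch CSV matrices plus a CSV manifest.

    The manifest columns (``patient_id, epoch_index, label, origin_sec,
    truncated_preictal``) are part of the public contract; synthetic and
    real data use the identical layout.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for e in eset.epochs:
        fname = f"epoch_{e.epoch_index:06d}.csv"
        np.savetxt(directory / fname, e.data, delimiter=",")
        rows.append({
            "patient_id": e.patient_id, "epoch_index": e.epoch_index,
            "label": e.label, "origin_sec": e.origin_sec,
            "truncated_preictal": e.truncated_preictal, "file": fname,
        })
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS + ["file"]).to_csv(manifest, index=False)
    return manifest


def load_epoch_set(directory: str | Path) -> EpochSet:
    """Load an epoch set written by :func:`save_epoch_set`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    epochs = []
    for _, row in manifest.iterrows():
        data = np.loadtxt(directory / row["file"], delimiter=",", ndmin=2)
        epochs.append(Epoch(
            data=data, label=int(row["label"]),
            patient_id=str(row["patient_id"]), epoch_index=int(row["epoch_index"]),
            origin_sec=float(row["origin_sec"]),
            truncated_preictal=bool(row["truncated_preictal"]),
        ))
    return EpochSet(epochs=epochs)
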