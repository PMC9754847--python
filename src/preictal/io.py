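"""Reading EEG recordings and seizure annotations into canonical containers.

EDF/EDF+ files are read through MNE. Seizure annotations are plain CSV
tables with ``onset_sec`` / ``offset_sec`` columns on a per-patient
continuous timeline; converting dataset-specific annotation dialects
(e.g. CHB-MIT ``summary.txt``) to this CSV is a documented user task.
"""

from __future__ import annotations

import logging
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "SeizureAnnotation",
    "canonical_label",
    "read_edf",
    "write_edf",
    "select_channels",
    "read_annotations",
    "CHANNEL_PRESETS",
]

#: Montage presets: one canonical, user-editable channel list per montage.
#: "chbmit21" is a 21-signal bipolar double-banana list in 10-20
#: nomenclature; "fhpku19" the 19 referential 10-20 electrodes.
CHANNEL_PRESETS: dict[str, list[str]] = {
    "chbmit21": [
        "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
        "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
        "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
        "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
        "FZ-CZ", "CZ-PZ", "T7-FT9", "FT9-FT10", "FT10-T8",
    ],
    "fhpku19": [
        "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4",
        "O1", "O2", "F7", "F8", "T3", "T4", "T5", "T6",
        "FZ", "CZ", "PZ",
    ],
}


def canonical_label(label: str) -> str:
    """Normalize an electrode label across EDF dialects.

    Uppercases, strips whitespace, removes a leading ``EEG`` qualifier and a
    trailing ``-REF`` reference suffix. Bipolar labels keep their ``A-B``
    form.
    """
    lab = label.strip().upper()
    if lab.startswith("EEG "):
        lab = lab[4:].strip()
    if lab.endswith("-REF"):
        lab = lab[:-4]
    return lab.strip()


@dataclass
class Recording:
    """A block of multi-channel EEG on a per-patient continuous timeline.

    Attributes
    ----------
    channel_labels : list of str
        Ordered channel names as stored in the file.
    sampling_rate : float
        Samples per second, shared by all channels.
    signals : ndarray of shape (n_channels, n_samples)
        Signal values in acquisition units (microvolts for scalp EEG).
    start_time_sec : float
        Offset of the first sample on the patient timeline; multi-file
        recordings are concatenated by the caller using these offsets.
    montage : str
        ``"bipolar"`` (adjacent-electrode differences, CHB-MIT style) or
        ``"referential"`` (electrode minus fixed reference).
    """

    channel_labels: list[str]
    sampling_rate: float
    signals: np.ndarray
    start_time_sec: float = 0.0
    montage: str = "referential"

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D (channels x samples) array")
        if self.signals.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{len(self.channel_labels)} labels but "
                f"{self.signals.shape[0]} signal rows"
            )
        if self.signals.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        canon = [canonical_label(c) for c in self.channel_labels]
        if len(set(canon)) != len(canon):
            dupes = {c for c in canon if canon.count(c) > 1}
            raise ValueError(f"duplicate channel labels after canonicalization: {sorted(dupes)}")
        if self.montage not in ("bipolar", "referential"):
            raise ValueError("montage must be 'bipolar' or 'referential'")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_sec(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def end_time_sec(self) -> float:
        return self.start_time_sec + self.duration_sec


@dataclass
class SeizureAnnotation:
    """Seizure events as (onset_sec, offset_sec) pairs, sorted and disjoint."""

    events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        events = [(float(a), float(b)) for a, b in self.events]
        for onset, offset in events:
            if not onset < offset:
                raise ValueError(f"seizure onset {onset} must precede offset {offset}")
        events.sort(key=lambda e: e[0])
        for (a0, b0), (a1, _b1) in zip(events, events[1:]):
            if a1 < b0:
                raise ValueError(f"overlapping seizure events: ({a0},{b0}) and onset {a1}")
        self.events = events

    def __len__(self) -> int:
        return len(self.events)


def read_edf(path: str | Path, *, start_time_sec: float = 0.0,
             montage: str = "referential") -> Recording:
    """Read an EDF/EDF+ file into a :class:`Recording`.

    All stored channels are returned, labels as stored in the header,
    sampling rate from the header, signals in the file's physical units
    (microvolts for EEG channels).
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise ValueError(f"unreadable or invalid EDF file {path}: {exc}") from exc
    rates = {raw.info["sfreq"]}
    if len(rates) != 1:
        raise ValueError(f"channels with differing sampling rates in {path}")
    data = raw.get_data()
    # MNE rescales voltage channels to volts; report microvolts, the EDF
    # acquisition unit for scalp EEG. Non-voltage (misc) channels pass through.
    units = np.array([
        1e6 if ch["unit"] == 107 else 1.0  # FIFF_UNIT_V == 107
        for ch in raw.info["chs"]
    ])
    return Recording(
        channel_labels=list(raw.ch_names),
        sampling_rate=float(raw.info["sfreq"]),
        signals=data * units[:, None],
        start_time_sec=start_time_sec,
        montage=montage,
    )


def write_edf(path: str | Path, rec: Recording) -> None:
    """Write a :class:`Recording` as a minimal single-record-per-second EDF.

    Fixture-grade writer: 16-bit quantization over the per-channel signal
    range, one data record per second. Intended for tests and synthetic
    recordings, not clinical archival.
    """
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF fixture writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = rec.n_samples // fs
    if n_records * fs != rec.n_samples:
        raise ValueError("signal length must be a whole number of seconds")
    nch = rec.n_channels
    sig = rec.signals[:, : n_records * fs]

    phys_min = sig.min(axis=1)
    phys_max = sig.max(axis=1)
    # avoid zero physical range for constant channels
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((sig - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("X", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 + 256 * nch), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),
        pad(str(nch), 4),
    ])
    fields = [
        (16, rec.channel_labels),
        (80, ["" for _ in range(nch)]),                     # transducer
        (8, ["uV" for _ in range(nch)]),                    # physical dimension
        (8, [f"{v:.6g}" for v in phys_min]),
        (8, [f"{v:.6g}" for v in phys_max]),
        (8, [str(dig_min) for _ in range(nch)]),
        (8, [str(dig_max) for _ in range(nch)]),
        (80, ["" for _ in range(nch)]),                     # prefiltering
        (8, [str(fs) for _ in range(nch)]),
        (32, ["" for _ in range(nch)]),                     # reserved
    ]
    for width, values in fields:
        header += b"".join(pad(str(v), width) for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(struct.pack(f"<{nch * fs}h", *block.ravel()))


def select_channels(rec: Recording, channel_spec: Sequence[str]) -> Recording:
    """Restrict a recording to the requested channels, in requested order.

    Labels are matched after canonicalization so edge indices are comparable
    across epochs and recordings. Duplicate stored labels resolve to the
    first occurrence with a logged warning.
    """
    wanted = [canonical_label(c) for c in channel_spec]
    stored = [canonical_label(c) for c in rec.channel_labels]
    index: dict[str, int] = {}
    for i, lab in enumerate(stored):
        if lab in index:
            logger.warning("duplicate channel %s; keeping first occurrence", lab)
            continue
        index[lab] = i
    missing = [c for c in wanted if c not in index]
    if missing:
        raise KeyError(f"requested channels missing from recording: {missing}")
    rows = [index[c] for c in wanted]
    return Recording(
        channel_labels=[rec.channel_labels[r] for r in rows],
        sampling_rate=rec.sampling_rate,
        signals=rec.signals[rows],
        start_time_sec=rec.start_time_sec,
        montage=rec.montage,
    )


def read_annotations(path: str | Path) -> SeizureAnnotation:
    """Read a seizure-annotation CSV with ``onset_sec``/``offset_sec`` columns."""
    df = pd.read_csv(path)
    required = {"onset_sec", "offset_sec"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"annotation CSV must have columns {sorted(required)}, got {list(df.columns)}"
        )
    events = list(zip(df["onset_sec"].astype(float), df["offset_sec"].astype(float)))
    return SeizureAnnotation(events=events)
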