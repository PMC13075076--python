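"""Core data model and file I/O for the tongue motor-imagery pipeline.

The fixed 14-channel consumer-headset montage (10-20 sites, mastoid
referenced) is the frozen channel-order contract for the whole package:
feature column *j* always corresponds to label *j* of
:func:`standard_montage`.

Recordings travel as :class:`RawRecording` (continuous multichannel signal
in microvolts plus event annotations), trials as :class:`TrialEpoch`
(baseline / execution / imagery segments with the command label).

On disk, two dialects are supported:

* **CSV** — one column per channel (header row = labels, values in µV),
  with an ``<stem>.events.csv`` sidecar (``onset_sample,label``) and an
  optional ``<stem>.meta.json`` sidecar for sampling rate and trial
  metadata.  Plain-text, diff-able, fixture-friendly.
* **EDF** — standard 16-bit European Data Format, written by the bundled
  minimal writer (:mod:`tonguemi._edf`) and read back through
  :func:`mne.io.read_raw_edf`.  Events/metadata use the same sidecars.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The six imagined tongue actions, in fixed (tie-breaking) order:
#: mouth-corner left/right, cheek-bulge left/right, upper/lower lip.
COMMANDS: tuple[str, ...] = ("LL", "LR", "CL", "CR", "LU", "LD")

#: Movement pattern blocks: each pattern pairs the two commands trained
#: together (lateral corner, lateral cheek, vertical lip).
PATTERNS: dict[str, tuple[str, str]] = {
    "P1": ("LL", "LR"),
    "P2": ("CL", "CR"),
    "P3": ("LU", "LD"),
}

_MONTAGE_LABELS = (
    "AF3", "AF4", "F3", "F4", "F7", "F8", "FC5",
    "FC6", "T7", "T8", "P7", "P8", "O1", "O2",
)

#: Left/right homologous electrode pairs of the montage, used to mirror
#: topographies across the midline.
MIRROR_PAIRS: tuple[tuple[str, str], ...] = (
    ("AF3", "AF4"), ("F3", "F4"), ("F7", "F8"), ("FC5", "FC6"),
    ("T7", "T8"), ("P7", "P8"), ("O1", "O2"),
)


@dataclass(frozen=True)
class ChannelSet:
    """Ordered, unique EEG channel labels plus reference labels."""

    labels: tuple[str, ...]
    references: tuple[str, ...] = ("M1", "M2")

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "references", tuple(self.references))

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """0-based position of *label* in the fixed order."""
        return self.labels.index(label)


def standard_montage() -> ChannelSet:
    """The fixed 14-channel 10-20 montage (AF3 ... O2), M1/M2 referenced."""
    return ChannelSet(labels=_MONTAGE_LABELS, references=("M1", "M2"))


def command_pattern(command: str) -> str:
    """Pattern id ('P1'/'P2'/'P3') that a command belongs to."""
    for pid, cmds in PATTERNS.items():
        if command in cmds:
            return pid
    raise ValueError(f"unknown command {command!r}; expected one of {COMMANDS}")


@dataclass
class RawRecording:
    """Continuous multichannel EEG with event annotations.

    ``data`` is channels x samples in µV; ``events`` is a list of
    ``(onset_sample, label)`` pairs with strictly increasing 0-based
    onsets.  Epoch boundaries are half-open ``[start, end)`` in samples.
    """

    data: np.ndarray
    fs: float = 256.0
    channels: ChannelSet = field(default_factory=standard_montage)
    events: list[tuple[int, str]] = field(default_factory=list)
    subject_id: str = ""
    session_id: str = ""
    pattern_id: str = ""
    trial_index: int = -1
    command: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples array")
        self.events = [(int(s), str(lbl)) for s, lbl in self.events]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "RawRecording":
        """Copy of this recording with the signal matrix replaced."""
        return replace(self, data=np.asarray(data, dtype=np.float64),
                       events=list(self.events))


@dataclass
class TrialEpoch:
    """One trial cut into baseline / execution / imagery segments.

    Each segment is channels x samples (µV).  ``execution`` may be None
    when the protocol records only rest and imagery.
    """

    baseline: np.ndarray
    imagery: np.ndarray
    execution: np.ndarray | None
    command: str
    fs: float
    channels: ChannelSet
    subject_id: str = ""
    session_id: str = ""
    pattern_id: str = ""
    trial_index: int = -1

    def __post_init__(self) -> None:
        if self.command not in COMMANDS:
            raise ValueError(
                f"command {self.command!r} not one of {COMMANDS}")


def validate_recording(rec: RawRecording) -> list[str]:
    """Check RawRecording invariants, reporting issues instead of raising.

    Returns an empty list iff the sampling rate is positive, the data
    matrix matches the channel list, events are strictly increasing and
    in range, and no channel is constant (dead-electrode heuristic).
    """
    issues: list[str] = []
    if not rec.fs > 0:
        issues.append(f"non-positive sampling rate {rec.fs}")
    if rec.data.ndim != 2:
        issues.append("data is not 2-D")
        return issues
    if rec.n_channels != len(rec.channels):
        issues.append(
            f"data has {rec.n_channels} rows but montage lists "
            f"{len(rec.channels)} channels")
    if not np.all(np.isfinite(rec.data)):
        issues.append("data contains non-finite samples")
    onsets = [s for s, _ in rec.events]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        issues.append("events out of order (onsets not strictly increasing)")
    if any(s < 0 or s >= rec.n_samples for s in onsets):
        issues.append("event onset outside [0, n_samples)")
    n_named = min(rec.n_channels, len(rec.channels))
    for i in range(n_named):
        row = rec.data[i]
        if row.size and np.ptp(row) == 0.0:
            issues.append(
                f"channel {rec.channels.labels[i]} is constant "
                "(dead electrode?)")
    return issues


# ---------------------------------------------------------------------------
# recording readers / writers
# ---------------------------------------------------------------------------

def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.events.csv"), Path(f"{stem}.meta.json")


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("edf", "csv"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def _read_events(path: Path) -> list[tuple[int, str]]:
    if not path.exists():
        return []
    ev = pd.read_csv(path)
    return [(int(r.onset_sample), str(r.label)) for r in ev.itertuples()]


def _write_events(events: Sequence[tuple[int, str]], path: Path) -> None:
    pd.DataFrame(events, columns=["onset_sample", "label"]).to_csv(
        path, index=False)


_META_FIELDS = ("fs", "subject_id", "session_id", "pattern_id",
                "trial_index", "command")


def save_recording(rec: RawRecording, path: str | Path,
                   format: str | None = None) -> None:
    """Write a recording (CSV or EDF) with events/metadata sidecars."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        frame = pd.DataFrame(rec.data.T, columns=list(rec.channels.labels))
        frame.to_csv(path, index=False, float_format="%.6g")
    elif fmt == "edf":
        from ._edf import write_edf
        write_edf(path, rec.data, rec.fs, rec.channels.labels)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    events_path, meta_path = _sidecar_paths(path)
    _write_events(rec.events, events_path)
    meta = {k: getattr(rec, k) for k in _META_FIELDS}
    meta_path.write_text(json.dumps(meta, indent=1))


def load_recording(path: str | Path, format: str | None = None,
                   fs: float = 256.0) -> RawRecording:
    """Read a recording from CSV or EDF.

    Channel order is remapped to :func:`standard_montage` order when all
    14 labels are present; recordings missing required montage channels
    raise a ``ValueError`` naming the absent labels.  For CSV (which does
    not carry a sampling rate) *fs* is used unless a metadata sidecar
    states one; when the two disagree, the stored rate wins and a
    warning is logged.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    montage = standard_montage()
    if fmt == "csv":
        frame = pd.read_csv(path)
        labels = [str(c) for c in frame.columns]
        data = frame.to_numpy(dtype=np.float64).T
        file_fs = None
    elif fmt == "edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        labels = list(raw.ch_names)
        data = raw.get_data() * 1e6  # mne returns volts
        file_fs = float(raw.info["sfreq"])
    else:
        raise ValueError(f"unsupported format {fmt!r}")

    missing = [lbl for lbl in montage.labels if lbl not in labels]
    if missing:
        raise ValueError(
            f"recording {path.name} is missing required channels: "
            + ", ".join(missing))
    order = [labels.index(lbl) for lbl in montage.labels]
    data = data[order]

    events_path, meta_path = _sidecar_paths(path)
    events = _read_events(events_path)
    meta: dict = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())

    eff_fs = file_fs if file_fs is not None else float(meta.get("fs", fs))
    if meta.get("fs") is not None and not math.isclose(eff_fs, meta["fs"]):
        logger.warning("sampling rate mismatch for %s: file says %s, "
                       "metadata says %s; keeping %s",
                       path.name, eff_fs, meta["fs"], eff_fs)
    if file_fs is None and meta.get("fs") is None and fs != 256.0:
        eff_fs = fs

    rec = RawRecording(
        data=data, fs=eff_fs, channels=montage, events=events,
        subject_id=str(meta.get("subject_id", "")),
        session_id=str(meta.get("session_id", "")),
        pattern_id=str(meta.get("pattern_id", "")),
        trial_index=int(meta.get("trial_index", -1)),
        command=meta.get("command"),
    )
    issues = validate_recording(rec)
    # Dead-channel and event-order problems are diagnostics, not load
    # failures; structural mismatches have already raised above.
    for issue in issues:
        logger.warning("%s: %s", path.name, issue)
    return rec


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

#: Metadata columns of the feature-table schema, before the 14 ERD columns.
FEATURE_META_COLUMNS = ("subject_id", "session_id", "pattern_id",
                        "trial_index", "command")


def feature_columns(channels: ChannelSet) -> list[str]:
    """ERD feature column names, one per channel in montage order."""
    return [f"ERD_{lbl}" for lbl in channels.labels]


def save_feature_table(features: "FeatureMatrix", path: str | Path) -> None:
    """Write a feature matrix as CSV (one row per trial, 19 columns)."""
    if features.n_trials == 0:
        raise ValueError("refusing to write an empty feature matrix")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    features.frame.to_csv(path, index=False)


def load_feature_table(path: str | Path) -> "FeatureMatrix":
    """Read a feature-table CSV back into a :class:`FeatureMatrix`."""
    from .features import FeatureMatrix

    frame = pd.read_csv(
        path, dtype={c: str for c in FEATURE_META_COLUMNS if c != "trial_index"})
    erd_cols = [c for c in frame.columns if c.startswith("ERD_")]
    labels = tuple(c[len("ERD_"):] for c in erd_cols)
    return FeatureMatrix(frame, ChannelSet(labels=labels))
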