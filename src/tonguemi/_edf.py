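"""Minimal standard-EDF (16-bit) writer.

Writes one data record holding the whole signal, with per-channel
physical scaling chosen from the data range, which keeps the
quantization error below ``(max - min) / 65535`` per channel.  The
companion reader used throughout the package is :func:`mne.io.read_raw_edf`,
so round trips are checked against an independent implementation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    # shortest representation that fits the fixed-width ASCII field
    for fmt in (f"{value:g}", f"{value:.6g}", f"{value:.3f}", f"{value:.1f}"):
        if len(fmt) <= width:
            return _field(fmt, width)
    raise ValueError(f"cannot encode {value} in {width} chars")


def write_edf(path: str | Path, data: np.ndarray, fs: float,
              labels: Sequence[str], physical_dim: str = "uV") -> None:
    """Write channels x samples *data* (µV) as a standard EDF file."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    n_ch, n_samp = data.shape
    if len(labels) != n_ch:
        raise ValueError("one label per channel required")

    pmins = data.min(axis=1)
    pmaxs = data.max(axis=1)
    flat = pmaxs - pmins <= 0
    pmaxs[flat] = pmins[flat] + 1.0

    header_bytes = 256 + 256 * n_ch
    record_duration = n_samp / fs

    parts = [
        _field("0", 8),                      # version
        _field("X X X X", 80),               # local patient id (anonymous)
        _field("Startdate X X X X", 80),     # local recording id
        _field("01.01.00", 8),               # start date
        _field("00.00.00", 8),               # start time
        _field(str(header_bytes), 8),
        _field("", 44),                      # reserved (standard EDF)
        _field("1", 8),                      # number of data records
        _num(record_duration, 8),
        _field(str(n_ch), 4),
    ]
    for lbl in labels:
        parts.append(_field(lbl, 16))
    parts.extend(_field("", 80) for _ in range(n_ch))        # transducer
    parts.extend(_field(physical_dim, 8) for _ in range(n_ch))
    parts.extend(_num(p, 8) for p in pmins)
    parts.extend(_num(p, 8) for p in pmaxs)
    parts.extend(_field(str(_DIG_MIN), 8) for _ in range(n_ch))
    parts.extend(_field(str(_DIG_MAX), 8) for _ in range(n_ch))
    parts.extend(_field("", 80) for _ in range(n_ch))        # prefiltering
    parts.extend(_field(str(n_samp), 8) for _ in range(n_ch))
    parts.extend(_field("", 32) for _ in range(n_ch))        # reserved

    # Re-derive physical min/max from their ASCII encodings so the
    # digital scaling is computed against exactly what a reader parses.
    enc_pmins = np.array([float(_num(p, 8).decode()) for p in pmins])
    enc_pmaxs = np.array([float(_num(p, 8).decode()) for p in pmaxs])
    gain = (enc_pmaxs - enc_pmins) / (_DIG_MAX - _DIG_MIN)
    digital = np.rint(
        (data - enc_pmins[:, None]) / gain[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        fh.write(digital.tobytes())  # one record: signals sequentially
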