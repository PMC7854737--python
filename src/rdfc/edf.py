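"""Minimal EDF (European Data Format) writer for test fixtures.

Only writing is implemented here — reading goes through MNE (see
``preprocess.read_record``).  The writer emits a plain 16-bit EDF with
one-second data records and per-channel physical scaling, sufficient for
round-tripping synthetic signals through any standards-compliant reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_edf"]


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ascii bytes")
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    samples: np.ndarray,
    rate: float,
    labels: list[str],
    *,
    physical_dim: str = "uV",
    patient: str = "X X X X",
    recording: str = "Startdate X X X X",
) -> Path:
    """Write channels x time ``samples`` (in ``physical_dim`` units) as EDF.

    The sampling rate must be a positive integer (samples per 1 s data
    record) and the signal length a whole number of seconds; both are the
    natural shape of the synthetic fixtures this writer serves.
    """
    path = Path(path)
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    n_ch, n_samp = samples.shape
    if len(labels) != n_ch:
        raise ValueError("one label per channel required")
    spr = int(round(rate))
    if spr <= 0 or abs(rate - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    if n_samp % spr:
        raise ValueError("signal length must be a whole number of 1 s records")
    n_records = n_samp // spr

    dig_min, dig_max = -32768, 32767
    phys_min = np.empty(n_ch)
    phys_max = np.empty(n_ch)
    digital = np.empty((n_ch, n_samp), dtype="<i2")
    for i in range(n_ch):
        lo = float(np.min(samples[i]))
        hi = float(np.max(samples[i]))
        if hi <= lo:  # constant channel: give it a unit span
            lo, hi = lo - 0.5, lo + 0.5
        span = hi - lo
        lo -= 0.001 * span
        hi += 0.001 * span
        # EDF header stores physical extremes in 8 ascii chars; quantize
        # to a representable value before deriving the gain.
        lo = float(f"{lo:.8g}"[:8])
        hi = float(f"{hi:.8g}"[:8])
        phys_min[i], phys_max[i] = lo, hi
        gain = (dig_max - dig_min) / (hi - lo)
        digital[i] = np.clip(
            np.round((samples[i] - lo) * gain) + dig_min, dig_min, dig_max
        ).astype("<i2")

    header = b""
    header += _field("0", 8)  # version
    header += _field(patient, 80)
    header += _field(recording, 80)
    header += _field("01.01.20", 8)  # start date
    header += _field("00.00.00", 8)  # start time
    header += _field(str(256 * (1 + n_ch)), 8)  # header bytes
    header += _field("", 44)  # reserved
    header += _field(str(n_records), 8)
    header += _field("1", 8)  # record duration, seconds
    header += _field(str(n_ch), 4)

    header += b"".join(_field(lab, 16) for lab in labels)
    header += b"".join(_field("", 80) for _ in labels)  # transducer
    header += b"".join(_field(physical_dim, 8) for _ in labels)
    header += b"".join(_field(f"{phys_min[i]:.8g}"[:8], 8) for i in range(n_ch))
    header += b"".join(_field(f"{phys_max[i]:.8g}"[:8], 8) for i in range(n_ch))
    header += b"".join(_field(str(dig_min), 8) for _ in labels)
    header += b"".join(_field(str(dig_max), 8) for _ in labels)
    header += b"".join(_field("", 80) for _ in labels)  # prefiltering
    header += b"".join(_field(str(spr), 8) for _ in labels)
    header += b"".join(_field("", 32) for _ in labels)  # reserved

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            sl = slice(rec * spr, (rec + 1) * spr)
            for i in range(n_ch):
                fh.write(digital[i, sl].tobytes())
    return path
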