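"""Minimal EDF (European Data Format) reader/writer for EEG signals.

Implements the standard 16-bit EDF container: a 256-byte fixed header,
256 bytes per signal of signal headers, then contiguous data records of
little-endian int16 samples.  Only continuous, equal-rate signals are
supported, which is all the pipeline needs.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError

_HDR = 256


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise DataError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _fmt_num(x: float, width: int) -> str:
    # shortest decimal representation that fits the fixed-width ascii field
    for prec in range(width - 2, -1, -1):
        s = f"{x:.{prec}f}".rstrip("0").rstrip(".") if prec else f"{x:.0f}"
        if len(s) <= width:
            return s
    raise DataError(f"cannot format {x} in {width} ascii bytes")


def write_edf(
    path,
    signals: np.ndarray,
    labels,
    sampling_rate: float,
    physical_dimension: str = "uV",
) -> None:
    """Write ``signals`` (n_channels, n_samples) as a 16-bit EDF file.

    Record duration is 1 s when the sample count divides evenly by the
    sampling rate, otherwise a single record spanning the whole signal is
    written so that no padding alters the sample count.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_channels, n_samples = signals.shape
    if len(labels) != n_channels:
        raise DataError("one label per channel required")
    fs_int = int(round(sampling_rate))
    if abs(sampling_rate - fs_int) < 1e-9 and n_samples % fs_int == 0:
        n_records, spr, rec_dur = n_samples // fs_int, fs_int, 1.0
    else:
        n_records, spr, rec_dur = 1, n_samples, n_samples / sampling_rate

    phys_max = np.maximum(np.max(np.abs(signals), axis=1), 1.0)
    dig_max = 32767
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(_HDR * (1 + n_channels)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field(_fmt_num(rec_dur, 8), 8),
            _field(str(n_channels), 4),
        ]
    )
    sig_fields = [
        (16, [str(lbl) for lbl in labels]),
        (80, [""] * n_channels),
        (8, [physical_dimension] * n_channels),
        (8, [_fmt_num(-pm, 8) for pm in phys_max]),
        (8, [_fmt_num(pm, 8) for pm in phys_max]),
        (8, [str(-dig_max)] * n_channels),
        (8, [str(dig_max)] * n_channels),
        (80, [""] * n_channels),
        (8, [str(spr)] * n_channels),
        (32, [""] * n_channels),
    ]
    header += b"".join(
        _field(v, width) for width, values in sig_fields for v in values
    )

    digital = np.empty_like(signals, dtype=np.int16)
    for c in range(n_channels):
        scaled = signals[c] / phys_max[c] * dig_max
        digital[c] = np.clip(np.round(scaled), -dig_max, dig_max).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            chunk = digital[:, r * spr : (r + 1) * spr]
            fh.write(chunk.astype("<i2").tobytes())


def read_edf(path):
    """Read an EDF file; returns ``(signals, labels, sampling_rate)``.

    Signals are rescaled to physical units.  All channels must share one
    sampling rate (mixed-rate EDFs are out of scope).
    """
    with open(path, "rb") as fh:
        head = fh.read(_HDR)
        if len(head) < _HDR:
            raise DataError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            rec_dur = float(head[244:252].decode("ascii").strip())
            n_channels = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise DataError(f"{path}: unreadable EDF header") from exc
        sig_head = fh.read(_HDR * n_channels)
        if len(sig_head) < _HDR * n_channels:
            raise DataError(f"{path}: truncated EDF signal headers")

        def col(offset: int, width: int):
            base = offset * n_channels
            return [
                sig_head[base + i * width : base + (i + 1) * width]
                .decode("ascii")
                .strip()
                for i in range(n_channels)
            ]

        labels = col(0, 16)
        phys_min = [float(x) for x in col(16 + 80 + 8, 8)]
        phys_max = [float(x) for x in col(16 + 80 + 8 + 8, 8)]
        dig_min = [int(x) for x in col(16 + 80 + 8 + 16, 8)]
        dig_max = [int(x) for x in col(16 + 80 + 8 + 24, 8)]
        spr = [int(x) for x in col(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(s / rec_dur for s in spr)) != 1:
            raise DataError(f"{path}: channels with differing sampling rates")

        raw = np.frombuffer(fh.read(), dtype="<i2")

    per_record = sum(spr)
    if raw.size < n_records * per_record:
        raise DataError(f"{path}: data shorter than header declares")
    raw = raw[: n_records * per_record].reshape(n_records, per_record)
    signals = np.empty((n_channels, n_records * spr[0]), dtype=float)
    offsets = np.concatenate([[0], np.cumsum(spr)])
    for c in range(n_channels):
        dig = raw[:, offsets[c] : offsets[c + 1]].reshape(-1).astype(float)
        gain = (phys_max[c] - phys_min[c]) / (dig_max[c] - dig_min[c])
        signals[c] = phys_min[c] + gain * (dig - dig_min[c])
    return signals, labels, spr[0] / rec_dur
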