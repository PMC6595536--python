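"""Brick-wall FFT decomposition of a frame into EEG frequency bands.

Each band keeps exactly the DFT bins whose frequency lies in the half-open
interval ``[lo, hi)``; all other bins (including DC) are zeroed before the
inverse transform.  With disjoint half-open bands no bin is double-counted,
so band energies add exactly (Parseval) to the energy of the one-shot
band-pass over the union of the bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "BAND_NAMES",
    "extract_bands",
    "brickwall_filter",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[lo, hi)`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigError(
                f"band {self.name!r}: lo ({self.lo}) must be < hi ({self.hi})"
            )


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.25, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("sigma", 12.0, 16.0),
    BandDefinition("beta", 16.0, 40.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def _validate_bands(bands, sampling_rate: float) -> None:
    nyquist = sampling_rate / 2.0
    for band in bands:
        if band.hi > nyquist:
            raise ConfigError(
                f"band {band.name!r} upper edge {band.hi} Hz exceeds the "
                f"Nyquist frequency {nyquist} Hz"
            )


def _bin_mask(
    n: int, sampling_rate: float, lo: float, hi: float, edge_mode: str = "half_open"
) -> np.ndarray:
    """Boolean mask over rfft bins selecting frequencies in ``[lo, hi)``.

    ``edge_mode='nearest_bin'`` first snaps the band edges to the nearest bin
    frequency (half-up) and then applies the same half-open rule; at the
    default resolution this only affects edges that fall between bins.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    if edge_mode == "nearest_bin":
        df = sampling_rate / n
        lo = np.floor(lo / df + 0.5) * df
        hi = np.floor(hi / df + 0.5) * df
    elif edge_mode != "half_open":
        raise ConfigError(f"unknown edge_mode {edge_mode!r}")
    return (freqs >= lo) & (freqs < hi)


def brickwall_filter(
    frame: np.ndarray,
    sampling_rate: float,
    lo: float,
    hi: float,
    edge_mode: str = "half_open",
) -> np.ndarray:
    """Ideal (brick-wall) band-pass of ``frame`` to ``[lo, hi)`` Hz.

    The negative-frequency half-spectrum is handled implicitly by the real
    FFT, so the output is real by construction.
    """
    frame = np.asarray(frame, dtype=float)
    spectrum = np.fft.rfft(frame)
    mask = _bin_mask(frame.shape[-1], sampling_rate, lo, hi, edge_mode)
    spectrum = np.where(mask, spectrum, 0.0)
    return np.fft.irfft(spectrum, n=frame.shape[-1])


def extract_bands(
    frame: np.ndarray,
    sampling_rate: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    edge_mode: str = "half_open",
) -> dict[str, np.ndarray]:
    """Split ``frame`` into band-limited time-domain signals.

    Parameters
    ----------
    frame
        Real-valued samples of one frame.
    sampling_rate
        Samples per second.
    bands
        Band definitions; every upper edge must be at or below Nyquist.
    edge_mode
        How DFT bins at band edges are assigned; see :func:`brickwall_filter`.

    Returns
    -------
    dict mapping band name to a real sequence of the frame's length.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 1 or frame.size == 0:
        raise ConfigError("frame must be a non-empty 1-D sequence")
    _validate_bands(bands, sampling_rate)
    n = frame.size
    spectrum = np.fft.rfft(frame)
    out: dict[str, np.ndarray] = {}
    for band in bands:
        mask = _bin_mask(n, sampling_rate, band.lo, band.hi, edge_mode)
        out[band.name] = np.fft.irfft(np.where(mask, spectrum, 0.0), n=n)
    return out
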