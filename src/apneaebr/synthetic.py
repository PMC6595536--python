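"""Seeded synthetic two-channel EEG with a controllable band-energy shift.

The generator writes band-structured Gaussian noise in consecutive blocks
aligned to the downstream frame grid.  Non-apnea blocks concentrate energy
in the low bands (delta-dominant); blocks covered by a scheduled apnea event
shift energy toward the high bands (sigma, beta).  Per-band noise is
synthesised with the same FFT brick-wall used by the analysis stage and then
rescaled, so each block's band-energy fractions equal the configured weights
exactly before channel noise is added.  Both channels share the
band-structured component and receive independent additive white noise,
which is what makes two-channel averaging pay off downstream.

Event onsets land on the block grid and durations are continuous, so every
event fully contains at least one analysis frame while frames straddling an
event edge are excluded by the labelling stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bands import DEFAULT_BANDS, _bin_mask
from .errors import ConfigError
from .io import AnnotationSet, Event, Recording, DEFAULT_CHANNELS

__all__ = [
    "SyntheticConfig",
    "DEFAULT_WEIGHTS_NON_APNEA",
    "DEFAULT_WEIGHTS_APNEA",
    "generate_band_noise",
    "generate_recording",
]

DEFAULT_WEIGHTS_NON_APNEA: dict[str, float] = {
    "delta": 0.70, "theta": 0.15, "alpha": 0.08, "sigma": 0.04, "beta": 0.03,
}
DEFAULT_WEIGHTS_APNEA: dict[str, float] = {
    "delta": 0.25, "theta": 0.15, "alpha": 0.15, "sigma": 0.20, "beta": 0.25,
}


@dataclass(frozen=True)
class SyntheticConfig:
    sampling_rate: float = 128.0
    duration: float = 600.0
    band_weights_non_apnea: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS_NON_APNEA)
    )
    band_weights_apnea: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS_APNEA)
    )
    n_events: int = 5
    event_duration_range: tuple[float, float] = (10.0, 25.0)
    inter_event_gap_min: float = 30.0
    channel_noise_sd: float = 0.25
    block_duration: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        for name, weights in (
            ("band_weights_non_apnea", self.band_weights_non_apnea),
            ("band_weights_apnea", self.band_weights_apnea),
        ):
            missing = {b.name for b in DEFAULT_BANDS} - set(weights)
            if missing:
                raise ConfigError(f"{name} lacks bands {sorted(missing)}")
            vals = np.array([weights[b.name] for b in DEFAULT_BANDS])
            if (vals < 0).any():
                raise ConfigError(f"{name} has negative weights")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1, got {vals.sum()!r}")
        lo, hi = self.event_duration_range
        if not 0 < lo <= hi:
            raise ConfigError("event_duration_range must satisfy 0 < min <= max")
        if lo < self.block_duration:
            raise ConfigError(
                "minimum event duration must be >= block_duration so every "
                "event fully contains one frame"
            )
        if self.n_events < 0 or self.duration <= 0 or self.sampling_rate <= 0:
            raise ConfigError("n_events >= 0 and positive duration/rate required")
        if self.channel_noise_sd < 0:
            raise ConfigError("channel_noise_sd must be >= 0")


def generate_band_noise(
    band: tuple[float, float],
    n_samples: int,
    sampling_rate: float,
    target_energy: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """White Gaussian noise brick-wall filtered to ``band`` and rescaled so
    its sum of squares equals ``target_energy`` exactly."""
    lo, hi = band
    if not (0 <= lo < hi <= sampling_rate / 2):
        raise ConfigError(
            f"invalid band edges ({lo}, {hi}) for sampling rate {sampling_rate}"
        )
    if n_samples <= 0:
        raise ConfigError("n_samples must be positive")
    if target_energy < 0:
        raise ConfigError("target_energy must be >= 0")
    white = rng.standard_normal(n_samples)
    if target_energy == 0.0:
        return np.zeros(n_samples)
    mask = _bin_mask(n_samples, sampling_rate, lo, hi)
    filtered = np.fft.irfft(np.where(mask, np.fft.rfft(white), 0.0), n=n_samples)
    energy = float(np.sum(filtered**2))
    if energy == 0.0:
        raise ConfigError(
            f"band ({lo}, {hi}) Hz contains no DFT bin at n={n_samples}, "
            f"fs={sampling_rate}; cannot reach a positive target energy"
        )
    return filtered * np.sqrt(target_energy / energy)


def _schedule_events(config: SyntheticConfig, rng: np.random.Generator) -> list[Event]:
    """Rejection-sample non-overlapping events with grid-aligned onsets."""
    if config.n_events == 0:
        return []
    dmin, dmax = config.event_duration_range
    gap = config.inter_event_gap_min
    if config.n_events * (dmax + gap) > config.duration:
        raise ConfigError(
            f"cannot place {config.n_events} events of up to {dmax}s with "
            f"{gap}s gaps in {config.duration}s"
        )
    grid = config.block_duration
    n_slots = int(np.floor((config.duration - dmax) / grid)) + 1
    placed: list[tuple[float, float]] = []
    attempts = 0
    stuck = 0
    while len(placed) < config.n_events:
        attempts += 1
        if attempts > 2000 * config.n_events:
            raise ConfigError(
                "event schedule infeasible: rejection sampling exhausted "
                "(reduce n_events or inter_event_gap_min, or extend duration)"
            )
        onset = float(rng.integers(0, n_slots)) * grid
        duration = float(rng.uniform(dmin, dmax))
        if all(
            onset + duration + gap <= o or o + d + gap <= onset
            for o, d in placed
        ):
            placed.append((onset, duration))
            stuck = 0
        else:
            stuck += 1
            if stuck >= 200:  # partial schedule jammed: restart from empty
                placed.clear()
                stuck = 0
    return [Event(o, d, "apnea") for o, d in sorted(placed)]


def _block_conditions(
    config: SyntheticConfig, events: list[Event], n_blocks: int
) -> np.ndarray:
    """Per-block apnea flag: majority overlap with the event union."""
    flags = np.zeros(n_blocks, dtype=bool)
    for b in range(n_blocks):
        t0 = b * config.block_duration
        t1 = min((b + 1) * config.block_duration, config.duration)
        overlap = sum(
            max(0.0, min(t1, e.end) - max(t0, e.onset)) for e in events
        )
        flags[b] = overlap > (t1 - t0) / 2.0
    return flags


def generate_recording(config: SyntheticConfig) -> tuple[Recording, AnnotationSet]:
    """Synthesise a two-channel recording and its annotation schedule.

    Deterministic for a given config (seed included); the per-sample energy
    density of the shared band-structured component is 1.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    events = _schedule_events(config, rng)

    fs = config.sampling_rate
    n_total = int(round(config.duration * fs))
    block_len = int(round(config.block_duration * fs))
    n_blocks = int(np.ceil(n_total / block_len))
    flags = _block_conditions(config, events, n_blocks)

    shared = np.empty(n_total)
    for b in range(n_blocks):
        i0, i1 = b * block_len, min((b + 1) * block_len, n_total)
        n = i1 - i0
        weights = (
            config.band_weights_apnea if flags[b] else config.band_weights_non_apnea
        )
        block = np.zeros(n)
        for band in DEFAULT_BANDS:
            w = weights[band.name]
            block += generate_band_noise((band.lo, band.hi), n, fs, w * n, rng)
        shared[i0:i1] = block

    data = np.tile(shared, (2, 1))
    if config.channel_noise_sd > 0:
        data = data + rng.normal(0.0, config.channel_noise_sd, size=data.shape)

    recording = Recording(
        sampling_rate=fs, labels=list(DEFAULT_CHANNELS), data=data
    )
    return recording, AnnotationSet(list(events))


def null_config(config: SyntheticConfig) -> SyntheticConfig:
    """Copy of ``config`` whose apnea weights equal its non-apnea weights
    (no class signal) — the negative control for end-to-end tests."""
    return replace(
        config, band_weights_apnea=dict(config.band_weights_non_apnea)
    )
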