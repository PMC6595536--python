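"""Band energies and inter-band energy-ratio feature vectors.

The full feature vector is the ten ordered ratios

    delta-theta, delta-alpha, delta-sigma, delta-beta, theta-alpha,
    theta-sigma, theta-beta, alpha-sigma, alpha-beta, sigma-beta

where ``p-q`` denotes ``E_p / E_q`` (lower band in the numerator).  The
reduced set is the first five of these.  Ratios are scale-invariant, so the
features are unaffected by per-frame gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, DEFAULT_BANDS, BandDefinition, extract_bands
from .errors import ConfigError, DataError, DegenerateBandError

__all__ = [
    "FeatureVector",
    "RATIO_NAMES_FULL",
    "RATIO_NAMES_REDUCED",
    "band_energy",
    "energy_ratio",
    "featurize",
    "featurize_frames",
    "write_feature_matrix",
    "read_feature_matrix",
]

# (numerator, denominator) band indices, in the fixed published order.
_RATIO_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 1), (0, 2), (0, 3), (0, 4), (1, 2),
    (1, 3), (1, 4), (2, 3), (2, 4), (3, 4),
)

RATIO_NAMES_FULL: tuple[str, ...] = tuple(
    f"{BAND_NAMES[p]}-{BAND_NAMES[q]}" for p, q in _RATIO_PAIRS
)
RATIO_NAMES_REDUCED: tuple[str, ...] = RATIO_NAMES_FULL[:5]


@dataclass(frozen=True)
class FeatureVector:
    values: np.ndarray
    names: tuple[str, ...]
    feature_set: str

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ConfigError("feature values and names differ in length")


def band_energy(band_signal: np.ndarray) -> float:
    """Sum of squared samples of one band-limited signal."""
    band_signal = np.asarray(band_signal, dtype=float)
    if band_signal.size == 0:
        raise DataError("band signal is empty")
    return float(np.sum(band_signal**2))


def energy_ratio(e_p: float, e_q: float, q_name: str = "denominator") -> float:
    if e_q <= 0.0:
        raise DegenerateBandError(
            f"band {q_name!r} has zero energy; cannot form an energy ratio "
            "(flat or broken frame?)"
        )
    return e_p / e_q


def _ratio_count(feature_set: str) -> int:
    if feature_set == "full":
        return 10
    if feature_set == "reduced":
        return 5
    raise ConfigError(f"unknown feature_set {feature_set!r}")


def featurize(
    frame: np.ndarray,
    sampling_rate: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    feature_set: str = "full",
    floor_zero_energy: bool = False,
) -> FeatureVector:
    """Compute the inter-band energy-ratio feature vector of one frame.

    ``floor_zero_energy`` replaces an exactly-zero band energy with
    ``1e-12 x`` the total frame energy instead of raising, for batch runs
    over noisy data.
    """
    k = _ratio_count(feature_set)
    band_signals = extract_bands(frame, sampling_rate, bands)
    energies = np.array([band_energy(band_signals[b.name]) for b in bands])
    if floor_zero_energy:
        total = float(np.sum(np.asarray(frame, dtype=float) ** 2))
        energies = np.maximum(energies, 1e-12 * max(total, 1e-300))
    names = []
    values = np.empty(k)
    for i, (p, q) in enumerate(_RATIO_PAIRS[:k]):
        values[i] = energy_ratio(energies[p], energies[q], bands[q].name)
        names.append(f"{bands[p].name}-{bands[q].name}")
    return FeatureVector(values=values, names=tuple(names), feature_set=feature_set)


def featurize_frames(
    frames: np.ndarray,
    sampling_rate: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    feature_set: str = "full",
    floor_zero_energy: bool = False,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Feature matrix (n_frames, n_ratios) for a stack of frames."""
    frames = np.atleast_2d(np.asarray(frames, dtype=float))
    rows = [
        featurize(f, sampling_rate, bands, feature_set, floor_zero_energy)
        for f in frames
    ]
    names = rows[0].names if rows else tuple(RATIO_NAMES_FULL[:_ratio_count(feature_set)])
    return np.array([r.values for r in rows]).reshape(len(rows), -1), names


def write_feature_matrix(
    path,
    features: np.ndarray,
    names,
    labels,
    frame_starts,
    subject_id: str,
) -> None:
    """Write the per-frame feature matrix as TSV (the stage interchange format)."""
    df = pd.DataFrame(np.asarray(features, dtype=float), columns=list(names))
    df.insert(0, "label", list(labels))
    df.insert(0, "frame_start_s", np.asarray(frame_starts, dtype=float))
    df.insert(0, "subject_id", subject_id)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_matrix(path):
    """Read a feature matrix TSV.

    Returns ``(features, labels, frame_starts, subject_id, names)``.
    """
    df = pd.read_csv(path, sep="\t")
    meta = ["subject_id", "frame_start_s", "label"]
    for col in meta:
        if col not in df.columns:
            raise DataError(f"feature matrix {path} lacks required column {col!r}")
    names = tuple(c for c in df.columns if c not in meta)
    subjects = df["subject_id"].unique()
    subject_id = str(subjects[0]) if len(subjects) == 1 else ""
    return (
        df[list(names)].to_numpy(dtype=float),
        df["label"].to_numpy(dtype=object),
        df["frame_start_s"].to_numpy(dtype=float),
        subject_id,
        names,
    )
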