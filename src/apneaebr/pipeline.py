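"""End-to-end wiring: recording + annotations -> balanced feature matrix.

Order of stages follows the method's flow: average the two channels,
segment, label against annotations, balance the classes, preprocess each
frame, then featurize.
"""

from __future__ import annotations

import numpy as np

from .bands import DEFAULT_BANDS
from .features import featurize_frames
from .framing import balance, label_frames, preprocess_frames, segment
from .io import AnnotationSet, Recording, average_channels

__all__ = ["extract_subject_features"]


def extract_subject_features(
    recording: Recording,
    annotations: AnnotationSet,
    channels: tuple[str, str] | None = None,
    frame_duration: float = 10.0,
    guard: float = 30.0,
    balance_seed: int = 0,
    feature_set: str = "full",
    bands=DEFAULT_BANDS,
    floor_zero_energy: bool = False,
):
    """Run the full per-subject feature pipeline.

    Returns ``(features, names, labels, frame_starts)`` where features is a
    class-balanced (n_frames, n_ratios) matrix.
    """
    signal = average_channels(recording, channels)
    frames = segment(signal, recording.sampling_rate, frame_duration)
    frames = label_frames(frames, annotations, guard=guard)
    frames = balance(frames, seed=balance_seed)
    if len(frames) == 0:
        return (
            np.empty((0, 10 if feature_set == "full" else 5)),
            (),
            np.array([], dtype=object),
            np.array([]),
        )
    frames = preprocess_frames(frames)
    features, names = featurize_frames(
        frames.samples,
        recording.sampling_rate,
        bands=bands,
        feature_set=feature_set,
        floor_zero_energy=floor_zero_energy,
    )
    return features, names, frames.labels, frames.starts
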