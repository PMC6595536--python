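"""Framing, labelling, class balancing and per-frame preprocessing.

The averaged signal is cut into consecutive non-overlapping frames anchored
at the recording start (10 s by default).  A frame is labelled apnea when it
lies entirely inside one annotated apnea interval, non-apnea when it is at
least ``guard`` seconds away from every apnea interval, and is excluded
otherwise, so no retained frame mixes the two conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, FlatFrameError
from .io import APNEA_LABEL_SUBSTRINGS, AnnotationSet

__all__ = [
    "FrameSet",
    "segment",
    "label_frames",
    "balance",
    "preprocess",
    "preprocess_frames",
]

APNEA = "apnea"
NON_APNEA = "non_apnea"


@dataclass
class FrameSet:
    """Fixed-length frames with start times and (optionally) class labels."""

    samples: np.ndarray  # (n_frames, frame_len)
    starts: np.ndarray  # seconds
    frame_duration: float
    sampling_rate: float
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(
            -1, int(round(self.frame_duration * self.sampling_rate)) or 1
        )
        self.starts = np.asarray(self.starts, dtype=float)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.starts):
                raise DataError("labels and starts differ in length")

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def frame_length(self) -> int:
        return self.samples.shape[1]

    def take(self, indices) -> "FrameSet":
        indices = np.asarray(indices, dtype=int)
        return FrameSet(
            samples=self.samples[indices],
            starts=self.starts[indices],
            frame_duration=self.frame_duration,
            sampling_rate=self.sampling_rate,
            labels=None if self.labels is None else self.labels[indices],
        )

    def class_counts(self) -> dict[str, int]:
        if self.labels is None:
            raise DataError("FrameSet is unlabelled")
        values, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))

    def to_dir(self, directory) -> None:
        """Serialise to delimited text + manifest for stand-alone stages."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "frames.tsv", self.samples, fmt="%.10g", delimiter="\t")
        manifest = pd.DataFrame(
            {
                "frame_start_s": self.starts,
                "label": self.labels if self.labels is not None else [""] * len(self),
            }
        )
        manifest.to_csv(directory / "manifest.tsv", sep="\t", index=False)
        pd.Series(
            {
                "frame_duration": self.frame_duration,
                "sampling_rate": self.sampling_rate,
            }
        ).to_csv(directory / "params.tsv", sep="\t", header=False)

    @classmethod
    def from_dir(cls, directory) -> "FrameSet":
        from pathlib import Path

        directory = Path(directory)
        params = pd.read_csv(
            directory / "params.tsv", sep="\t", header=None, index_col=0
        )[1]
        manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
        samples = np.loadtxt(directory / "frames.tsv", delimiter="\t", ndmin=2)
        labels = manifest["label"].astype(str).to_numpy(dtype=object)
        has_labels = not (manifest["label"].isna() | (labels == "")).any()
        return cls(
            samples=samples,
            starts=manifest["frame_start_s"].to_numpy(dtype=float),
            frame_duration=float(params["frame_duration"]),
            sampling_rate=float(params["sampling_rate"]),
            labels=labels if has_labels else None,
        )


def segment(
    signal: np.ndarray, sampling_rate: float, frame_duration: float = 10.0
) -> FrameSet:
    """Cut a signal into consecutive non-overlapping frames.

    The trailing remainder shorter than one frame is dropped.
    """
    signal = np.asarray(signal, dtype=float)
    frame_len = int(round(frame_duration * sampling_rate))
    if frame_len <= 0:
        raise ConfigError("frame_duration x sampling_rate must be >= 1 sample")
    n_frames = signal.size // frame_len
    if n_frames == 0:
        raise DataError(
            f"signal of {signal.size} samples is shorter than one "
            f"{frame_len}-sample frame"
        )
    samples = signal[: n_frames * frame_len].reshape(n_frames, frame_len)
    starts = np.arange(n_frames) * frame_duration
    return FrameSet(
        samples=samples,
        starts=starts,
        frame_duration=frame_duration,
        sampling_rate=sampling_rate,
    )


def label_frames(
    frames: FrameSet,
    annotations: AnnotationSet,
    guard: float = 30.0,
    label_whitelist: tuple[str, ...] = APNEA_LABEL_SUBSTRINGS,
) -> FrameSet:
    """Label frames apnea / non-apnea from annotated intervals.

    Frames that neither sit fully inside an apnea interval nor keep the
    guard distance from every interval are removed.
    """
    intervals = annotations.apnea_intervals(label_whitelist)
    keep: list[int] = []
    labels: list[str] = []
    for i, start in enumerate(frames.starts):
        end = start + frames.frame_duration
        inside = any(lo <= start and end <= hi for lo, hi in intervals)
        if inside:
            keep.append(i)
            labels.append(APNEA)
            continue
        distance = min(
            (max(lo - end, start - hi, 0.0) for lo, hi in intervals),
            default=np.inf,
        )
        if distance >= guard:
            keep.append(i)
            labels.append(NON_APNEA)
    out = frames.take(keep)
    out.labels = np.asarray(labels, dtype=object)
    return out


def balance(frames: FrameSet, seed: int = 0) -> FrameSet:
    """Keep all apnea frames and an equal-size seeded subsample of non-apnea.

    Uniform subsampling without replacement; frame order is preserved.
    """
    if frames.labels is None:
        raise DataError("balance() needs a labelled FrameSet")
    labels = frames.labels.astype(str)
    apnea_idx = np.flatnonzero(labels == APNEA)
    non_idx = np.flatnonzero(labels == NON_APNEA)
    if apnea_idx.size == 0:
        warnings.warn("no apnea frames: balanced set is empty", stacklevel=2)
        return frames.take([])
    if non_idx.size < apnea_idx.size:
        raise DataError(
            f"only {non_idx.size} non-apnea frames for {apnea_idx.size} apnea "
            "frames; reduce the guard distance or extend the recording"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(non_idx, size=apnea_idx.size, replace=False)
    return frames.take(np.sort(np.concatenate([apnea_idx, chosen])))


def preprocess(frame: np.ndarray) -> np.ndarray:
    """Remove the DC offset, then normalise to unit maximum amplitude.

    The frame mean is subtracted and the result divided by its maximum
    absolute value, so the output has mean 0 and max |.| = 1.  Idempotent.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise DataError("cannot preprocess an empty frame")
    if np.ptp(frame) == 0.0:  # exact-constant frames leave only rounding residue
        raise FlatFrameError("flat frame: zero amplitude after mean removal")
    centred = frame - frame.mean()
    peak = np.max(np.abs(centred))
    if peak == 0.0:
        raise FlatFrameError("flat frame: zero amplitude after mean removal")
    return centred / peak


def preprocess_frames(frames: FrameSet) -> FrameSet:
    """Apply :func:`preprocess` to every frame of a FrameSet."""
    out = frames.take(np.arange(len(frames)))
    out.samples = np.stack([preprocess(f) for f in frames.samples])
    return out
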