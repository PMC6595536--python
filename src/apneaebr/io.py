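"""Recording and annotation I/O, and the two-channel time-domain average.

Recordings are read from EDF or delimited text (one column per channel);
annotations are a 3-column text format: ``onset_s<TAB>duration_s<TAB>label``,
one event per line, seconds from recording start.  Annotated intervals are
half-open ``[onset, onset + duration)``; overlapping events are merged into
their union after parsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AnnotationParseError, ConfigError, DataError, MissingChannelError
from . import edf as _edf

__all__ = [
    "Recording",
    "Event",
    "AnnotationSet",
    "DEFAULT_CHANNELS",
    "APNEA_LABEL_SUBSTRINGS",
    "read_recording",
    "write_delimited",
    "read_annotations",
    "write_annotations",
    "average_channels",
]

DEFAULT_CHANNELS: tuple[str, str] = ("C3-A2", "C4-A1")
APNEA_LABEL_SUBSTRINGS: tuple[str, ...] = ("apnea", "hypopnea")


@dataclass
class Recording:
    """Multichannel uniformly sampled signal."""

    sampling_rate: float
    labels: list[str]
    data: np.ndarray  # (n_channels, n_samples)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise DataError("channel labels and data rows differ in count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise MissingChannelError(
                f"channel {label!r} not found; available: {self.labels}"
            ) from None


@dataclass(frozen=True)
class Event:
    onset: float
    duration: float
    label: str

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class AnnotationSet:
    """Ordered, non-overlapping events on a recording's timeline."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = _normalise(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def apnea_intervals(
        self, label_whitelist: tuple[str, ...] = APNEA_LABEL_SUBSTRINGS
    ) -> list[tuple[float, float]]:
        """Half-open ``(start, end)`` intervals counted as apnea."""
        return [
            (e.onset, e.end)
            for e in self.events
            if any(s in e.label for s in label_whitelist)
        ]


def _normalise(events: list[Event]) -> list[Event]:
    for e in events:
        if e.duration <= 0:
            raise AnnotationParseError(f"event at {e.onset}s has non-positive duration")
    events = sorted(
        (Event(e.onset, e.duration, e.label.strip().lower()) for e in events),
        key=lambda e: (e.onset, e.end),
    )
    merged: list[Event] = []
    for e in events:
        if merged and e.onset < merged[-1].end:  # overlap -> union
            prev = merged[-1]
            label = prev.label if prev.label == e.label else f"{prev.label}+{e.label}"
            merged[-1] = Event(prev.onset, max(prev.end, e.end) - prev.onset, label)
        else:
            merged.append(e)
    return merged


def read_annotations(path) -> AnnotationSet:
    """Parse a 3-column (onset, duration, label) annotation text file."""
    events: list[Event] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise AnnotationParseError(
                f"{path}:{lineno}: expected 'onset duration label', got {line!r}"
            )
        try:
            onset, duration = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise AnnotationParseError(
                f"{path}:{lineno}: non-numeric onset/duration in {line!r}"
            ) from exc
        if duration <= 0:
            raise AnnotationParseError(
                f"{path}:{lineno}: duration must be positive, got {duration}"
            )
        events.append(Event(onset, duration, " ".join(parts[2:])))
    return AnnotationSet(events)


def write_annotations(path, annotations: AnnotationSet) -> None:
    with open(path, "w") as fh:
        for e in annotations.events:
            fh.write(f"{e.onset:.6g}\t{e.duration:.6g}\t{e.label}\n")


def _sniff_delimiter(first_line: str) -> str | None:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return None  # whitespace


def read_recording(
    path,
    format: str | None = None,
    sampling_rate: float | None = None,
    labels: list[str] | None = None,
) -> Recording:
    """Read a recording from EDF or delimited text.

    ``format`` is inferred from the suffix when omitted (``.edf`` vs
    anything else).  Delimited files need an explicit ``sampling_rate`` and
    get positional labels ``ch1, ch2, ...`` unless ``labels`` is given.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        signals, edf_labels, fs = _edf.read_edf(path)
        return Recording(sampling_rate=fs, labels=edf_labels, data=signals)
    if format == "delimited":
        if sampling_rate is None:
            raise ConfigError("sampling_rate is required for delimited recordings")
        with open(path) as fh:
            first = fh.readline()
        data = np.loadtxt(path, delimiter=_sniff_delimiter(first), ndmin=2)
        data = data.T  # columns are channels
        if labels is None:
            labels = [f"ch{i + 1}" for i in range(data.shape[0])]
        return Recording(sampling_rate=sampling_rate, labels=list(labels), data=data)
    raise ConfigError(f"unknown recording format {format!r}")


def write_delimited(path, recording: Recording, delimiter: str = "\t") -> None:
    """Dump a recording as delimited text, one column per channel."""
    np.savetxt(path, recording.data.T, fmt="%.8g", delimiter=delimiter)


def average_channels(
    recording: Recording, labels: tuple[str, str] | None = DEFAULT_CHANNELS
) -> np.ndarray:
    """Element-wise mean of two channels (noise-reduction step).

    With ``labels=None`` a two-channel recording is averaged positionally.
    """
    if labels is None:
        if recording.data.shape[0] != 2:
            raise ConfigError(
                "labels=None requires exactly two channels; "
                f"recording has {recording.data.shape[0]}"
            )
        a, b = recording.data
    else:
        a, b = recording.channel(labels[0]), recording.channel(labels[1])
    return (a + b) / 2.0
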