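"""Core in-memory containers for multichannel muscle recordings.

A :class:`Recording` holds a raw multichannel time series (EMG voltages or
OPM-MMG magnetic flux) together with its sampling rate and per-channel
metadata; an :class:`EventTable` holds the movement onsets and class labels;
an :class:`EnvelopeSeries` is the 200 Hz band-power envelope derived from a
recording by the preprocessing pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: canonical class order used throughout the package
CLASS_LABELS = ("DII", "DV", "NoMove")
#: the two movement classes (NoMove windows are sampled from pre-onset rest)
MOVEMENT_LABELS = ("DII", "DV")

MODALITIES = ("EMG", "MMG")
AXES = ("Y", "Z", "none")
SIDES = ("ulnar", "radial")


@dataclass(frozen=True)
class Channel:
    """Metadata for one sensor channel.

    Parameters
    ----------
    name : str
        Channel name, e.g. ``"EMG-2"`` or ``"OPM-4Z"``.
    modality : {"EMG", "MMG"}
    axis : {"Y", "Z", "none"}
        Sensitive axis for biaxial OPM channels; ``"none"`` for EMG.
    side : {"ulnar", "radial"}
        Anatomical side of the forearm the sensor sits on.
    """

    name: str
    modality: str
    axis: str = "none"
    side: str = "radial"

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.axis not in AXES:
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")


def _validate_multichannel(data: np.ndarray, channels: list[Channel], fs: float) -> None:
    if data.ndim != 2:
        raise ValueError("data must be 2-D (channels x samples)")
    if data.shape[0] != len(channels):
        raise ValueError(
            f"data has {data.shape[0]} rows but {len(channels)} channels declared"
        )
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    if not np.all(np.isfinite(data)):
        raise ValueError("data contains NaN or Inf")


@dataclass
class Recording:
    """Raw multichannel time series with sampling rate and channel metadata."""

    data: np.ndarray  # (channels, samples)
    fs: float
    channels: list[Channel]
    session_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        _validate_multichannel(self.data, self.channels, self.fs)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def modality(self) -> str:
        mods = {c.modality for c in self.channels}
        if len(mods) != 1:
            raise ValueError("recording mixes modalities")
        return mods.pop()


@dataclass
class EnvelopeSeries:
    """Per-channel band-power envelope of a recording, resampled (default 200 Hz).

    Values are instantaneous amplitudes (magnitude of the analytic signal) and
    are therefore non-negative.
    """

    data: np.ndarray  # (channels, samples)
    fs: float
    channels: list[Channel]
    session_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        _validate_multichannel(self.data, self.channels, self.fs)
        if np.any(self.data < 0):
            raise ValueError("envelope values must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EventTable:
    """Movement onsets, durations and class labels for one session."""

    onsets: np.ndarray  # seconds from recording start
    durations: np.ndarray  # seconds
    labels: np.ndarray  # str, drawn from label_set
    label_set: tuple[str, ...] = MOVEMENT_LABELS

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if not (len(self.onsets) == len(self.durations) == len(self.labels)):
            raise ValueError("onsets, durations, labels must have equal length")
        if len(self.onsets) > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")
        unknown = set(self.labels) - set(self.label_set)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in declared set {self.label_set}")

    def __len__(self) -> int:
        return len(self.onsets)

    def validate_against(self, duration: float) -> None:
        """Check every event lies inside a recording of the given duration."""
        if len(self) and np.any(self.onsets + self.durations > duration + 1e-9):
            raise ValueError("event extends past the end of the recording")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"onset_s": self.onsets, "duration_s": self.durations, "label": self.labels}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label_set=MOVEMENT_LABELS) -> "EventTable":
        return cls(
            onsets=df["onset_s"].to_numpy(),
            durations=df["duration_s"].to_numpy(),
            labels=df["label"].to_numpy(),
            label_set=label_set,
        )


@dataclass(frozen=True)
class Trial:
    """One cued movement trial, used as the unit of cross-validation splits."""

    session: int  # index into the session list
    index: int  # event index within the session
    onset: float  # seconds within the session
    label: str
    trial_start: float  # trial boundary start, seconds
    trial_end: float


def build_trial_table(
    events: list[EventTable], trial_len: float, session_durations: list[float] | None = None
) -> list[Trial]:
    """Flatten per-session event tables into a global trial list.

    Trial boundaries are the cue grid (``trial_len`` seconds per trial); windows
    sampled later are constrained to stay inside their trial.
    """
    trials: list[Trial] = []
    for s, table in enumerate(events):
        dur = session_durations[s] if session_durations is not None else np.inf
        for i in range(len(table)):
            start = np.floor(table.onsets[i] / trial_len) * trial_len
            end = min(start + trial_len, dur)
            trials.append(
                Trial(
                    session=s,
                    index=i,
                    onset=float(table.onsets[i]),
                    label=str(table.labels[i]),
                    trial_start=float(start),
                    trial_end=float(end),
                )
            )
    return trials
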