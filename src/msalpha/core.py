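"""Core in-memory containers shared across the pipeline.

Voltages are microvolts throughout; time is seconds at the API boundary and
milliseconds only in reported microstate durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["EEGRecording", "EpochSet", "UNASSIGNED"]

#: Sentinel label for samples that cannot be assigned to any microstate
#: (zero spatial variance).
UNASSIGNED = -1


@dataclass
class EEGRecording:
    """A multichannel EEG segment: ``data`` is samples x channels in µV."""

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D samples x channels array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length does not match channel count")
        if len(set(self.channel_labels)) != self.n_channels:
            raise ValueError("channel labels must be unique")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape[0] != self.n_channels:
                raise ValueError("positions must align 1:1 with channels")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        """Same metadata, new sample matrix."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class EpochSet:
    """Equal-length artifact-screened epochs cut from one recording."""

    epochs: list[EEGRecording]
    epoch_length_s: float
    rejected_count: int = 0
    interpolation_log: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {e.data.shape for e in self.epochs}
        if len(shapes) > 1:
            raise ValueError(f"epochs differ in shape: {shapes}")
        if self.epochs:
            n = round(self.epoch_length_s * self.fs)
            if abs(self.epoch_length_s * self.fs - n) > 1e-9:
                raise ValueError("epoch_length_s x fs must be an integer sample count")

    @property
    def fs(self) -> float:
        return self.epochs[0].fs

    @property
    def n_channels(self) -> int:
        return self.epochs[0].n_channels

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    def concatenated(self) -> np.ndarray:
        """All epochs stacked along time (samples x channels)."""
        return np.concatenate([e.data for e in self.epochs], axis=0)
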