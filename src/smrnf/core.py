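"""Core domain types shared by every stage of the pipeline.

The study design being simulated: 16-channel 10-20 EEG at 256 Hz, one
baseline run plus six feedback runs of 3 min each, four groups
(3D/2D visual paradigm x real/sham feedback), SMR (12-15 Hz) trained at Cz
with Theta (4-7 Hz) and Beta (16-30 Hz) as artifact-control bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BandDefinition",
    "SMR",
    "THETA",
    "BETA",
    "CANONICAL_BANDS",
    "Montage",
    "SessionLayout",
    "ArtifactEvent",
    "EEGRecording",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [f_lo, f_hi] in Hz with an optional centre override."""

    name: str
    f_lo: float
    f_hi: float
    _f_center: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise ValueError(f"invalid band edges ({self.f_lo}, {self.f_hi})")

    @property
    def f_center(self) -> float:
        return self._f_center if self._f_center is not None else 0.5 * (self.f_lo + self.f_hi)

    @property
    def bandwidth(self) -> float:
        return self.f_hi - self.f_lo

    def validate_for_rate(self, sample_rate: float) -> None:
        if self.f_hi >= sample_rate / 2.0:
            raise ValueError(
                f"band {self.name} [{self.f_lo}, {self.f_hi}] Hz exceeds the "
                f"Nyquist frequency {sample_rate / 2.0} Hz"
            )


SMR = BandDefinition("SMR", 12.0, 15.0)
THETA = BandDefinition("Theta", 4.0, 7.0)
BETA = BandDefinition("Beta", 16.0, 30.0)
CANONICAL_BANDS: dict[str, BandDefinition] = {b.name: b for b in (SMR, THETA, BETA)}

#: The 12 scalp electrodes analysed offline (10-20 names, row order fixed).
DEFAULT_EEG_LABELS = ("F3", "Fz", "F4", "C3", "Cz", "C4", "CPz", "P3", "Pz", "P4", "O1", "O2")
DEFAULT_EOG_LABELS = ("EOG1", "EOG2", "EOG3")
#: M1 is the online reference (left mastoid), M2 is recorded for offline
#: conversion to a linked-mastoid reference.
DEFAULT_REF_LABELS = ("M1", "M2")


@dataclass(frozen=True)
class Montage:
    """Channel bookkeeping: scalp EEG, EOG, mastoid references, feedback site."""

    eeg_labels: tuple[str, ...] = DEFAULT_EEG_LABELS
    eog_labels: tuple[str, ...] = DEFAULT_EOG_LABELS
    ref_labels: tuple[str, ...] = DEFAULT_REF_LABELS
    feedback_channel: str = "Cz"

    def __post_init__(self) -> None:
        if self.feedback_channel not in self.eeg_labels:
            raise ValueError("feedback channel must be a scalp EEG channel")
        all_labels = self.eeg_labels + self.eog_labels + self.ref_labels
        if len(set(all_labels)) != len(all_labels):
            raise ValueError("duplicate channel labels in montage")

    @property
    def all_labels(self) -> tuple[str, ...]:
        return self.eeg_labels + self.eog_labels + self.ref_labels

    @property
    def n_channels(self) -> int:
        return len(self.all_labels)

    def index(self, label: str) -> int:
        return self.all_labels.index(label)

    def indices(self, labels) -> list[int]:
        return [self.index(l) for l in labels]

    @property
    def eeg_indices(self) -> list[int]:
        return self.indices(self.eeg_labels)

    @property
    def eog_indices(self) -> list[int]:
        return self.indices(self.eog_labels)


@dataclass(frozen=True)
class SessionLayout:
    """Run structure of one session: 1 baseline + 6 feedback runs, 3 min each."""

    n_baseline_runs: int = 1
    n_feedback_runs: int = 6
    run_duration: float = 180.0  # seconds
    sample_rate: float = 256.0  # Hz

    def __post_init__(self) -> None:
        if self.n_baseline_runs < 1 or self.n_feedback_runs < 1:
            raise ValueError("run counts must be positive")
        if self.run_duration <= 0 or self.sample_rate <= 0:
            raise ValueError("run_duration and sample_rate must be positive")

    @property
    def n_runs(self) -> int:
        return self.n_baseline_runs + self.n_feedback_runs

    @property
    def samples_per_run(self) -> int:
        return int(round(self.run_duration * self.sample_rate))

    def run_label(self, run_index: int) -> str:
        """0 -> 'baseline', 1..6 -> 'fb1'..'fb6'."""
        if run_index == 0:
            return "baseline"
        return f"fb{run_index}"


@dataclass(frozen=True)
class ArtifactEvent:
    """A logged artifact: onset/duration in seconds, kind 'blink' or 'muscle'."""

    onset: float
    duration: float
    kind: str


@dataclass
class EEGRecording:
    """One run of multi-channel EEG in microvolts.

    ``data`` is (n_channels, n_samples); channel order follows
    ``montage.all_labels``.  ``event_log`` records every injected artifact so
    tests can compare signal content against ground truth.
    """

    data: np.ndarray
    sample_rate: float
    montage: Montage
    run_label: str = "baseline"
    subject_id: str = "S00"
    event_log: list[ArtifactEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels, montage expects "
                f"{self.montage.n_channels}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channel(self, label: str) -> np.ndarray:
        """Return one channel's samples (a view)."""
        return self.data[self.montage.index(label)]

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(), event_log=list(self.event_log))
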