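"""Core data containers shared across the package.

A :class:`SignalTrace` is a uniformly sampled voltage time-series (tremor
monitor or EMG); a :class:`SpikeTrain` is a sorted list of event times with
optional simple/complex labels. Both are frozen dataclasses: analysis
operations return new objects rather than mutating their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SignalTrace",
    "SpikeTrain",
    "SIMPLE",
    "COMPLEX",
    "UNLABELLED",
]

#: Event labels used in :class:`SpikeTrain.labels`.
SIMPLE = "S"
COMPLEX = "C"
UNLABELLED = "U"


@dataclass(frozen=True)
class SignalTrace:
    """Uniformly sampled voltage time-series.

    Parameters
    ----------
    samples:
        Voltage samples (volts). Stored as a float64 array.
    fs_hz:
        Sampling rate in samples per second, must be positive.
    t0_s:
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    fs_hz: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if samples.size == 0:
            raise ValueError("trace must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("trace contains non-finite samples")
        if not (self.fs_hz > 0):
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Recording span in seconds (n / fs)."""
        return self.samples.size / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0_s + np.arange(self.samples.size) / self.fs_hz


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted single-unit event times with per-event labels.

    Purkinje-cell trains carry simple-spike (``"S"``) and complex-spike
    (``"C"``) labels; cerebellar-nuclei trains are all-unlabelled (``"U"``).

    Parameters
    ----------
    times_s:
        Strictly increasing event times in seconds.
    labels:
        Per-event label, one of ``{"S", "C", "U"}``. If omitted, all events
        are unlabelled.
    duration_s:
        Recording span in seconds; must cover the events. If omitted, the
        span of the event times is used.
    """

    times_s: np.ndarray
    labels: np.ndarray | None = None
    duration_s: float | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=np.float64)
        if times.ndim != 1:
            raise ValueError("times_s must be one-dimensional")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("event times must be strictly increasing")
        labels = self.labels
        if labels is None:
            labels = np.full(times.size, UNLABELLED, dtype="U1")
        else:
            labels = np.asarray(labels, dtype="U1")
            if labels.shape != times.shape:
                raise ValueError("labels must match times_s in length")
            bad = set(np.unique(labels)) - {SIMPLE, COMPLEX, UNLABELLED}
            if bad:
                raise ValueError(f"unknown labels: {sorted(bad)}")
        duration = self.duration_s
        if duration is None:
            duration = float(times[-1] - times[0]) if times.size >= 2 else 0.0
        span = float(times[-1] - times[0]) if times.size >= 2 else 0.0
        if duration < span:
            raise ValueError("duration_s must cover the event span")
        object.__setattr__(self, "times_s", times)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "duration_s", float(duration))

    def __len__(self) -> int:
        return self.times_s.size

    def select(self, label: str) -> np.ndarray:
        """Event times carrying ``label``."""
        return self.times_s[self.labels == label]

    @property
    def is_labelled(self) -> bool:
        return bool(np.any(self.labels != UNLABELLED))
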