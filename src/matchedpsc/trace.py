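"""Core containers for voltage-clamp current traces and user marks.

A :class:`Trace` is a single uniformly sampled whole-cell current recording
(in pA, typically digitized at 10 kHz) with optional photostimulation
metadata: the laser-onset time and the (row, col) index of the stimulation
site on the mapping grid.  Excitatory events (EPSCs) are inward, i.e.
negative deflections; inhibitory events (IPSCs) are outward and are handled
by sign inversion, tracked through the ``polarity`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np

INWARD = "inward"
INVERTED = "inverted"


@dataclass
class Trace:
    """A uniformly sampled current recording.

    Parameters
    ----------
    samples :
        Current values in pA.
    sampling_rate :
        Sampling rate in Hz (default 10 kHz).
    laser_onset :
        Photostimulation onset in ms from the start of the trace, or None
        for recordings without a stimulus (e.g. spontaneous activity).
    site :
        (row, col) index on the photostimulation grid, or None.
    polarity :
        ``"inward"`` for native EPSC recordings, ``"inverted"`` after sign
        inversion of an outward (IPSC) recording.
    """

    samples: np.ndarray
    sampling_rate: float = 10_000.0
    laser_onset: Optional[float] = None
    site: Optional[Tuple[int, int]] = None
    polarity: str = INWARD

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.polarity not in (INWARD, INVERTED):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.laser_onset is not None:
            if not 0.0 <= self.laser_onset <= self.duration_ms:
                raise ValueError("laser_onset lies outside the trace extent")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def dt_ms(self) -> float:
        """Sampling interval in ms."""
        return 1000.0 / self.sampling_rate

    @property
    def duration_ms(self) -> float:
        return self.n_samples * self.dt_ms

    def time_ms(self) -> np.ndarray:
        """Sample times in ms (first sample at t = 0)."""
        return np.arange(self.n_samples) * self.dt_ms

    def index_at(self, t_ms: float) -> int:
        """Nearest sample index to a time in ms."""
        return int(round(t_ms / self.dt_ms))

    def with_samples(self, samples: np.ndarray, **changes) -> "Trace":
        return replace(self, samples=samples, **changes)


@dataclass(frozen=True)
class MarkedEvent:
    """A user-marked training EPSC: onset/offset/peak sample indices.

    Indices are 0-based with inclusive endpoints.  The peak is the negative
    extremum between onset and offset; when not supplied it is located
    automatically.
    """

    onset_index: int
    offset_index: int
    peak_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.onset_index >= self.offset_index:
            raise ValueError("onset_index must precede offset_index")
        if self.peak_index is not None:
            if not self.onset_index < self.peak_index < self.offset_index:
                raise ValueError("peak_index must lie strictly inside the mark")

    def resolve_peak(self, trace: Trace) -> int:
        """Peak index, locating the negative extremum if not supplied."""
        if self.peak_index is not None:
            return self.peak_index
        seg = trace.samples[self.onset_index : self.offset_index + 1]
        return self.onset_index + int(np.argmin(seg))
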