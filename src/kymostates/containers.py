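"""Core data containers: kymographs, height/time traces and ground truth.

All heights are in nanometres, all times in seconds.  A kymograph is a
time x lateral-position grid: row ``i`` is the scan line acquired at
``i * line_period`` and each column is one lateral pixel.  Traces and
state sequences are sampled once per scan line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError

__all__ = ["TraceTruth", "HeightTrace", "Kymograph", "TopographyImage", "n_samples_for"]


def n_samples_for(duration: float, period: float) -> int:
    """Number of samples at times ``k * period`` strictly below ``duration``.

    Samples are placed at ``t = 0, period, 2*period, ...`` and the last one
    satisfies ``t < duration`` (up to a relative tolerance guarding float
    round-off).  With a 3.3 ms line period, 60 s of recording gives 18182
    lines.
    """
    if period <= 0:
        raise ConfigurationError("sampling period must be positive")
    return int(np.floor(duration / period - 1e-9)) + 1


@dataclass
class TraceTruth:
    """Ground-truth piecewise-constant state sequence of one protomer.

    Parameters
    ----------
    change_times
        Strictly increasing interior segment boundaries in seconds.  The
        first segment starts at 0 and the last ends at ``duration``.
    state_labels
        One label per segment; adjacent labels differ.
    segment_heights
        Mean height above the membrane baseline per segment (nm).
    duration
        Total span in seconds.  The final dwell is truncated here and is
        therefore right-censored; the first dwell is left-censored.
    """

    change_times: np.ndarray
    state_labels: list
    segment_heights: np.ndarray
    duration: float
    sampling_period: Optional[float] = None
    last_truncated: bool = True
    seed: Optional[int] = None
    active: bool = True

    def __post_init__(self):
        self.change_times = np.asarray(self.change_times, dtype=float)
        self.segment_heights = np.asarray(self.segment_heights, dtype=float)
        if self.change_times.size and np.any(np.diff(self.change_times) <= 0):
            raise ConfigurationError("change_times must be strictly increasing")
        if len(self.state_labels) != self.change_times.size + 1:
            raise ConfigurationError("need one label per segment")
        if self.segment_heights.size != len(self.state_labels):
            raise ConfigurationError("need one height per segment")
        for a, b in zip(self.state_labels[:-1], self.state_labels[1:]):
            if a == b:
                raise ConfigurationError("adjacent segments must have distinct labels")

    @property
    def n_segments(self) -> int:
        return len(self.state_labels)

    def segment_index_at(self, times: np.ndarray) -> np.ndarray:
        """Index of the segment containing each time point."""
        return np.searchsorted(self.change_times, np.asarray(times), side="right")

    def heights_at(self, times: np.ndarray) -> np.ndarray:
        return self.segment_heights[self.segment_index_at(times)]

    def labels_at(self, times: np.ndarray) -> np.ndarray:
        labels = np.asarray(self.state_labels, dtype=object)
        return labels[self.segment_index_at(times)]

    def transition_sample_indices(self, period: float, n_samples: int) -> np.ndarray:
        """Sample index of the first sample after each true transition."""
        idx = np.ceil(self.change_times / period - 1e-9).astype(int)
        return idx[(idx > 0) & (idx < n_samples)]

    def segment_durations(self) -> np.ndarray:
        bounds = np.concatenate([[0.0], self.change_times, [self.duration]])
        return np.diff(bounds)


@dataclass
class HeightTrace:
    """Height versus time of one protomer, relative to the membrane baseline."""

    times: np.ndarray
    heights: np.ndarray
    track_id: Optional[int] = None
    condition: Optional[str] = None
    truth: Optional[TraceTruth] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.times.shape != self.heights.shape:
            raise ConfigurationError("times and heights must have equal length")

    @property
    def sampling_period(self) -> float:
        if self.times.size < 2:
            raise ConfigurationError("trace too short to define a sampling period")
        return float(self.times[1] - self.times[0])

    @property
    def n_samples(self) -> int:
        return self.times.size


@dataclass
class Kymograph:
    """Line-scan record: rows are scan lines in time order, columns pixels."""

    heights: np.ndarray
    line_period: float
    pixel_size: float
    meta: dict = field(default_factory=dict)
    truths: Optional[list] = None

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ConfigurationError("kymograph must be a 2D array")
        if not np.all(np.isfinite(self.heights)):
            raise ConfigurationError("kymograph contains non-finite values")
        if self.line_period <= 0 or self.pixel_size <= 0:
            raise ConfigurationError("line_period and pixel_size must be positive")

    @property
    def n_lines(self) -> int:
        return self.heights.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.heights.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_lines) * self.line_period


@dataclass
class TopographyImage:
    """2D height map of a membrane area (nm) with square pixels."""

    heights: np.ndarray
    pixel_size: float

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if not np.all(np.isfinite(self.heights)):
            raise ConfigurationError("topography contains non-finite values")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be positive")
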