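"""Shared data containers for transmission traces and discrete state sequences.

The observable throughout the package is the photodiode transmission voltage
through a double nanohole: a trapped protein's conformation sets the mean
transmission level, so the voltage axis doubles as the conformational
reaction coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["TransmissionTrace", "StateSequence", "as_rng"]


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce ``seed`` (int, Generator or None) into a numpy Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class TransmissionTrace:
    """A voltage time series from a single trapping event.

    Parameters
    ----------
    samples : ndarray
        Transmission voltage in volts, one value per ADC sample.
    sampling_rate : float
        Acquisition rate in Hz (100 kHz in the reference experiments).
    temperature : float
        Local temperature at the trap, in kelvin.
    metadata : dict
        Free-form provenance: PSF sigma, LSB, seeds, generator ground truth.
    """

    samples: np.ndarray
    sampling_rate: float
    temperature: float = 310.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return self.samples.size / self.sampling_rate

    def copy_with(self, samples: np.ndarray, **extra_meta: Any) -> "TransmissionTrace":
        """New trace with replaced samples and updated metadata."""
        meta = dict(self.metadata)
        meta.update(extra_meta)
        return TransmissionTrace(samples, self.sampling_rate, self.temperature, meta)


@dataclass
class StateSequence:
    """Discrete conformational state per analysis slice.

    Label 0 is always the lowest-voltage (most compact) state; for the
    three-state monomer the labels are N=0, F=1, E=2, for the dimer C=0, O=1.
    """

    labels: np.ndarray
    slice_duration: float
    n_states: int
    centers: np.ndarray | None = None  # slice-mean voltage per state, ascending

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D array")
        if self.n_states not in (2, 3):
            raise ValueError("n_states must be 2 or 3")
        if self.slice_duration <= 0:
            raise ValueError("slice_duration must be positive")
        if self.labels.min() < 0 or self.labels.max() >= self.n_states:
            raise ValueError("labels must lie in [0, n_states)")
        if self.centers is not None:
            self.centers = np.asarray(self.centers, dtype=float)

    @property
    def n_slices(self) -> int:
        return self.labels.size

    @property
    def duration(self) -> float:
        return self.labels.size * self.slice_duration
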