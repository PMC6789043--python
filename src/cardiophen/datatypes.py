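"""Core signal containers shared across analysis modules."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageStack", "FluorescenceTrace", "VoltageTrace", "MIN_FRAME_RATE"]

#: Imaging below this frame rate under-resolves T50R; generation and analysis warn.
MIN_FRAME_RATE = 20.0


@dataclass
class ImageStack:
    """A fluorescence video: ``frames`` is (time, rows, cols), intensities float.

    Parameters
    ----------
    frames : ndarray
        3-D intensity array.
    frame_rate : float
        Acquisition rate in Hz.
    pixel_size : float
        Physical pixel size in micrometres per pixel.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be a 3-D array with at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.frame_rate < MIN_FRAME_RATE:
            warnings.warn(
                f"frame rate {self.frame_rate} fps is below the recommended "
                f"{MIN_FRAME_RATE} fps floor for transient kinetics",
                stacklevel=2,
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class FluorescenceTrace:
    """A mean-intensity time series, optionally background corrected."""

    time: np.ndarray
    value: np.ndarray
    background_corrected: bool = False
    source_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape or self.time.ndim != 1:
            raise ValueError("time and value must be 1-D arrays of equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    def window(self, t0: float, t1: float) -> "FluorescenceTrace":
        sel = (self.time >= t0) & (self.time <= t1)
        return FluorescenceTrace(
            self.time[sel], self.value[sel], self.background_corrected
        )


# Valid trace kinds for voltage recordings.
VOLTAGE_KINDS = ("patch_ap", "patch_gapfree", "optical_wave")


@dataclass
class VoltageTrace:
    """A membrane-potential trace (mV) or optical voltage-dye trace (dF units).

    ``kind`` determines the units: ``patch_ap`` and ``patch_gapfree`` are in mV
    (already tip-potential corrected upstream), ``optical_wave`` is normalized
    fluorescence.
    """

    time: np.ndarray
    value: np.ndarray
    kind: str = "patch_ap"
    _uniform_rtol: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape or self.time.ndim != 1:
            raise ValueError("time and value must be 1-D arrays of equal length")
        if self.kind not in VOLTAGE_KINDS:
            raise ValueError(f"kind must be one of {VOLTAGE_KINDS}")
        if self.time.size >= 3:
            steps = np.diff(self.time)
            if np.ptp(steps) > self._uniform_rtol * np.mean(steps):
                raise ValueError("voltage traces must be uniformly sampled")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt
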