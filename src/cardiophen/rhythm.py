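"""Beat detection, interval-variability statistics and the Poincare ellipse.

Spontaneous beating is summarized by the beat-interval series BI_n, its
absolute successive change dBI_n = |BI_{n+1} - BI_n|, the fraction of dBI
exceeding a pro-arrhythmia threshold (250 ms by convention), and the shape of
the lag-1 Poincare scatter (BI_n, BI_{n+1}).  The scatter is summarized by a
95% covariance ellipse: centered on the componentwise mean, axes along the
eigenvectors of the sample covariance, half-lengths sqrt(chi2_{0.95,2} *
eigenvalue).  The major/minor axis ratio quantifies rhythm regularity: an
elongated ellipse means uniform intervals, a rounder one means beat-to-beat
instability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import chi2

from .datatypes import FluorescenceTrace, VoltageTrace

__all__ = [
    "BeatSeries",
    "PoincareEllipse",
    "VariabilityStats",
    "detect_beats",
    "fit_poincare_ellipse",
    "variability_stats",
]

#: Default dBI threshold (s) above which a beat-interval change is flagged.
DELTA_BI_THRESHOLD_S = 0.250
#: Default refractory period (s) for beat detection.
REFRACTORY_S = 0.25


@dataclass
class BeatSeries:
    """Beat times (s), with derived intervals and successive changes."""

    beat_times: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.ndim != 1 or self.beat_times.size < 2:
            raise ValueError("need at least 2 beats")
        if not np.all(np.diff(self.beat_times) > 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)

    @property
    def delta_bi(self) -> np.ndarray:
        return np.abs(np.diff(self.intervals))

    @property
    def n_beats(self) -> int:
        return self.beat_times.size


@dataclass
class PoincareEllipse:
    """95%-confidence covariance ellipse of the (BI_n, BI_{n+1}) scatter."""

    center: tuple[float, float]
    major_axis: float
    minor_axis: float
    angle: float
    axis_ratio: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.major_axis < self.minor_axis:
            raise ValueError("major axis must be >= minor axis")
        if self.axis_ratio < 1:
            raise ValueError("axis ratio must be >= 1")


@dataclass
class VariabilityStats:
    """Interval-variability summary; ellipse is None when the covariance is
    singular (all intervals identical)."""

    mean_bi: float
    mean_delta_bi: float
    frac_delta_above: float
    threshold: float
    ellipse: PoincareEllipse | None


def detect_beats(
    trace: FluorescenceTrace | VoltageTrace,
    *,
    refractory: float = REFRACTORY_S,
    prominence_frac: float = 0.3,
    min_beats: int = 11,
) -> BeatSeries:
    """Detect beat times at transient peaks.

    Peaks must exceed an adaptive prominence threshold (a fraction of the
    trace's dynamic range) and be separated by the refractory period.
    Fewer than 2 beats is an error; fewer than ``min_beats`` warns because
    downstream variability statistics then rest on very few interval pairs.
    """
    v = np.asarray(trace.value, dtype=float)
    t = np.asarray(trace.time, dtype=float)
    span = np.ptp(v)
    if span == 0:
        raise ValueError("fewer than 2 beats detected (flat trace)")
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(round(refractory / dt)))
    peaks, _ = find_peaks(v, prominence=prominence_frac * span, distance=distance)
    if peaks.size < 2:
        raise ValueError(f"fewer than 2 beats detected ({peaks.size})")
    if peaks.size < min_beats:
        warnings.warn(
            f"only {peaks.size} beats detected; variability statistics are "
            f"unreliable below {min_beats}",
            stacklevel=2,
        )
    return BeatSeries(beat_times=t[peaks])


def fit_poincare_ellipse(
    x: np.ndarray, y: np.ndarray, confidence: float = 0.95
) -> PoincareEllipse | None:
    """Fit the covariance chi-square ellipse to a 2-D point cloud.

    Returns ``None`` when the sample covariance is (numerically) singular,
    in which case the ellipse is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least 2 point pairs")
    cov = np.cov(x, y)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] <= 0 or evals[0] <= 1e-12 * evals[1]:
        return None
    scale = chi2.ppf(confidence, df=2)
    major = float(np.sqrt(scale * evals[1]))
    minor = float(np.sqrt(scale * evals[0]))
    vmax = evecs[:, 1]
    return PoincareEllipse(
        center=(float(np.mean(x)), float(np.mean(y))),
        major_axis=major,
        minor_axis=minor,
        angle=float(np.arctan2(vmax[1], vmax[0])),
        axis_ratio=major / minor,
        confidence=confidence,
    )


def variability_stats(
    series: BeatSeries,
    threshold: float = DELTA_BI_THRESHOLD_S,
    *,
    confidence: float = 0.95,
    min_pairs: int = 10,
) -> VariabilityStats:
    """Mean BI, mean dBI, fraction dBI strictly above threshold, and the
    Poincare ellipse of successive interval pairs."""
    bi = series.intervals
    dbi = series.delta_bi
    if dbi.size == 0:
        raise ValueError("need at least 3 beats for variability statistics")
    x, y = bi[:-1], bi[1:]
    if x.size < min_pairs:
        warnings.warn(
            f"only {x.size} interval pairs for the ellipse fit "
            f"(recommended >= {min_pairs})",
            stacklevel=2,
        )
    ellipse = fit_poincare_ellipse(x, y, confidence)
    if ellipse is None:
        warnings.warn("singular interval covariance; ellipse undefined",
                      stacklevel=2)
    return VariabilityStats(
        mean_bi=float(np.mean(bi)),
        mean_delta_bi=float(np.mean(dbi)),
        frac_delta_above=float(np.mean(dbi > threshold)),
        threshold=threshold,
        ellipse=ellipse,
    )
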