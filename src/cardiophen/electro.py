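"""Action-potential and optical-wave metrics.

``ap_metrics`` measures a single evoked action potential from a whole-cell
patch-clamp trace: APD50/APD90 (time from the maximum-dV/dt upstroke to the
50%/90% repolarization crossings, measured relative to peak minus resting
potential), peak amplitude, resting potential (from a gap-free recording when
available) and the repolarization tau.  ``optical_wave_metrics`` measures
voltage-dye waves from a monolayer: per-wave amplitude, maximum depolarization
rate, and wave durations WD50/WD90 (widths at the 50% and 90% repolarization
levels), averaged over waves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .calcium import fit_tau
from .datatypes import FluorescenceTrace, VoltageTrace

__all__ = ["APMetrics", "WaveMetrics", "ap_metrics", "optical_wave_metrics"]


@dataclass
class APMetrics:
    """Single-AP metric bundle; durations in ms, potentials in mV, tau in s."""

    apd50: float
    apd90: float
    peak_amplitude: float
    resting_potential: float
    tau_decay: float | None
    upstroke_time: float

    def __post_init__(self) -> None:
        if self.apd50 > self.apd90:
            raise ValueError("APD50 must not exceed APD90")
        if self.resting_potential >= self.peak_amplitude:
            raise ValueError("resting potential must be below the AP peak")


@dataclass
class WaveMetrics:
    """Optical-wave metric bundle; durations in ms, amplitude in dF units."""

    wd50: float
    wd90: float
    amplitude: float
    max_depol_rate: float
    n_waves: int = 1

    def __post_init__(self) -> None:
        if self.wd50 > self.wd90:
            raise ValueError("WD50 must not exceed WD90")


def _downward_crossing(
    time: np.ndarray, value: np.ndarray, start: int, level: float
) -> float | None:
    hits = np.nonzero(value[start + 1 :] <= level)[0]
    if hits.size == 0:
        return None
    i = start + 1 + int(hits[0])
    v0, v1 = value[i - 1], value[i]
    if v1 == v0:
        return float(time[i])
    frac = (v0 - level) / (v0 - v1)
    return float(time[i - 1] + frac * (time[i] - time[i - 1]))


def _upward_crossing(
    time: np.ndarray, value: np.ndarray, stop: int, level: float
) -> float:
    """Last upward crossing of ``level`` before index ``stop`` (the upstroke
    flank of a wave peaking at ``stop``)."""
    below = np.nonzero(value[:stop] < level)[0]
    if below.size == 0:
        return float(time[0])
    i = int(below[-1])
    v0, v1 = value[i], value[i + 1]
    if v1 == v0:
        return float(time[i + 1])
    frac = (level - v0) / (v1 - v0)
    return float(time[i] + frac * (time[i + 1] - time[i]))


def ap_metrics(
    trace: VoltageTrace,
    gapfree: VoltageTrace | None = None,
    *,
    min_amplitude: float = 1.0,
) -> APMetrics:
    """Measure one evoked action potential.

    The upstroke is the point of maximum dV/dt; repolarization percentages
    are measured relative to (peak - resting).  ``resting_potential`` is the
    mean of the diastolic (most negative decile) samples of the gap-free
    recording when provided, otherwise the pre-upstroke mean.

    Raises
    ------
    ValueError
        When no AP is detected (dV/dt or amplitude below threshold) or the
        trace never repolarizes to 90%.
    """
    if trace.kind != "patch_ap":
        raise ValueError("ap_metrics expects a patch_ap trace")
    t, v = trace.time, trace.value
    if np.ptp(v) < min_amplitude:
        raise ValueError("no AP detected: trace amplitude below threshold")
    dv = np.diff(v) / trace.dt
    # Require an upstroke clearly faster than the trace's average drift.
    if dv.max() < 10.0 * np.ptp(v) / (t[-1] - t[0]):
        raise ValueError("no AP detected: dV/dt below threshold")
    up = int(np.argmax(dv)) + 1
    t_up = float(t[up])

    peak_idx = up + int(np.argmax(v[up:]))
    peak = float(v[peak_idx])

    if gapfree is not None:
        if gapfree.kind != "patch_gapfree":
            raise ValueError("gapfree trace must have kind 'patch_gapfree'")
        gv = gapfree.value
        resting = float(np.mean(np.sort(gv)[: max(1, gv.size // 10)]))
    else:
        pre = v[: max(1, up - 1)]
        resting = float(np.mean(pre))

    span = peak - resting
    if span <= 0:
        raise ValueError("no AP detected: peak does not exceed resting potential")

    durations = {}
    for pct in (50, 90):
        level = peak - pct / 100.0 * span
        cross = _downward_crossing(t, v, peak_idx, level)
        if cross is None:
            raise ValueError(f"trace never repolarizes to {pct}%")
        durations[pct] = (cross - t_up) * 1e3  # ms

    try:
        tau = fit_tau(
            FluorescenceTrace(t, v), peak_index=peak_idx, f0=resting
        ).tau
    except (ValueError, RuntimeError):
        tau = None

    return APMetrics(
        apd50=durations[50],
        apd90=durations[90],
        peak_amplitude=peak,
        resting_potential=resting,
        tau_decay=tau,
        upstroke_time=t_up,
    )


def optical_wave_metrics(
    trace: VoltageTrace,
    *,
    prominence_frac: float = 0.3,
    refractory: float = 0.25,
    min_waves: int = 3,
) -> WaveMetrics:
    """Measure voltage-dye waves and average per-wave metrics.

    Per wave: amplitude = peak minus the local diastolic baseline,
    max_depol_rate = maximum dF/dt on the upstroke, and WD50/WD90 = widths of
    the wave at the 50% and 90% repolarization levels (between the upstroke
    and repolarization crossings of each level).
    """
    if trace.kind != "optical_wave":
        raise ValueError("optical_wave_metrics expects an optical_wave trace")
    t, v = trace.time, trace.value
    span = np.ptp(v)
    if span == 0:
        raise ValueError("no waves detected: flat trace")
    distance = max(1, int(round(refractory / trace.dt)))
    peaks, _ = find_peaks(v, prominence=prominence_frac * span, distance=distance)
    if peaks.size == 0:
        raise ValueError("no waves detected")
    if peaks.size < min_waves:
        warnings.warn(
            f"only {peaks.size} waves detected (expected >= {min_waves})",
            stacklevel=2,
        )

    bounds = [0, *((peaks[:-1] + peaks[1:]) // 2).tolist(), v.size]
    per_wave: list[WaveMetrics] = []
    for j, p in enumerate(peaks):
        left, right = int(bounds[j]), int(bounds[j + 1])
        seg_pre = v[left : p + 1]
        seg_post = v[p:right]
        baseline = 0.5 * (seg_pre.min() + seg_post.min())
        amp = float(v[p] - baseline)
        if amp <= 0:
            continue
        rates = np.diff(v[left : p + 1]) / trace.dt
        widths = {}
        ok = True
        for pct in (50, 90):
            level = v[p] - pct / 100.0 * amp
            t_on = _upward_crossing(t[left:right], v[left:right], int(p) - left, level)
            t_off = _downward_crossing(t[left:right], v[left:right], int(p) - left, level)
            if t_off is None:
                ok = False
                break
            widths[pct] = (t_off - t_on) * 1e3  # ms
        if not ok:
            continue
        per_wave.append(
            WaveMetrics(
                wd50=widths[50],
                wd90=widths[90],
                amplitude=amp,
                max_depol_rate=float(rates.max()) if rates.size else 0.0,
            )
        )
    if not per_wave:
        raise ValueError("no measurable waves in trace")
    return WaveMetrics(
        wd50=float(np.mean([w.wd50 for w in per_wave])),
        wd90=float(np.mean([w.wd90 for w in per_wave])),
        amplitude=float(np.mean([w.amplitude for w in per_wave])),
        max_depol_rate=float(np.mean([w.max_depol_rate for w in per_wave])),
        n_waves=len(per_wave),
    )
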