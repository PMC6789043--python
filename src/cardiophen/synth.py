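"""Synthetic data generators with known ground truth for every modality.

Every generator can be driven by a named preset (see
:mod:`cardiophen.presets`) that encodes the study's printed group means, so
each analysis stage is testable by parameter recovery: generate noiselessly
from a preset, run the analysis, and the preset values must come back.

Shape conventions shared by the signal generators:

* Calcium transients and micropost twitches rise linearly to peak over
  ``t_peak`` (resp. ``t_rise``) and relax along a *shifted* exponential
  ``(exp(-s/tau) - c) / (1 - c)`` with ``c = exp(-T_rel/tau)``, which is an
  exponential in form (``A*exp(-s/tau) + C``) but reaches the baseline
  exactly at the end of the relaxation window, followed by a diastolic hold.
  A free-offset exponential fit therefore recovers tau exactly, while the
  baseline before each upstroke is exactly F0 — both of which a truncated
  pure exponential at physiological pacing would spoil.
* Action potentials are a single-sample upstroke followed by an exponential
  repolarization with ``tau = APD90 / ln 10``, placing the 90% crossing
  analytically at APD90 after the upstroke.
* Beat-interval series follow a stationary Gaussian AR(1) whose lag-1
  correlation ``rho`` is chosen from the target Poincare axis ratio ``r``
  via the population identity ``r = sqrt((1+rho)/(1-rho))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse
from skimage.draw import disk as draw_disk

from .calcium import TransientMetrics
from .datatypes import FluorescenceTrace, ImageStack, VoltageTrace
from .electro import APMetrics, WaveMetrics
from .microposts import K_POST_DEFAULT, POST_SPACING_DEFAULT, MicropostRecording
from .mito_flux import MITOSTRESS_SEGMENTS, PALMITATE_SEGMENTS, MitoMetrics, OCRAssay
from .presets import Preset, get_preset
from .rhythm import BeatSeries

__all__ = [
    "NoiseModel",
    "ImagingSimulation",
    "APSimulation",
    "WaveSimulation",
    "BeatEventsSimulation",
    "MicropostSimulation",
    "OCRSimulation",
    "BulkExprSimulation",
    "ScCountsSimulation",
    "LipidTableSimulation",
    "MaskSimulation",
    "gen_imaging",
    "gen_electro",
    "gen_micropost",
    "gen_ocr",
    "gen_omics",
    "gen_masks",
]


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise specification; ``kind='none'`` means deterministic."""

    kind: str = "none"
    sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian"):
            raise ValueError("noise kind must be 'none' or 'gaussian'")
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, arr: np.ndarray, rng: np.random.Generator | None = None):
        if self.kind == "none" or self.sd == 0:
            return arr
        rng = rng if rng is not None else self.rng()
        return arr + rng.normal(0.0, self.sd, size=arr.shape)


def _resolve(preset: Preset | str | None, modality: str) -> Preset | None:
    if preset is None:
        return None
    if isinstance(preset, str):
        return get_preset(modality, preset)
    if preset.modality != modality:
        raise ValueError(
            f"preset {preset.name!r} has modality {preset.modality!r}, "
            f"expected {modality!r}"
        )
    return preset


# ---------------------------------------------------------------------------
# Transient waveform shared by calcium imaging and micropost twitches.


@dataclass(frozen=True)
class _TransientShape:
    """Unit waveform: linear rise (t_rise), shifted-exponential relaxation
    (t_relax, constant tau), diastolic hold; one beat per ``period``."""

    period: float
    t_rise: float
    t_relax: float
    tau: float

    def __post_init__(self) -> None:
        if self.t_rise <= 0 or self.t_relax <= 0 or self.tau <= 0:
            raise ValueError("t_rise, t_relax and tau must be positive")
        if self.t_rise + self.t_relax > self.period + 1e-12:
            raise ValueError(
                "beat period too short for the rise + relaxation envelope "
                "(pacing too fast for this transient)"
            )

    @property
    def offset_c(self) -> float:
        return float(np.exp(-self.t_relax / self.tau))

    def unit_value(self, t: np.ndarray, lead_in: float, n_beats: int) -> np.ndarray:
        """Waveform in [0, 1]; beats start at lead_in + b*period."""
        t = np.asarray(t, dtype=float)
        w = np.zeros_like(t)
        active = (t >= lead_in) & (t < lead_in + n_beats * self.period)
        phase = np.mod(t[active] - lead_in, self.period)
        c = self.offset_c
        rising = phase < self.t_rise
        relaxing = ~rising & (phase < self.t_rise + self.t_relax)
        wa = np.zeros_like(phase)
        wa[rising] = phase[rising] / self.t_rise
        s = phase[relaxing] - self.t_rise
        wa[relaxing] = (np.exp(-s / self.tau) - c) / (1.0 - c)
        w[active] = wa
        return w

    def recovery_time(self, fraction: float) -> float:
        """Time from peak to the given recovery fraction of the amplitude."""
        c = self.offset_c
        level = (1.0 - fraction) * (1.0 - c) + c
        return float(-self.tau * np.log(level))


# ---------------------------------------------------------------------------
# Calcium imaging.


@dataclass
class ImagingSimulation:
    """A synthetic calcium stack plus its ground truth."""

    stack: ImageStack
    mask: np.ndarray
    trace: FluorescenceTrace
    metrics: TransientMetrics
    background: float
    params: dict = field(default_factory=dict)


def gen_imaging(
    preset: Preset | str | None = None,
    *,
    fold: float | None = None,
    tau: float | None = None,
    f0: float = 100.0,
    background: float = 10.0,
    t_peak: float = 0.2,
    t_dia: float = 0.3,
    pacing: float = 0.5,
    n_beats: int = 5,
    frame_rate: float = 50.0,
    shape: tuple[int, int] = (64, 64),
    pixel_size: float = 0.5,
    cell_radius_frac: float = 0.3,
    noise: NoiseModel | None = None,
) -> ImagingSimulation:
    """Generate a single-cell calcium-imaging stack with known kinetics.

    The cell is a centred disc; in-cell raw intensity is
    ``background + F0 + (F - F0) * w(t)`` with the package's transient
    waveform, background pixels sit at the constant ``background`` level, so
    the background-corrected in-cell mean is exactly ``F0 + (F - F0) * w(t)``.
    Stacks are paced at ``pacing`` Hz and must cover at least five beats.
    """
    noise = noise or NoiseModel()
    p = _resolve(preset, "calcium")
    if p is not None:
        fold = p.value("fold") if fold is None else fold
        tau = p.value("tau") if tau is None else tau
    if fold is None or tau is None:
        raise ValueError("need a calcium preset or explicit fold and tau")
    if fold < 1:
        raise ValueError("fold must be >= 1")
    if pacing <= 0:
        raise ValueError("pacing must be positive")
    if n_beats < 5:
        raise ValueError("stack duration must cover at least 5 beats")

    period = 1.0 / pacing
    if period - t_peak - t_dia <= 0:
        raise ValueError(
            "beat period too short for the rise and diastolic hold: "
            "pacing too fast for this transient shape"
        )
    shape_fn = _TransientShape(
        period=period, t_rise=t_peak, t_relax=period - t_peak - t_dia, tau=tau
    )
    duration = t_dia + n_beats * period
    n_frames = int(round(duration * frame_rate)) + 1
    time = np.arange(n_frames) / frame_rate
    w = shape_fn.unit_value(time, t_dia, n_beats)

    amp = f0 * (fold - 1.0)
    cell_value = background + f0 + amp * w  # raw in-cell intensity per frame

    mask = np.zeros(shape, dtype=bool)
    radius = max(2, int(round(cell_radius_frac * min(shape))))
    rr, cc = draw_disk((shape[0] // 2, shape[1] // 2), radius, shape=shape)
    mask[rr, cc] = True

    frames = np.full((n_frames, *shape), background, dtype=float)
    frames[:, mask] = cell_value[:, None]
    frames = noise.apply(frames)

    t50r = shape_fn.recovery_time(0.5)
    t90r = shape_fn.recovery_time(0.9)
    metrics = TransientMetrics(
        F=f0 * fold,
        F0=f0,
        fold=fold,
        t_peak=t_peak,
        t50r=t50r,
        t90r=t90r,
        r_peak=amp / t_peak,
        r50r=0.5 * amp / t50r,
        r90r=0.9 * amp / t90r,
        tau=tau,
    )
    return ImagingSimulation(
        stack=ImageStack(frames, frame_rate=frame_rate, pixel_size=pixel_size),
        mask=mask,
        trace=FluorescenceTrace(time, f0 + amp * w, background_corrected=True),
        metrics=metrics,
        background=background,
        params={
            "fold": fold, "tau": tau, "f0": f0, "background": background,
            "t_peak": t_peak, "t_dia": t_dia, "pacing": pacing,
            "n_beats": n_beats, "frame_rate": frame_rate,
            "pixel_size": pixel_size, "noise": noise,
        },
    )


# ---------------------------------------------------------------------------
# Electrophysiology.


@dataclass
class APSimulation:
    trace: VoltageTrace
    metrics: APMetrics
    params: dict = field(default_factory=dict)


@dataclass
class WaveSimulation:
    trace: VoltageTrace
    metrics: WaveMetrics
    params: dict = field(default_factory=dict)


@dataclass
class BeatEventsSimulation:
    series: BeatSeries
    rho: float
    axis_ratio: float
    mean_bi: float
    sd_bi: float


def _gen_patch_ap(
    preset, apd90_ms, resting_mv, peak_mv, sample_rate, pre_s, noise
) -> APSimulation:
    p = _resolve(preset, "patch")
    if p is not None and apd90_ms is None:
        apd90_ms = p.value("apd90")
    if apd90_ms is None:
        raise ValueError("need a patch preset or explicit apd90_ms")
    apd90 = apd90_ms / 1e3
    tau = apd90 / np.log(10.0)
    dt = 1.0 / sample_rate
    duration = pre_s + 7.0 * tau
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    v = np.full(n, resting_mv, dtype=float)
    up = int(round(pre_s / dt))
    v[up:] = resting_mv + (peak_mv - resting_mv) * np.exp(-(t[up:] - t[up]) / tau)
    v = noise.apply(v)
    metrics = APMetrics(
        apd50=tau * np.log(2.0) * 1e3,
        apd90=apd90_ms,
        peak_amplitude=peak_mv,
        resting_potential=resting_mv,
        tau_decay=tau,
        upstroke_time=t[up],
    )
    return APSimulation(
        trace=VoltageTrace(t, v, kind="patch_ap"),
        metrics=metrics,
        params={"apd90_ms": apd90_ms, "resting_mv": resting_mv,
                "peak_mv": peak_mv, "sample_rate": sample_rate},
    )


def _gen_optical_wave(
    n_waves, period, base_width, amplitude, baseline, sample_rate, noise
) -> WaveSimulation:
    if base_width >= period:
        raise ValueError("base_width must be shorter than the period")
    lead = 0.25 * period
    duration = lead + n_waves * period
    dt = 1.0 / sample_rate
    t = np.arange(int(round(duration / dt)) + 1) * dt
    v = np.full_like(t, baseline)
    half = base_width / 2.0
    for b in range(n_waves):
        start = lead + b * period
        tri = 1.0 - np.abs(t - (start + half)) / half
        v += amplitude * np.clip(tri, 0.0, None)
    v = noise.apply(v)
    metrics = WaveMetrics(
        wd50=0.5 * base_width * 1e3,
        wd90=0.9 * base_width * 1e3,
        amplitude=amplitude,
        max_depol_rate=amplitude / half,
        n_waves=n_waves,
    )
    return WaveSimulation(
        trace=VoltageTrace(t, v, kind="optical_wave"),
        metrics=metrics,
        params={"n_waves": n_waves, "period": period, "base_width": base_width,
                "amplitude": amplitude, "sample_rate": sample_rate},
    )


def _gen_beat_events(
    preset, n, rho, cov, mean_bi, sd_bi, seed
) -> BeatEventsSimulation:
    if n < 10:
        raise ValueError("beat_events requires n >= 10")
    if cov is not None:
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError("lag covariance must be 2x2")
        evals = np.linalg.eigvalsh(cov)
        if evals.min() <= 0:
            raise ValueError("lag covariance must be positive definite")
        sd_bi = float(np.sqrt(cov[0, 0]))
        rho = float(cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1]))
    elif rho is None:
        p = _resolve(preset, "rhythm")
        if p is None:
            raise ValueError("need a rhythm preset, rho, or a lag covariance")
        r = p.value("axis_ratio")
        rho = (r**2 - 1.0) / (r**2 + 1.0)
    if not -1.0 < rho < 1.0:
        raise ValueError("lag-1 correlation must be in (-1, 1)")

    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = z[0]
    innov = np.sqrt(1.0 - rho**2)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov * z[i]
    intervals = mean_bi + sd_bi * x
    if np.any(intervals <= 0):
        raise ValueError(
            "generated non-positive intervals; reduce sd_bi relative to mean_bi"
        )
    beat_times = np.concatenate([[0.0], np.cumsum(intervals)])
    return BeatEventsSimulation(
        series=BeatSeries(beat_times),
        rho=float(rho),
        axis_ratio=float(np.sqrt((1.0 + rho) / (1.0 - rho))),
        mean_bi=mean_bi,
        sd_bi=sd_bi,
    )


def gen_electro(
    preset: Preset | str | None = None,
    kind: str = "patch_ap",
    *,
    apd90_ms: float | None = None,
    resting_mv: float = -75.0,
    peak_mv: float = 35.0,
    sample_rate: float = 10_000.0,
    pre_s: float = 0.05,
    n_waves: int = 5,
    period: float = 1.0,
    base_width: float = 0.5,
    amplitude: float = 1.0,
    baseline: float = 0.1,
    wave_sample_rate: float = 200.0,
    n: int = 500,
    rho: float | None = None,
    cov: np.ndarray | None = None,
    mean_bi: float = 1.5,
    sd_bi: float = 0.1,
    seed: int | None = None,
    noise: NoiseModel | None = None,
):
    """Generate an electrophysiology object of the requested ``kind``.

    ``patch_ap``: stylized evoked action potential with analytically placed
    APD50/APD90 crossings.  ``optical_wave``: train of symmetric triangular
    voltage-dye waves (WD50/WD90 known in closed form).  ``beat_events``:
    stationary AR(1) beat-interval series whose population Poincare ellipse
    axis ratio equals the preset target (or follows the supplied ``rho`` /
    2x2 lag covariance).
    """
    noise = noise or NoiseModel()
    if kind == "patch_ap":
        return _gen_patch_ap(
            preset, apd90_ms, resting_mv, peak_mv, sample_rate, pre_s, noise
        )
    if kind == "optical_wave":
        return _gen_optical_wave(
            n_waves, period, base_width, amplitude, baseline, wave_sample_rate,
            noise,
        )
    if kind == "beat_events":
        if seed is None and noise.seed is not None:
            seed = noise.seed
        return _gen_beat_events(preset, n, rho, cov, mean_bi, sd_bi, seed)
    raise ValueError("kind must be patch_ap, optical_wave or beat_events")


# ---------------------------------------------------------------------------
# Microposts.


@dataclass
class MicropostSimulation:
    recording: MicropostRecording
    deflections: np.ndarray  # ground-truth (frames, posts) um
    twitch_force: float
    twitch_velocity: float
    power: float
    params: dict = field(default_factory=dict)


def gen_micropost(
    preset: Preset | str | None = None,
    *,
    twitch_force: float | None = None,
    power: float | None = None,
    n_posts: int = 4,
    k: float = K_POST_DEFAULT,
    spacing: float = POST_SPACING_DEFAULT,
    frame_rate: float = 250.0,
    n_beats: int = 3,
    period: float = 1.0,
    t_dia: float = 0.2,
    weights: np.ndarray | None = None,
    noise: NoiseModel | None = None,
) -> MicropostSimulation:
    """Generate post-top centroid waveforms with a known peak twitch force.

    The peak total deflection is ``twitch_force / k`` split unevenly across
    posts (each deflecting toward the cell centroid); the per-post waveform
    is the shared linear-rise / shifted-exponential transient shape.  When a
    ``power`` target is given, the rise time is solved from
    ``t_rise = F^2 / (k * P)`` (peak of force x total-deflection velocity for
    a linear rise) and snapped to the frame grid.
    """
    noise = noise or NoiseModel()
    p = _resolve(preset, "micropost")
    if p is not None:
        twitch_force = p.value("twitch_force") if twitch_force is None else twitch_force
        if power is None and "power" in p.parameters:
            power = p.value("power")
    if twitch_force is None:
        raise ValueError("need a micropost preset or explicit twitch_force")
    if n_posts < 1:
        raise ValueError("need at least one post")
    if k <= 0:
        raise ValueError("spring constant must be positive")

    d_total = twitch_force / k
    t_rise = d_total * twitch_force / power if power else 0.15
    t_rise = max(1, round(t_rise * frame_rate)) / frame_rate  # frame-aligned
    t_relax = period - t_rise - t_dia
    shape_fn = _TransientShape(
        period=period, t_rise=t_rise, t_relax=t_relax, tau=t_relax / 4.0
    )

    duration = t_dia + n_beats * period
    n_frames = int(round(duration * frame_rate)) + 1
    time = np.arange(n_frames) / frame_rate
    w = shape_fn.unit_value(time, t_dia, n_beats)

    if weights is None:
        weights = np.arange(1, n_posts + 1, dtype=float)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    peak_defl = d_total * weights  # per-post peak deflection, um

    n_cols = int(np.ceil(np.sqrt(n_posts)))
    grid = np.array(
        [(spacing * (i % n_cols), spacing * (i // n_cols)) for i in range(n_posts)],
        dtype=float,
    )
    center = grid.mean(axis=0)
    dirs = center - grid
    norms = np.linalg.norm(dirs, axis=1)
    dirs = np.where(norms[:, None] > 0, dirs / np.where(norms == 0, 1, norms)[:, None],
                    np.array([1.0, 0.0]))

    deflections = w[:, None] * peak_defl[None, :]  # (frames, posts)
    positions = grid[None, :, :] + deflections[:, :, None] * dirs[None, :, :]
    positions = noise.apply(positions)

    return MicropostSimulation(
        recording=MicropostRecording(
            positions=positions,
            frame_rate=frame_rate,
            rest_positions=grid,
            k_post=k,
            spacing=spacing,
        ),
        deflections=deflections,
        twitch_force=twitch_force,
        twitch_velocity=d_total / t_rise,
        power=k * d_total**2 / t_rise,
        params={"twitch_force": twitch_force, "power": power, "k": k,
                "n_posts": n_posts, "t_rise": t_rise, "period": period,
                "frame_rate": frame_rate},
    )


# ---------------------------------------------------------------------------
# Extracellular flux.


@dataclass
class OCRSimulation:
    assay: OCRAssay  # raw, well-level pmol/min
    per_cell_plateaus: dict[str, float]
    metrics: MitoMetrics | None = None
    utilization: float | None = None
    params: dict = field(default_factory=dict)


def gen_ocr(
    preset: Preset | str | None = None,
    assay: str = "mitostress",
    *,
    plateaus: tuple[float, float, float, float] | None = None,
    non_mito: float = 10.0,
    baseline: float = 60.0,
    step1: float = 10.0,
    utilization: float = 40.0,
    wells: int = 6,
    points_per_segment: int = 3,
    interval_s: float = 390.0,
    cell_counts: np.ndarray | None = None,
    noise: NoiseModel | None = None,
) -> OCRSimulation:
    """Generate a plate OCR time course with plateau segments.

    For a mitostress assay the per-cell plateau levels (basal, oligomycin,
    FCCP, antimycin/rotenone) are chosen so that the mitostress metric
    formulas return the preset targets exactly; ``plateaus`` overrides them
    directly.  For a palmitate assay the plateaus are (baseline, baseline +
    step1, previous + utilization, reduced baseline), so the utilization
    metric returns ``utilization`` exactly.  Raw well OCR is the per-cell
    level times the well's cell count.
    """
    noise = noise or NoiseModel()
    if wells < 1:
        raise ValueError("need at least one well")
    if cell_counts is None:
        cell_counts = 1000.0 + 50.0 * np.arange(wells)
    cell_counts = np.asarray(cell_counts, dtype=float)
    if np.any(cell_counts <= 0):
        raise ValueError("cell counts must be positive")

    metrics = None
    util = None
    if assay == "mitostress":
        segments = MITOSTRESS_SEGMENTS
        if plateaus is None:
            p = _resolve(preset, "mitostress")
            if p is None:
                raise ValueError("need a mitostress preset or explicit plateaus")
            leak = p.value("proton_leak")
            oligo = non_mito + leak
            levels = {
                "basal": oligo + p.value("atp_production"),
                "oligomycin": oligo,
                "FCCP": oligo + p.value("max_ocr"),
                "antimycin_rotenone": non_mito,
            }
        else:
            if len(plateaus) != 4:
                raise ValueError("mitostress needs 4 plateau levels")
            levels = dict(zip(segments, plateaus))
        metrics = MitoMetrics(
            basal=levels["basal"],
            max_ocr=levels["FCCP"] - levels["oligomycin"],
            atp_production=levels["basal"] - levels["oligomycin"],
            proton_leak=levels["oligomycin"] - levels["antimycin_rotenone"],
            non_mito=levels["antimycin_rotenone"],
        )
    elif assay == "palmitate":
        segments = PALMITATE_SEGMENTS
        if plateaus is None:
            levels = {
                "baseline": baseline,
                "palmitate1": baseline + step1,
                "palmitate2": baseline + step1 + utilization,
                "etomoxir": 0.5 * baseline,
            }
        else:
            if len(plateaus) != 4:
                raise ValueError("palmitate assay needs 4 plateau levels")
            levels = dict(zip(segments, plateaus))
        util = levels["palmitate2"] - levels["palmitate1"]
    else:
        raise ValueError("assay must be 'mitostress' or 'palmitate'")

    missing = [s for s in segments if s not in levels]
    if missing:
        raise ValueError(f"missing segment levels: {missing}")
    if any(v < 0 for v in levels.values()):
        raise ValueError("OCR plateau levels must be non-negative")

    seg_labels = [s for s in segments for _ in range(points_per_segment)]
    time = np.arange(len(seg_labels)) * interval_s
    per_cell = np.array([levels[s] for s in seg_labels], dtype=float)
    ocr = cell_counts[:, None] * per_cell[None, :]
    ocr = noise.apply(ocr)

    return OCRSimulation(
        assay=OCRAssay(
            wells=[f"W{i + 1}" for i in range(wells)],
            time=time,
            ocr=ocr,
            segments=seg_labels,
            cell_counts=cell_counts,
            per_cell=False,
            segment_order=segments,
        ),
        per_cell_plateaus=levels,
        metrics=metrics,
        utilization=util,
        params={"assay": assay, "points_per_segment": points_per_segment,
                "wells": wells},
    )


# ---------------------------------------------------------------------------
# Omics tables.


@dataclass
class BulkExprSimulation:
    expr: pd.DataFrame  # genes x samples
    conditions: pd.Series
    up_genes: set[str]
    down_genes: set[str]
    below_floor_genes: set[str]


@dataclass
class ScCountsSimulation:
    adata: AnnData
    fail_mito: list[str]
    fail_genes: list[str]
    fail_umis: list[str]
    per_cell: pd.DataFrame  # planted total_umis, n_genes, mito_fraction


@dataclass
class LipidTableSimulation:
    table: "object"  # LipidTable (import kept local to avoid cycle at typing)
    panel_truth: dict[str, pd.Series]


def _gen_bulk_expr(
    rng: np.random.Generator,
    n_genes: int,
    conditions: dict[str, int],
    control: str,
    n_up: int,
    n_down: int,
    up_fold: float,
    down_fold: float,
    n_below_floor: int,
    base_mean_range: tuple[float, float],
    noise_cv: float,
) -> BulkExprSimulation:
    if not conditions or control not in conditions:
        raise ValueError("conditions must be non-empty and include the control")
    if n_up + n_down + n_below_floor > n_genes:
        raise ValueError("planted genes exceed the gene count")
    if not (up_fold > 1.5 and 0 <= down_fold < 1 / 1.5):
        raise ValueError(
            "planted folds must exceed the 1.5-fold threshold by construction"
        )
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    up = set(genes[:n_up])
    down = set(genes[n_up : n_up + n_down])
    low = set(genes[n_up + n_down : n_up + n_down + n_below_floor])

    samples, labels = [], []
    for cond, size in conditions.items():
        for r in range(size):
            samples.append(f"{cond}_{r + 1}")
            labels.append(cond)
    cond_series = pd.Series(labels, index=samples)

    base = rng.uniform(*base_mean_range, size=n_genes)
    expr = pd.DataFrame(index=genes, columns=samples, dtype=float)
    n_samples = len(samples)
    for j, s in enumerate(samples):
        mean = base.copy()
        if cond_series[s] != control:
            mean[:n_up] *= up_fold
            mean[n_up : n_up + n_down] *= down_fold
        mean[n_up + n_down : n_up + n_down + n_below_floor] = 0.4 / n_samples
        if noise_cv > 0:
            mean = np.clip(mean * (1 + noise_cv * rng.standard_normal(n_genes)), 0, None)
        expr[s] = mean
    return BulkExprSimulation(
        expr=expr, conditions=cond_series, up_genes=up, down_genes=down,
        below_floor_genes=low,
    )


def _gen_sc_counts(
    rng: np.random.Generator,
    n_cells: int,
    n_genes: int,
    n_mito_genes: int,
    n_fail_mito: int,
    n_fail_genes: int,
    n_fail_umis: int,
    fail_mito_fraction: float,
    fail_gene_count: int,
    fail_umi_count: int,
) -> ScCountsSimulation:
    n_fail = n_fail_mito + n_fail_genes + n_fail_umis
    if n_fail > n_cells:
        raise ValueError("more planted failures than cells")
    if n_genes <= 250 + n_mito_genes:
        raise ValueError("need enough genes to straddle the detected-gene threshold")

    var_names = [f"MT-{i + 1}" for i in range(n_mito_genes)] + [
        f"GENE{i:04d}" for i in range(n_genes - n_mito_genes)
    ]
    mito_idx = np.arange(n_mito_genes)
    nonmito_idx = np.arange(n_mito_genes, n_genes)

    rows, cols, vals = [], [], []
    truth = []
    for c in range(n_cells):
        if c < n_fail_mito:
            u, g, m = 4000, 240, fail_mito_fraction
        elif c < n_fail_mito + n_fail_genes:
            u, g, m = 3000, fail_gene_count, 0.10
        elif c < n_fail:
            # Fails only the UMI floor: detected genes stay above 200.
            u, g, m = fail_umi_count, min(220, fail_umi_count // 4), 0.10
        else:
            u = int(20 * rng.integers(150, 450))  # multiples of 20
            g = int(rng.integers(220, 290))
            m = float(rng.choice([0.05, 0.10, 0.15, 0.20]))
        mito_umis = int(round(u * m))
        n_mito_used = min(n_mito_genes, mito_umis) if mito_umis > 0 else 0
        n_nonmito = g - n_mito_used
        chosen = rng.choice(nonmito_idx, size=n_nonmito, replace=False)

        gene_ids = np.concatenate([mito_idx[:n_mito_used], chosen])
        counts = np.ones(g, dtype=int)
        extra_mito = mito_umis - n_mito_used
        if n_mito_used > 0 and extra_mito > 0:
            counts[:n_mito_used] += rng.multinomial(
                extra_mito, np.full(n_mito_used, 1 / n_mito_used)
            )
        extra = (u - mito_umis) - n_nonmito
        if extra < 0:
            raise ValueError("UMI total too small for the detected-gene target")
        if extra > 0:
            counts[n_mito_used:] += rng.multinomial(
                extra, np.full(n_nonmito, 1 / n_nonmito)
            )
        rows.extend([c] * g)
        cols.extend(gene_ids.tolist())
        vals.extend(counts.tolist())
        truth.append({"total_umis": u, "n_genes": g, "mito_fraction": mito_umis / u})

    x = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_cells, n_genes), dtype=np.float64
    )
    obs_names = [f"CELL{i:04d}" for i in range(n_cells)]
    adata = AnnData(X=x)
    adata.obs_names = obs_names
    adata.var_names = var_names
    adata.var["mito"] = [v.startswith("MT-") for v in var_names]
    return ScCountsSimulation(
        adata=adata,
        fail_mito=obs_names[:n_fail_mito],
        fail_genes=obs_names[n_fail_mito : n_fail_mito + n_fail_genes],
        fail_umis=obs_names[n_fail_mito + n_fail_genes : n_fail],
        per_cell=pd.DataFrame(truth, index=obs_names),
    )


#: Species panel used by the lipid-table generator: covers every summarized
#: class, with hydroxylated and unknown features.
_LIPID_PANEL = [
    ("AC(8:0)", True),
    ("AC(10:0)", True),
    ("AC(16:0)", True),
    ("AC(18:1)", True),
    ("AC(16:0-OH)", True),
    ("AC(18:1-OH)", True),
    ("FFA(16:1)", True),
    ("FFA(18:1)", True),
    ("FFA(16:0-OH)", True),
    ("TG(16:0/18:1/18:2)", True),
    ("TG(18:1/18:1/18:2)", True),
    ("tetra[18:2]-CL", True),
    ("[18:1][18:1][18:2][18:2]", True),
    ("CL(14:0/18:1/18:2/18:2)", True),
    ("CL(16:0/18:2/18:2/20:2)", True),
    ("MLCL(18:2/18:2/18:2)", True),
    ("unknown_feature_1", False),
    ("unknown_feature_2", False),
]


def _gen_lipid_table(
    rng: np.random.Generator,
    groups: dict[str, int],
    long_chain_ac_scale: dict[str, float] | None,
) -> LipidTableSimulation:
    from .lipids import (
        LONG_CHAIN_MIN_CARBONS,
        LipidTable,
        parse_lipid_name,
    )

    if not groups:
        raise ValueError("need at least one sample group")
    samples, labels = [], []
    for g, size in groups.items():
        for r in range(size):
            samples.append(f"{g}_{r + 1}")
            labels.append(g)
    names = [n for n, _ in _LIPID_PANEL]
    identified = pd.Series({n: f for n, f in _LIPID_PANEL})
    ab = pd.DataFrame(
        rng.lognormal(mean=8.0, sigma=0.3, size=(len(names), len(samples))),
        index=names,
        columns=samples,
    )
    if long_chain_ac_scale:
        for name in names:
            if not identified[name]:
                continue
            sp = parse_lipid_name(name)
            is_lc_ac = sp.lipid_class == "AC" and any(
                ch.carbons >= LONG_CHAIN_MIN_CARBONS for ch in sp.chains
            )
            if not is_lc_ac:
                continue
            for grp, factor in long_chain_ac_scale.items():
                cols = [s for s, l in zip(samples, labels) if l == grp]
                ab.loc[name, cols] *= factor

    table = LipidTable(
        abundance=ab, groups=pd.Series(labels, index=samples), identified=identified
    )

    # Construction-time bookkeeping: plain per-class sums by explicit loops.
    def plain_sum(match) -> pd.Series:
        total = pd.Series(0.0, index=samples)
        for name, known in _LIPID_PANEL:
            if known and match(parse_lipid_name(name)):
                total += ab.loc[name]
        return total

    truth = {
        "long_chain_acylcarnitines": plain_sum(
            lambda s: s.lipid_class == "AC"
            and any(c.carbons >= LONG_CHAIN_MIN_CARBONS for c in s.chains)
        ),
        "triglycerides": plain_sum(lambda s: s.lipid_class == "TG"),
        "cl_with_14_0": plain_sum(
            lambda s: s.lipid_class == "CL"
            and any(c.carbons == 14 and c.double_bonds == 0 for c in s.chains)
        ),
        "hydroxylated_long_chain_acylcarnitines": plain_sum(
            lambda s: s.lipid_class == "AC"
            and s.hydroxylated
            and any(c.carbons >= LONG_CHAIN_MIN_CARBONS for c in s.chains)
        ),
    }
    return LipidTableSimulation(table=table, panel_truth=truth)


def gen_omics(
    kind: str,
    *,
    seed: int | None = None,
    # bulk_expr
    n_genes: int = 300,
    conditions: dict[str, int] | None = None,
    control: str = "EV",
    n_up: int = 10,
    n_down: int = 10,
    up_fold: float = 2.0,
    down_fold: float = 0.5,
    n_below_floor: int = 5,
    base_mean_range: tuple[float, float] = (50.0, 500.0),
    noise_cv: float = 0.0,
    # sc_counts
    n_cells: int = 60,
    n_sc_genes: int = 600,
    n_mito_genes: int = 10,
    n_fail_mito: int = 3,
    n_fail_genes: int = 2,
    n_fail_umis: int = 2,
    fail_mito_fraction: float = 0.45,
    fail_gene_count: int = 150,
    fail_umi_count: int = 1500,
    # lipid_table
    groups: dict[str, int] | None = None,
    long_chain_ac_scale: dict[str, float] | None = None,
):
    """Generate an omics table of the requested ``kind`` with planted truth.

    ``bulk_expr``: normalized genes x samples expression with planted up- /
    downregulated genes that exceed the 1.5-fold DE threshold by
    construction, plus genes below the expression floor.  ``sc_counts``:
    sparse cells x genes UMI matrix with cells planted to violate exactly the
    stated QC thresholds.  ``lipid_table``: species x samples abundances in
    the package's lipid-name dialect, with at least one species per
    summarized class and per-panel sums recorded at construction.
    """
    rng = np.random.default_rng(seed)
    if kind == "bulk_expr":
        if conditions is None:
            conditions = {"EV": 3, "MiMaC": 3}
        return _gen_bulk_expr(
            rng, n_genes, conditions, control,
            n_up, n_down, up_fold, down_fold, n_below_floor,
            base_mean_range, noise_cv,
        )
    if kind == "sc_counts":
        return _gen_sc_counts(
            rng, n_cells, n_sc_genes, n_mito_genes, n_fail_mito, n_fail_genes,
            n_fail_umis, fail_mito_fraction, fail_gene_count, fail_umi_count,
        )
    if kind == "lipid_table":
        if groups is None:
            groups = {"WT_12D_GlcFA": 3, "Mut_12D_GlcFA": 3, "KO_12D_GlcFA": 3}
        return _gen_lipid_table(rng, groups, long_chain_ac_scale)
    raise ValueError("kind must be bulk_expr, sc_counts or lipid_table")


# ---------------------------------------------------------------------------
# Morphometric masks.


@dataclass
class MaskSimulation:
    mask: np.ndarray
    labels: np.ndarray
    truth: pd.DataFrame  # label, area_px, area_um2
    pixel_size: float


def gen_masks(
    preset: Preset | str | None = None,
    *,
    target_area_um2: float | None = None,
    n_objects: int = 4,
    pixel_size: float = 0.5,
    margin: int = 8,
) -> MaskSimulation:
    """Binary mask of rasterized discs with known pixel areas.

    Disc radii are chosen so each object's continuous area matches the
    target (from the cell-area preset or ``target_area_um2``); the recorded
    truth is the exact rasterized pixel count.
    """
    p = _resolve(preset, "area")
    if p is not None and target_area_um2 is None:
        target_area_um2 = p.value("cell_area")
    if target_area_um2 is None:
        raise ValueError("need an area preset or explicit target_area_um2")
    radius_px = np.sqrt(target_area_um2 / np.pi) / pixel_size
    cell = int(np.ceil(2 * radius_px)) + 2 * margin
    n_cols = int(np.ceil(np.sqrt(n_objects)))
    n_rows = int(np.ceil(n_objects / n_cols))
    mask = np.zeros((n_rows * cell, n_cols * cell), dtype=bool)
    labels = np.zeros_like(mask, dtype=int)
    rows = []
    for i in range(n_objects):
        r0 = (i // n_cols) * cell + cell // 2
        c0 = (i % n_cols) * cell + cell // 2
        rr, cc = draw_disk((r0, c0), radius_px, shape=mask.shape)
        mask[rr, cc] = True
        labels[rr, cc] = i + 1
        rows.append(
            {"label": i + 1, "area_px": rr.size, "area_um2": rr.size * pixel_size**2}
        )
    return MaskSimulation(
        mask=mask, labels=labels, truth=pd.DataFrame(rows), pixel_size=pixel_size
    )
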