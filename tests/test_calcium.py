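"""Calcium-transient pipeline: extraction, per-beat kinetics, tau fit."""

import numpy as np
import pytest

from cardiophen import synth
from cardiophen.calcium import extract_trace, fit_tau, transient_metrics
from cardiophen.datatypes import FluorescenceTrace, ImageStack
from cardiophen.synth import NoiseModel


def _uniform_stack(cell=100.0, bg=10.0, n_frames=10):
    frames = np.full((n_frames, 32, 32), bg)
    frames[:, 8:24, 8:24] = cell
    return ImageStack(frames, frame_rate=50.0)


class TestExtractTrace:
    def test_uniform_cell_minus_background(self):
        """In-cell 100 over background 10 -> constant trace at 90."""
        trace = extract_trace(_uniform_stack())
        np.testing.assert_allclose(trace.value, 90.0)
        assert trace.background_corrected

    def test_all_zero_stack_raises(self):
        with pytest.raises(ValueError, match="no foreground"):
            extract_trace(ImageStack(np.zeros((5, 16, 16)), frame_rate=50.0))

    def test_matches_ground_truth_mask_oracle(self, wt_imaging):
        """Extraction equals the per-frame mean over the generator's true
        mask minus the true background."""
        sim = wt_imaging
        trace = extract_trace(sim.stack)
        oracle = sim.stack.frames[:, sim.mask].mean(axis=1) - sim.background
        np.testing.assert_allclose(trace.value, oracle, atol=1e-9)

    def test_noisy_stack_within_noise_tolerance(self):
        sd = 0.5
        sim = synth.gen_imaging(
            "WT_12D_GlcFA", noise=NoiseModel(kind="gaussian", sd=sd, seed=5)
        )
        trace = extract_trace(sim.stack)
        # mean over ~1100 cell pixels: per-frame sd ~ sd/sqrt(n); allow 6 sigma
        n_cell = sim.mask.sum()
        assert np.max(np.abs(trace.value - sim.trace.value)) < 6 * sd / np.sqrt(n_cell)


def _triangular_trace():
    """F0=1, rise to F=2 at 0.5 s, linear return to baseline over 1 s."""
    dt = 0.005
    t = np.arange(0, 3.0, dt)
    v = np.ones_like(t)
    rise = (t >= 0.5) & (t < 1.0)
    fall = (t >= 1.0) & (t < 2.0)
    v[rise] = 1.0 + (t[rise] - 0.5) / 0.5
    v[fall] = 2.0 - (t[fall] - 1.0)
    return FluorescenceTrace(t, v)


class TestTransientMetrics:
    def test_triangular_closed_form(self):
        """Linear decay: fold 2, T_peak 0.5, T50R 0.5, T90R 0.9 s."""
        with pytest.warns(UserWarning, match="transients"):
            ana = transient_metrics(_triangular_trace())
        m = ana.per_beat[0]
        assert m.fold == pytest.approx(2.0, rel=0.02)
        assert m.t_peak == pytest.approx(0.5, abs=0.03)
        assert m.t50r == pytest.approx(0.5, abs=0.01)
        assert m.t90r == pytest.approx(0.9, abs=0.01)
        # rate identities follow from the definitions
        amp = m.F - m.F0
        assert m.r50r == pytest.approx(0.5 * amp / m.t50r)
        assert m.r90r == pytest.approx(0.9 * amp / m.t90r)

    def test_constant_trace_raises(self):
        t = np.arange(0, 5, 0.02)
        with pytest.raises(ValueError, match="no transients"):
            transient_metrics(FluorescenceTrace(t, np.ones_like(t)))

    def test_wt_preset_end_to_end_fold(self, wt_imaging):
        """Noiseless WT stack: mean fold equals the preset target 2.03."""
        ana = transient_metrics(extract_trace(wt_imaging.stack), pacing=0.5)
        assert ana.mean.fold == pytest.approx(2.03, rel=1e-6)

    def test_mut_preset_end_to_end_fold(self, mut_imaging):
        ana = transient_metrics(extract_trace(mut_imaging.stack), pacing=0.5)
        assert ana.mean.fold == pytest.approx(1.55, rel=1e-6)

    def test_t50r_never_exceeds_t90r(self, wt_imaging):
        ana = transient_metrics(extract_trace(wt_imaging.stack), pacing=0.5)
        for m in ana.per_beat:
            assert m.t50r <= m.t90r
            # R90R/R50R = (0.9/0.5) * (T50R/T90R)
            assert m.r90r / m.r50r == pytest.approx(1.8 * m.t50r / m.t90r)

    def test_fold_invariant_to_positive_scaling(self, wt_imaging):
        """Scaling the background-corrected trace leaves fold unchanged."""
        trace = extract_trace(wt_imaging.stack)
        scaled = FluorescenceTrace(trace.time, 3.7 * trace.value)
        a = transient_metrics(trace, pacing=0.5)
        b = transient_metrics(scaled, pacing=0.5)
        assert b.mean.fold == pytest.approx(a.mean.fold, rel=1e-12)

    @pytest.mark.parametrize("sd", [2.0, 0.5, 0.1])
    def test_metrics_converge_to_truth_as_noise_vanishes(self, sd):
        """Tolerance sweep: every metric approaches ground truth as sd -> 0."""
        sim = synth.gen_imaging(
            "WT_12D_GlcFA", noise=NoiseModel(kind="gaussian", sd=sd, seed=11)
        )
        ana = transient_metrics(extract_trace(sim.stack), pacing=0.5)
        truth = sim.metrics
        # noise on the mean trace scales as sd/sqrt(n_cell_px) ~ sd/33
        slack = 0.05 * sd / truth.F0 + 1e-6
        assert ana.mean.fold == pytest.approx(truth.fold, rel=slack)
        assert ana.mean.t50r == pytest.approx(truth.t50r, rel=10 * slack + 0.02)


class TestFitTau:
    def test_noiseless_exponential_self_fit(self):
        t = np.arange(0, 4, 0.01)
        v = 50.0 * np.exp(-t / 1.0) + 100.0
        fit = fit_tau(FluorescenceTrace(t, v), peak_index=0, f0=100.0)
        assert fit.tau == pytest.approx(1.0, abs=1e-6)

    def test_wt_preset_tau_recovered_to_3_decimals(self, wt_imaging):
        ana = transient_metrics(
            extract_trace(wt_imaging.stack), pacing=0.5, with_tau=True
        )
        assert ana.mean.tau == pytest.approx(0.63, abs=5e-4)

    def test_mut_preset_tau_recovered(self, mut_imaging):
        ana = transient_metrics(
            extract_trace(mut_imaging.stack), pacing=0.5, with_tau=True
        )
        assert ana.mean.tau == pytest.approx(0.76, abs=5e-4)

    def test_noisy_fit_matches_grid_search_oracle(self):
        """Nonlinear fit within 2% of a dense tau-grid oracle (A, C solved
        linearly at each tau)."""
        rng = np.random.default_rng(0)
        t = np.arange(0, 3, 0.01)
        amp, tau_true, c = 40.0, 0.8, 100.0
        v = amp * np.exp(-t / tau_true) + c + rng.normal(0, 0.05 * amp, t.size)
        trace = FluorescenceTrace(t, v)
        fit = fit_tau(trace, peak_index=0, f0=c)

        # Oracle: dense grid over tau; per tau the model is linear in (A, C).
        # Restricted to the same 10-90% recovery window as the estimand.
        start = np.nonzero(v <= c + 0.9 * amp)[0][0]
        end = np.nonzero(v <= c + 0.1 * amp)[0][0]
        tt, vv = t[start:end], v[start:end]
        best = (np.inf, None)
        for tau in np.linspace(0.2, 2.0, 1801):
            design = np.column_stack([np.exp(-tt / tau), np.ones_like(tt)])
            coef, res, *_ = np.linalg.lstsq(design, vv, rcond=None)
            sse = float(res[0]) if res.size else np.sum(
                (vv - design @ coef) ** 2
            )
            if sse < best[0]:
                best = (sse, tau)
        assert fit.tau == pytest.approx(best[1], rel=0.02)

    def test_too_few_samples_raises(self):
        t = np.array([0.0, 0.1, 0.2])
        v = np.array([10.0, 9.5, 9.4])
        with pytest.raises(ValueError, match="samples|relaxation"):
            fit_tau(FluorescenceTrace(t, v), peak_index=0, f0=0.0)

    def test_non_decaying_segment_raises(self):
        t = np.arange(0, 1, 0.01)
        v = np.linspace(1.0, 2.0, t.size)
        with pytest.raises(ValueError, match="relaxation|decaying"):
            fit_tau(FluorescenceTrace(t, v), peak_index=0, f0=0.0)
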