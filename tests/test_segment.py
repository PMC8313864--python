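"""Tests for percentile-projection segmentation and signal extraction."""

import numpy as np
import pytest

import optorelease as opt
from optorelease.kinetics import LightSchedule

from conftest import jaccard


def _toy_stack(n_frames=20, shape=(48, 48)):
    """Tiny three-channel stack with a centered square cell layout."""
    protein = np.zeros((n_frames,) + shape)
    mito = np.zeros_like(protein)
    nuc = np.zeros_like(protein)
    protein[:, 8:40, 8:40] = 50.0
    nuc[:, 18:30, 18:30] = 200.0
    mito[:, 10:14, 10:38] = 200.0
    data = np.stack([protein, mito, nuc], axis=1)
    return opt.ImageStack(
        data, {"protein": 0, "mitochondria": 1, "nucleus": 2}, 0.2, 4.0
    )


class TestPercentileProjection:
    def test_constant_stack_unchanged(self):
        frames = np.full((10, 8, 8), 3.5)
        out = opt.percentile_projection(frames, 5, 30.0)
        assert np.allclose(out, 3.5)

    def test_hundredth_percentile_is_windowed_max(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(size=(12, 6, 6))
        out = opt.percentile_projection(frames, 6, 100.0)
        assert np.allclose(out[0], frames[:6].max(axis=0))
        assert np.allclose(out[6], frames[6:].max(axis=0))

    def test_two_windows_split_a_100_frame_movie(self):
        """100 frames with 50-frame windows project frames 1-50 and 51-100."""
        frames = np.concatenate(
            [np.zeros((50, 4, 4)), np.ones((50, 4, 4))]
        )
        out = opt.percentile_projection(frames, 50, 50.0)
        assert np.allclose(out[:50], 0.0)
        assert np.allclose(out[50:], 1.0)

    def test_remainder_absorbed_by_last_window(self):
        frames = np.arange(7, dtype=float)[:, None, None] * np.ones((7, 2, 2))
        out = opt.percentile_projection(frames, 3, 100.0)
        # windows: 0-2, 3-6 (last absorbs the remainder)
        assert np.allclose(out[0], 2.0)
        assert np.allclose(out[3], 6.0)

    def test_bad_percentile_rejected(self):
        with pytest.raises(ValueError):
            opt.percentile_projection(np.zeros((4, 2, 2)), 2, 101.0)


class TestHybridChannel:
    def test_zero_protein_reduces_to_marker_max(self):
        stack = _toy_stack()
        stack.data[:, 0] = 0.0
        hybrid = opt.build_hybrid_channel(stack)
        mito = stack.channel("mitochondria")
        nuc = stack.channel("nucleus")
        expected = np.maximum(mito / mito.max(), nuc / nuc.max())
        assert np.allclose(hybrid, expected)

    def test_hybrid_dominates_each_rescaled_channel(self):
        stack = _toy_stack()
        hybrid = opt.build_hybrid_channel(stack)
        for role in ("protein", "mitochondria", "nucleus"):
            ch = stack.channel(role).astype(float)
            rescaled = (ch - ch.min()) / (ch.max() - ch.min())
            assert np.all(hybrid >= rescaled - 1e-12)

    def test_missing_role_rejected(self):
        stack = _toy_stack()
        broken = opt.ImageStack(
            stack.data[:, :2], {"protein": 0, "mitochondria": 1}, 0.2, 4.0
        )
        with pytest.raises(ValueError):
            opt.build_hybrid_channel(broken)


class TestThresholdInterpolation:
    def test_worked_two_seed_example(self):
        """Seeds at frames 25 (T=10) and 75 (T=20): midpoint 15, flat tails."""
        th = opt.interpolate_thresholds([25, 75], [10.0, 20.0], 100)
        assert th[50] == pytest.approx(15.0)
        assert np.allclose(th[:26], 10.0)
        assert np.allclose(th[75:], 20.0)

    def test_equal_seed_values_give_constant(self):
        th = opt.interpolate_thresholds([10, 30, 50], [4.0, 4.0, 4.0], 60)
        assert np.allclose(th, 4.0)

    def test_single_seed_is_constant_everywhere(self):
        th = opt.interpolate_thresholds([12], [9.0], 40)
        assert np.allclose(th, 9.0)

    def test_unsorted_seeds_rejected(self):
        with pytest.raises(ValueError):
            opt.interpolate_thresholds([30, 10], [1.0, 2.0], 50)


class TestSegmentation:
    def test_known_geometry_recovered(self, small_cell_spec, standard_rates):
        sched = opt.LightSchedule.from_blocks([(5, False), (30, True), (25, False)])
        trace = opt.simulate_trace(standard_rates, sched)
        geom = opt.make_cell_geometry(small_cell_spec)
        stack, _ = opt.render_movie(geom, trace, small_cell_spec)
        masks = opt.segment_compartments(stack, opt.WindowProfile(n_seeds=2))
        for name in ("cell", "nucleus", "mitochondria", "cytoplasm"):
            assert jaccard(getattr(masks, name)[0], getattr(geom, name)) >= 0.9
        # set relations hold on every frame
        masks.validate()
        assert not np.any(masks.cytoplasm & masks.mitochondria)

    def test_threshold_above_maximum_raises_with_frame(self, small_cell_spec,
                                                       standard_rates):
        sched = opt.LightSchedule.from_blocks([(4, False), (4, True)])
        trace = opt.simulate_trace(standard_rates, sched)
        geom = opt.make_cell_geometry(small_cell_spec)
        stack, _ = opt.render_movie(geom, trace, small_cell_spec)
        profile = opt.WindowProfile(
            n_seeds=1,
            thresholds={
                "hybrid": np.array([1e9]),
                "nucleus": np.array([1e9]),
                "mitochondria": np.array([1e9]),
            },
        )
        with pytest.raises(ValueError, match="frame"):
            opt.segment_compartments(stack, profile)


class TestExtractSignals:
    @staticmethod
    def _toy_masks(n_frames=20, shape=(48, 48)):
        cell = np.zeros(shape, bool)
        cell[8:40, 8:40] = True
        nuc = np.zeros(shape, bool)
        nuc[18:30, 18:30] = True
        mito = np.zeros(shape, bool)
        mito[10:14, 10:38] = True
        cyto = cell & ~(nuc | mito)
        tile = lambda m: np.repeat(m[None], n_frames, axis=0)
        return opt.CompartmentMasks(tile(cell), tile(nuc), tile(mito), tile(cyto))

    def test_unit_protein_counts_pixels(self):
        stack = _toy_stack()
        stack.data[:, 0] = 1.0
        masks = self._toy_masks()
        trace = opt.extract_signals(stack, masks)
        assert np.allclose(trace.M, masks.mitochondria[0].sum())
        assert np.allclose(trace.C, masks.cytoplasm[0].sum())
        assert np.allclose(trace.N, masks.nucleus[0].sum())

    def test_zero_protein_gives_zero_totals(self):
        stack = _toy_stack()
        masks = self._toy_masks()
        stack.data[:, 0] = 0.0
        trace = opt.extract_signals(stack, masks)
        assert np.allclose(trace.M, 0.0) and np.allclose(trace.N, 0.0)

    def test_round_trip_correlates_with_generating_ode(
        self, small_cell_spec, standard_rates, standard_schedule
    ):
        trace = opt.simulate_trace(standard_rates, standard_schedule)
        geom = opt.make_cell_geometry(small_cell_spec)
        stack, _ = opt.render_movie(geom, trace, small_cell_spec)
        masks = opt.segment_compartments(stack, opt.WindowProfile(n_seeds=2))
        raw = opt.extract_signals(stack, masks, standard_schedule)
        norm = opt.renormalise_per_frame(opt.bilinear_normalise(raw))
        for est, true in zip(norm.stacked(), trace.stacked()):
            assert np.corrcoef(est, true)[0, 1] >= 0.99


class TestRegionalGain:
    def _schedule(self, n_pre=5, n_lit=60, n_post=5, dt=4.0):
        return LightSchedule.from_blocks(
            [(n_pre, False), (n_lit, True), (n_post, False)], frame_interval_s=dt
        )

    def test_equal_pre_post_gives_256(self):
        sched = self._schedule()
        frames = np.ones((70, 8, 8)) * 100.0
        gain16, gain8 = opt.regional_gain_map(frames, sched)
        assert np.all(gain16 == 256)
        assert np.all(gain8 == 255)  # 8-bit export saturates

    def test_halved_intensity_gives_128(self):
        sched = self._schedule()
        frames = np.ones((70, 8, 8)) * 200.0
        frames[55:] = 100.0  # frames after 200 s of light (50 frames at 4 s)
        gain16, gain8 = opt.regional_gain_map(frames, sched)
        assert np.all(gain16 == 128)
        assert np.all(gain8 == 128)

    def test_zero_pre_pixels_masked_out(self):
        sched = self._schedule()
        frames = np.ones((70, 8, 8)) * 100.0
        frames[:5, :2, :2] = 0.0
        gain16, _ = opt.regional_gain_map(frames, sched)
        assert np.all(gain16[0, 0] == 0)

    def test_uniform_release_is_spatially_flat(
        self, small_cell_spec, standard_rates, standard_schedule
    ):
        trace = opt.simulate_trace(standard_rates, standard_schedule)
        geom = opt.make_cell_geometry(small_cell_spec)
        stack, _ = opt.render_movie(geom, trace, small_cell_spec)
        frames = stack.channel("protein")
        gain16, _ = opt.regional_gain_map(frames, standard_schedule)
        # only bins lying fully inside the cytoplasm are comparable
        h, w = ((s // 2) * 2 for s in geom.cytoplasm.shape)
        binned_all = geom.cytoplasm[:h, :w].reshape(h // 2, 2, w // 2, 2).all(axis=(1, 3))
        vals = gain16[binned_all[: gain16.shape[0], : gain16.shape[1]]].astype(float)
        # 2x2 binning of 1% noise on a uniform release: a few percent spread
        assert vals.std() / vals.mean() < 0.05


class TestPulseAveraging:
    def _staggered(self):
        return opt.default_protocols("opto-staggered")

    def test_identical_segments_have_zero_sd(self):
        sched = self._staggered()
        trace = np.zeros(sched.n_frames)
        pulses = [99, 119, 139, 159]
        for p in pulses:
            seg = min(20, sched.n_frames - p)
            trace[p : p + seg] = np.linspace(1.0, 0.0, seg)
        out = opt.average_pulse_response(trace, sched)
        assert np.allclose(out["sd"], 0.0)
        assert out["mean"].shape[-1] >= 1

    def test_mean_of_three_segments(self):
        sched = opt.LightSchedule.from_blocks(
            [(1, True), (2, False), (1, True), (2, False), (1, True), (2, False)]
        )
        trace = np.array([1.0, 2.0, 3.0, 3.0, 2.0, 1.0, 2.0, 2.0, 2.0])
        out = opt.average_pulse_response(trace, sched, response_len=3)
        assert np.allclose(out["mean"][0], [2.0, 2.0, 2.0])

    def test_single_pulse_rejected(self):
        sched = opt.LightSchedule.from_blocks([(5, False), (1, True), (10, False)])
        with pytest.raises(ValueError):
            opt.average_pulse_response(np.zeros(16), sched)

    def test_unequal_spacing_rejected(self):
        sched = opt.LightSchedule.from_blocks(
            [(1, True), (2, False), (1, True), (5, False), (1, True), (2, False)]
        )
        with pytest.raises(ValueError):
            opt.average_pulse_response(np.zeros(12), sched)
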