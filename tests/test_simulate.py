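"""Simulator ground truth: LIF dynamics, rendering decay, motion injection,
noise statistics, and bit-exact reproducibility."""

import numpy as np
import pytest

from califlow import simulate
from califlow.motion import invert_warp, warp_frame
from califlow.simulate import (LIFParams, MaskSet, MotionConfig,
                               NetworkTopology, NoiseConfig, SimConfig,
                               add_noise, generate_masks, inject_motion,
                               render_frames, sample_motion_track,
                               simulate_bundle, simulate_spikes)


def topology(n=20, frac_a=0.5, seed=0):
    return NetworkTopology.random(n, frac_a, np.random.default_rng(seed))


class TestSpikes:
    def test_no_drive_means_no_spikes(self):
        lif = LIFParams(theta=0.0, stim_rate=0.0)
        sp = simulate_spikes(topology(), lif, 200, np.random.default_rng(1))
        assert sp.sum() == 0

    def test_two_coactive_parents_add_2w(self):
        # one child with two parents; parents forced to "fire" by direct
        # construction of the scalar update: child potential gains 2w the
        # frame after both parents spike
        topo = NetworkTopology(3, [0, 1], [2], {2: [0, 1]})
        lif = LIFParams(theta=0.0, stim_rate=1.0, w=0.2,
                        v_threshold=0.15)  # every frame a stimulus event
        sp = simulate_spikes(topo, lif, 3, np.random.default_rng(0))
        # parents spike at t=0 (stimulus 0.2 > 0.15); child receives 0.4 at
        # t=1 and crosses its threshold
        assert sp[0, 0] == 1 and sp[1, 0] == 1
        assert sp[2, 1] == 1

    def test_refractory_gap_enforced(self):
        lif = LIFParams()
        sp = simulate_spikes(topology(40), lif, 2000,
                             np.random.default_rng(2))
        for i in range(sp.shape[0]):
            times = np.flatnonzero(sp[i])
            if len(times) > 1:
                assert np.diff(times).min() > lif.refractory

    def test_rate_matches_scalar_euler_oracle(self):
        # brute-force scalar simulation of the same update rule for one
        # isolated stimulus-free neuron, compared at matched noise draws
        lif = LIFParams(stim_rate=0.0)
        n_steps = 30_000
        rng = np.random.default_rng(3)
        v = lif.v_rest
        refr = 0
        count = 0
        noise = lif.theta * lif.lam * 0.5
        eps = rng.standard_normal(n_steps)
        for t in range(n_steps):
            v += (lif.v_rest - v) / lif.lam - noise * eps[t]
            if t >= refr and v > lif.v_threshold:
                count += 1
                v = lif.v_rest
                refr = t + 1 + lif.refractory
        oracle_rate = count / n_steps

        topo = NetworkTopology(1, [0], [], {})
        sp = simulate_spikes(topo, lif, n_steps, np.random.default_rng(4))
        rate = sp.mean()
        assert rate == pytest.approx(oracle_rate, abs=3 * np.sqrt(
            oracle_rate / n_steps) + 2e-3)

    def test_silent_neurons_never_fire(self):
        sp = simulate_spikes(topology(20), LIFParams(), 2000,
                             np.random.default_rng(5), silent={3, 7})
        assert sp[3].sum() == 0 and sp[7].sum() == 0
        assert sp.sum() > 0

    def test_bad_lambda_rejected(self):
        with pytest.raises(ValueError):
            LIFParams(lam=0.0)


class TestRender:
    def _one_neuron(self, spike_frames, T=30):
        sp = np.zeros((1, T), dtype=np.uint8)
        sp[0, spike_frames] = 1
        masks = generate_masks(1, (32, 32), 6.8, 6.8,
                               np.random.default_rng(0))
        return sp, masks

    def test_half_life_decay_hits_64_at_8_frames(self):
        sp, masks = self._one_neuron([0])
        video = render_frames(sp, masks, 8.0)
        px = np.argwhere(masks.masks[0])[0]
        assert video[8, px[0], px[1]] == pytest.approx(64.0, abs=1e-4)

    def test_trace_matches_closed_form_between_spikes(self):
        sp, masks = self._one_neuron([0, 17])
        video = render_frames(sp, masks, 8.0)
        px = np.argwhere(masks.masks[0])[0]
        trace = video[:, px[0], px[1]]
        for t in range(1, 17):
            assert trace[t] == pytest.approx(128 * 2 ** (-t / 8), rel=1e-5)
        assert trace[17] == 128.0

    def test_no_spikes_all_zero(self):
        sp, masks = self._one_neuron([])
        assert render_frames(sp, masks, 8.0).sum() == 0

    def test_overlapping_masks_take_pixel_max(self):
        masks = np.zeros((2, 16, 16), dtype=bool)
        masks[0, 4:9, 4:9] = True
        masks[1, 6:11, 6:11] = True
        ms = MaskSet(masks, np.zeros((2, 2)), np.array([5, 5]),
                     np.array([5, 5]))
        sp = np.zeros((2, 3), dtype=np.uint8)
        sp[0, 0] = 1   # neuron 0 bright, neuron 1 decaying from nothing
        sp[1, 2] = 1
        video = render_frames(sp, ms, 8.0)
        # overlap pixel at t=2: neuron 0 decayed to ~107.6, neuron 1 at 128
        assert video[2, 7, 7] == pytest.approx(128.0)
        assert video[2, 4, 4] == pytest.approx(128 * 2 ** (-2 / 8), rel=1e-5)

    def test_shape_mismatch_rejected(self):
        sp, masks = self._one_neuron([0])
        with pytest.raises(ValueError):
            render_frames(np.zeros((2, 10), dtype=np.uint8), masks, 8.0)


class TestMasks:
    def test_masks_connected_and_nonempty(self):
        ms = generate_masks(50, (300, 300), 6.8387, 6.7634,
                            np.random.default_rng(1))
        from scipy import ndimage
        for i in range(50):
            assert ms.masks[i].any()
            _, n = ndimage.label(ms.masks[i])
            assert n == 1

    def test_mean_sizes_near_targets(self):
        ms = generate_masks(100, (400, 400), 6.8387, 6.7634,
                            np.random.default_rng(2))
        assert ms.widths.mean() == pytest.approx(6.8387, rel=0.10)
        assert ms.heights.mean() == pytest.approx(6.7634, rel=0.10)

    def test_no_two_masks_identical(self):
        ms = generate_masks(40, (300, 300), 6.8, 6.8,
                            np.random.default_rng(3))
        flat = ms.masks.reshape(40, -1)
        for i in range(40):
            for j in range(i + 1, 40):
                assert not np.array_equal(flat[i], flat[j])

    def test_grid_too_small_raises(self):
        with pytest.raises(ValueError):
            generate_masks(500, (40, 40), 6.8, 6.8,
                           np.random.default_rng(4))


class TestMotionInjection:
    def test_p_rot_zero_means_no_rotation(self):
        track = sample_motion_track(500, MotionConfig(p_rot=0),
                                    np.random.default_rng(0))
        assert np.all(track[:, 2] == 0)

    def test_rotation_frequency_matches_p_rot(self):
        track = sample_motion_track(
            1800, MotionConfig(p_rot=10, alpha_rot=5.16),
            np.random.default_rng(1))
        freq = np.mean(track[1:, 2] != 0)
        # binomial 99% CI around 0.10 for n=1799
        assert abs(freq - 0.10) < 3 * np.sqrt(0.1 * 0.9 / 1799)
        nz = track[track[:, 2] != 0, 2]
        assert np.all(np.abs(nz) <= 5.16)

    def test_constant_drift_first_steps(self):
        track = sample_motion_track(
            5, MotionConfig(drift_mode="constant_trajectory"),
            np.random.default_rng(2))
        assert track[0, 0] == 0 and track[0, 1] == 0
        assert (track[1, 0], track[1, 1]) == (1, 0)
        assert (track[2, 0], track[2, 1]) == (2, 0)

    def test_drift_ranges(self):
        small = sample_motion_track(400, MotionConfig(drift_mode="small"),
                                    np.random.default_rng(3))
        assert np.all(np.abs(small[:, :2]) <= 3.0)
        large = sample_motion_track(400, MotionConfig(drift_mode="large"),
                                    np.random.default_rng(4))
        mags = np.abs(large[1:, :2])
        assert np.all((mags >= 7.0) & (mags <= 10.0))

    def test_injected_motion_is_invertible_on_checkerboard(self):
        # warping the moved frame by the inverse track recovers the clean
        # frame up to interpolation error, bounded on a checkerboard
        yy, xx = np.mgrid[0:120, 0:120]
        from scipy import ndimage
        board = ndimage.gaussian_filter(
            (((yy // 8) + (xx // 8)) % 2 * 200.0), 1.0)
        clean = np.repeat(board[None], 6, axis=0).astype(np.float32)
        cfg = MotionConfig(p_rot=50, alpha_rot=6.0)
        moved, track = inject_motion(clean, cfg, np.random.default_rng(5))
        for t in range(6):
            rec = warp_frame(moved[t], *invert_warp(*track[t]))
            interior = (slice(25, -25), slice(25, -25))
            rmse = np.sqrt(np.mean((rec[interior] - clean[t][interior]) ** 2))
            assert rmse < 12.0  # interpolation-noise bound for this pattern


class TestNoise:
    def test_zero_levels_identity(self):
        video = np.full((4, 8, 8), 50, dtype=np.float32)
        out = add_noise(video, NoiseConfig(0.0, 0.0),
                        np.random.default_rng(0))
        assert np.array_equal(out, video)

    def test_colored_marginal_std(self):
        z = np.zeros((3000, 6, 6), dtype=np.float32)
        out = add_noise(z, NoiseConfig(0.0, 1.5), np.random.default_rng(1),
                        clamp=False)
        assert out.std() == pytest.approx(1.5 * 0.4, rel=0.05)

    def test_shot_std_and_whiteness(self):
        z = np.zeros((2000, 5, 5), dtype=np.float32)
        out = add_noise(z, NoiseConfig(0.5, 0.0), np.random.default_rng(2),
                        clamp=False)
        assert out.std() == pytest.approx(0.5, rel=0.05)
        x = out[:, 2, 2]
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(lag1) < 0.08

    def test_colored_autocorrelation_positive(self):
        z = np.zeros((4000, 3, 3), dtype=np.float32)
        out = add_noise(z, NoiseConfig(0.0, 1.0), np.random.default_rng(3),
                        clamp=False)
        x = out[:, 1, 1]
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert lag1 == pytest.approx(0.8, abs=0.06)

    @pytest.mark.parametrize("label,s,c", [
        ("s05c15", 0.5, 1.5), ("s01c05", 0.1, 0.5), ("s03c10", 0.3, 1.0)])
    def test_label_grammar(self, label, s, c):
        cfg = NoiseConfig.from_label(label)
        assert (cfg.shot_level, cfg.colored_level) == (s, c)
        assert cfg.label == label

    def test_bad_label_rejected(self):
        with pytest.raises(ValueError):
            NoiseConfig.from_label("x05c15")


class TestBundle:
    def test_bit_exact_reproducibility(self):
        cfg = SimConfig(n_neurons=10, n_frames=40, grid=(100, 100),
                        motion=MotionConfig(p_rot=20, alpha_rot=4.0),
                        noise=NoiseConfig(0.3, 0.5))
        a = simulate_bundle(cfg, 123)
        b = simulate_bundle(cfg, 123)
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.spikes, b.spikes)
        assert np.array_equal(a.motion_track, b.motion_track)
        assert np.array_equal(a.masks.masks, b.masks.masks)

    def test_different_seed_differs(self):
        cfg = SimConfig(n_neurons=10, n_frames=20, grid=(100, 100))
        a = simulate_bundle(cfg, 1)
        b = simulate_bundle(cfg, 2)
        assert not np.array_equal(a.spikes, b.spikes)

    def test_forced_silent_count(self):
        cfg = SimConfig(n_neurons=25, n_frames=300, grid=(200, 200),
                        n_silent=3)
        b = simulate_bundle(cfg, 9)
        assert len(b.active_neurons) == 22

    def test_first_frame_unmoved(self):
        cfg = SimConfig(n_neurons=10, n_frames=20, grid=(100, 100))
        b = simulate_bundle(cfg, 3)
        assert np.all(b.motion_track[0] == 0)
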