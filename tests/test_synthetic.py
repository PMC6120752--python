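import numpy as np
import pytest
from scipy.integrate import quad

from dendroca import behavior as beh
from dendroca import stats as st
from dendroca import synthetic as syn


class TestKernel:
    def test_pure_decay_reaches_1_over_e_after_tau(self):
        # 40 Hz sampling puts t = tau = 150 ms exactly on the frame grid
        k = syn.gcamp_kernel(0.0, 0.150, 40.0)
        idx = 6
        assert k[0] == 1.0
        assert k[idx] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_peak_sample_is_one_and_nonnegative(self):
        for tr, td in ((0.0, 0.1), (0.01, 0.15), (0.05, 0.4)):
            k = syn.gcamp_kernel(tr, td, 30.0)
            assert k.max() == 1.0
            assert np.all(k >= 0)
            assert k.size >= 5 * td * 30.0

    def test_double_exponential_matches_quadrature(self):
        tr, td, fr = 0.010, 0.150, 1000.0
        k = syn.gcamp_kernel(tr, td, fr)
        tp = syn.kernel_peak_time(tr, td)
        assert tp > 0
        peak = np.exp(-tp / td) - np.exp(-tp / tr)
        ref, _ = quad(lambda t: (np.exp(-t / td) - np.exp(-t / tr)) / peak, 0, k.size / fr)
        # the sampled kernel is normalized to its sampled peak; rescale to
        # the continuous normalization before comparing the integrals
        scale = syn.evaluate_kernel(np.argmax(k) / fr, tr, td)
        assert np.trapezoid(k * scale, dx=1 / fr) == pytest.approx(ref, rel=1e-3)

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            syn.gcamp_kernel(0.2, 0.1, 30.0)
        with pytest.raises(ValueError):
            syn.gcamp_kernel(0.0, -1.0, 30.0)


class TestLickBouts:
    def test_zero_trials_empty_log(self):
        cfg = syn.SimConfig(duration=50.0, seed=0)
        log = syn.simulate_lick_bouts(cfg, 0)
        assert log.n_trials == 0
        assert log.lick_times.size == 0

    def test_within_bout_rate_matches_lick_period(self):
        cfg = syn.SimConfig(duration=100.0, seed=2, lick_period=0.13, bout_duration=3.0)
        log = syn.simulate_lick_bouts(cfg, 9)
        ili = np.diff(log.lick_times)
        within = ili[ili < 0.5]
        assert 1.0 / within.mean() == pytest.approx(1 / 0.13, rel=0.05)

    def test_fixed_seed_is_bit_identical(self):
        cfg = syn.SimConfig(duration=60.0, seed=7)
        a = syn.simulate_lick_bouts(cfg, 5)
        b = syn.simulate_lick_bouts(cfg, 5)
        assert a == b

    def test_each_trial_has_cue_water_and_bout(self):
        cfg = syn.SimConfig(duration=60.0, seed=3)
        log = syn.simulate_lick_bouts(cfg, 5)
        assert log.cue_onsets.size == log.water_times.size == 5
        for on, off in zip(log.cue_onsets, log.cue_offsets):
            licks = log.lick_times[(log.lick_times > off) & (log.lick_times < on + cfg.trial_interval)]
            assert licks.size > 10  # a real bout, not a stray lick


class TestEventTrain:
    def test_zero_rate_gives_empty_train(self):
        cfg = syn.SimConfig(duration=100.0, seed=0, base_rate=0.0)
        assert syn.simulate_event_train(cfg, None).size == 0

    def test_homogeneous_rate_matches_poisson_expectation(self):
        counts = []
        for seed in range(100):
            cfg = syn.SimConfig(
                duration=200.0, seed=seed, base_rate=1.5, lick_boost=1.0
            )
            counts.append(syn.simulate_event_train(cfg, None).size)
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 300.0) < 3 * max(se, 1.0)

    def test_lick_boost_raises_in_epoch_rate(self):
        ratios = []
        for seed in range(5):
            cfg = syn.SimConfig(duration=200.0, seed=seed)
            log = syn.simulate_lick_bouts(cfg, 19, np.random.default_rng(seed))
            train = syn.simulate_event_train(cfg, log, np.random.default_rng(seed + 1))
            grid = np.arange(0, cfg.duration, 1 / 30)
            glab = beh.epoch_labels(grid, log.lick_times)
            elab = beh.epoch_labels(train, log.lick_times)
            t_in = (glab == beh.LICKING).mean() * cfg.duration
            t_out = (glab == beh.NON_LICKING).mean() * cfg.duration
            r_in = (elab == beh.LICKING).sum() / t_in
            r_out = (elab == beh.NON_LICKING).sum() / t_out
            ratios.append(r_in / r_out)
        assert np.mean(ratios) == pytest.approx(5.0, rel=0.15)

    def test_refractory_gap_enforced(self):
        cfg = syn.SimConfig(duration=300.0, seed=4)
        log = syn.simulate_lick_bouts(cfg, 29)
        train = syn.simulate_event_train(cfg, log)
        assert np.all(np.diff(train) >= 2 / cfg.frame_rate - 1e-12)

    def test_rate_conservation_with_dead_time(self):
        cfg = syn.SimConfig(duration=10000 / 1.5, seed=5, lick_boost=1.0)
        train = syn.simulate_event_train(cfg, None)
        assert train.size / cfg.duration == pytest.approx(1.5, rel=0.05)


class TestRenderTrace:
    def test_no_events_no_noise_is_constant_baseline(self):
        cfg = syn.SimConfig(duration=5.0, seed=0, noise_sigma=0.0)
        tr, _ = syn.render_trace([], [], cfg)
        assert np.allclose(tr.samples, cfg.baseline_f)

    def test_single_event_peak_within_discretization(self):
        cfg = syn.SimConfig(duration=5.0, seed=0, noise_sigma=0.0)
        tr, gt = syn.render_trace([2.0], [0.223], cfg)
        peak_dff = tr.samples.max() / cfg.baseline_f - 1.0
        # sampled peak can fall below the continuous peak by at most the
        # curvature loss over half a frame
        assert 0.223 * 0.88 <= peak_dff <= 0.223 + 1e-9

    def test_disinhibited_scales_only_movement_amps(self):
        cfg = syn.SimConfig(duration=30.0, seed=1, cno_gain_move=1.15, noise_sigma=0.0)
        licks = np.arange(10.0, 13.0, 0.13)
        events = np.array([5.0, 11.0, 20.0])
        amps = np.array([0.2, 0.2, 0.2])
        _, gt = syn.render_trace(events, amps, cfg, licks, syn.DISINHIBITED)
        assert gt.event_amps[1] == pytest.approx(0.2 * 1.15)
        assert gt.event_amps[0] == gt.event_amps[2] == 0.2

    def test_nonpositive_amplitude_rejected(self):
        cfg = syn.SimConfig(duration=5.0, seed=0)
        with pytest.raises(ValueError):
            syn.render_trace([1.0], [0.0], cfg)


class TestRenderMovie:
    def test_single_mask_pixels_follow_source(self):
        cfg = syn.SimConfig(duration=2.0, seed=0, noise_sigma=0.0)
        mask = np.zeros((16, 16), bool)
        mask[4:10, 4:8] = True
        trace = 1.0 + 0.3 * np.sin(np.arange(60) / 5.0)
        movie, shifts = syn.render_movie(
            mask, trace, 0.0, cfg, noise_sigma_px=0.0, psf_sigma_px=0.0
        )
        assert np.allclose(movie[:, 5, 5], trace)
        assert np.allclose(movie[:, 0, 0], 0.0)
        assert np.all(shifts == 0)

    def test_disjoint_sources_give_block_correlations(self, rng):
        cfg = syn.SimConfig(duration=2.0, seed=0, noise_sigma=0.0)
        masks = syn.dendrite_band_masks(2, (16, 16), margin=2)
        traces = rng.standard_normal((2, 200)) + 5.0
        movie, _ = syn.render_movie(
            masks, traces, 0.0, cfg, noise_sigma_px=0.0, psf_sigma_px=0.0
        )
        px = movie.reshape(200, -1)
        in0 = np.nonzero(masks[0].ravel())[0]
        in1 = np.nonzero(masks[1].ravel())[0]
        c_within = np.corrcoef(px[:, in0[0]], px[:, in0[-1]])[0, 1]
        c_across = np.corrcoef(px[:, in0[0]], px[:, in1[0]])[0, 1]
        assert c_within == pytest.approx(1.0, abs=1e-9)
        assert abs(c_across) < 0.2

    def test_shape_mismatch_rejected(self):
        cfg = syn.SimConfig(duration=1.0, seed=0)
        with pytest.raises(ValueError):
            syn.render_movie(np.ones((2, 8, 8)), np.ones((3, 30)), 0.0, cfg)


class TestBranchPair:
    def test_zero_jitter_gives_identical_branches(self):
        cfg = syn.SimConfig(duration=60.0, seed=0, branch_jitter_sd=0.0)
        _, _, gt = syn.simulate_branch_pair(cfg)
        assert np.allclose(gt["amps_branch1"], gt["amps_branch2"])
        v = st.branch_variability(gt["amps_branch1"], gt["amps_branch2"])
        assert np.all(v == 0)

    def test_variability_matches_lognormal_monte_carlo(self, rng):
        sd = 0.2
        z1 = np.exp(sd * rng.standard_normal(10**6) - sd**2 / 2)
        z2 = np.exp(sd * rng.standard_normal(10**6) - sd**2 / 2)
        expected = np.mean(2 * np.abs(z1 - z2) / (z1 + z2))
        cfg = syn.SimConfig(duration=400.0, seed=3, branch_jitter_sd=sd)
        _, _, gt = syn.simulate_branch_pair(cfg)
        emp = np.mean(st.branch_variability(gt["amps_branch1"], gt["amps_branch2"]))
        assert emp == pytest.approx(expected, rel=0.1)

    def test_fixed_seed_reproducible(self):
        cfg = syn.SimConfig(duration=30.0, seed=11)
        a = syn.simulate_branch_pair(cfg)
        b = syn.simulate_branch_pair(cfg)
        assert np.array_equal(a[0].samples, b[0].samples)
        assert np.array_equal(a[1].samples, b[1].samples)


class TestSessionInvariants:
    def test_identical_config_and_seed_bit_identical(self):
        cfg = syn.SimConfig(duration=40.0, seed=9)
        a = syn.simulate_session(cfg)
        b = syn.simulate_session(cfg)
        assert np.array_equal(a.traces[0].samples, b.traces[0].samples)
        assert np.array_equal(
            a.ground_truth[0].event_times, b.ground_truth[0].event_times
        )

    def test_condition_contract_amp_ratio_exact(self):
        g = 1.25
        base = dict(duration=100.0, seed=2)
        ctrl = syn.simulate_session(syn.SimConfig(**base))
        dis = syn.simulate_session(
            syn.SimConfig(cno_gain_move=g, **base), condition=syn.DISINHIBITED
        )
        gc, gd = ctrl.ground_truth[0], dis.ground_truth[0]
        move = gc.epoch_of_event == beh.LICKING
        assert move.sum() > 10
        ratio = gd.event_amps[move].mean() / gc.event_amps[move].mean()
        assert ratio == pytest.approx(g, abs=1e-12)
        rest = gc.epoch_of_event == beh.NON_LICKING
        assert np.array_equal(gd.event_amps[rest], gc.event_amps[rest])

    def test_ground_truth_validation(self):
        with pytest.raises(ValueError):
            syn.GroundTruth(event_times=[2.0, 1.0], event_amps=[0.1, 0.1])
        with pytest.raises(ValueError):
            syn.GroundTruth(event_times=[1.0], event_amps=[-0.1])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            syn.SimConfig(tau_decay=0.005, tau_rise=0.01)
        with pytest.raises(ValueError):
            syn.SimConfig(cno_gain_move=0.8)
        with pytest.raises(ValueError):
            syn.SimConfig(mean_amp=0.0)
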