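import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from dendroca import stats as st
from dendroca import synthetic as syn

from oracles import branch_variability_oracle, mdm_oracle

pos = hst.floats(1e-3, 1e3)


class TestMdmRatio:
    def test_all_equal_is_unity(self):
        assert st.mdm_ratio(dff_cno_move=0.3, dff_ctrl_move=0.3, dff_cno_rest=0.3, dff_ctrl_rest=0.3) == 1.0

    def test_pure_movement_enhancement(self):
        r = st.mdm_ratio(dff_cno_move=1.2, dff_ctrl_move=1.0, dff_cno_rest=1.0, dff_ctrl_rest=1.0)
        assert r == pytest.approx(1.2)

    def test_nonpositive_input_rejected(self):
        with pytest.raises(ValueError):
            st.mdm_ratio(dff_cno_move=0.0, dff_ctrl_move=1.0, dff_cno_rest=1.0, dff_ctrl_rest=1.0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(a=pos, b=pos, c=pos, d=pos, scale=pos)
    def test_matches_oracle_and_scaling_invariance(self, a, b, c, d, scale):
        r = st.mdm_ratio(dff_cno_move=a, dff_ctrl_move=b, dff_cno_rest=c, dff_ctrl_rest=d)
        assert r == pytest.approx(mdm_oracle(a, b, c, d), rel=1e-12)
        rs = st.mdm_ratio(
            dff_cno_move=a * scale,
            dff_ctrl_move=b * scale,
            dff_cno_rest=c * scale,
            dff_ctrl_rest=d * scale,
        )
        assert rs == pytest.approx(r, rel=1e-9)


class TestMdmMap:
    def test_identical_sessions_all_unity(self):
        act = np.full(20, 0.4)
        ratios, frac = st.mdm_map(act, act, act, act)
        assert np.allclose(ratios, 1.0)

    def test_null_noise_fraction_near_half(self, rng):
        n = 4000
        base = rng.lognormal(0, 0.1, 4 * n).reshape(4, n)
        ratios, frac = st.mdm_map(*base)
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_gain_on_subset_of_rois_recovered(self, rng):
        # 70% of ROIs carry a movement-specific gain; unaffected ROIs sit
        # exactly at the null, so the fraction above 1 recovers the 0.70
        n = 1000
        ctrl_m = rng.lognormal(0, 0.02, n)
        gained = np.arange(n) < 700
        cno_m = ctrl_m * np.where(gained, 1.3, 1.0)
        rest = rng.lognormal(0, 0.02, n)
        ratios, frac = st.mdm_map(ctrl_m, cno_m, rest, rest)
        assert frac == pytest.approx(0.70, abs=0.05)
        assert np.allclose(ratios[gained], 1.3)

    def test_invariant_to_common_fluorescence_scaling(self, rng):
        arrs = [rng.lognormal(0, 0.2, 50) for _ in range(4)]
        r1, f1 = st.mdm_map(*arrs)
        r2, f2 = st.mdm_map(*(2.0 * a for a in arrs))
        assert np.allclose(r1, r2)
        assert f1 == f2

    def test_unmatched_rois_rejected(self):
        with pytest.raises(ValueError):
            st.mdm_map([1.0], [1.0, 2.0], [1.0], [1.0])


class TestRocEffectFraction:
    def test_identical_distributions_near_chance(self, rng):
        a = rng.normal(0, 1, 5000)
        b = rng.normal(0, 1, 5000)
        auc, pct = st.roc_effect_fraction(a, b)
        assert auc == pytest.approx(0.5, abs=0.02)
        assert pct < 3.0

    def test_complete_separation(self):
        auc, pct = st.roc_effect_fraction([1.0, 2.0], [10.0, 11.0])
        assert auc == 1.0 and pct == 100.0

    def test_shifted_fraction_recovered(self, rng):
        for f in (0.0, 0.3, 0.66, 1.0):
            ctrl = rng.normal(1.0, 0.2, 10_000)
            shifted = rng.random(10_000) < f
            cno = rng.normal(1.0, 0.2, 10_000) + np.where(shifted, 2.0, 0.0)
            _, pct = st.roc_effect_fraction(ctrl, cno)
            assert pct == pytest.approx(100 * f, abs=5.0)

    def test_monotone_in_shifted_fraction(self, rng):
        pcts = []
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            ctrl = rng.normal(1.0, 0.2, 4000)
            cno = rng.normal(1.0, 0.2, 4000) + np.where(rng.random(4000) < f, 2.0, 0.0)
            pcts.append(st.roc_effect_fraction(ctrl, cno)[1])
        assert np.all(np.diff(pcts) >= -1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            st.roc_effect_fraction([], [1.0])


class TestBranchVariability:
    def test_equal_amplitudes_zero(self):
        assert st.branch_variability(1.0, 1.0) == 0.0

    def test_one_sided_limit_is_two(self):
        assert st.branch_variability(0.7, 0.0) == 2.0

    def test_hand_computed_value(self):
        assert st.branch_variability(0.3, 0.1) == pytest.approx(1.0)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            st.branch_variability(0.0, 0.0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(a=pos, b=pos, c=pos)
    def test_oracle_symmetry_scale_invariance_and_bounds(self, a, b, c):
        v = st.branch_variability(a, b)
        assert v == pytest.approx(branch_variability_oracle(a, b), rel=1e-12)
        assert v == pytest.approx(st.branch_variability(b, a), rel=1e-12)
        assert v == pytest.approx(st.branch_variability(c * a, c * b), rel=1e-9)
        assert 0.0 <= v <= 2.0


class TestFitDecayPeak:
    def make_decay(self, a=0.5, tau=0.15, stim=0.5, fr=500.0, dur=1.5):
        t = np.arange(0, dur, 1 / fr)
        return np.where(t >= stim, a * np.exp(-(t - stim) / tau), 0.0)

    def test_noiseless_exponential_recovered(self):
        fit = st.fit_decay_peak(self.make_decay(), 500.0, 0.5)
        assert fit.converged
        assert fit.peak == pytest.approx(0.5, rel=0.01)
        assert fit.tau == pytest.approx(0.15, rel=0.01)

    def test_zero_trace_gives_zero_peak(self):
        fit = st.fit_decay_peak(np.zeros(800), 500.0, 0.5)
        assert fit.peak == 0.0
        assert not fit.converged

    def test_blanked_artifact_region_recovered(self):
        y = self.make_decay()
        y[250:270] = 5.0  # stimulus artifact that would dominate a raw max
        fit = st.fit_decay_peak(y, 500.0, 0.5, blank_window=(0.5, 0.54))
        assert fit.peak == pytest.approx(0.5, rel=0.03)

    def test_too_few_decay_samples_rejected(self):
        with pytest.raises(ValueError):
            st.fit_decay_peak(np.ones(20), 500.0, 0.035)


class TestSupralinearity:
    def test_exact_sum_is_100_percent(self):
        cs = syn.simulate_conjunctive_set(gain=1.0, noise_sigma=0.0, seed=0)
        assert st.supralinearity(cs) == pytest.approx(100.0, abs=1e-6)

    def test_scaled_sum_is_110_percent(self):
        cs = syn.simulate_conjunctive_set(gain=1.10, noise_sigma=0.0, seed=0)
        assert st.supralinearity(cs) == pytest.approx(110.0, abs=1e-6)

    def test_noisy_gain_recovery_at_ten_trials(self):
        vals = [
            st.supralinearity(syn.simulate_conjunctive_set(gain=1.2, seed=s))
            for s in range(20)
        ]
        assert np.mean(vals) == pytest.approx(120.0, abs=4.0)

    def test_null_distribution_centered_at_100(self):
        vals = np.array(
            [st.supralinearity(syn.simulate_conjunctive_set(gain=1.0, seed=s)) for s in range(60)]
        )
        se = vals.std() / np.sqrt(vals.size)
        assert abs(vals.mean() - 100.0) < 2 * se + 0.5
        # symmetric about 100: mean and median agree within sampling error
        assert abs(np.median(vals) - vals.mean()) < 1.5

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            st.ConjunctiveSet(np.ones(10), np.ones(9), np.ones(10), 0.5, 500.0)


class TestNeuropilCorrect:
    def test_zero_neuropil_identity(self, rng):
        b = rng.random(100)
        assert np.allclose(st.neuropil_correct(b, np.zeros(100)), b)

    def test_equal_signals_cancel(self, rng):
        b = rng.random(100)
        assert np.allclose(st.neuropil_correct(b, b), 0.0)

    def test_contaminated_bouton_recovers_source(self, rng):
        n = 2000
        source = np.convolve(rng.poisson(0.05, n) * 0.3, np.exp(-np.arange(20) / 5))[:n]
        background = np.convolve(rng.poisson(0.08, n) * 0.2, np.exp(-np.arange(20) / 5))[:n]
        bouton = source + 0.4 * background + 0.01 * rng.standard_normal(n)
        corrected = st.neuropil_correct(bouton, 0.4 * background)
        assert np.corrcoef(corrected, source)[0, 1] > 0.95

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            st.neuropil_correct(np.ones(5), np.ones(6))
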