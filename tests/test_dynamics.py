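"""Temporal-dynamics features: aperiodic fit, analytic signal, DFA, and
broken-detailed-balance statistics, with closed-form and robust-regression
oracles."""

import numpy as np
import pytest
from scipy import stats

import icueeg as q
from icueeg.dynamics import (
    entropy_production_rate, flux_curl, transition_model, _band_window_bounds,
)
from icueeg.spectral import SpectrumSet
from tests_helpers import make_segment


def _spectrum(psd, freqs):
    psd = np.atleast_2d(np.asarray(psd, float))
    return SpectrumSet(freqs=np.asarray(freqs, float), psd=psd,
                       window_count=np.full(psd.shape[0], 6),
                       labels=list(q.STANDARD_1020[: psd.shape[0]]), fs=256.0)


class TestAperiodicFit:
    def test_noiseless_power_law_exact(self):
        freqs = np.arange(0.5, 40.05, 0.1)
        fit = q.fit_aperiodic(_spectrum(100.0 * freqs**-2.0, freqs))
        assert fit.exponent == pytest.approx(2.0, abs=1e-12)
        assert fit.offset == pytest.approx(2.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_spectrum_zero_exponent(self):
        freqs = np.arange(0.5, 40.05, 0.1)
        fit = q.fit_aperiodic(_spectrum(np.full(freqs.size, 3.0), freqs))
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)

    def test_planted_alpha_peak_masked(self):
        """f^-2 background with a 3x Gaussian alpha bump: exponent recovered
        within 0.1, and consistent with an independent Theil-Sen robust
        slope on the same log-log array."""
        freqs = np.arange(0.5, 40.05, 0.1)
        background = 100.0 * freqs**-2.0
        peak = 3.0 * background * np.exp(-((freqs - 10.0) ** 2) / (2 * 1.5**2))
        fit = q.fit_aperiodic(_spectrum(background + peak, freqs))
        assert fit.exponent == pytest.approx(2.0, abs=0.1)
        m = (freqs >= 1.0) & (freqs <= 40.0)
        ts = stats.theilslopes(np.log10(background + peak)[m], np.log10(freqs[m]))
        assert fit.exponent == pytest.approx(-ts.slope, abs=0.1)

    def test_nonpositive_bins_excluded(self):
        freqs = np.arange(0.5, 40.05, 0.1)
        psd = 10.0 * freqs**-1.0
        psd[50:60] = 0.0
        fit = q.fit_aperiodic(_spectrum(psd, freqs))
        assert fit.exponent == pytest.approx(1.0, abs=1e-9)

    def test_narrow_range_rejected(self):
        freqs = np.arange(1.0, 2.0, 0.1)
        with pytest.raises(ValueError):
            q.fit_aperiodic(_spectrum(np.ones(freqs.size), freqs))


class TestBandAnalytic:
    def test_unit_sine_envelope_flat(self):
        t = np.arange(256 * 30) / 256.0
        seg = make_segment(np.sin(2 * np.pi * 10 * t)[None, :])
        env, _ = q.band_analytic(seg, "alpha")
        inner = env[0, 2560:-2560]
        np.testing.assert_allclose(inner, 1.0, atol=0.02)

    def test_envelope_recovers_modulator(self):
        t = np.arange(256 * 60) / 256.0
        modulator = 1.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t)
        seg = make_segment((modulator * np.sin(2 * np.pi * 10 * t))[None, :])
        env, _ = q.band_analytic(seg, "alpha")
        r = np.corrcoef(env[0, 2560:-2560], modulator[2560:-2560])[0, 1]
        assert r > 0.99

    def test_phase_advances_one_cycle_per_period(self):
        t = np.arange(256 * 30) / 256.0
        seg = make_segment(np.sin(2 * np.pi * 10 * t)[None, :])
        _, phase = q.band_analytic(seg, "alpha")
        unwrapped = np.unwrap(phase[0, 2560:-2560])
        cycles = (unwrapped[-1] - unwrapped[0]) / (2 * np.pi)
        expected = 10.0 * (unwrapped.size / 256.0)
        assert cycles == pytest.approx(expected, rel=0.01)


class TestKuramoto:
    def test_identical_phases_full_synchrony(self):
        phases = np.tile(np.linspace(0, 20, 1000), (5, 1))
        np.testing.assert_allclose(q.kuramoto_order(phases), 1.0)

    def test_evenly_spaced_phases_zero(self):
        base = np.linspace(0, 20, 1000)
        phases = np.vstack([base + k * 2 * np.pi / 4 for k in range(4)])
        np.testing.assert_allclose(q.kuramoto_order(phases), 0.0, atol=1e-12)

    def test_quarter_cycle_lag(self):
        base = np.zeros((1, 10))
        phases = np.vstack([base, base + np.pi / 2])
        np.testing.assert_allclose(q.kuramoto_order(phases), np.sqrt(2) / 2)


class TestDFA:
    def test_white_noise_is_half(self):
        est = [q.dfa(np.random.default_rng(s).standard_normal(2**16)).hurst
               for s in range(1, 21)]
        assert np.mean(est) == pytest.approx(0.5, abs=0.05)

    def test_linear_trend_supra_diffusive(self):
        """A deterministic ramp integrates to a quadratic profile whose
        residual scaling exceeds H = 1.5."""
        r = q.dfa(np.linspace(0.0, 1.0, 2**14))
        assert r.hurst >= 1.5

    def test_sum_of_white_envelopes_is_half(self):
        rng = np.random.default_rng(3)
        series = rng.standard_normal((19, 2**15)).sum(axis=0)
        assert q.dfa(series).hurst == pytest.approx(0.5, abs=0.06)

    def test_constant_series_flagged_degenerate(self):
        r = q.dfa(np.ones(2**14))
        assert np.isnan(r.hurst)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            q.dfa(np.zeros(32), n_min=16)

    def test_window_bounds_respect_band_resolution(self):
        """The smallest DFA window is one oscillation period, floored at the
        band's envelope-resolution scale (2 / bandwidth)."""
        n_min, n_max = _band_window_bounds(153600, 256.0, "delta")
        assert n_min == round(256.0 / np.sqrt(0.5 * 4.0))  # one delta cycle
        n_min_a, _ = _band_window_bounds(153600, 256.0, "alpha")
        assert n_min_a == round(2 * 256.0 / 5.0)  # alpha resolution floor
        assert n_max == 153600 // 4


class TestLRTC:
    def test_amplitude_dfa_tracks_envelope_hurst(self):
        """Generator-driven oracle: fGn envelopes with H = 0.7 yield an
        amplitude-DFA estimate within 0.1."""
        est = []
        for s in range(3):
            rec = q.generate_recording(
                q.EEGProfile(duration=600.0, seed=50 + s, envelope_hurst=0.7))
            est.append(q.lrtc_amplitude(make_segment(rec.samples), "alpha").hurst)
        assert np.mean(est) == pytest.approx(0.7, abs=0.1)

    def test_constant_amplitude_oscillation_degenerate(self):
        t = np.arange(256 * 600) / 256.0
        seg = make_segment(np.sin(2 * np.pi * 10 * t)[None, :])
        r = q.lrtc_amplitude(seg, "alpha")
        # near-degenerate envelope: flagged by poor log-log linearity
        assert np.isnan(r.hurst) or r.fit_r2 < 0.95

    def test_full_synchrony_phase_degenerate(self):
        t = np.arange(256 * 600) / 256.0
        x = np.tile(np.sin(2 * np.pi * 10 * t), (4, 1))
        r = q.lrtc_phase(make_segment(x), "alpha")
        assert np.isnan(r.hurst) or r.fit_r2 < 0.95


class TestPCTrajectory:
    def test_rank_one_data_single_component(self):
        rng = np.random.default_rng(0)
        source = rng.normal(size=256 * 60)
        mixing = rng.normal(size=(8, 1))
        seg = make_segment(mixing @ source[None, :])
        traj = q.pc_trajectory(seg)
        x = seg.samples - seg.samples.mean(axis=1, keepdims=True)
        vals = np.linalg.eigvalsh(x @ x.T / x.shape[1])[::-1]
        assert vals[0] / vals.sum() >= 0.99
        assert traj.shape == (2, seg.samples.shape[1])

    def test_two_sources_recovered_up_to_sign(self):
        rng = np.random.default_rng(1)
        s1, s2 = rng.normal(size=(2, 256 * 60))
        mix = np.array([[1.0, 0.1], [1.0, -0.1], [0.1, 1.0], [-0.1, 1.0]])
        seg = make_segment(mix @ np.vstack([s1, s2]) * 5.0)
        traj = q.pc_trajectory(seg)
        # the 2-D trajectory spans the source subspace
        r1 = max(abs(np.corrcoef(traj[0], s1)[0, 1]),
                 abs(np.corrcoef(traj[0], s2)[0, 1]))
        r2 = max(abs(np.corrcoef(traj[1], s1)[0, 1]),
                 abs(np.corrcoef(traj[1], s2)[0, 1]))
        assert r1 > 0.95 and r2 > 0.95

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        seg = make_segment(rng.normal(size=(6, 256 * 30)))
        a, b = q.pc_trajectory(seg), q.pc_trajectory(seg)
        np.testing.assert_array_equal(a, b)


class TestTransitionModel:
    def test_symmetric_joint_gives_zero_ep_and_curl(self):
        rng = np.random.default_rng(0)
        raw = rng.random((9, 9))
        sym = (raw + raw.T) / 2.0
        sym /= sym.sum()
        assert entropy_production_rate(sym) == pytest.approx(0.0, abs=1e-15)
        assert flux_curl(sym, 3) == pytest.approx(0.0, abs=1e-15)

    def test_two_state_closed_form(self):
        """F_AB = 0.4, F_BA = 0.1 -> EP = 0.3 ln 4 nats/step."""
        joint = np.zeros((9, 9))
        joint[0, 1], joint[1, 0] = 0.4, 0.1
        joint[0, 0] = 0.5
        assert entropy_production_rate(joint) == pytest.approx(0.3 * np.log(4.0))

    def test_deterministic_cycle_positive_curl(self):
        """A clockwise cycle through 4 grid states yields positive
        circulation under the clockwise-positive orientation convention and
        non-negative (regularized) entropy production."""
        # states on the lower-left plaquette of the 3x3 grid:
        # (0,0) -> (0,1) -> (1,1) -> (1,0) -> ... is clockwise in (x, y)
        cycle = [0, 1, 4, 3]
        seq = np.array(cycle * 200)
        joint = np.zeros((9, 9))
        for a, b in zip(seq[:-1], seq[1:]):
            joint[a, b] += 1
        joint /= joint.sum()
        # counterclockwise-positive convention: clockwise cycle -> negative,
        # its time reverse -> positive
        assert flux_curl(joint, 3) < 0
        assert flux_curl(joint.T, 3) > 0
        assert entropy_production_rate(joint) >= 0.0

    def test_time_reversal_antisymmetry(self):
        """Reversing the trajectory transposes the joint matrix: the curl
        changes sign and the entropy production is unchanged."""
        rng = np.random.default_rng(5)
        traj = np.cumsum(rng.normal(size=(2, 5000)), axis=1)
        fwd = transition_model(traj)
        rev = transition_model(traj[:, ::-1])
        assert rev.flux_curl == pytest.approx(-fwd.flux_curl, abs=1e-12)
        assert rev.entropy_production == pytest.approx(fwd.entropy_production,
                                                       rel=1e-9)
        assert fwd.entropy_production >= 0.0

    def test_joint_normalized_and_equal_occupancy(self):
        rng = np.random.default_rng(6)
        tm = transition_model(rng.normal(size=(2, 9000)))
        assert tm.joint_freq.sum() == pytest.approx(1.0)
        occupancy = tm.joint_freq.sum(axis=1)
        np.testing.assert_allclose(occupancy, 1.0 / 9.0, atol=0.01)

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            transition_model(np.zeros((2, 50)))
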