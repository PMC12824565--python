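"""Pairing, step detection, vetting, correction factors, E and S algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fretspt.fretscore import (
    CorrectionFactors,
    FretTrace,
    compute_fret_efficiency,
    compute_stoichiometry,
    concatenate_donor,
    detect_intensity_steps,
    estimate_correction_factors,
    fit_gaussian_histogram,
    pair_trajectories,
    vet_fret_trace,
)
from fretspt.simulate import simulate_trace_set
from fretspt.track import Trajectory


def make_traj(tid, frames, xy, channel="donor"):
    frames = np.asarray(frames)
    xy = np.asarray(xy, dtype=float)
    return Trajectory(tid, channel, frames, xy,
                      np.full(len(frames), 1000.0),
                      np.full(len(frames), 20.0))


def make_trace(i_dd, i_ad, xy=None, i_aa=None, f0=0):
    n = len(i_dd)
    if xy is None:
        xy = np.zeros((n, 2))
    return FretTrace(donor_traj_id=0, acceptor_traj_id=1,
                     frames=np.arange(f0, f0 + n),
                     I_DD=np.asarray(i_dd, dtype=float),
                     I_AD=np.asarray(i_ad, dtype=float),
                     xy_donor=np.asarray(xy, dtype=float),
                     xy_acceptor=np.asarray(xy, dtype=float),
                     I_AA=None if i_aa is None else np.asarray(i_aa, float))


class TestPairing:
    def test_comoving_pair_found(self, rng):
        base = np.cumsum(rng.normal(0, 0.05, (30, 2)), axis=0) + 5.0
        d = make_traj(0, range(30), base)
        a = make_traj(0, range(30), base + 0.05 / np.sqrt(2), "acceptor")
        pairs, d_only, a_only = pair_trajectories([d], [a])
        assert len(pairs) == 1 and not d_only and not a_only

    def test_distant_acceptor_unpaired(self, rng):
        base = np.cumsum(rng.normal(0, 0.05, (30, 2)), axis=0) + 5.0
        d = make_traj(0, range(30), base)
        a = make_traj(0, range(30), base + 0.4, "acceptor")
        pairs, d_only, a_only = pair_trajectories([d], [a])
        assert not pairs and len(d_only) == 1 and len(a_only) == 1

    def test_nearest_donor_wins(self, rng):
        base = np.cumsum(rng.normal(0, 0.03, (30, 2)), axis=0) + 5.0
        near = make_traj(0, range(30), base + 0.08 / np.sqrt(2))
        far = make_traj(1, range(30), base + 0.20 / np.sqrt(2))
        a = make_traj(0, range(30), base, "acceptor")
        pairs, d_only, _ = pair_trajectories([far, near], [a])
        assert len(pairs) == 1
        assert pairs[0][0].id == 0  # the 80 nm candidate
        # exhaustive check: it is indeed the closer one
        m_near = np.median(np.hypot(*(near.xy - a.xy).T))
        m_far = np.median(np.hypot(*(far.xy - a.xy).T))
        assert m_near < m_far


class TestStepDetection:
    def test_constant_noise_has_no_steps(self, rng):
        series = 1000 + rng.normal(0, 30, 200)
        assert detect_intensity_steps(series) == []

    def test_single_step_located(self, rng):
        series = np.where(np.arange(100) < 50, 1000.0, 0.0)
        series += rng.normal(0, 30, 100)
        steps = detect_intensity_steps(series)
        assert len(steps) == 1
        k, before, after = steps[0]
        assert abs(k - 50) <= 1
        assert abs(before - 1000) < 30 and abs(after) < 30

    def test_two_step_staircase(self, rng):
        series = np.concatenate([np.full(60, 1000.0), np.full(60, 500.0),
                                 np.full(60, 0.0)])
        series += rng.normal(0, 30, 180)
        steps = detect_intensity_steps(series)
        assert len(steps) == 2
        assert abs(steps[0][0] - 60) <= 1 and abs(steps[1][0] - 120) <= 1

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            detect_intensity_steps(np.ones(5))


class TestVetting:
    def test_pathway1_trace_accepted_with_correct_loss_frame(self):
        traces = simulate_trace_set(30, seed=50, snr=8.0)
        hits = 0
        for df, tr in traces:
            t = make_trace(df.I_DD, df.I_AD,
                           xy=df[["x_um", "y_um"]].to_numpy())
            t = vet_fret_trace(t)
            if t.accepted:
                hits += 1
                assert abs(t.acceptor_loss_frame - tr.acceptor_loss_frame) <= 1
        assert hits >= 27

    def test_two_acceptor_punctum_rejected_multistep(self):
        traces = simulate_trace_set(30, seed=51, multi_step=True, snr=8.0)
        rejected = 0
        for df, tr in traces:
            t = make_trace(df.I_DD, df.I_AD)
            t = vet_fret_trace(t)
            if not t.accepted and t.reason == "multi-step":
                rejected += 1
        assert rejected >= 28

    def test_flat_trace_rejected(self, rng):
        n = 80
        t = make_trace(3000 + rng.normal(0, 30, n), 150 + rng.normal(0, 30, n))
        t = vet_fret_trace(t)
        assert not t.accepted
        assert t.reason == "no acceptor loss"

    def test_leakage_level_acceptor_rejected(self, rng):
        # donor bleach seen through crosstalk is not a FRET pair
        n = 100
        i_dd = np.where(np.arange(n) < 60, 3000.0, 0.0) + rng.normal(0, 30, n)
        i_ad = np.where(np.arange(n) < 60, 150.0, 0.0) + rng.normal(0, 20, n)
        t = vet_fret_trace(make_trace(i_dd, i_ad))
        assert not t.accepted
        assert t.reason == "acceptor at leakage level"

    def test_simultaneous_loss_accepted_as_pathway2_signature(self, rng):
        traces = simulate_trace_set(20, seed=52, snr=8.0, p_internalize=1.0)
        accepted = 0
        for df, tr in traces:
            t = make_trace(df.I_DD, df.I_AD)
            t = vet_fret_trace(t)
            accepted += t.accepted
        assert accepted >= 18


class TestConcatenation:
    def _accepted_trace(self, loss=40, n=60):
        i_dd = np.where(np.arange(n) < loss, 300.0, 0.0)
        i_ad = np.where(np.arange(n) < loss, 2900.0, 0.0)
        rng = np.random.default_rng(0)
        xy = np.cumsum(rng.normal(0, 0.03, (n, 2)), axis=0) + 5.0
        xy[loss:] = np.nan
        t = make_trace(i_dd + rng.normal(0, 30, n), i_ad + rng.normal(0, 30, n),
                       xy=xy)
        t.accepted = True
        t.acceptor_loss_frame = loss
        return t, xy

    def test_near_continuation_concatenated(self):
        t, xy = self._accepted_trace()
        last = xy[39]
        cont = make_traj(7, range(41, 80),
                         np.tile(last + 0.07, (39, 1)))
        out = concatenate_donor(t, [cont])
        assert out.concatenated_traj_id == 7
        assert out.frames[-1] == 79
        assert np.isfinite(out.xy_donor[45]).all()

    def test_no_candidate_within_radius(self):
        t, xy = self._accepted_trace()
        cont = make_traj(7, range(41, 80), np.tile(xy[39] + 0.3, (39, 1)))
        out = concatenate_donor(t, [cont])
        assert out.concatenated_traj_id is None

    def test_nearest_of_two_chosen(self):
        t, xy = self._accepted_trace()
        last = xy[39]
        near = make_traj(8, range(41, 80), np.tile(last + 0.08 / np.sqrt(2), (39, 1)))
        far = make_traj(9, range(41, 80), np.tile(last + 0.20 / np.sqrt(2), (39, 1)))
        out = concatenate_donor(t, [far, near])
        assert out.concatenated_traj_id == 8


class TestCorrectionFactors:
    def _donor_only(self, alpha, n=60, rng=None):
        i_dd = np.full(n, 3000.0)
        i_ad = alpha * i_dd
        if rng is not None:
            i_dd = i_dd + rng.normal(0, 20, n)
            i_ad = i_ad + rng.normal(0, 20, n)
        return make_trace(i_dd, i_ad)

    def test_exact_ratio_recovered(self):
        traces = [self._donor_only(0.1) for _ in range(6)]
        f = estimate_correction_factors(traces, [], [])
        assert f.alpha == pytest.approx(0.1, abs=1e-12)

    def test_zero_factors(self, rng):
        traces = [self._donor_only(0.0, rng=rng) for _ in range(10)]
        f = estimate_correction_factors(traces, [], [])
        assert abs(f.alpha) < 0.01
        assert f.delta == 0.0

    def test_gamma_recovered_from_bleach_steps(self, rng):
        gamma_true, q, e = 1.2, 3000.0, 0.9
        fret = []
        for k in range(50):
            n, loss = 80, 40
            i_dd = np.where(np.arange(n) < loss, (1 - e) * q, q)
            i_ad = np.where(np.arange(n) < loss, gamma_true * e * q, 0.0)
            t = make_trace(i_dd + rng.normal(0, 30, n),
                           i_ad + rng.normal(0, 30, n))
            t.accepted = True
            t.acceptor_loss_frame = loss
            fret.append(t)
        donors = [self._donor_only(0.0, rng=rng) for _ in range(6)]
        f = estimate_correction_factors(donors, [], fret)
        assert abs(f.gamma - gamma_true) / gamma_true < 0.10
        assert f.n_gamma == 50

    def test_alpha_delta_grid_recovery(self, rng):
        # across the {0, 0.05, 0.1} grid both factors come back within 0.01
        for alpha in (0.0, 0.05, 0.1):
            donors = [self._donor_only(alpha, rng=rng) for _ in range(20)]
            for delta in (0.0, 0.05, 0.1):
                acceptors = []
                for _ in range(20):
                    i_aa = 3000.0 + rng.normal(0, 20, 60)
                    t = make_trace(np.zeros(60), delta * 3000.0
                                   + rng.normal(0, 20, 60), i_aa=i_aa)
                    acceptors.append(t)
                f = estimate_correction_factors(donors, acceptors, [])
                assert abs(f.alpha - alpha) < 0.01
                assert abs(f.delta - delta) < 0.01

    def test_insufficient_traces_raise(self):
        with pytest.raises(ValueError, match="donor-only"):
            estimate_correction_factors([self._donor_only(0.1)], [], [])


class TestEfficiencyAlgebra:
    def test_no_transfer_limit(self):
        t = make_trace([500.0] * 12, [0.0] * 12)
        e = compute_fret_efficiency(t, CorrectionFactors(gamma=1.0))
        assert np.allclose(e, 0.0)

    def test_symmetric_case(self):
        t = make_trace([400.0] * 12, [400.0] * 12)
        e = compute_fret_efficiency(t, CorrectionFactors(gamma=1.0))
        assert np.allclose(e, 0.5)

    def test_worked_example(self):
        t = make_trace([300.0], [700.0], i_aa=[500.0])
        f = CorrectionFactors(alpha=0.05, delta=0.1, gamma=1.2)
        e = compute_fret_efficiency(t, f)
        # F_corr = 700 - 15 - 50 = 635; E = 635 / (360 + 635)
        assert e[0] == pytest.approx(635.0 / 995.0, rel=1e-12)

    def test_matches_hand_algebra_on_random_tuples(self, rng):
        for _ in range(20):
            i_dd = rng.uniform(100, 2000)
            i_ad = rng.uniform(100, 4000)
            i_aa = rng.uniform(100, 3000)
            alpha, delta = rng.uniform(0, 0.15, 2)
            gamma = rng.uniform(0.5, 2.0)
            t = make_trace([i_dd], [i_ad], i_aa=[i_aa])
            e = compute_fret_efficiency(
                t, CorrectionFactors(alpha=alpha, delta=delta, gamma=gamma))
            fc = i_ad - alpha * i_dd - delta * i_aa
            expected = fc / (gamma * i_dd + fc) if gamma * i_dd + fc > 0 \
                else np.nan
            if np.isnan(expected):
                assert np.isnan(e[0])
            else:
                assert e[0] == pytest.approx(expected, rel=1e-12)

    def test_invalid_denominator_flagged_nan(self):
        t = make_trace([10.0], [-500.0])
        e = compute_fret_efficiency(t, CorrectionFactors(gamma=1.0))
        assert np.isnan(e[0])

    @given(st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_gain_invariance(self, scale):
        base_dd = np.array([300.0, 500.0, 800.0])
        base_ad = np.array([900.0, 1500.0, 100.0])
        f = CorrectionFactors(alpha=0.05, delta=0.0, gamma=1.2)
        e1 = compute_fret_efficiency(make_trace(base_dd, base_ad), f)
        e2 = compute_fret_efficiency(
            make_trace(base_dd * scale, base_ad * scale), f)
        assert np.allclose(e1, e2, rtol=1e-9)


class TestStoichiometry:
    def test_limits_and_example(self):
        f = CorrectionFactors(gamma=1.0, beta=1.0)
        t = make_trace([500.0], [500.0], i_aa=[0.0])
        assert compute_stoichiometry(t, f)[0] == pytest.approx(1.0)
        t = make_trace([500.0], [500.0], i_aa=[1000.0])
        # F_corr = 500, gamma I_DD = 500 -> S = 1000/2000
        assert compute_stoichiometry(t, f)[0] == pytest.approx(0.5)

    def test_acceptor_only_limit(self):
        f = CorrectionFactors(gamma=1.0, beta=1.0)
        t = make_trace([0.0], [0.0], i_aa=[1000.0])
        assert compute_stoichiometry(t, f)[0] == pytest.approx(0.0)

    def test_missing_alex_data_raises(self):
        t = make_trace([500.0], [500.0])
        with pytest.raises(ValueError, match="ALEX"):
            compute_stoichiometry(t, CorrectionFactors())


class TestGaussianHistogram:
    def test_known_distribution_recovered(self, rng):
        values = rng.normal(0.9, 0.05, 500)
        fit = fit_gaussian_histogram(values, bins=30)
        assert abs(fit.mean - 0.9) < 0.01
        assert abs(fit.sd - 0.05) < 0.015
        assert not fit.poor_fit

    def test_degenerate_sample_raises(self):
        with pytest.raises(ValueError):
            fit_gaussian_histogram(np.full(100, 0.5))

    def test_too_few_values_raise(self, rng):
        with pytest.raises(ValueError):
            fit_gaussian_histogram(rng.normal(0, 1, 10))

    def test_bimodal_flagged(self, rng):
        values = np.concatenate([rng.normal(0.2, 0.02, 300),
                                 rng.normal(0.9, 0.02, 300)])
        fit = fit_gaussian_histogram(values, bins=40)
        assert fit.poor_fit
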