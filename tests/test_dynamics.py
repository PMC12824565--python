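"""MSD, diffusion fits, motion classification, jump angles, lifetimes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fretspt.dynamics import (
    analyze_segment,
    classify_motion,
    compare_groups,
    compute_jump_angles,
    compute_msd,
    fit_lifetime,
    fit_msd,
    jump_angle_histogram,
)

DT = 0.04


def brute_force_msd(frames, xy, dt):
    """All-pairs reference implementation (endpoints present)."""
    frames = np.asarray(frames)
    xy = np.asarray(xy, dtype=float)
    span = frames[-1] - frames[0]
    out = {}
    for n in range(1, span + 1):
        sq = []
        for i, fi in enumerate(frames):
            j = np.nonzero(frames == fi + n)[0]
            if len(j):
                d = xy[j[0]] - xy[i]
                sq.append(d[0] ** 2 + d[1] ** 2)
        if sq:
            out[n] = (float(np.mean(sq)), len(sq))
    lags = sorted(out)
    return (np.array(lags) * dt, np.array([out[k][0] for k in lags]),
            np.array([out[k][1] for k in lags]))


def free_walk(rng, n, D, dt=DT, sigma_loc=0.0):
    steps = rng.normal(0, np.sqrt(2 * D * dt), (n - 1, 2))
    xy = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
    if sigma_loc:
        xy = xy + rng.normal(0, sigma_loc, (n, 2))
    return xy


def confined_walk(rng, n, D, R, dt=DT, sigma_loc=0.02):
    pos = np.zeros((n, 2))
    p = np.zeros(2)
    for i in range(1, n):
        p = p + rng.normal(0, np.sqrt(2 * D * dt), 2)
        r = np.hypot(*p)
        if r > R:
            p *= (2 * R - r) / r
        pos[i] = p
    return pos + rng.normal(0, sigma_loc, (n, 2))


class TestComputeMsd:
    def test_uniform_motion_hand_example(self):
        # (0,0), (1,0), (2,0), (3,0) at 1 s -> MSD 1, 4, 9
        xy = np.array([[0.0, 0], [1, 0], [2, 0], [3, 0], [4, 0]])
        lags, msd, counts = compute_msd(np.arange(5), xy, 1.0)
        assert np.allclose(msd, [1.0, 4.0, 9.0, 16.0])
        assert np.array_equal(counts, [4, 3, 2, 1])

    def test_stationary_is_zero(self):
        xy = np.tile([2.0, 3.0], (10, 1))
        lags, msd, counts = compute_msd(np.arange(10), xy, DT)
        assert np.allclose(msd, 0.0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            compute_msd(np.arange(4), np.zeros((4, 2)), DT)

    def test_matches_brute_force_with_gaps(self, rng):
        # exact equality against the all-pairs oracle on gappy tracks
        for rep in range(100):
            n = int(rng.integers(6, 25))
            frames = np.sort(rng.choice(np.arange(40), n, replace=False))
            xy = rng.normal(0, 1, (n, 2))
            lags, msd, counts = compute_msd(frames, xy, DT)
            blags, bmsd, bcounts = brute_force_msd(frames, xy, DT)
            assert np.allclose(lags, blags)
            assert np.allclose(msd, bmsd)
            assert np.array_equal(counts, bcounts)

    def test_ensemble_mean_is_4dt(self, rng):
        D = 0.1
        msds = []
        for _ in range(3000):
            xy = free_walk(rng, 12, D)
            lags, msd, counts = compute_msd(np.arange(12), xy, DT, max_lag=5)
            msds.append(msd)
        mean = np.mean(msds, axis=0)
        se = np.std(msds, axis=0) / np.sqrt(len(msds))
        expected = 4 * D * (np.arange(1, 6) * DT)
        assert np.all(np.abs(mean - expected) < 3 * se)


class TestFitMsd:
    def test_noiseless_closed_form_exact(self):
        # MSD(n) = 0.4 n dt + 0.0016 -> D = 0.1, sigma_dyn = 20 nm, to 6 sig
        lags_s = np.arange(1, 5) * DT
        msd = 4 * 0.1 * lags_s + 4 * (0.02) ** 2
        fit = fit_msd(lags_s, msd, np.array([10, 9, 8, 7]), model="free")
        assert fit["D"] == pytest.approx(0.1, rel=1e-6)
        assert fit["sigma_dyn_nm"] == pytest.approx(20.0, rel=1e-6)

    def test_negative_intercept_flagged_not_imaginary(self):
        lags_s = np.arange(1, 5) * DT
        msd = 4 * 0.1 * lags_s - 0.001
        fit = fit_msd(lags_s, msd, np.ones(4), model="free")
        assert fit["sigma_dyn_nm"] is None
        assert fit["D"] == pytest.approx(0.1, rel=1e-6)

    def test_singular_input_raises(self):
        with pytest.raises(ValueError):
            fit_msd(np.array([DT]), np.array([0.1]), np.array([1]),
                    model="free")

    def test_median_D_recovery_on_short_segments(self, rng):
        D = 0.1
        Ds = []
        for _ in range(500):
            xy = free_walk(rng, 20, D, sigma_loc=0.02)
            lags, msd, counts = compute_msd(np.arange(20), xy, DT, max_lag=10)
            Ds.append(fit_msd(lags, msd, counts, model="free")["D"])
        assert abs(np.median(Ds) - D) / D < 0.10

    def test_confined_model_fits_confined_motion_better(self, rng):
        wins = 0
        for _ in range(40):
            xy = confined_walk(rng, 60, 0.1, 0.2)
            lags, msd, counts = compute_msd(np.arange(60), xy, DT, max_lag=30)
            free = fit_msd(lags, msd, counts, model="free")
            pred = free["slope"] * lags + free["intercept"]
            free_rss = float(((msd - pred) ** 2).sum())
            conf = fit_msd(lags, msd, counts, model="confined")
            wins += conf["rss"] < free_rss
        assert wins >= 36


class TestClassifyMotion:
    def test_exactly_linear_is_free(self):
        lags_s = np.arange(1, 11) * DT
        msd = 4 * 0.1 * lags_s + 0.001
        cls, dev = classify_motion(lags_s, msd, np.arange(20, 10, -1),
                                   n_positions=20)
        assert cls == "free"
        assert abs(dev) < 1e-9

    def test_false_confinement_rate_bounded(self, rng):
        calls = []
        for _ in range(400):
            r = analyze_segment(0, np.arange(20), free_walk(rng, 20, 0.066,
                                                            sigma_loc=0.02),
                                DT)
            calls.append(r.motion_class == "confined")
        assert np.mean(calls) <= 0.15

    def test_strong_confinement_detected(self, rng):
        calls = []
        for _ in range(200):
            r = analyze_segment(0, np.arange(60),
                                confined_walk(rng, 60, 0.066, 0.2), DT)
            calls.append(r.motion_class == "confined")
        assert np.mean(calls) >= 0.85


class TestJumpAngles:
    def test_collinear_forward_is_zero(self):
        xy = np.column_stack([np.arange(10) * 0.1, np.zeros(10)])
        ang = compute_jump_angles(np.arange(10), xy)
        assert np.allclose(ang, 0.0)

    def test_reversals_are_180(self):
        x = np.array([0.0, 0.1, 0.0, 0.1, 0.0, 0.1])
        xy = np.column_stack([x, np.zeros(6)])
        ang = compute_jump_angles(np.arange(6), xy)
        assert np.allclose(ang, 180.0)

    def test_gap_spanning_triples_excluded(self):
        frames = np.array([0, 1, 2, 4, 5, 6])
        xy = np.column_stack([np.arange(6) * 0.1, np.zeros(6)])
        ang = compute_jump_angles(frames, xy)
        # triples (0,1,2) and (4,5,6) only
        assert len(ang) == 2

    def test_zero_length_step_skipped(self):
        xy = np.array([[0.0, 0], [0.0, 0], [1.0, 0], [2.0, 0]])
        ang = compute_jump_angles(np.arange(4), xy)
        assert len(ang) == 1  # only the (1,2,3) triple has nonzero steps

    def test_free_diffusion_angles_uniform(self, rng):
        xy = free_walk(rng, 10002, 0.1)
        ang = compute_jump_angles(np.arange(10002), xy)
        assert len(ang) == 10000
        counts, _ = np.histogram(ang, bins=18, range=(0, 180))
        res = stats.chisquare(counts)
        assert res.pvalue > 0.01

    def test_histogram_normalized(self, rng):
        ang = rng.uniform(0, 180, 500)
        edges, freq = jump_angle_histogram(ang)
        assert freq.sum() == pytest.approx(1.0)
        assert len(freq) == 18


class TestLifetime:
    def test_known_exponential_recovered(self, rng):
        d = rng.exponential(1.0, 5000)
        d = np.floor(d / DT) * DT
        d = d[d > 0]
        fit = fit_lifetime(d, DT)
        assert abs(fit.tau_s - 1.0) / 1.0 < 0.05

    def test_discretization_bias_below_one_frame(self, rng):
        # tau = 10 frame intervals: frame rounding must not shift the
        # estimate by more than one frame
        tau = 10 * DT
        d = np.floor(rng.exponential(tau, 5000) / DT) * DT
        d = d[d > 0]
        fit = fit_lifetime(d, DT, exclude_first_bin=False)
        assert abs(fit.tau_s - tau) < DT

    def test_long_durations_excluded(self, rng):
        d = np.concatenate([rng.exponential(0.5, 3000) + 0.01,
                            np.full(50, 12.0)])
        fit = fit_lifetime(d, DT)
        assert fit.n_excluded_long == 50
        assert fit.n_traces == 3000

    def test_degenerate_histogram_raises(self):
        with pytest.raises(ValueError):
            fit_lifetime(np.full(100, 0.5), DT)

    def test_too_few_durations_raise(self, rng):
        with pytest.raises(ValueError):
            fit_lifetime(rng.exponential(1.0, 10), DT)

    def test_survival_mode_handles_truncated_small_samples(self, rng):
        taus = []
        for _ in range(50):
            d = rng.exponential(1.13, 2000)
            d = d[d >= 0.8][:120]
            d = np.floor(d / DT) * DT
            taus.append(fit_lifetime(d, DT, bin_frames="auto",
                                     method="survival").tau_s)
        assert abs(np.mean(taus) - 1.13) < 0.08


class TestCompareGroups:
    def test_identical_samples_not_significant(self):
        x = np.linspace(0.01, 0.2, 50)
        res = compare_groups(x, x)
        assert res.p_value > 0.99
        assert res.significance == "n.s."

    def test_type_one_error_calibrated(self, rng):
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.normal(0.1, 0.05, 100)
            b = rng.normal(0.1, 0.05, 100)
            if compare_groups(a, b).p_value < 0.05:
                hits += 1
        assert abs(hits / n_rep - 0.05) <= 0.02

    def test_power_on_reported_populations(self, rng):
        # distributions mimicking the dimer/monomer D populations
        a = rng.normal(0.066, 0.044, 200)
        b = rng.normal(0.109, 0.068, 200)
        res = compare_groups(a, b)
        assert res.p_value < 0.001
        assert res.significance == "***"

    def test_small_sample_raises(self):
        with pytest.raises(ValueError):
            compare_groups([0.1] * 3, [0.2] * 10)
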