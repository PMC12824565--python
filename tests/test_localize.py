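"""Spot detection, sub-pixel localization accuracy, precision, registration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fretspt.localize import (
    ChannelTransform,
    DetectionParams,
    detect_spots,
    estimate_precision,
    localize_movie,
    register_channels,
)
from fretspt.simulate import (
    SimulationConfig,
    simulate_bead_movie,
    simulate_movie,
    _stamp_spot,
)

PX = 159.0  # nm


def synthetic_frame(positions_px, photons, shape=(64, 64), bg=10.0,
                    baseline=100.0, gain=2.0, sigma_px=150.0 / PX, seed=0):
    """Render spots at given pixel positions onto a Poisson background."""
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=np.int64)
    for (x, y), n in zip(positions_px, photons):
        _stamp_spot(img, x, y, n, sigma_px, rng, 6)
    img = img + rng.poisson(bg, size=shape)
    return np.clip(baseline + gain * img, 0, 65535).astype(np.uint16)


PARAMS = DetectionParams(psf_sigma_nm=150.0)


class TestDetectSpots:
    def test_blank_frame_yields_nothing(self):
        frame = synthetic_frame([], [], seed=1)
        df = detect_spots(frame, "donor", PARAMS, PX, 2.0, 100.0)
        assert len(df) == 0

    def test_single_emitter_subpixel_accuracy(self):
        x, y = 30.3, 25.7  # px
        frame = synthetic_frame([(x, y)], [3000], seed=2)
        df = detect_spots(frame, "donor", PARAMS, PX, 2.0, 100.0)
        assert len(df) == 1
        assert abs(df.x_um[0] * 1000 / PX - x) < 0.1
        assert abs(df.y_um[0] * 1000 / PX - y) < 0.1
        assert abs(df.photons[0] - 3000) / 3000 < 0.15

    def test_two_emitters_both_found(self):
        pos = [(20.2, 20.6), (30.2, 20.6)]  # 10 px apart
        frame = synthetic_frame(pos, [3000, 3000], seed=3)
        df = detect_spots(frame, "donor", PARAMS, PX, 2.0, 100.0)
        assert len(df) == 2
        got = np.sort(df.x_um.to_numpy() * 1000 / PX)
        assert np.all(np.abs(got - np.array([20.2, 30.2])) < 0.5)
        assert np.all(np.abs(df.y_um.to_numpy() * 1000 / PX - 20.6) < 0.5)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros(10), "donor", PARAMS, PX)
        with pytest.raises(ValueError):
            detect_spots(np.zeros((4, 4)), "donor", PARAMS, PX)

    def test_localization_bias_below_5nm(self):
        # spots at random sub-pixel phases: mean displacement stays < 5 nm
        rng = np.random.default_rng(4)
        errs = []
        for k in range(150):
            x = 30.0 + rng.uniform(-0.5, 0.5)
            y = 28.0 + rng.uniform(-0.5, 0.5)
            frame = synthetic_frame([(x, y)], [3000], seed=100 + k)
            df = detect_spots(frame, "donor", PARAMS, PX, 2.0, 100.0)
            if len(df) == 1:
                errs.append([df.x_um[0] * 1000 - x * PX,
                             df.y_um[0] * 1000 - y * PX])
        errs = np.array(errs)
        assert len(errs) > 140
        assert np.all(np.abs(errs.mean(axis=0)) < 5.0)

    def test_recall_and_precision_on_movie(self):
        # simulated sparse movie: >= 95% of visible emitters recovered and
        # >= 95% of detections match a true emitter within 1 px
        c = SimulationConfig(field_size=(128, 128), n_frames=15,
                             emitter_density=0.05, dimer_fraction=0.5, seed=8)
        movie, truth = simulate_movie(c)
        locs = localize_movie(movie)
        donor = locs[locs.channel == "donor"]
        px_um = PX / 1000.0
        margin = 5 * px_um
        h_um, w_um = c.field_um
        hits = misses = false = 0
        for t in range(c.n_frames):
            vis = (np.isfinite(truth.xy[:, t, 0])
                   & ~truth.donor_bleached[:, t]
                   & (truth.xy[:, t, 0] > margin)
                   & (truth.xy[:, t, 0] < w_um - margin)
                   & (truth.xy[:, t, 1] > margin)
                   & (truth.xy[:, t, 1] < h_um - margin))
            txy = truth.xy[vis, t]
            dxy = donor[donor.frame == t][["x_um", "y_um"]].to_numpy()
            if not len(txy):
                continue
            for p in txy:
                d = np.hypot(*(dxy - p).T) if len(dxy) else np.array([9.9])
                if d.min() < px_um:
                    hits += 1
                else:
                    misses += 1
            for q in dxy:
                d = np.hypot(*(truth.xy[np.isfinite(truth.xy[:, t, 0]), t]
                               - q).T)
                if d.min() >= px_um:
                    false += 1
        recall = hits / (hits + misses)
        n_det = len(donor)
        precision = 1.0 - false / n_det
        assert recall >= 0.95
        assert precision >= 0.95


class TestPrecision:
    def test_monotone_in_photons_and_background(self):
        p1 = estimate_precision(500, 10, 150, PX)
        p2 = estimate_precision(5000, 10, 150, PX)
        p3 = estimate_precision(500, 40, 150, PX)
        assert p2 < p1 < p3
        # asymptotic limit
        assert estimate_precision(1e12, 10, 150, PX) < 0.01

    def test_zero_photons_raise(self):
        with pytest.raises(ValueError):
            estimate_precision(0, 10, 150, PX)

    def test_estimate_tracks_true_scatter(self):
        # RMS localization error within a factor 1.3 of the estimate
        rng = np.random.default_rng(9)
        errs, est = [], []
        for k in range(200):
            x = 30.0 + rng.uniform(-0.5, 0.5)
            y = 28.0 + rng.uniform(-0.5, 0.5)
            frame = synthetic_frame([(x, y)], [1000], seed=300 + k)
            df = detect_spots(frame, "donor", PARAMS, PX, 2.0, 100.0)
            if len(df) == 1:
                errs.append([df.x_um[0] * 1000 - x * PX,
                             df.y_um[0] * 1000 - y * PX])
                est.append(df.precision_nm[0])
        errs = np.array(errs)
        rms = math.sqrt(np.mean(errs[:, 0] ** 2 + errs[:, 1] ** 2) / 2.0)
        ratio = rms / np.mean(est)
        assert 1 / 1.3 < ratio < 1.3


class TestRegistration:
    def test_identity_channels(self):
        c = SimulationConfig(field_size=(128, 128), seed=13)
        beads = simulate_bead_movie(c, n_beads=10, n_frames=10)
        tr = register_channels(beads)
        assert tr.n_fiducials >= 5
        assert tr.rms_residual_nm < 10.0
        assert np.allclose(tr.matrix, np.eye(2), atol=5e-3)
        assert np.all(np.abs(tr.offset) < 0.01)

    def test_known_shift_recovered(self):
        dx, dy = 0.16, -0.08  # um
        c = SimulationConfig(field_size=(128, 128), seed=14,
                             acceptor_misalignment=(1, 0, dx, 0, 1, dy))
        beads = simulate_bead_movie(c, n_beads=10, n_frames=10)
        tr = register_channels(beads)
        # transform maps acceptor coords back onto donor coords
        inv_offset = -np.linalg.inv(tr.matrix) @ tr.offset
        assert np.allclose(-tr.offset, [dx, dy], atol=0.005) or \
            np.allclose(inv_offset, [-dx, -dy], atol=0.005)
        probe = np.array([5.0, 5.0])
        mapped = tr.apply(probe + [dx, dy])
        assert np.allclose(mapped, probe, atol=0.005)

    def test_rotation_and_scaling_residual(self):
        th = math.radians(0.5)
        s = 1.001
        mis = (s * math.cos(th), -s * math.sin(th), 0.05,
               s * math.sin(th), s * math.cos(th), -0.02)
        c = SimulationConfig(field_size=(128, 128), seed=15,
                             acceptor_misalignment=mis)
        beads = simulate_bead_movie(c, n_beads=12, n_frames=10)
        tr = register_channels(beads)
        assert tr.rms_residual_nm < 10.0
        # forward-apply the known misalignment, then the fitted inverse map
        pts = np.random.default_rng(0).uniform(4, 16, size=(50, 2))
        M = np.array(mis).reshape(2, 3)
        acc = pts @ M[:, :2].T + M[:, 2]
        back = tr.apply(acc)
        assert np.all(np.hypot(*(back - pts).T) * 1000 < 10.0)

    def test_too_few_beads_raise(self):
        c = SimulationConfig(field_size=(96, 96), seed=16)
        beads = simulate_bead_movie(c, n_beads=2, n_frames=5)
        with pytest.raises(ValueError):
            register_channels(beads)


class TestTransform:
    @given(st.floats(-0.3, 0.3), st.floats(-0.3, 0.3),
           st.floats(-0.02, 0.02), st.floats(0.98, 1.02))
    @settings(max_examples=30, deadline=None)
    def test_inverse_roundtrip(self, tx, ty, rot, scale):
        m = scale * np.array([[math.cos(rot), -math.sin(rot)],
                              [math.sin(rot), math.cos(rot)]])
        tr = ChannelTransform(matrix=m, offset=np.array([tx, ty]))
        pts = np.array([[1.0, 2.0], [10.0, 3.5], [7.7, 19.2]])
        back = tr.inverse().apply(tr.apply(pts))
        assert np.all(np.abs(back - pts) < 1e-9)

    def test_text_roundtrip(self, tmp_path):
        tr = ChannelTransform(matrix=np.array([[1.001, 0.002], [-0.002, 0.999]]),
                              offset=np.array([0.05, -0.03]))
        p = tmp_path / "t.txt"
        tr.to_text(p)
        tr2 = ChannelTransform.from_text(p)
        assert np.allclose(tr2.matrix, tr.matrix)
        assert np.allclose(tr2.offset, tr.offset)
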