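"""Spot detection, sub-pixel Gaussian localization and channel registration.

Detection is a difference-of-Gaussians band-pass followed by local-maximum
candidate picking against a robust (median + k*MAD) threshold; each candidate
is refined by least-squares fitting of a pixel-integrated symmetric 2-D
Gaussian plus constant background.  All candidates of a frame are fit in one
batched, damped Gauss-Newton solve, which is what makes whole-movie
localization tractable in pure numpy.

The PSF radius is "data driven": the width is fit freely for the first
``n_sigma_calibration`` accepted spots, then frozen at their median for the
remaining frames, stabilizing fits of dim (FRET-quenched) donors.

Channel registration maps acceptor-channel coordinates into donor-channel
coordinates via a full 2-D affine transform fit to fiducial beads matched by
mutual nearest neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import erf

from .simulate import Movie

__all__ = [
    "DetectionParams",
    "ChannelTransform",
    "detect_spots",
    "localize_movie",
    "estimate_precision",
    "register_channels",
]

LOC_COLUMNS = ["frame", "channel", "x_um", "y_um", "photons", "bg",
               "sigma_nm", "precision_nm"]


@dataclass
class DetectionParams:
    """Knobs of the detection + fitting stage.

    threshold_k is the significance threshold in robust sigmas of the
    band-passed frame; 4 is the package default.  ``overlap_mode`` chooses what happens when two
    candidates fall within one fit window: ``"drop"`` keeps the brighter one,
    ``"joint"`` fits both as a two-component mixture.
    """

    threshold_k: float = 4.0
    fit_window: int = 9              # px, odd
    psf_sigma_nm: float = 150.0      # initial guess for the fit
    n_sigma_calibration: int = 200   # free-sigma fits before freezing the median
    overlap_mode: str = "drop"       # "drop" | "joint"
    min_separation_px: Optional[float] = None  # default: 2.5 * psf sigma
    residual_pass: bool = True       # re-detect on the model-subtracted image
    max_iter: int = 25
    min_photons: float = 30.0
    min_significance: float = 5.0    # A / sigma_A gate on the fitted amplitude

    def __post_init__(self) -> None:
        if self.fit_window % 2 == 0 or self.fit_window < 5:
            raise ValueError("fit_window must be odd and >= 5")
        if self.overlap_mode not in ("drop", "joint"):
            raise ValueError("overlap_mode must be 'drop' or 'joint'")


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------

def _bandpass(img: np.ndarray, sigma_px: float) -> np.ndarray:
    g1 = ndimage.gaussian_filter(img, sigma_px)
    g2 = ndimage.gaussian_filter(img, 2.5 * sigma_px)
    return g1 - g2

def _find_candidates(img_ph: np.ndarray, sigma_px: float, k: float,
                     window: int) -> np.ndarray:
    """(row, col) integer candidate positions from the band-passed image."""
    f = _bandpass(img_ph, sigma_px)
    med = np.median(f)
    mad = np.median(np.abs(f - med))
    thr = med + k * 1.4826 * mad
    mx = ndimage.maximum_filter(f, size=3, mode="nearest")
    peaks = (f >= mx) & (f > thr)
    half = window // 2
    peaks[:half, :] = peaks[-half:, :] = False
    peaks[:, :half] = peaks[:, -half:] = False
    rc = np.argwhere(peaks)
    if len(rc) > 1:
        order = np.lexsort((rc[:, 1], rc[:, 0]))
        rc = rc[order]
    return rc


def _resolve_overlaps(rc: np.ndarray, img_ph: np.ndarray, min_sep: float,
                      mode: str) -> Tuple[np.ndarray, list]:
    """Split candidates into isolated ones and unresolvable pairs.

    Pairs closer than ``min_sep`` pixels (of order two PSF widths) cannot be
    fit as independent single spots: in "drop" mode the dimmer member is
    discarded, in "joint" mode the pair is returned for mixture fitting.
    Candidates farther apart than that are fit separately even when their
    windows overlap — the constant-background term absorbs the neighbour's
    tail, which costs far less than dropping a genuine emitter.
    """
    if len(rc) < 2:
        return rc, []
    keep = np.ones(len(rc), dtype=bool)
    pairs = []
    d2 = ((rc[:, None, :] - rc[None, :, :]) ** 2).sum(-1)
    close = np.triu(d2 < min_sep ** 2, k=1)
    for i, j in np.argwhere(close):
        if not (keep[i] and keep[j]):
            continue
        if mode == "drop":
            bi = img_ph[rc[i, 0], rc[i, 1]]
            bj = img_ph[rc[j, 0], rc[j, 1]]
            keep[j if bi >= bj else i] = False
        else:
            pairs.append((rc[i], rc[j]))
            keep[i] = keep[j] = False
    return rc[keep], pairs


# ---------------------------------------------------------------------------
# batched pixel-integrated Gaussian fit
# ---------------------------------------------------------------------------

def _erf_profile(centers: np.ndarray, coord: np.ndarray, sigma: np.ndarray):
    """Pixel-integrated 1-D Gaussian profile and its d/dcoord, d/dsigma.

    centers: (w,) pixel centre offsets; coord: (n,1); sigma: (n,1).
    Returns (n, w) arrays: weight, dw/dcoord, dw/dsigma.
    """
    lo = centers - 0.5
    hi = centers + 0.5
    s2 = sigma * math.sqrt(2.0)
    z_lo = (lo - coord) / s2
    z_hi = (hi - coord) / s2
    w = 0.5 * (erf(z_hi) - erf(z_lo))
    inv = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    g_lo = np.exp(-((lo - coord) ** 2) / (2 * sigma ** 2))
    g_hi = np.exp(-((hi - coord) ** 2) / (2 * sigma ** 2))
    dw_dc = inv * (g_lo - g_hi)
    dw_ds = inv / sigma * ((lo - coord) * g_lo - (hi - coord) * g_hi)
    return w, dw_dc, dw_ds


def _pixel_weights_centered(coord: float, sigma_px: float, lo: int,
                            hi: int) -> np.ndarray:
    """Pixel-integrated unit Gaussian at ``coord`` (pixel-centre convention)."""
    edges = np.arange(lo, hi + 1, dtype=float) - 0.5
    z = (edges - coord) / (sigma_px * math.sqrt(2.0))
    return np.diff(0.5 * (1.0 + erf(z)))


def fit_gaussian_spots(windows: np.ndarray, sigma0_px: float,
                       fit_sigma: bool = True, max_iter: int = 25,
                       tol: float = 1e-4):
    """Batched damped Gauss-Newton fit of N windows, each (w, w) photons.

    Model: b + A * wx(x0, sigma) (x) wy(y0, sigma), with wx/wy the
    pixel-integrated Gaussian so A is directly the integrated photon count.

    Returns dict of arrays (x0, y0, A, b, sigma, converged), coordinates in
    pixels relative to the window's top-left pixel centre.
    """
    n, w, _ = windows.shape
    centers = np.arange(w, dtype=float)
    Y = windows.reshape(n, -1)

    bg = np.minimum(np.median(windows[:, 0, :], axis=1),
                    np.median(windows[:, -1, :], axis=1))
    peak = windows.reshape(n, -1).max(axis=1) - bg
    A = np.maximum(peak, 1.0) * 2.0 * math.pi * sigma0_px ** 2
    tot = np.maximum(Y.sum(axis=1) - bg * w * w, 1.0)
    yy, xx = np.mgrid[0:w, 0:w].astype(float)
    x0 = ((windows - bg[:, None, None]) * xx).reshape(n, -1).sum(1) / tot
    y0 = ((windows - bg[:, None, None]) * yy).reshape(n, -1).sum(1) / tot
    x0 = np.clip(x0, 1.0, w - 2.0)
    y0 = np.clip(y0, 1.0, w - 2.0)
    b = np.maximum(bg, 0.0)
    sigma = np.full(n, sigma0_px)
    lam = np.full(n, 1e-3)
    active = np.ones(n, dtype=bool)

    n_par = 5 if fit_sigma else 4
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        cx = x0[idx, None]
        cy = y0[idx, None]
        sg = sigma[idx, None]
        wx, dwx_dc, dwx_ds = _erf_profile(centers, cx, sg)
        wy, dwy_dc, dwy_ds = _erf_profile(centers, cy, sg)
        shape = wy[:, :, None] * wx[:, None, :]          # (m, w, w)
        model = b[idx, None, None] + A[idx, None, None] * shape
        resid = (windows[idx] - model).reshape(len(idx), -1)

        Ai = A[idx, None, None]
        J = np.empty((len(idx), w * w, n_par))
        J[:, :, 0] = (Ai * wy[:, :, None] * dwx_dc[:, None, :]).reshape(len(idx), -1)
        J[:, :, 1] = (Ai * dwy_dc[:, :, None] * wx[:, None, :]).reshape(len(idx), -1)
        J[:, :, 2] = shape.reshape(len(idx), -1)
        J[:, :, 3] = 1.0
        if fit_sigma:
            J[:, :, 4] = (Ai * (dwy_ds[:, :, None] * wx[:, None, :]
                                + wy[:, :, None] * dwx_ds[:, None, :])
                          ).reshape(len(idx), -1)

        JtJ = np.einsum("npi,npj->nij", J, J)
        Jtr = np.einsum("npi,np->ni", J, resid)
        JtJ[:, np.arange(n_par), np.arange(n_par)] *= (1.0 + lam[idx])[:, None]
        try:
            delta = np.linalg.solve(JtJ, Jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            JtJ[:, np.arange(n_par), np.arange(n_par)] += 1e-9
            delta = np.linalg.solve(JtJ, Jtr[..., None])[..., 0]

        x0[idx] += delta[:, 0]
        y0[idx] += delta[:, 1]
        A[idx] += delta[:, 2]
        b[idx] += delta[:, 3]
        if fit_sigma:
            sigma[idx] = np.clip(sigma[idx] + delta[:, 4],
                                 0.3 * sigma0_px, 3.0 * sigma0_px)
        x0[idx] = np.clip(x0[idx], 0.0, w - 1.0)
        y0[idx] = np.clip(y0[idx], 0.0, w - 1.0)
        moved = np.abs(delta[:, :2]).max(axis=1)
        lam[idx] = np.where(moved > 0.5, lam[idx] * 2.0, lam[idx] * 0.7)
        done = moved < tol
        active[idx[done]] = False

    converged = ~active
    return {"x0": x0, "y0": y0, "A": A, "b": b, "sigma": sigma,
            "converged": converged}


def _fit_joint_pair(window: np.ndarray, p1: np.ndarray, p2: np.ndarray,
                    sigma_px: float):
    """Two-component Gaussian mixture fit over one enlarged window.

    Slow scipy path used only for the rare overlapping-candidate case.
    """
    from scipy.optimize import least_squares

    h, w = window.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    def model(p):
        b, a1, x1, y1, a2, x2, y2 = p
        g1 = a1 / (2 * math.pi * sigma_px ** 2) * np.exp(
            -((xx - x1) ** 2 + (yy - y1) ** 2) / (2 * sigma_px ** 2))
        g2 = a2 / (2 * math.pi * sigma_px ** 2) * np.exp(
            -((xx - x2) ** 2 + (yy - y2) ** 2) / (2 * sigma_px ** 2))
        return b + g1 + g2

    bg = float(np.median(window[0, :]))
    amp0 = max(window.max() - bg, 1.0) * 2 * math.pi * sigma_px ** 2
    p0 = [bg, amp0, p1[1], p1[0], amp0, p2[1], p2[0]]
    res = least_squares(lambda p: (model(p) - window).ravel(), p0, method="lm",
                        max_nfev=400)
    b, a1, x1, y1, a2, x2, y2 = res.x
    out = []
    for a, x, y in ((a1, x1, y1), (a2, x2, y2)):
        if a > 0 and 0 <= x < w and 0 <= y < h:
            out.append({"x0": x, "y0": y, "A": a, "b": max(b, 0.0),
                        "sigma": sigma_px, "converged": res.success})
    return out


# ---------------------------------------------------------------------------
# precision
# ---------------------------------------------------------------------------

def estimate_precision(photons, background, sigma_nm, pixel_nm) -> np.ndarray:
    """Mortensen-style static localization precision (nm) of an MLE/LSQ fit.

    sigma_loc^2 = (sa^2/N) * (16/9 + 8*pi*sa^2*b / (N*a^2)), with
    sa^2 = sigma^2 + a^2/12, N integrated photons, b background photons per
    pixel, a the pixel size.  Decreases monotonically with photon count.
    """
    photons = np.asarray(photons, dtype=float)
    if np.any(photons <= 0):
        raise ValueError("photon count must be > 0 for a precision estimate")
    background = np.maximum(np.asarray(background, dtype=float), 0.0)
    sa2 = np.asarray(sigma_nm, dtype=float) ** 2 + pixel_nm ** 2 / 12.0
    var = (sa2 / photons) * (16.0 / 9.0
                             + 8.0 * math.pi * sa2 * background
                             / (photons * pixel_nm ** 2))
    return np.sqrt(var)


# ---------------------------------------------------------------------------
# frame- and movie-level drivers
# ---------------------------------------------------------------------------

def _photon_image(frame: np.ndarray, baseline: float, gain: float) -> np.ndarray:
    return (frame.astype(float) - baseline) / gain


def detect_spots(frame_image: np.ndarray, channel: str, params: DetectionParams,
                 pixel_nm: float, camera_gain: float = 1.0,
                 camera_baseline: float = 0.0, frame_index: int = 0,
                 fixed_sigma_px: Optional[float] = None) -> pd.DataFrame:
    """Detect and fit spots in one channel image; returns a localization table.

    The image is converted to photons via the camera gain/baseline first.
    Fits that do not converge, run to the window edge, or end with
    non-positive amplitude are discarded.
    """
    if frame_image.ndim != 2:
        raise ValueError("frame_image must be 2-D")
    if params.fit_window > min(frame_image.shape):
        raise ValueError("fit window larger than image")
    img_ph = _photon_image(frame_image, camera_baseline, camera_gain)
    sigma_px = (params.psf_sigma_nm / pixel_nm if fixed_sigma_px is None
                else fixed_sigma_px)
    half = params.fit_window // 2

    def _fit_candidates(image, rc, extra_var_img=None):
        out = []
        if not len(rc):
            return out
        wins = np.stack([image[r - half:r + half + 1, c - half:c + half + 1]
                         for r, c in rc])
        fit = fit_gaussian_spots(wins, sigma_px,
                                 fit_sigma=fixed_sigma_px is None,
                                 max_iter=params.max_iter)
        for i, (r, c) in enumerate(rc):
            if not fit["converged"][i]:
                continue
            x0, y0 = fit["x0"][i], fit["y0"][i]
            edge = 0.75
            if not (edge <= x0 <= params.fit_window - 1 - edge
                    and edge <= y0 <= params.fit_window - 1 - edge):
                continue
            A = fit["A"][i]
            if A < params.min_photons:
                continue
            # shot-noise significance of the integrated amplitude: rejects
            # noise bumps that pass the band-pass threshold and still fit
            b = max(fit["b"][i], 0.0)
            b_noise = b
            if extra_var_img is not None:
                # fitting a residual image: the subtracted model's shot
                # noise is still present even though its mean is gone
                b_noise += float(np.median(
                    extra_var_img[r - 1:r + 2, c - 1:c + 2]))
            n_eff = 4.0 * math.pi * fit["sigma"][i] ** 2
            sigma_A = math.sqrt(max(A, 0.0) + n_eff * b_noise)
            if A < params.min_significance * sigma_A:
                continue
            out.append((c - half + x0, r - half + y0, A, b, fit["sigma"][i]))
        return out

    rc = _find_candidates(img_ph, sigma_px, params.threshold_k, params.fit_window)
    min_sep = (params.min_separation_px if params.min_separation_px is not None
               else 2.5 * sigma_px)
    rc, pairs = _resolve_overlaps(rc, img_ph, min_sep, params.overlap_mode)
    rows = _fit_candidates(img_ph, rc)

    if params.residual_pass and rows:
        # subtract the fitted spots and look again: a dim emitter on a bright
        # neighbour's flank has no local maximum of its own in the first pass
        model = np.zeros_like(img_ph)
        H, W = img_ph.shape
        for x, y, A, b, sg in rows:
            cx, cy = int(math.floor(x)), int(math.floor(y))
            x0_, x1_ = max(0, cx - half), min(W, cx + half + 1)
            y0_, y1_ = max(0, cy - half), min(H, cy + half + 1)
            if x0_ >= x1_ or y0_ >= y1_:
                continue
            wx = _pixel_weights_centered(x, sg, x0_, x1_)
            wy = _pixel_weights_centered(y, sg, y0_, y1_)
            model[y0_:y1_, x0_:x1_] += A * np.outer(wy, wx)
        resid = img_ph - model
        rc2 = _find_candidates(resid, sigma_px, params.threshold_k,
                               params.fit_window)
        if len(rc2) and rows:
            prev = np.array([(r[1], r[0]) for r in rows])  # (row, col)
            d2 = ((rc2[:, None, :] - prev[None, :, :]) ** 2).sum(-1)
            rc2 = rc2[d2.min(axis=1) > max(2.0, min_sep) ** 2]
        rows.extend(_fit_candidates(resid, rc2, extra_var_img=model))

    for p1, p2 in pairs:
        r0 = max(0, min(p1[0], p2[0]) - half)
        r1 = min(frame_image.shape[0], max(p1[0], p2[0]) + half + 1)
        c0 = max(0, min(p1[1], p2[1]) - half)
        c1 = min(frame_image.shape[1], max(p1[1], p2[1]) + half + 1)
        win = img_ph[r0:r1, c0:c1]
        for f in _fit_joint_pair(win, p1 - (r0, c0), p2 - (r0, c0), sigma_px):
            if f["converged"] and f["A"] >= params.min_photons:
                rows.append((c0 + f["x0"], r0 + f["y0"], f["A"], f["b"],
                             f["sigma"]))

    if not rows:
        return pd.DataFrame(columns=LOC_COLUMNS)
    arr = np.array(rows)
    # pixel centre of pixel j is at j, so +0.5 converts to the half-open
    # pixel-edge convention: position (in px units) = coordinate + 0.5
    x_um = (arr[:, 0] + 0.5) * pixel_nm / 1000.0
    y_um = (arr[:, 1] + 0.5) * pixel_nm / 1000.0
    sigma_nm = arr[:, 4] * pixel_nm
    prec = estimate_precision(arr[:, 2], arr[:, 3], sigma_nm, pixel_nm)
    return pd.DataFrame({
        "frame": frame_index, "channel": channel, "x_um": x_um, "y_um": y_um,
        "photons": arr[:, 2], "bg": arr[:, 3], "sigma_nm": sigma_nm,
        "precision_nm": prec,
    })


def localize_movie(movie: Movie, params: Optional[DetectionParams] = None,
                   channels: Tuple[str, ...] = ("donor", "acceptor")) -> pd.DataFrame:
    """Localize every frame of both channels of a movie.

    The PSF width is fit freely until ``n_sigma_calibration`` spots have been
    accepted, then frozen at their median for all remaining frames (the
    median is also re-applied per channel).
    """
    params = params or DetectionParams(psf_sigma_nm=movie.config.psf_sigma)
    cfg = movie.config
    out = []
    for channel in channels:
        stack = movie.donor() if channel == "donor" else movie.acceptor()
        free_sigmas: list = []
        fixed: Optional[float] = None
        for t in range(movie.n_frames):
            df = detect_spots(stack[t], channel, params, cfg.pixel_size,
                              cfg.camera_gain, cfg.camera_baseline,
                              frame_index=t, fixed_sigma_px=fixed)
            if fixed is None and len(df):
                free_sigmas.extend(df["sigma_nm"] / cfg.pixel_size)
                if len(free_sigmas) >= params.n_sigma_calibration:
                    fixed = float(np.median(free_sigmas))
            out.append(df)
    if not out:
        return pd.DataFrame(columns=LOC_COLUMNS)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# channel registration
# ---------------------------------------------------------------------------

@dataclass
class ChannelTransform:
    """Affine map from acceptor-channel into donor-channel coordinates (um)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))  # (2, 2)
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))  # (2,)
    rms_residual_nm: float = 0.0
    n_fiducials: int = 0

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return xy @ self.matrix.T + self.offset

    def inverse(self) -> "ChannelTransform":
        inv = np.linalg.inv(self.matrix)
        return ChannelTransform(matrix=inv, offset=-inv @ self.offset,
                                rms_residual_nm=self.rms_residual_nm,
                                n_fiducials=self.n_fiducials)

    @classmethod
    def identity(cls) -> "ChannelTransform":
        return cls()

    def to_text(self, path) -> None:
        m, o = self.matrix, self.offset
        with open(path, "w") as fh:
            fh.write("# affine acceptor->donor: a b tx c d ty (um)\n")
            fh.write(f"{m[0,0]:.9f} {m[0,1]:.9f} {o[0]:.9f} "
                     f"{m[1,0]:.9f} {m[1,1]:.9f} {o[1]:.9f}\n")

    @classmethod
    def from_text(cls, path) -> "ChannelTransform":
        with open(path) as fh:
            vals = [float(x) for line in fh if not line.startswith("#")
                    for x in line.split()]
        a, b, tx, c, d, ty = vals[:6]
        return cls(matrix=np.array([[a, b], [c, d]]),
                   offset=np.array([tx, ty]))


def _average_bead_positions(locs: pd.DataFrame, match_radius_um: float = 0.5):
    """Collapse per-frame bead localizations into per-bead mean positions.

    References seen in fewer than half the frames are dropped: a genuine
    bead is present in (nearly) every frame, a noise detection is not.
    """
    if not len(locs):
        return np.empty((0, 2))
    n_frames = locs["frame"].nunique()
    first = locs[locs["frame"] == locs["frame"].min()]
    refs = first[["x_um", "y_um"]].to_numpy()
    members = [[r] for r in refs]
    rest = locs[locs["frame"] != locs["frame"].min()]
    xy = rest[["x_um", "y_um"]].to_numpy()
    for p in xy:
        d = np.hypot(*(refs - p).T)
        j = int(np.argmin(d)) if len(d) else -1
        if j >= 0 and d[j] < match_radius_um:
            members[j].append(p)
    # per-bead median across frames: robust to an occasional stray detection
    out = [np.median(np.array(m), axis=0) for m in members
           if len(m) >= max(2, n_frames // 2)]
    return np.array(out) if out else np.empty((0, 2))


def register_channels(bead_movie: Movie,
                      params: Optional[DetectionParams] = None,
                      residual_gate_nm: float = 20.0) -> ChannelTransform:
    """Fit the acceptor->donor affine transform from a fiducial-bead movie.

    Beads are localized in both channels in every frame, averaged per bead,
    matched across channels by mutual nearest neighbour, and the affine
    coefficients solved by least squares.  Raises if fewer than three beads
    match; warns (via the returned rms) if residuals exceed the gate.
    """
    import warnings

    params = params or DetectionParams(psf_sigma_nm=bead_movie.config.psf_sigma,
                                       threshold_k=6.0)
    locs = localize_movie(bead_movie, params)
    donor = _average_bead_positions(locs[locs["channel"] == "donor"])
    acceptor = _average_bead_positions(locs[locs["channel"] == "acceptor"])
    if len(donor) < 3 or len(acceptor) < 3:
        raise ValueError("fewer than 3 beads localized per channel")

    # mutual nearest neighbours
    d2 = ((acceptor[:, None, :] - donor[None, :, :]) ** 2).sum(-1)
    a_to_d = d2.argmin(axis=1)
    d_to_a = d2.argmin(axis=0)
    pairs = [(i, a_to_d[i]) for i in range(len(acceptor))
             if d_to_a[a_to_d[i]] == i]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 mutually matched beads")
    src = acceptor[[i for i, _ in pairs]]
    dst = donor[[j for _, j in pairs]]
    if np.linalg.matrix_rank(src - src.mean(0)) < 2:
        raise ValueError("matched beads are collinear; affine fit is degenerate")

    def _fit(src_, dst_):
        X = np.column_stack([src_, np.ones(len(src_))])
        coef, *_ = np.linalg.lstsq(X, dst_, rcond=None)
        matrix = coef[:2].T
        offset = coef[2]
        resid = dst_ - (src_ @ matrix.T + offset)
        return matrix, offset, np.hypot(resid[:, 0], resid[:, 1])

    matrix, offset, r = _fit(src, dst)
    if len(src) > 4:
        # one trim round: a bead contaminated in one channel would otherwise
        # leak tens of nm into the affine coefficients
        gate = max(3.0 * np.median(r), 5e-3)
        keep = r <= gate
        if keep.sum() >= 3 and keep.sum() < len(src):
            src, dst = src[keep], dst[keep]
            matrix, offset, r = _fit(src, dst)
    rms_nm = float(np.sqrt((r ** 2).mean()) * 1000.0)
    if rms_nm > residual_gate_nm:
        warnings.warn(f"channel registration rms residual {rms_nm:.1f} nm "
                      f"exceeds gate {residual_gate_nm} nm")
    return ChannelTransform(matrix=matrix, offset=offset,
                            rms_residual_nm=rms_nm, n_fiducials=len(pairs))
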