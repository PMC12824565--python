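"""FRET-trace construction, vetting and corrected FRET efficiency.

Donor and acceptor trajectories are paired by co-movement within a search
radius; intensity time series are read back from the movie by fixed-aperture
photometry at the (registered) trajectory positions, so the donor signal is
followed through frames where one channel was not independently detected.
Candidate traces are vetted on their photobleaching step structure: the
acceptor must lose its signal in exactly one step, the donor in at most one,
and the donor must respond at the acceptor loss — an intensity increase
(dimer dissociation, pathway 1) or a simultaneous drop of both signals to
background (complex loss, pathway 2).  Multi-step puncta (several acceptors)
are rejected.

Corrected FRET efficiency follows the standard multilab convention:
``F_corr = I_AD - alpha*I_DD - delta*I_AA`` and
``E = F_corr / (gamma*I_DD + F_corr)``, with alpha (donor leakage) estimated
from donor-only traces, delta (direct excitation) from acceptor-only traces
under alternating excitation (or supplied from calibration), and gamma from
the intensity steps across acceptor bleaching events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .localize import ChannelTransform
from .simulate import Movie
from .track import Trajectory

__all__ = [
    "FretTrace",
    "CorrectionFactors",
    "GaussianFit",
    "pair_trajectories",
    "extract_intensity_series",
    "detect_intensity_steps",
    "vet_fret_trace",
    "concatenate_donor",
    "estimate_correction_factors",
    "compute_fret_efficiency",
    "compute_stoichiometry",
    "fit_gaussian_histogram",
]


@dataclass
class FretTrace:
    """Paired donor/acceptor intensities and coordinates on one frame axis.

    ``frames`` is contiguous over the donor span; acceptor coordinates are
    NaN where the acceptor was not localized.  ``E`` is filled by
    :func:`compute_fret_efficiency` on frames before ``acceptor_loss_frame``.
    """

    donor_traj_id: int
    acceptor_traj_id: Optional[int]
    frames: np.ndarray              # (n,) contiguous ints
    I_DD: np.ndarray                # photons
    I_AD: np.ndarray
    xy_donor: np.ndarray            # (n, 2) um, NaN on donor gap frames
    xy_acceptor: np.ndarray         # (n, 2) um in donor coords, NaN when absent
    I_AA: Optional[np.ndarray] = None
    precision_nm: Optional[np.ndarray] = None
    E: Optional[np.ndarray] = None
    S: Optional[np.ndarray] = None
    acceptor_loss_frame: Optional[int] = None   # absolute frame index
    accepted: bool = False
    reason: str = ""
    concatenated_traj_id: Optional[int] = None

    def __len__(self) -> int:
        return len(self.frames)

    def loss_index(self) -> Optional[int]:
        """Index into the trace arrays of the acceptor loss frame."""
        if self.acceptor_loss_frame is None:
            return None
        return int(self.acceptor_loss_frame - self.frames[0])

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self)
        data = {
            "frame": self.frames,
            "I_DD": self.I_DD,
            "I_AD": self.I_AD,
            "I_AA": self.I_AA if self.I_AA is not None else np.full(n, np.nan),
            "E": self.E if self.E is not None else np.full(n, np.nan),
            "S": self.S if self.S is not None else np.full(n, np.nan),
            "x_um": self.xy_donor[:, 0],
            "y_um": self.xy_donor[:, 1],
            "xa_um": self.xy_acceptor[:, 0],
            "ya_um": self.xy_acceptor[:, 1],
        }
        return pd.DataFrame(data)

    def metadata(self) -> dict:
        """Sidecar record: ids, loss frame, acceptance verdict."""
        return {
            "donor_traj_id": self.donor_traj_id,
            "acceptor_traj_id": self.acceptor_traj_id,
            "concatenated_traj_id": self.concatenated_traj_id,
            "acceptor_loss_frame": self.acceptor_loss_frame,
            "accepted": self.accepted,
            "reason": self.reason,
            "n_frames": len(self),
        }

    def to_csv(self, path, metadata_path=None) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")
        if metadata_path is not None:
            import json

            with open(metadata_path, "w") as fh:
                json.dump(self.metadata(), fh, indent=2)


@dataclass
class CorrectionFactors:
    """Global photophysical correction factors with across-trace spreads."""

    alpha: float = 0.0
    delta: float = 0.0
    gamma: float = 1.0
    beta: float = 1.0
    alpha_sd: float = 0.0
    delta_sd: float = 0.0
    gamma_sd: float = 0.0
    beta_sd: float = 0.0
    n_alpha: int = 0
    n_delta: int = 0
    n_gamma: int = 0
    n_beta: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.delta < 0:
            raise ValueError("alpha and delta must be >= 0")
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be > 0")


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def pair_trajectories(
    donor_trajs: Sequence[Trajectory],
    acceptor_trajs: Sequence[Trajectory],
    transform: Optional[ChannelTransform] = None,
    pair_radius_nm: float = 250.0,
    min_overlap: int = 3,
) -> Tuple[List[Tuple[Trajectory, Trajectory]], List[Trajectory], List[Trajectory]]:
    """Pair co-moving donor and acceptor trajectories.

    Acceptor coordinates are mapped into donor-channel coordinates first.
    A pair is a candidate when the median distance over time-overlapping
    frames is below ``pair_radius_nm``; each trajectory joins at most one
    pair, nearest median distance first, ties broken by lower trajectory id.
    Returns (pairs, unpaired donor trajectories, unpaired acceptor
    trajectories mapped to donor coordinates).
    """
    transform = transform or ChannelTransform.identity()
    radius_um = pair_radius_nm / 1000.0
    mapped = []
    for a in acceptor_trajs:
        mapped.append(Trajectory(id=a.id, channel=a.channel, frames=a.frames,
                                 xy=transform.apply(a.xy), photons=a.photons,
                                 precision_nm=a.precision_nm))
    cand = []
    for a in mapped:
        af = {int(f): k for k, f in enumerate(a.frames)}
        for d in donor_trajs:
            common = [(af[int(f)], k) for k, f in enumerate(d.frames)
                      if int(f) in af]
            if len(common) < min_overlap:
                continue
            ai = np.array([c[0] for c in common])
            di = np.array([c[1] for c in common])
            dist = np.hypot(*(a.xy[ai] - d.xy[di]).T)
            med = float(np.median(dist))
            if med <= radius_um:
                cand.append((med, a.id, d.id, a, d))
    cand.sort(key=lambda c: (c[0], c[2], c[1]))
    used_a, used_d = set(), set()
    pairs = []
    for med, aid, did, a, d in cand:
        if aid in used_a or did in used_d:
            continue
        used_a.add(aid)
        used_d.add(did)
        pairs.append((d, a))
    donor_only = [d for d in donor_trajs if d.id not in used_d]
    acceptor_only = [a for a in mapped if a.id not in used_a]
    return pairs, donor_only, acceptor_only


# ---------------------------------------------------------------------------
# aperture photometry
# ---------------------------------------------------------------------------

def _interp_positions(frames: np.ndarray, traj: Trajectory) -> np.ndarray:
    """Positions at every requested frame; linear across gaps, clamped ends."""
    x = np.interp(frames, traj.frames, traj.xy[:, 0])
    y = np.interp(frames, traj.frames, traj.xy[:, 1])
    return np.column_stack([x, y])


def _fast_median(a: np.ndarray) -> float:
    n = len(a)
    if n == 0:
        return 0.0
    k = n // 2
    p = np.partition(a, k)
    if n % 2:
        return float(p[k])
    return float(0.5 * (p[k] + p[:k + 1].max()))


def _aperture_sum(img_ph: np.ndarray, x_px: float, y_px: float,
                  r_ap: int, r_bg_in: int, r_bg_out: int) -> float:
    """Background-subtracted photon sum in a disk around (x_px, y_px)."""
    H, W = img_ph.shape
    cx, cy = int(round(x_px - 0.5)), int(round(y_px - 0.5))
    r = r_bg_out
    x0, x1 = max(0, cx - r), min(W, cx + r + 1)
    y0, y1 = max(0, cy - r), min(H, cy + r + 1)
    if x0 >= x1 or y0 >= y1:
        return 0.0
    sub = img_ph[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx + 0.5 - x_px) ** 2 + (yy + 0.5 - y_px) ** 2
    ap = d2 <= r_ap ** 2
    ann = (d2 >= r_bg_in ** 2) & (d2 <= r_bg_out ** 2)
    if not ap.any():
        return 0.0
    bg = _fast_median(sub[ann]) if ann.any() else 0.0
    return float(sub[ap].sum() - bg * ap.sum())


def extract_intensity_series(
    movie: Movie,
    frames: np.ndarray,
    xy_donor_um: np.ndarray,
    transform: Optional[ChannelTransform] = None,
    aperture_px: int = 3,
    annulus_px: Tuple[int, int] = (5, 7),
    photon_stacks: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """I_DD and I_AD (photons) at given donor-channel positions.

    The acceptor-channel position is the donor position pushed through the
    inverse registration transform.  Background is the median of a local
    annulus, removed per frame and per channel.  ``photon_stacks`` may carry
    the photon-converted (donor, acceptor) stacks to avoid reconverting the
    movie for every trace.
    """
    cfg = movie.config
    px_um = cfg.pixel_size / 1000.0
    inv = (transform or ChannelTransform.identity()).inverse()
    xy_acc_um = inv.apply(xy_donor_um)
    if photon_stacks is None:
        photon_stacks = photon_converted_stacks(movie)
    donor, acceptor = photon_stacks
    i_dd = np.zeros(len(frames))
    i_ad = np.zeros(len(frames))
    for k, f in enumerate(frames):
        if f < 0 or f >= movie.n_frames or not np.isfinite(xy_donor_um[k]).all():
            i_dd[k] = i_ad[k] = np.nan
            continue
        xd, yd = xy_donor_um[k] / px_um
        xa, ya = xy_acc_um[k] / px_um
        i_dd[k] = _aperture_sum(donor[f], xd, yd, aperture_px, *annulus_px)
        i_ad[k] = _aperture_sum(acceptor[f], xa, ya, aperture_px, *annulus_px)
    return i_dd, i_ad


def photon_converted_stacks(movie: Movie) -> Tuple[np.ndarray, np.ndarray]:
    """(donor, acceptor) stacks in photon units (float32)."""
    cfg = movie.config
    conv = ((movie.frames.astype(np.float32) - cfg.camera_baseline)
            / cfg.camera_gain)
    w = movie.channel_split
    return conv[:, :, :w], conv[:, :, w:]


def build_fret_trace(
    movie: Movie,
    donor_traj: Trajectory,
    acceptor_traj: Optional[Trajectory],
    transform: Optional[ChannelTransform] = None,
    pad_frames: int = 10,
    aperture_px: int = 3,
    photon_stacks: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> FretTrace:
    """Assemble a FretTrace for a (paired or donor-only) trajectory.

    The frame axis is the donor span extended by ``pad_frames`` beyond the
    last donor frame (position held fixed) so that the donor's own bleach
    step to background is part of the series.
    """
    f0 = donor_traj.start_frame
    f1 = min(donor_traj.end_frame + pad_frames, movie.n_frames - 1)
    frames = np.arange(f0, f1 + 1)
    xy = _interp_positions(frames, donor_traj)
    i_dd, i_ad = extract_intensity_series(movie, frames, xy, transform,
                                          aperture_px=aperture_px,
                                          photon_stacks=photon_stacks)
    xy_donor = np.full((len(frames), 2), np.nan)
    idx = donor_traj.frames - f0
    xy_donor[idx] = donor_traj.xy
    xy_acc = np.full((len(frames), 2), np.nan)
    if acceptor_traj is not None:
        tr = transform or ChannelTransform.identity()
        a_xy = tr.apply(acceptor_traj.xy) if acceptor_traj.channel == "acceptor" \
            else acceptor_traj.xy
        for k, f in enumerate(acceptor_traj.frames):
            if f0 <= f <= f1:
                xy_acc[int(f) - f0] = a_xy[k]
    prec = np.full(len(frames), np.nan)
    prec[idx] = donor_traj.precision_nm
    return FretTrace(
        donor_traj_id=donor_traj.id,
        acceptor_traj_id=None if acceptor_traj is None else acceptor_traj.id,
        frames=frames, I_DD=i_dd, I_AD=i_ad, xy_donor=xy_donor,
        xy_acceptor=xy_acc, precision_nm=prec)


# ---------------------------------------------------------------------------
# change-point detection
# ---------------------------------------------------------------------------

def _sse(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """Sum of squared deviations of series[i:j] from its mean, via prefix sums."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return s2 - s * s / n


def noise_sigma(series: np.ndarray) -> float:
    """Robust noise sigma from the median absolute first difference."""
    d = np.diff(series)
    d = d[np.isfinite(d)]
    if not len(d):
        return 0.0
    return float(np.median(np.abs(d)) / (0.6745 * math.sqrt(2.0)))


def detect_intensity_steps(series: np.ndarray, penalty_factor: float = 3.0,
                           min_segment: int = 3) -> List[Tuple[int, float, float]]:
    """Mean-shift change points by binary segmentation with a BIC-style penalty.

    Recursively splits at the index maximizing the drop in squared error;
    a split is kept while the drop exceeds ``penalty_factor * sigma^2 *
    log(n)``, sigma estimated from the median absolute first difference, so a
    constant series plus noise yields no points.  Returns ``(index,
    mean_before, mean_after)`` with ``index`` the first frame of the right
    segment, sorted ascending.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise ValueError("series must have at least 10 frames")
    finite = np.isfinite(x)
    x = np.where(finite, x, np.nanmedian(x))
    n = len(x)
    sigma = noise_sigma(x)
    if sigma == 0.0:
        sigma = 1e-12
    pen = penalty_factor * sigma ** 2 * math.log(n)
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x * x)])

    points: List[int] = []

    def split(i: int, j: int) -> None:
        if j - i < 2 * min_segment:
            return
        total = _sse(prefix, prefix2, i, j)
        ks = np.arange(i + min_segment, j - min_segment + 1)
        if not len(ks):
            return
        s_left = prefix[ks] - prefix[i]
        s2_left = prefix2[ks] - prefix2[i]
        n_left = ks - i
        sse_left = s2_left - s_left ** 2 / n_left
        s_right = prefix[j] - prefix[ks]
        s2_right = prefix2[j] - prefix2[ks]
        n_right = j - ks
        sse_right = s2_right - s_right ** 2 / n_right
        gain = total - (sse_left + sse_right)
        kbest = int(np.argmax(gain))
        if gain[kbest] > pen:
            k = int(ks[kbest])
            points.append(k)
            split(i, k)
            split(k, j)

    split(0, n)
    points.sort()
    out = []
    bounds = [0] + points + [n]
    for b, k in enumerate(points):
        left = x[bounds[b]:k]
        right = x[k:bounds[b + 2]]
        out.append((k, float(left.mean()), float(right.mean())))
    return out


# ---------------------------------------------------------------------------
# vetting
# ---------------------------------------------------------------------------

def vet_fret_trace(
    trace: FretTrace,
    window: int = 5,
    k_sigma: float = 2.0,
    bg_fraction: float = 0.3,
    simultaneous_tol: int = 3,
    penalty_factor: float = 3.0,
    min_fret_ratio: float = 0.25,
) -> FretTrace:
    """Accept or reject a candidate trace on its step structure.

    Accepted iff the acceptor series has exactly one downward step to
    background level, the donor has at most one downward step, and at the
    acceptor loss the donor either rises by at least ``k_sigma`` noise sigmas
    (anti-correlation; dimer dissociation) or drops to background within
    ``simultaneous_tol`` frames (simultaneous loss of the complex).  The
    pre-loss acceptor signal must also exceed ``min_fret_ratio`` times the
    donor signal: an "acceptor" at the donor-leakage level is not a FRET
    pair but a lone donor seen through channel crosstalk.
    Rejection is a result with a recorded reason, never an error.
    """
    if len(trace) < 10:
        trace.accepted = False
        trace.reason = "too short"
        return trace
    a_steps = detect_intensity_steps(trace.I_AD, penalty_factor)
    d_steps = detect_intensity_steps(trace.I_DD, penalty_factor)

    a_down = [s for s in a_steps if s[2] < s[1]]
    d_down = [s for s in d_steps if s[2] < s[1]]
    a_level = max((s[1] for s in a_down), default=np.nanmax(trace.I_AD))

    # acceptor must vanish exactly once; several loss steps = several dyes
    major_a_down = [s for s in a_down if (s[1] - s[2]) > bg_fraction * max(a_level, 1e-9)]
    if len(major_a_down) > 1:
        trace.accepted = False
        trace.reason = "multi-step"
        return trace
    if len(major_a_down) == 0:
        trace.accepted = False
        trace.reason = "no acceptor loss"
        return trace
    k, before, after = major_a_down[0]
    if after > bg_fraction * before:
        trace.accepted = False
        trace.reason = "acceptor does not reach background"
        return trace
    dd_pre = np.nanmean(trace.I_DD[max(0, k - 2 * window):k])
    if not (before > min_fret_ratio * max(dd_pre, 1e-9)):
        trace.accepted = False
        trace.reason = "acceptor at leakage level"
        return trace

    d_level = max((s[1] for s in d_down), default=np.nanmax(trace.I_DD))
    major_d_down = [s for s in d_down if (s[1] - s[2]) > bg_fraction * max(d_level, 1e-9)]
    if len(major_d_down) > 1:
        trace.accepted = False
        trace.reason = "multi-step"
        return trace

    sig = noise_sigma(trace.I_DD[:k]) if k >= 3 else noise_sigma(trace.I_DD)
    w0 = max(0, k - window)
    w1 = min(len(trace), k + window)
    pre = np.nanmean(trace.I_DD[w0:k]) if k > w0 else np.nan
    post = np.nanmean(trace.I_DD[k:w1]) if w1 > k else np.nan
    rises = np.isfinite(pre) and np.isfinite(post) and \
        (post - pre) >= k_sigma * max(sig, 1e-12)

    simultaneous = False
    for kd, bd, ad in major_d_down:
        if abs(kd - k) <= simultaneous_tol and ad <= bg_fraction * max(bd, 1e-9):
            simultaneous = True
            break

    if not (rises or simultaneous):
        trace.accepted = False
        trace.reason = "no anti-correlation"
        return trace

    trace.accepted = True
    trace.reason = "pathway2-simultaneous-loss" if (simultaneous and not rises) else ""
    trace.acceptor_loss_frame = int(trace.frames[0] + k)
    return trace


def concatenate_donor(
    trace: FretTrace,
    donor_trajs: Sequence[Trajectory],
    movie: Optional[Movie] = None,
    transform: Optional[ChannelTransform] = None,
    search_radius_nm: float = 250.0,
    max_gap: int = 3,
    photon_stacks: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> FretTrace:
    """Extend the donor series with its nearest continuation trajectory.

    Looks for a donor trajectory starting within ``max_gap`` frames of the
    acceptor loss (or of the current donor end) and within
    ``search_radius_nm`` of the position where the acceptor disappeared;
    appends the nearest one.  Without a candidate the trace is left
    unchanged (a pathway-2 candidate).
    """
    if trace.acceptor_loss_frame is None:
        return trace
    li = trace.loss_index()
    ref_idx = None
    for i in range(min(li, len(trace) - 1), -1, -1):
        if np.isfinite(trace.xy_donor[i]).all():
            ref_idx = i
            break
    if ref_idx is None:
        return trace
    ref_xy = trace.xy_donor[ref_idx]
    donor_end = int(trace.frames[0] + np.max(np.nonzero(
        np.isfinite(trace.xy_donor[:, 0]))[0]))
    radius_um = search_radius_nm / 1000.0

    best = None
    for t in donor_trajs:
        if t.id == trace.donor_traj_id:
            continue
        gap = t.start_frame - donor_end
        if not (1 <= gap <= max_gap + 1):
            continue
        dist = float(np.hypot(*(t.xy[0] - ref_xy)))
        if dist <= radius_um and (best is None or dist < best[0]
                                  or (dist == best[0] and t.id < best[1].id)):
            best = (dist, t)
    if best is None:
        return trace
    cont = best[1]

    f0 = trace.frames[0]
    new_end = int(cont.end_frame)
    frames = np.arange(f0, new_end + 1)
    n = len(frames)

    def grow(arr, fill=np.nan):
        out = np.full((n,) + arr.shape[1:], fill)
        out[:len(arr)] = arr
        return out

    xy_donor = grow(trace.xy_donor)
    prec = grow(trace.precision_nm if trace.precision_nm is not None
                else np.full(len(trace), np.nan))
    for k, f in enumerate(cont.frames):
        xy_donor[int(f) - f0] = cont.xy[k]
        prec[int(f) - f0] = cont.precision_nm[k]
    i_dd = grow(trace.I_DD)
    i_ad = grow(trace.I_AD)
    if movie is not None:
        ext = frames[len(trace):]
        xy_ext = _interp_positions(ext, cont)
        dd, ad = extract_intensity_series(movie, ext, xy_ext, transform,
                                          photon_stacks=photon_stacks)
        i_dd[len(trace):] = dd
        i_ad[len(trace):] = ad
    trace.frames = frames
    trace.I_DD = i_dd
    trace.I_AD = i_ad
    trace.xy_donor = xy_donor
    trace.xy_acceptor = grow(trace.xy_acceptor)
    trace.precision_nm = prec
    trace.concatenated_traj_id = cont.id
    return trace


# ---------------------------------------------------------------------------
# correction factors, E, S
# ---------------------------------------------------------------------------

def _donor_active_mask(trace: FretTrace, penalty_factor: float = 3.0) -> np.ndarray:
    """Frames before the donor's own bleach step (all, if no step)."""
    mask = np.isfinite(trace.I_DD)
    if len(trace) >= 10:
        steps = [s for s in detect_intensity_steps(trace.I_DD, penalty_factor)
                 if s[2] < 0.5 * s[1]]
        if steps:
            mask[steps[0][0]:] = False
    return mask


def estimate_correction_factors(
    donor_only_traces: Sequence[FretTrace],
    acceptor_only_traces: Sequence[FretTrace],
    fret_traces: Sequence[FretTrace],
    window: int = 5,
    delta_fallback: Optional[float] = None,
    min_traces: int = 5,
) -> CorrectionFactors:
    """Tracewise alpha / delta / gamma / beta, averaged for global use.

    alpha: mean over donor-only traces of <I_AD>/<I_DD> (donor-active frames).
    delta: mean over acceptor-only traces of <I_AD>/<I_AA> (needs alternating
    excitation); without such traces ``delta_fallback`` is used (default 0).
    gamma: mean over accepted traces with a donor signal after acceptor loss
    of  -(Delta I_AD')/(Delta I_DD)  across the acceptor-loss step, where
    I_AD' is leakage/direct-excitation corrected.
    beta: from accepted alternating-excitation traces,
    <I_AA> / (gamma*<I_DD> + <F_corr>).
    """
    if len(donor_only_traces) < min_traces:
        raise ValueError(
            f"insufficient donor-only calibration traces "
            f"({len(donor_only_traces)} < {min_traces})")

    alphas = []
    for t in donor_only_traces:
        m = _donor_active_mask(t)
        if m.sum() < 3:
            continue
        dd = np.nanmean(t.I_DD[m])
        if dd > 0:
            alphas.append(max(np.nanmean(t.I_AD[m]), 0.0) / dd)
    if len(alphas) < min_traces:
        raise ValueError("insufficient usable donor-only traces for alpha")
    alpha = float(np.mean(alphas))

    deltas = []
    for t in acceptor_only_traces:
        if t.I_AA is None:
            continue
        m = np.isfinite(t.I_AA) & (t.I_AA > 0)
        if m.sum() < 3:
            continue
        deltas.append(max(np.nanmean(t.I_AD[m]), 0.0) / np.nanmean(t.I_AA[m]))
    if deltas:
        delta = float(np.mean(deltas))
        delta_sd, n_delta = float(np.std(deltas)), len(deltas)
    else:
        if delta_fallback is None and acceptor_only_traces:
            raise ValueError("acceptor-only traces lack I_AA; provide "
                             "delta_fallback for single-excitation data")
        delta = float(delta_fallback or 0.0)
        delta_sd, n_delta = 0.0, 0

    gammas = []
    for t in fret_traces:
        if not t.accepted or t.acceptor_loss_frame is None:
            continue
        k = t.loss_index()
        w0, w1 = max(0, k - window), min(len(t), k + window)
        if k - w0 < 2 or w1 - k < 2:
            continue
        iaa_pre = np.nanmean(t.I_AA[w0:k]) if t.I_AA is not None else 0.0
        iaa_post = np.nanmean(t.I_AA[k:w1]) if t.I_AA is not None else 0.0
        ad_pre = np.nanmean(t.I_AD[w0:k]) - alpha * np.nanmean(t.I_DD[w0:k]) \
            - delta * iaa_pre
        ad_post = np.nanmean(t.I_AD[k:w1]) - alpha * np.nanmean(t.I_DD[k:w1]) \
            - delta * iaa_post
        dd_pre = np.nanmean(t.I_DD[w0:k])
        dd_post = np.nanmean(t.I_DD[k:w1])
        d_dd = dd_post - dd_pre
        d_ad = ad_pre - ad_post
        if d_dd > 0 and d_ad > 0:
            gammas.append(d_ad / d_dd)
    if len(fret_traces) >= min_traces and len(gammas) < min_traces:
        # not enough pathway-1 steps; fall back to gamma = 1 with a warning sd
        gammas = gammas or [1.0]
    gamma = float(np.mean(gammas)) if gammas else 1.0

    betas = []
    for t in fret_traces:
        if not t.accepted or t.I_AA is None or t.acceptor_loss_frame is None:
            continue
        k = t.loss_index()
        if k < 3:
            continue
        dd = np.nanmean(t.I_DD[:k])
        ad = np.nanmean(t.I_AD[:k])
        aa = np.nanmean(t.I_AA[:k])
        fc = ad - alpha * dd - delta * aa
        denom = gamma * dd + fc
        if denom > 0 and aa > 0:
            betas.append(aa / denom)
    beta = float(np.mean(betas)) if betas else 1.0

    return CorrectionFactors(
        alpha=alpha, delta=delta, gamma=gamma, beta=beta,
        alpha_sd=float(np.std(alphas)), delta_sd=delta_sd,
        gamma_sd=float(np.std(gammas)) if gammas else 0.0,
        beta_sd=float(np.std(betas)) if betas else 0.0,
        n_alpha=len(alphas), n_delta=n_delta, n_gamma=len(gammas),
        n_beta=len(betas))


def compute_fret_efficiency(trace: FretTrace,
                            factors: CorrectionFactors) -> np.ndarray:
    """Per-frame corrected FRET efficiency on frames before acceptor loss.

    ``F_corr = I_AD - alpha*I_DD - delta*I_AA`` (the I_AA term is dropped
    without alternating-excitation data); ``E = F_corr/(gamma*I_DD + F_corr)``.
    Values are reported unclipped; frames with a non-positive total are NaN
    (flagged invalid) and excluded from histograms downstream.
    """
    i_aa = trace.I_AA if trace.I_AA is not None else 0.0
    f_corr = trace.I_AD - factors.alpha * trace.I_DD - factors.delta * i_aa
    denom = factors.gamma * trace.I_DD + f_corr
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(denom > 0, f_corr / denom, np.nan)
    li = trace.loss_index()
    if li is not None:
        e[li:] = np.nan
    trace.E = e
    return e


def compute_stoichiometry(trace: FretTrace,
                          factors: CorrectionFactors) -> np.ndarray:
    """Per-frame stoichiometry S for alternating-excitation traces."""
    if trace.I_AA is None:
        raise ValueError("ALEX data required: trace has no I_AA series")
    f_corr = trace.I_AD - factors.alpha * trace.I_DD - factors.delta * trace.I_AA
    num = factors.gamma * trace.I_DD + f_corr
    denom = num + trace.I_AA / factors.beta
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(denom > 0, num / denom, np.nan)
    trace.S = s
    return s


# ---------------------------------------------------------------------------
# histogram fitting
# ---------------------------------------------------------------------------

@dataclass
class GaussianFit:
    mean: float
    sd: float
    amplitude: float
    mean_stderr: float
    sd_stderr: float
    r_squared: float
    poor_fit: bool  # single Gaussian explains < 80% of histogram variance


def fit_gaussian_histogram(values: Sequence[float], bins: int = 30,
                           range_: Optional[Tuple[float, float]] = None
                           ) -> GaussianFit:
    """Least-squares Gaussian fit to a histogram of values.

    Requires >= 30 values and non-degenerate spread; a bimodal sample shows
    up as ``poor_fit`` via the fraction of histogram variance explained.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 30:
        raise ValueError(f"need >= 30 values, got {len(v)}")
    if np.ptp(v) == 0:
        raise ValueError("degenerate sample: all values identical")
    counts, edges = np.histogram(v, bins=bins, range=range_)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, mu, sd):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sd ** 2))

    p0 = [counts.max(), float(np.mean(v)), max(float(np.std(v)), 1e-6)]
    try:
        popt, pcov = curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Gaussian histogram fit failed to converge; histogram counts: "
            f"{counts.tolist()}") from exc
    a, mu, sd = popt
    sd = abs(sd)
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    pred = gauss(centers, *popt)
    ss_res = float(((counts - pred) ** 2).sum())
    ss_tot = float(((counts - counts.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return GaussianFit(mean=float(mu), sd=float(sd), amplitude=float(a),
                       mean_stderr=float(perr[1]), sd_stderr=float(perr[2]),
                       r_squared=r2, poor_fit=r2 < 0.8)
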