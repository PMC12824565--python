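"""Diffusion, motion-class, jump-angle and lifetime analysis of segments.

The diffusion coefficient comes from a weighted linear fit of the first four
points of the time-averaged MSD, ``MSD(t) = 4 D t + 4 sigma_dyn^2``, whose
intercept carries the dynamic localization precision; segments are classified
confined when the long-lag MSD falls below the short-lag linear extrapolation
by more than a threshold (equivalently, the confined model
``MSD(t) = L^2 (1 - exp(-t/tau_c)) + 4 sigma_dyn^2`` reaches its plateau
inside the observation window).  Dimer lifetimes are the FRET-segment
durations, histogrammed and fit with a single exponential decay after
excluding durations above 10 s; group comparisons use the two-sided
Mann-Whitney U test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "MsdResult", "LifetimeFit", "GroupComparison",
    "compute_msd", "fit_msd", "classify_motion", "analyze_segment",
    "compute_jump_angles", "jump_angle_histogram",
    "fit_lifetime", "compare_groups",
]


@dataclass
class MsdResult:
    """MSD curve and fits for one trajectory segment."""

    segment_id: int
    lags_s: np.ndarray
    msd: np.ndarray            # um^2
    counts: np.ndarray         # displacement pairs per lag
    D: float = np.nan          # um^2/s, from the first-four-lag free fit
    D_stderr: float = np.nan
    sigma_dyn_nm: Optional[float] = None  # None when the intercept is negative
    motion_class: str = ""     # "free" | "confined"
    confined_L_um: Optional[float] = None
    confined_tau_s: Optional[float] = None
    free_rss: float = np.nan
    confined_rss: float = np.nan
    deviation: float = np.nan  # relative long-lag deviation below the free line


@dataclass
class LifetimeFit:
    """Single-exponential fit of the dimer-lifetime histogram."""

    tau_s: float
    tau_stderr_s: float
    n_traces: int              # traces entering the histogram (after exclusions)
    n_excluded_long: int       # durations > max_duration_s removed before fitting
    bin_edges_s: np.ndarray
    counts: np.ndarray
    fit_note: str = ""


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    significance: str  # "n.s.", "*", "**", "***"


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

def compute_msd(frames: np.ndarray, xy: np.ndarray, frame_interval: float,
                max_lag: Optional[int] = None
                ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-averaged MSD of one segment with explicit gaps.

    For lag n the mean is over all index pairs (i, i+n) whose two end frames
    are both present; pairs spanning missing frames at their endpoints are
    thereby excluded, so gap-closed frames never contribute interpolated
    displacements.  Returns (lags_s, msd_um2, counts).
    """
    frames = np.asarray(frames, dtype=int)
    xy = np.asarray(xy, dtype=float)
    if len(frames) < 5:
        raise ValueError("segment too short: need >= 5 positions")
    span = int(frames[-1] - frames[0])
    if max_lag is None:
        max_lag = span
    max_lag = min(max_lag, span)
    # dense arrays over the frame span, NaN on missing frames
    dense = np.full((span + 1, 2), np.nan)
    dense[frames - frames[0]] = xy
    lags = np.arange(1, max_lag + 1)
    msd = np.full(len(lags), np.nan)
    counts = np.zeros(len(lags), dtype=int)
    for k, n in enumerate(lags):
        d = dense[n:] - dense[:-n]
        sq = d[:, 0] ** 2 + d[:, 1] ** 2
        good = np.isfinite(sq)
        counts[k] = int(good.sum())
        if counts[k]:
            msd[k] = float(sq[good].mean())
    keep = counts > 0
    return lags[keep] * frame_interval, msd[keep], counts[keep]


def fit_msd(lags_s: np.ndarray, msd: np.ndarray, counts: np.ndarray,
            model: str = "free", n_points: int = 4,
            confined_max_lag: Optional[int] = None) -> dict:
    """Fit the free or confined MSD model.

    free:     MSD(t) = 4 D t + 4 sigma^2, weighted linear least squares on
              the first ``n_points`` lags (weights = pair counts).
    confined: MSD(t) = L^2 (1 - exp(-t/tau_c)) + 4 sigma^2, nonlinear fit
              over lags up to ``confined_max_lag`` (default: all provided).

    A negative intercept leaves D reported but sigma_dyn not estimable.
    """
    lags_s = np.asarray(lags_s, dtype=float)
    msd = np.asarray(msd, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if model == "free":
        if len(lags_s) < 2:
            raise ValueError("need >= 2 lags for the free fit")
        m = min(n_points, len(lags_s))
        t, y, w = lags_s[:m], msd[:m], counts[:m]
        if np.ptp(y) == 0 and np.ptp(t) == 0:
            raise ValueError("singular fit: all lags equal")
        W = np.diag(w)
        X = np.column_stack([t, np.ones(m)])
        A = X.T @ W @ X
        try:
            coef = np.linalg.solve(A, X.T @ W @ y)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular MSD fit") from exc
        slope, intercept = coef
        resid = y - X @ coef
        dof = max(m - 2, 1)
        s2 = float(resid @ W @ resid) / dof
        cov = s2 * np.linalg.inv(A)
        D = slope / 4.0
        D_stderr = math.sqrt(max(cov[0, 0], 0.0)) / 4.0
        if intercept >= 0:
            sigma_dyn_nm = math.sqrt(intercept / 4.0) * 1000.0
        else:
            sigma_dyn_nm = None
        pred = X @ coef
        rss = float(((y - pred) ** 2).sum())
        return {"D": float(D), "D_stderr": float(D_stderr),
                "sigma_dyn_nm": sigma_dyn_nm, "intercept": float(intercept),
                "slope": float(slope), "rss": rss}
    elif model == "confined":
        m = len(lags_s) if confined_max_lag is None else min(confined_max_lag,
                                                             len(lags_s))
        t, y = lags_s[:m], msd[:m]
        if len(t) < 3:
            raise ValueError("need >= 3 lags for the confined fit")

        def conf(tt, L2, tau_c, off):
            return L2 * (1.0 - np.exp(-tt / tau_c)) + off

        L2_0 = max(float(y.max()), 1e-9)
        tau_0 = max(float(t[min(len(t) - 1, max(1, int(np.argmax(y >= 0.63 * y.max()))))]), t[0])
        try:
            popt, pcov = curve_fit(
                conf, t, y, p0=[L2_0, tau_0, 0.0],
                bounds=([0, t[0] / 50.0, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=5000)
        except RuntimeError:
            return {"L_um": None, "tau_c_s": None, "rss": np.inf}
        L2, tau_c, off = popt
        rss = float(((y - conf(t, *popt)) ** 2).sum())
        return {"L_um": math.sqrt(max(L2, 0.0)), "tau_c_s": float(tau_c),
                "offset": float(off), "rss": rss}
    raise ValueError(f"unknown model {model!r}")


def classify_motion(lags_s: np.ndarray, msd: np.ndarray, counts: np.ndarray,
                    free_fit: Optional[dict] = None,
                    theta: float = 0.3, z_gate: float = 0.75,
                    n_positions: Optional[int] = None) -> Tuple[str, float]:
    """Confined/free decision from the long-lag deviation below the free line.

    The free model is fit to the first four lags and extrapolated; the mean
    relative shortfall of the measured MSD over the last half of the
    available lags is the deviation.  A segment is confined when the
    deviation exceeds both ``theta`` (practical significance: the MSD has
    visibly plateaued) and ``z_gate`` times the single-track noise scale of a
    time-averaged MSD at the tail lags, ``sqrt(2 n / (3 (N - n)))`` — without
    the gate, the heavy statistical fluctuation of short-track MSDs
    misclassifies a large fraction of genuinely free segments.  Returns
    (class, deviation).
    """
    if free_fit is None:
        free_fit = fit_msd(lags_s, msd, counts, model="free")
    pred = free_fit["slope"] * lags_s + free_fit["intercept"]
    half = max(len(lags_s) // 2, min(4, len(lags_s) - 1))
    tail = slice(half, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        shortfall = 1.0 - msd[tail] / pred[tail]
    shortfall = shortfall[np.isfinite(shortfall)]
    if not len(shortfall):
        return "free", 0.0
    dev = float(np.average(shortfall, weights=counts[tail][:len(shortfall)]))
    if n_positions is None:
        n_positions = len(lags_s) * 2  # max_lag defaults to half the span
    n_mid = float(np.mean(np.arange(len(lags_s))[tail] + 1))
    sigma_null = math.sqrt(2.0 * n_mid / (3.0 * max(n_positions - n_mid, 1.0)))
    gate = max(theta, z_gate * sigma_null)
    return ("confined" if dev > gate else "free"), dev


def analyze_segment(segment_id: int, frames: np.ndarray, xy: np.ndarray,
                    frame_interval: float, theta: float = 0.3,
                    max_lag: Optional[int] = None) -> MsdResult:
    """MSD + free fit + confined fit + classification for one segment."""
    n_pos = len(frames)
    if max_lag is None:
        max_lag = max(4, n_pos // 2)
    lags_s, msd, counts = compute_msd(frames, xy, frame_interval, max_lag)
    free = fit_msd(lags_s, msd, counts, model="free")
    res = MsdResult(segment_id=segment_id, lags_s=lags_s, msd=msd,
                    counts=counts, D=free["D"], D_stderr=free["D_stderr"],
                    sigma_dyn_nm=free["sigma_dyn_nm"], free_rss=free["rss"])
    if len(lags_s) >= 3:
        conf = fit_msd(lags_s, msd, counts, model="confined")
        res.confined_L_um = conf.get("L_um")
        res.confined_tau_s = conf.get("tau_c_s")
        res.confined_rss = conf.get("rss", np.inf)
    cls, dev = classify_motion(lags_s, msd, counts, free, theta=theta,
                               n_positions=n_pos)
    res.motion_class = cls
    res.deviation = dev
    return res


# ---------------------------------------------------------------------------
# jump angles
# ---------------------------------------------------------------------------

def compute_jump_angles(frames: np.ndarray, xy: np.ndarray,
                        fold: bool = True) -> np.ndarray:
    """Angles between consecutive displacement vectors, degrees.

    Only frame triples (f, f+1, f+2) with all three positions present
    contribute; displacements spanning gaps are excluded.  Angles are folded
    to [0, 180] for histogramming (180 = reversal).  Zero-length
    displacements are skipped.
    """
    frames = np.asarray(frames, dtype=int)
    xy = np.asarray(xy, dtype=float)
    if len(frames) < 3:
        raise ValueError("need >= 3 positions for jump angles")
    span = int(frames[-1] - frames[0])
    dense = np.full((span + 1, 2), np.nan)
    dense[frames - frames[0]] = xy
    v = dense[1:] - dense[:-1]          # displacement f -> f+1
    v1, v2 = v[:-1], v[1:]
    good = np.isfinite(v1).all(axis=1) & np.isfinite(v2).all(axis=1)
    n1 = np.hypot(v1[:, 0], v1[:, 1])
    n2 = np.hypot(v2[:, 0], v2[:, 1])
    good &= (n1 > 0) & (n2 > 0)
    v1, v2 = v1[good], v2[good]
    dot = (v1 * v2).sum(axis=1)
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    ang = np.degrees(np.arctan2(cross, dot))  # (-180, 180]
    if fold:
        ang = np.abs(ang)
    else:
        ang = np.mod(ang, 360.0)
    return ang


def jump_angle_histogram(angles: Sequence[float], n_bins: int = 18
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Relative-frequency histogram over [0, 180], normalized to sum 1."""
    counts, edges = np.histogram(angles, bins=n_bins, range=(0.0, 180.0))
    total = counts.sum()
    freq = counts / total if total else counts.astype(float)
    return edges, freq


# ---------------------------------------------------------------------------
# lifetimes
# ---------------------------------------------------------------------------

def fit_lifetime(durations_s: Sequence[float], frame_interval: float = 0.040,
                 bin_frames=2, max_duration_s: float = 10.0,
                 exclude_first_bin: bool = True,
                 min_durations: int = 30,
                 method: str = "counts") -> LifetimeFit:
    """Single-exponential decay fit to the distribution of FRET durations.

    Durations above ``max_duration_s`` are excluded before fitting (they are
    dominated by immobile aggregates rather than single complexes).  The
    histogram starts at the shortest observed duration — the minimum
    trajectory length censors short dwells, and the exponential's
    memorylessness makes the fit over the observed support unbiased; with
    ``method="counts"`` the first populated bin can additionally be dropped
    (default) to blunt the censoring edge.

    ``method`` selects what A exp(-t/tau) is fit to: ``"counts"`` fits the
    histogram counts; ``"survival"`` fits the empirical survival fraction at
    the bin edges, which is markedly more stable when traces are few.
    ``bin_frames`` is the bin width in frame intervals, or ``"auto"`` to
    target roughly sqrt(n) bins over the observed range.
    """
    d = np.asarray(durations_s, dtype=float)
    d = d[np.isfinite(d)]
    n_long = int((d > max_duration_s).sum())
    d = d[d <= max_duration_s]
    if len(d) < min_durations:
        raise ValueError(f"need >= {min_durations} durations, got {len(d)}")
    if np.ptp(d) == 0:
        raise ValueError("degenerate histogram: all durations equal")
    if bin_frames == "auto":
        n_bins = max(6, int(math.ceil(math.sqrt(len(d)))))
        bin_frames = max(2, int(math.ceil(
            np.ptp(d) / n_bins / frame_interval)))
    width = bin_frames * frame_interval
    # the grid starts exactly at the shortest observed duration: the sample
    # is left-truncated there, and padding the axis below it would fake a
    # flat region of the decay
    lo = float(d.min())
    n_edges = int(np.ceil((d.max() - lo) / width)) + 1
    edges = lo + width * np.arange(n_edges + 1)
    counts, edges = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    populated = np.nonzero(counts > 0)[0]

    def expdec(t, a, tau):
        return a * np.exp(-t / tau)

    tau0 = max(float(np.mean(d) - d.min()), frame_interval)
    note = f"bin width {bin_frames} frames"
    if method == "survival":
        surv = np.array([(d >= t).mean() for t in edges[:-1]])
        use = surv > 0
        if use.sum() < 3:
            raise ValueError("fewer than 3 populated bins")
        popt, pcov = curve_fit(expdec, edges[:-1][use], surv[use],
                               p0=[1.0, tau0],
                               bounds=([0.0, frame_interval / 100.0],
                                       [np.inf, np.inf]), maxfev=10000)
        note += "; survival-fraction fit"
    elif method == "counts":
        use = np.arange(len(counts)) >= populated[0]
        if exclude_first_bin and len(populated) > 3:
            use[populated[0]] = False
            note += "; first populated bin excluded (minimum-length censoring)"
        if (counts[use] > 0).sum() < 3:
            raise ValueError("fewer than 3 populated bins")
        popt, pcov = curve_fit(expdec, centers[use], counts[use].astype(float),
                               p0=[float(counts.max()), tau0],
                               bounds=([0.0, frame_interval / 100.0],
                                       [np.inf, np.inf]), maxfev=10000)
    else:
        raise ValueError(f"unknown method {method!r}")
    tau = float(popt[1])
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return LifetimeFit(tau_s=tau, tau_stderr_s=float(perr[1]),
                       n_traces=len(d), n_excluded_long=n_long,
                       bin_edges_s=edges, counts=counts, fit_note=note)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def msd_results_to_dataframe(results: Sequence[MsdResult],
                             kind: str = "") -> "pd.DataFrame":
    """Per-segment summary table (one row per MsdResult)."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "segment_id": r.segment_id,
            "kind": kind,
            "n_lags": len(r.lags_s),
            "D_um2_s": r.D,
            "D_stderr": r.D_stderr,
            "sigma_dyn_nm": (r.sigma_dyn_nm if r.sigma_dyn_nm is not None
                             else np.nan),
            "motion_class": r.motion_class,
            "deviation": r.deviation,
        })
    return pd.DataFrame(rows)


def compare_groups(d_coeffs_a: Sequence[float],
                   d_coeffs_b: Sequence[float]) -> GroupComparison:
    """Two-sided Mann-Whitney U test between two diffusion-coefficient sets.

    Significance bands: p > 0.05 n.s.; < 0.05 *; < 0.01 **; < 0.001 ***.
    """
    a = np.asarray(d_coeffs_a, dtype=float)
    b = np.asarray(d_coeffs_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 5 or len(b) < 5:
        raise ValueError("each sample needs n >= 5")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    p = float(res.pvalue)
    if p < 0.001:
        sig = "***"
    elif p < 0.01:
        sig = "**"
    elif p < 0.05:
        sig = "*"
    else:
        sig = "n.s."
    return GroupComparison(statistic=float(res.statistic), p_value=p,
                           n_a=len(a), n_b=len(b), significance=sig)
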