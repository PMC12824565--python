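"""Trajectory linking with gap closing and minimum-length filtering.

Frame-to-frame assignment is solved per frame pair by the Hungarian algorithm
on a squared-displacement cost matrix augmented with birth/death dummies
(cost = max_disp^2), the sparse-density equivalent of a LAP tracker.  Track
ends and starts are then merged across gaps of up to ``max_gap`` frames when
the end-start distance is below ``max_disp * sqrt(gap + 1)``.  Gap frames
carry no interpolated coordinates: they are simply absent from the
trajectory, and downstream MSD / jump-angle code skips pairs that span them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["Trajectory", "link_trajectories", "filter_trajectories",
           "trajectories_to_dataframe"]

DEFAULT_MAX_DISP = 4.0 * np.sqrt(4.0 * 0.5 * 0.040)  # ~1.13 um; D_max=0.5 um^2/s


@dataclass
class Trajectory:
    """A time-ordered sequence of sub-pixel localizations in one channel."""

    id: int
    channel: str
    frames: np.ndarray      # (n,) int, strictly increasing; gaps are absent frames
    xy: np.ndarray          # (n, 2) um
    photons: np.ndarray     # (n,)
    precision_nm: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError("trajectory frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def span(self) -> int:
        """Frames spanned, first to last inclusive."""
        if not len(self.frames):
            return 0
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])


def _assign(prev_xy: np.ndarray, cur_xy: np.ndarray, max_disp: float):
    """Hungarian assignment with birth/death dummies; returns (i_prev, i_cur)."""
    n, m = len(prev_xy), len(cur_xy)
    gate2 = max_disp ** 2
    d2 = ((prev_xy[:, None, :] - cur_xy[None, :, :]) ** 2).sum(-1)
    big = 1e12
    cost = np.full((n + m, n + m), 0.0)
    link = np.where(d2 <= gate2, d2, big)
    cost[:n, :m] = link
    cost[:n, m:] = big
    cost[:n, m:][np.arange(n), np.arange(n)] = gate2  # death
    cost[n:, :m] = big
    cost[n:, :m][np.arange(m), np.arange(m)] = gate2  # birth
    rows, cols = linear_sum_assignment(cost)
    out = []
    for r, c in zip(rows, cols):
        if r < n and c < m and cost[r, c] < gate2:
            out.append((r, c))
    return out


def link_trajectories(locs: pd.DataFrame, max_disp: float = DEFAULT_MAX_DISP,
                      max_gap: int = 3) -> List[Trajectory]:
    """Link a localization table (one channel) into trajectories.

    Localizations are first sorted by (frame, x, y), making the output
    invariant to their input ordering within a frame.  Duplicate rows (same
    frame and coordinates) raise, as they should have been merged upstream.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    cols = ["frame", "x_um", "y_um", "photons", "precision_nm"]
    if not len(locs):
        return []
    channel = str(locs["channel"].iloc[0]) if "channel" in locs else ""
    df = locs.sort_values(["frame", "x_um", "y_um"], kind="mergesort")
    dup = df.duplicated(subset=["frame", "x_um", "y_um"])
    if dup.any():
        raise ValueError("duplicate localization (same frame and coordinates)")

    frames_arr = df["frame"].to_numpy(dtype=int)
    xy_arr = df[["x_um", "y_um"]].to_numpy(dtype=float)
    ph_arr = (df["photons"].to_numpy(dtype=float) if "photons" in df
              else np.zeros(len(df)))
    pr_arr = (df["precision_nm"].to_numpy(dtype=float) if "precision_nm" in df
              else np.full(len(df), np.nan))

    unique_frames = np.unique(frames_arr)
    by_frame = {f: np.nonzero(frames_arr == f)[0] for f in unique_frames}

    # frame-to-frame linking between consecutive occupied frame pairs
    track_of = np.full(len(df), -1, dtype=int)
    tracks: List[List[int]] = []
    prev_frame: Optional[int] = None
    for f in unique_frames:
        cur_idx = by_frame[f]
        if prev_frame is not None and f - prev_frame == 1:
            prev_idx = by_frame[prev_frame]
            matches = _assign(xy_arr[prev_idx], xy_arr[cur_idx], max_disp)
        else:
            matches = []
        matched_cur = set()
        for r, c in matches:
            tid = track_of[prev_idx[r]]
            tracks[tid].append(int(cur_idx[c]))
            track_of[cur_idx[c]] = tid
            matched_cur.add(c)
        for c, gi in enumerate(cur_idx):
            if c not in matched_cur:
                track_of[gi] = len(tracks)
                tracks.append([int(gi)])
        prev_frame = int(f)

    # gap closing: match track ends to track starts across 2..max_gap+1 frames
    if max_gap > 0 and len(tracks) > 1:
        ends = np.array([t[-1] for t in tracks])
        starts = np.array([t[0] for t in tracks])
        end_f = frames_arr[ends]
        start_f = frames_arr[starts]
        cand = []
        for i in range(len(tracks)):
            for j in range(len(tracks)):
                if i == j:
                    continue
                gap = start_f[j] - end_f[i] - 1
                if 1 <= gap <= max_gap:
                    dist = np.hypot(*(xy_arr[starts[j]] - xy_arr[ends[i]]))
                    gate = max_disp * np.sqrt(gap + 1)
                    if dist <= gate:
                        cand.append((i, j, dist ** 2))
        if cand:
            is_ = sorted({i for i, _, _ in cand})
            js_ = sorted({j for _, j, _ in cand})
            ni, nj = len(is_), len(js_)
            imap = {v: k for k, v in enumerate(is_)}
            jmap = {v: k for k, v in enumerate(js_)}
            gate2 = (max_disp * np.sqrt(max_gap + 1)) ** 2
            big = 1e12
            cost = np.full((ni + nj, ni + nj), 0.0)
            cost[:ni, :nj] = big
            for i, j, c2 in cand:
                cost[imap[i], jmap[j]] = c2
            cost[:ni, nj:] = big
            cost[:ni, nj:][np.arange(ni), np.arange(ni)] = gate2
            cost[ni:, :nj] = big
            cost[ni:, :nj][np.arange(nj), np.arange(nj)] = gate2
            rows, cols = linear_sum_assignment(cost)
            successor = {}
            for r, c in zip(rows, cols):
                if r < ni and c < nj and cost[r, c] < gate2:
                    successor[is_[r]] = js_[c]
            # chain-merge linked tracks
            merged_into = {}
            for i in sorted(successor):
                root = i
                while root in merged_into:
                    root = merged_into[root]
                j = successor[i]
                tracks[root].extend(tracks[j])
                tracks[j] = []
                merged_into[j] = root
            tracks = [t for t in tracks if t]

    out = []
    order = sorted(range(len(tracks)),
                   key=lambda k: (frames_arr[tracks[k][0]],
                                  xy_arr[tracks[k][0], 0],
                                  xy_arr[tracks[k][0], 1]))
    for new_id, k in enumerate(order):
        idx = np.array(tracks[k])
        out.append(Trajectory(
            id=new_id, channel=channel, frames=frames_arr[idx],
            xy=xy_arr[idx], photons=ph_arr[idx], precision_nm=pr_arr[idx]))
    return out


def filter_trajectories(trajs: List[Trajectory],
                        min_length: int = 20) -> List[Trajectory]:
    """Drop trajectories spanning fewer than ``min_length`` frames."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    return [t for t in trajs if t.span >= min_length]


def trajectories_to_dataframe(trajs: List[Trajectory]) -> pd.DataFrame:
    rows = []
    for t in trajs:
        for k in range(len(t)):
            rows.append((t.id, t.channel, int(t.frames[k]), t.xy[k, 0],
                         t.xy[k, 1], t.photons[k], t.precision_nm[k]))
    return pd.DataFrame(rows, columns=["traj_id", "channel", "frame", "x_um",
                                       "y_um", "photons", "precision_nm"])
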