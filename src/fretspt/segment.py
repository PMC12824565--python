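"""Split accepted FRET traces into FRET-active and donor-only segments.

The three-step assignment: (1) donor and acceptor localizations of the same
frame closer than ``merge_radius`` are merged to one precision-weighted
position; (2) donor coordinates with a spatially matched acceptor are the
FRET segment; (3) donor coordinates without an acceptor match after the
acceptor loss form the donor-only segment.  Where the spatial boundary and
the intensity change point disagree by a few frames, the intensity change
point wins — it is the primary acceptance signal.

The termination pathway follows from the segmentation: a non-empty
donor-only segment means the dimer dissociated and the donor-labeled
receptor diffused on (pathway 1); donor and acceptor vanishing together
means the whole complex was lost, e.g. internalized (pathway 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fretscore import FretTrace

__all__ = ["SegmentedTrajectory", "merge_repeated_localizations",
           "segment_trajectory", "classify_pathway", "segments_to_dataframe"]


@dataclass
class SegmentedTrajectory:
    """FRET-active and donor-only coordinate segments of one accepted trace."""

    trace_id: int
    fret_frames: np.ndarray        # (n1,) absolute frame indices
    fret_xy: np.ndarray            # (n1, 2) um (merged donor/acceptor positions)
    donor_only_frames: np.ndarray  # (n2,) may be empty
    donor_only_xy: np.ndarray
    pathway: int                   # 1 or 2
    fret_duration_s: float
    frame_interval: float
    too_short_for_msd: bool = False
    edge_censored: bool = False    # FRET segment ends near the field border

    @property
    def n_fret_frames(self) -> int:
        return len(self.fret_frames)


def merge_repeated_localizations(
    donor_xy: np.ndarray,
    acceptor_xy: np.ndarray,
    donor_prec_nm: Optional[np.ndarray] = None,
    acceptor_prec_nm: Optional[np.ndarray] = None,
    merge_radius_nm: float = 250.0,
) -> np.ndarray:
    """Merge per-frame donor/acceptor positions into one coordinate series.

    Inputs are (n, 2) arrays on a shared frame axis (acceptor already in
    donor-channel coordinates; NaN where absent).  Pairs closer than the
    merge radius are replaced by the inverse-variance (precision) weighted
    mean; unmatched positions pass through unchanged.
    """
    donor_xy = np.asarray(donor_xy, dtype=float)
    acceptor_xy = np.asarray(acceptor_xy, dtype=float)
    n = len(donor_xy)
    if donor_prec_nm is None:
        donor_prec_nm = np.full(n, 20.0)
    if acceptor_prec_nm is None:
        acceptor_prec_nm = np.full(n, 20.0)
    radius_um = merge_radius_nm / 1000.0
    out = np.full((n, 2), np.nan)
    has_d = np.isfinite(donor_xy).all(axis=1)
    has_a = np.isfinite(acceptor_xy).all(axis=1)
    for i in range(n):
        if has_d[i] and has_a[i]:
            dist = np.hypot(*(donor_xy[i] - acceptor_xy[i]))
            if dist <= radius_um:
                wd = 1.0 / max(donor_prec_nm[i], 1e-6) ** 2
                wa = 1.0 / max(acceptor_prec_nm[i], 1e-6) ** 2
                out[i] = (wd * donor_xy[i] + wa * acceptor_xy[i]) / (wd + wa)
            else:
                out[i] = donor_xy[i]  # donor channel is the reference frame
        elif has_d[i]:
            out[i] = donor_xy[i]
        elif has_a[i]:
            out[i] = acceptor_xy[i]
    return out


def segment_trajectory(
    trace: FretTrace,
    frame_interval: float,
    merge_radius_nm: float = 250.0,
    max_gap: int = 3,
    min_msd_positions: int = 5,
) -> SegmentedTrajectory:
    """Split one accepted trace at its acceptor loss.

    The FRET segment holds frames up to the intensity-derived acceptor loss
    that carry a spatially matched acceptor (or the merged position); the
    donor-only segment holds donor positions after the loss.  The FRET
    duration is the number of FRET-segment frames (gap frames inside the
    segment count only when flanked by FRET frames) times the frame
    interval.
    """
    if not trace.accepted:
        raise ValueError("trace must be accepted before segmentation")
    if trace.acceptor_loss_frame is None:
        raise ValueError("accepted trace lacks acceptor_loss_frame")

    prec = (trace.precision_nm if trace.precision_nm is not None
            else np.full(len(trace), 20.0))
    merged = merge_repeated_localizations(
        trace.xy_donor, trace.xy_acceptor, prec, prec, merge_radius_nm)

    # the intensity change point is the boundary authority; acceptor-channel
    # detections after it are donor leakage, not a FRET partner
    boundary = trace.loss_index()

    has_pos = np.isfinite(merged).all(axis=1)
    fret_sel = np.nonzero(has_pos[:boundary])[0]
    has_d = np.isfinite(trace.xy_donor).all(axis=1)
    donor_sel = boundary + np.nonzero(has_d[boundary:])[0]

    # spatial continuity gate: the donor-only part must resume within the
    # search radius (scaled by the gap length) of the last FRET position,
    # otherwise the tracker grafted a different molecule's track onto a
    # complex that actually vanished
    if len(donor_sel) and len(fret_sel):
        last_xy = merged[fret_sel[-1]]
        first_xy = merged[donor_sel[0]] if np.isfinite(
            merged[donor_sel[0]]).all() else trace.xy_donor[donor_sel[0]]
        gap = max(int(donor_sel[0] - fret_sel[-1]), 1)
        gate_um = merge_radius_nm / 1000.0 * np.sqrt(gap)
        if np.hypot(*(first_xy - last_xy)) > gate_um:
            donor_sel = donor_sel[:0]

    f0 = int(trace.frames[0])
    fret_frames = f0 + fret_sel
    donor_frames = f0 + donor_sel

    # duration: FRET frames plus interior gap frames flanked by FRET frames
    if len(fret_sel):
        n_fret = int(fret_sel[-1] - fret_sel[0] + 1)
    else:
        n_fret = 0
    duration = n_fret * frame_interval

    seg = SegmentedTrajectory(
        trace_id=trace.donor_traj_id,
        fret_frames=fret_frames, fret_xy=merged[fret_sel],
        donor_only_frames=donor_frames, donor_only_xy=merged[donor_sel],
        pathway=0, fret_duration_s=duration, frame_interval=frame_interval,
        too_short_for_msd=len(fret_sel) < min_msd_positions)
    seg.pathway = classify_pathway(seg, max_gap=max_gap)
    return seg


def classify_pathway(seg: SegmentedTrajectory, max_gap: int = 3) -> int:
    """1 when the donor persists after acceptor loss, else 2.

    A handful of donor frames within the gap-closing window of the loss do
    not count as persistence (they are the tail of the same detection).
    """
    if len(seg.donor_only_frames) == 0:
        return 2
    if len(seg.fret_frames):
        last_fret = seg.fret_frames[-1]
        persistent = np.sum(seg.donor_only_frames > last_fret + max_gap)
        return 1 if persistent > 0 else 2
    return 1


def segments_to_dataframe(segs: Sequence[SegmentedTrajectory]) -> pd.DataFrame:
    rows = []
    for s in segs:
        for f, (x, y) in zip(s.fret_frames, s.fret_xy):
            rows.append((s.trace_id, "fret", int(f), x, y))
        for f, (x, y) in zip(s.donor_only_frames, s.donor_only_xy):
            rows.append((s.trace_id, "donor_only", int(f), x, y))
    return pd.DataFrame(rows, columns=["trace_id", "segment", "frame",
                                       "x_um", "y_um"])
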