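"""End-to-end analysis: movie -> localizations -> trajectories -> FRET traces
-> segments -> diffusion, lifetime and pathway statistics.

`analyze_movie` runs the full chain on one two-channel movie;
`pool_results` aggregates several movies into the study-level numbers
(lifetime tau, per-segment diffusion coefficients and their Mann-Whitney
comparison, FRET-efficiency histogram peak, confined fractions, pathway-1
fraction).  `run_study` simulates and analyzes a batch of movies from one
config — the synthetic counterpart of a measurement day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from . import dynamics, fretscore, segment
from .fretscore import CorrectionFactors, FretTrace, build_fret_trace
from .localize import ChannelTransform, DetectionParams, localize_movie
from .simulate import Movie, SimulationConfig, SimulationTruth, simulate_movie
from .track import Trajectory, filter_trajectories, link_trajectories

__all__ = ["AnalysisParams", "MovieResult", "StudySummary", "analyze_movie",
           "pool_results", "run_study"]


@dataclass
class AnalysisParams:
    """All pipeline knobs in one place (defaults follow the acquisition)."""

    detection: Optional[DetectionParams] = None
    max_disp_um: float = 1.1
    max_gap: int = 3
    min_length: int = 20
    pair_radius_nm: float = 250.0
    merge_radius_nm: float = 250.0
    concat_radius_nm: float = 250.0
    vet_window: int = 5
    vet_k_sigma: float = 2.0
    theta_confined: float = 0.3
    min_msd_positions: int = 5
    delta_fallback: Optional[float] = None
    aperture_px: int = 3
    # a FRET segment ending this close to the field border may simply have
    # diffused out of view: censored, excluded from lifetime/pathway stats
    edge_margin_um: float = 1.0


@dataclass
class MovieResult:
    """Per-movie pipeline output."""

    traces: List[FretTrace]              # accepted FRET traces
    rejected: List[FretTrace]
    segments: List[segment.SegmentedTrajectory]
    factors: Optional[CorrectionFactors]
    fret_msd: List[dynamics.MsdResult]
    donor_only_msd: List[dynamics.MsdResult]
    durations_s: List[float]
    mean_E: List[float]                  # per accepted trace
    n_donor_trajs: int = 0
    n_acceptor_trajs: int = 0


@dataclass
class StudySummary:
    """Pooled study-level numbers."""

    lifetime: Optional[dynamics.LifetimeFit]
    D_fret: np.ndarray
    D_donor_only: np.ndarray
    comparison: Optional[dynamics.GroupComparison]
    e_fit: Optional[fretscore.GaussianFit]
    confined_fraction_fret: float
    confined_fraction_donor_only: float
    pathway1_fraction: float
    n_traces: int
    theta_confined: float


def analyze_movie(movie: Movie,
                  transform: Optional[ChannelTransform] = None,
                  params: Optional[AnalysisParams] = None,
                  factors: Optional[CorrectionFactors] = None) -> MovieResult:
    """Run localization, tracking, FRET vetting and segmentation on one movie."""
    p = params or AnalysisParams()
    cfg = movie.config
    det = p.detection or DetectionParams(psf_sigma_nm=cfg.psf_sigma)
    transform = transform or ChannelTransform.identity()

    locs = localize_movie(movie, det)
    donor_trajs = filter_trajectories(
        link_trajectories(locs[locs["channel"] == "donor"],
                          p.max_disp_um, p.max_gap), p.min_length)
    acceptor_trajs = filter_trajectories(
        link_trajectories(locs[locs["channel"] == "acceptor"],
                          p.max_disp_um, p.max_gap), p.min_length)

    pairs, donor_only_trajs, _acc_only = fretscore.pair_trajectories(
        donor_trajs, acceptor_trajs, transform, p.pair_radius_nm)

    stacks = fretscore.photon_converted_stacks(movie)
    accepted: List[FretTrace] = []
    rejected: List[FretTrace] = []
    donor_pool = list(donor_only_trajs)
    for d, a in pairs:
        trace = build_fret_trace(movie, d, a, transform,
                                 aperture_px=p.aperture_px,
                                 photon_stacks=stacks)
        trace = fretscore.vet_fret_trace(trace, p.vet_window, p.vet_k_sigma)
        if trace.accepted:
            trace = fretscore.concatenate_donor(
                trace, donor_pool, movie, transform,
                p.concat_radius_nm, p.max_gap, photon_stacks=stacks)
            if trace.concatenated_traj_id is not None:
                donor_pool = [t for t in donor_pool
                              if t.id != trace.concatenated_traj_id]
            accepted.append(trace)
        else:
            rejected.append(trace)

    # calibration traces: donor-only trajectories get their own intensity
    # series; donors whose acceptor-channel track was pure leakage (rejected
    # with no acceptor loss and a leakage-level I_AD/I_DD) also qualify
    donor_only_traces = [build_fret_trace(movie, t, None, transform,
                                          aperture_px=p.aperture_px,
                                          photon_stacks=stacks)
                         for t in donor_pool]
    for trace in rejected:
        if trace.reason not in ("no acceptor loss", "acceptor at leakage level"):
            continue
        dd = np.nanmean(trace.I_DD)
        ad = np.nanmean(trace.I_AD)
        if dd > 0 and 0 <= ad / dd < 0.2:
            donor_only_traces.append(trace)
    if factors is None:
        try:
            factors = fretscore.estimate_correction_factors(
                donor_only_traces, [], accepted, window=p.vet_window,
                delta_fallback=p.delta_fallback)
        except ValueError:
            factors = None

    segments: List[segment.SegmentedTrajectory] = []
    fret_msd: List[dynamics.MsdResult] = []
    donor_msd: List[dynamics.MsdResult] = []
    durations: List[float] = []
    mean_E: List[float] = []
    for trace in accepted:
        if factors is not None:
            e = fretscore.compute_fret_efficiency(trace, factors)
            li = trace.loss_index()
            ev = e[:li] if li else e
            ev = ev[np.isfinite(ev)]
            if len(ev):
                mean_E.append(float(np.mean(ev)))
        seg = segment.segment_trajectory(
            trace, cfg.frame_interval, p.merge_radius_nm, p.max_gap,
            p.min_msd_positions)
        if len(seg.fret_frames):
            h_um, w_um = cfg.field_um
            x, y = seg.fret_xy[-1]
            m = p.edge_margin_um
            seg.edge_censored = (x < m or y < m or x > w_um - m
                                 or y > h_um - m)
        segments.append(seg)
        durations.append(seg.fret_duration_s)
        if not seg.too_short_for_msd:
            try:
                fret_msd.append(dynamics.analyze_segment(
                    trace.donor_traj_id, seg.fret_frames, seg.fret_xy,
                    cfg.frame_interval, theta=p.theta_confined))
            except ValueError:
                pass
        if len(seg.donor_only_frames) >= p.min_msd_positions:
            try:
                donor_msd.append(dynamics.analyze_segment(
                    trace.donor_traj_id, seg.donor_only_frames,
                    seg.donor_only_xy, cfg.frame_interval,
                    theta=p.theta_confined))
            except ValueError:
                pass

    return MovieResult(traces=accepted, rejected=rejected, segments=segments,
                       factors=factors, fret_msd=fret_msd,
                       donor_only_msd=donor_msd, durations_s=durations,
                       mean_E=mean_E, n_donor_trajs=len(donor_trajs),
                       n_acceptor_trajs=len(acceptor_trajs))


def pool_results(results: Sequence[MovieResult],
                 frame_interval: float = 0.040,
                 theta_confined: float = 0.3,
                 min_durations: int = 30,
                 min_duration_s: Optional[float] = None,
                 min_length: int = 20,
                 lifetime_max_duration_s: float = 10.0) -> StudySummary:
    """Aggregate per-movie results into study-level statistics.

    Durations below the minimum-trajectory-length cutoff are dropped from
    the lifetime, pathway and FRET-segment diffusion statistics: below that
    cutoff a FRET segment is observable only when its donor survives long
    enough to carry the trajectory past the length filter — a condition met
    by dissociation (pathway 1) but never by complex loss (pathway 2) — so
    keeping them would skew both the dwell histogram and the pathway split.
    """
    if min_duration_s is None:
        min_duration_s = min_length * frame_interval
    long_ids = {(i, s.trace_id) for i, r in enumerate(results)
                for s in r.segments if s.fret_duration_s >= min_duration_s}
    # a trace whose FRET part ends at the field border may have diffused out
    # of view rather than lost its acceptor: censored for kinetics
    uncensored = {(i, s.trace_id) for i, r in enumerate(results)
                  for s in r.segments if not s.edge_censored}
    kinetic_ids = long_ids & uncensored
    durations = [s.fret_duration_s for i, r in enumerate(results)
                 for s in r.segments if (i, s.trace_id) in kinetic_ids]
    d_fret = np.array([m.D for i, r in enumerate(results)
                       for m in r.fret_msd if (i, m.segment_id) in long_ids])
    d_donor = np.array([m.D for r in results for m in r.donor_only_msd])
    e_values = [e for r in results for e in r.mean_E]
    pathways = [s.pathway for i, r in enumerate(results)
                for s in r.segments if (i, s.trace_id) in kinetic_ids]

    lifetime = None
    if len(durations) >= min_durations:
        try:
            # pooled studies rarely have thousands of traces; the
            # survival-fraction fit with auto bins is the stable choice there
            lifetime = dynamics.fit_lifetime(
                durations, frame_interval, bin_frames="auto",
                method="survival", min_durations=min_durations,
                max_duration_s=lifetime_max_duration_s)
        except (ValueError, RuntimeError):
            lifetime = None
    comparison = None
    if len(d_fret) >= 5 and len(d_donor) >= 5:
        comparison = dynamics.compare_groups(d_fret, d_donor)
    e_fit = None
    if len(e_values) >= 30:
        try:
            e_fit = fretscore.fit_gaussian_histogram(e_values, bins=30,
                                                     range_=(0.0, 1.2))
        except (ValueError, RuntimeError):
            e_fit = None

    def _confined_fraction(msds):
        if not msds:
            return float("nan")
        return float(np.mean([m.motion_class == "confined" for m in msds]))

    p1 = float(np.mean([p == 1 for p in pathways])) if pathways else float("nan")
    return StudySummary(
        lifetime=lifetime, D_fret=d_fret, D_donor_only=d_donor,
        comparison=comparison, e_fit=e_fit,
        confined_fraction_fret=_confined_fraction(
            [m for i, r in enumerate(results) for m in r.fret_msd
             if (i, m.segment_id) in long_ids]),
        confined_fraction_donor_only=_confined_fraction(
            [m for r in results for m in r.donor_only_msd]),
        pathway1_fraction=p1,
        n_traces=sum(len(r.traces) for r in results),
        theta_confined=theta_confined)


def bleach_corrected_lifetime(tau_apparent_s: float,
                              tau_bleach_s: float) -> float:
    """Remove the photobleaching contribution from an apparent dwell time.

    FRET loss is a competing-risk process: dissociation at rate 1/tau_true
    and dye bleaching at rate 1/tau_bleach end the FRET segment
    independently, so 1/tau_apparent = 1/tau_true + 1/tau_bleach.
    ``tau_bleach_s`` comes from a no-dissociation control measurement (fixed
    cells in the live experiment; a k_off = 0 simulation here).
    """
    rate = 1.0 / tau_apparent_s - 1.0 / tau_bleach_s
    if rate <= 0:
        raise ValueError("bleach-limited lifetime must exceed the apparent "
                         "lifetime for a meaningful correction")
    return 1.0 / rate


def run_study(base_config: SimulationConfig, n_movies: int, seed: int,
              params: Optional[AnalysisParams] = None,
              lifetime_max_duration_s: float = 10.0) -> StudySummary:
    """Simulate and analyze ``n_movies`` movies differing only in seed."""
    params = params or AnalysisParams()
    results = []
    for k in range(n_movies):
        cfg = replace(base_config, seed=int(seed + k))
        movie, _truth = simulate_movie(cfg)
        results.append(analyze_movie(movie, params=params))
    return pool_results(results, base_config.frame_interval,
                        params.theta_confined,
                        min_length=params.min_length,
                        lifetime_max_duration_s=lifetime_max_duration_s)
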