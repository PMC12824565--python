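"""Ground-truthed synthetic two-channel TIRF movies and intensity traces.

Emulates live-cell single-molecule FRET imaging of membrane receptor dimers:
sparse emitters diffuse in 2-D (Brownian, optionally confined to a reflecting
disk), interconvert dimer -> monomer with exponential dwell times, transfer
energy from a donor to an acceptor dye while dimeric, bleach in a single step,
and are imaged as Gaussian spots on a split-field camera (left half donor
emission, right half acceptor emission, both under donor excitation).

Every stochastic draw comes from one seeded generator, so a config with a seed
reproduces its movie bit for bit.  The per-emitter, per-frame photon counts
actually placed in the image are recorded in :class:`SimulationTruth`, which is
the oracle used by the localization, tracking, vetting and diffusion tests.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import tifffile
from scipy.special import erf

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "Movie",
    "simulate_state_trajectories",
    "render_movie",
    "simulate_movie",
    "simulate_bead_movie",
    "simulate_intensity_trace",
    "simulate_trace_set",
]

# state codes used in SimulationTruth.state
STATE_MONOMER = 0
STATE_DIMER = 1
STATE_GONE = 2  # internalized or left the field; no signal from here on

_STATE_NAMES = {STATE_MONOMER: "monomer", STATE_DIMER: "dimer", STATE_GONE: "internalized"}


@dataclass
class SimulationConfig:
    """Acquisition geometry, motion, kinetics and photophysics of one movie.

    Geometry and timing default to the live-cell acquisition this package
    models: a 512 x 256 px camera frame split into two 256 x 256 px emission
    channels, 159 nm effective pixel size, 40 ms frame interval.

    Parameters
    ----------
    field_size : (height, width) of ONE channel in pixels.
    pixel_size : nm per pixel.
    frame_interval : s between frames.
    n_frames : number of frames.
    emitter_density : emitters per um^2 at the start of the movie.
    D_monomer, D_dimer : diffusion coefficients, um^2/s.
    k_off : dimer dissociation rate, 1/s.
    p_internalize : probability that a dissociation event removes both
        signals (pathway 2); otherwise the donor-labeled receptor continues
        as a diffusing monomer (pathway 1).
    confinement_radius : nm; when set, each emitter is confined to a
        reflecting disk of this radius around its initial position.
    E_true : FRET efficiency of the dimer state.
    photons_donor : expected detected donor photons per frame for an
        unquenched donor (E = 0).
    photons_acceptor : expected detected acceptor photons per frame under
        direct acceptor excitation (sets the scale of direct excitation).
    leak_alpha_true : donor emission leakage fraction into the acceptor
        channel (alpha).
    direct_delta_true : acceptor direct-excitation fraction under donor
        excitation (delta), relative to photons_acceptor.
    gamma_true : acceptor/donor detection-efficiency and quantum-yield
        imbalance (gamma).
    bleach_rate_donor, bleach_rate_acceptor : 1/s single-step bleach rates.
    background_mean : photons per pixel per frame.
    psf_sigma : nm, width of the symmetric Gaussian PSF.
    camera_gain : ADU per photon; camera_baseline : ADU offset.
    dimer_fraction : fraction of emitters born dimeric (the rest are born
        monomeric; association is not simulated).
    donor_only_dimer_fraction : fraction of dimers carrying no acceptor
        (incomplete labeling): dimer mobility, monomer photophysics.
    acceptor_misalignment : optional 6 affine coefficients (a, b, tx, c, d,
        ty) applied to channel-local positions (um) when rendering the
        acceptor half, emulating image-splitter misregistration.
    seed : RNG seed; same seed -> byte-identical movie.
    """

    field_size: Tuple[int, int] = (256, 256)
    pixel_size: float = 159.0
    frame_interval: float = 0.040
    n_frames: int = 600
    emitter_density: float = 0.05
    D_monomer: float = 0.109
    D_dimer: float = 0.066
    k_off: float = 1.0 / 1.13
    p_internalize: float = 0.7
    confinement_radius: Optional[float] = None
    E_true: float = 0.90
    photons_donor: float = 3000.0
    photons_acceptor: float = 3000.0
    leak_alpha_true: float = 0.05
    direct_delta_true: float = 0.02
    gamma_true: float = 1.1
    bleach_rate_donor: float = 0.03
    bleach_rate_acceptor: float = 0.03
    background_mean: float = 10.0
    psf_sigma: float = 150.0
    camera_gain: float = 2.0
    camera_baseline: float = 100.0
    dimer_fraction: float = 0.5
    donor_only_dimer_fraction: float = 0.0
    acceptor_misalignment: Optional[Tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        nonneg = {
            "emitter_density": self.emitter_density,
            "D_monomer": self.D_monomer,
            "D_dimer": self.D_dimer,
            "k_off": self.k_off,
            "photons_donor": self.photons_donor,
            "photons_acceptor": self.photons_acceptor,
            "leak_alpha_true": self.leak_alpha_true,
            "direct_delta_true": self.direct_delta_true,
            "bleach_rate_donor": self.bleach_rate_donor,
            "bleach_rate_acceptor": self.bleach_rate_acceptor,
            "background_mean": self.background_mean,
            "camera_gain": self.camera_gain,
            "camera_baseline": self.camera_baseline,
        }
        for name, value in nonneg.items():
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        if not (0.0 <= self.E_true <= 1.0):
            raise ValueError(f"E_true must be in [0, 1], got {self.E_true}")
        for name in ("p_internalize", "dimer_fraction", "donor_only_dimer_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frame_interval <= 0 or not np.isfinite(self.frame_interval):
            raise ValueError("frame_interval must be > 0")
        if self.gamma_true <= 0:
            raise ValueError("gamma_true must be > 0")
        if self.psf_sigma <= 0 or self.pixel_size <= 0:
            raise ValueError("psf_sigma and pixel_size must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.confinement_radius is not None and self.confinement_radius <= 0:
            raise ValueError("confinement_radius must be > 0 or None")

    # -- convenience geometry ------------------------------------------------
    @property
    def field_um(self) -> Tuple[float, float]:
        """(height, width) of one channel in um."""
        h, w = self.field_size
        return (h * self.pixel_size / 1000.0, w * self.pixel_size / 1000.0)

    @property
    def area_um2(self) -> float:
        h, w = self.field_um
        return h * w

    def to_text(self, path) -> None:
        """Write the config as a flat ``key = value`` text file."""
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_text(cls, path) -> "SimulationConfig":
        raw = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                raw[key.strip()] = val.strip()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            val = raw[f.name]
            if val == "None":
                kwargs[f.name] = None
            elif f.name in ("field_size", "acceptor_misalignment"):
                parts = [float(x) for x in val.split(",")]
                if f.name == "field_size":
                    kwargs[f.name] = (int(parts[0]), int(parts[1]))
                else:
                    kwargs[f.name] = tuple(parts)
            elif f.name in ("n_frames", "seed"):
                kwargs[f.name] = int(val)
            else:
                kwargs[f.name] = float(val)
        return cls(**kwargs)


@dataclass
class SimulationTruth:
    """Per-emitter, per-frame ground truth for one simulated movie.

    Arrays are indexed ``[emitter, frame]``; positions are channel-local um
    (x rightward, y downward, origin at the channel's top-left corner) and are
    NaN once an emitter has internalized or left the field.
    """

    xy: np.ndarray                 # (n, T, 2) um, NaN when gone
    state: np.ndarray              # (n, T) int8 state codes
    donor_bleached: np.ndarray     # (n, T) bool
    acceptor_bleached: np.ndarray  # (n, T) bool
    dissociation_frame: np.ndarray  # (n,) int, -1 if never dissociated in-movie
    pathway: np.ndarray            # (n,) int, 0 none / 1 / 2
    has_acceptor: np.ndarray       # (n,) bool (False for donor-only dimers and monomers)
    born_dimer: np.ndarray         # (n,) bool
    dwell_time_s: np.ndarray       # (n,) continuous exponential dwell draw (NaN for monomers)
    donor_photons: Optional[np.ndarray] = None    # (n, T) realized photons, filled by render
    acceptor_photons: Optional[np.ndarray] = None

    @property
    def n_emitters(self) -> int:
        return self.xy.shape[0]

    @property
    def n_frames(self) -> int:
        return self.xy.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        n, T = self.state.shape
        emitter = np.repeat(np.arange(n), T)
        frames = np.tile(np.arange(T), n)
        state_names = np.array([_STATE_NAMES[STATE_MONOMER], _STATE_NAMES[STATE_DIMER],
                                _STATE_NAMES[STATE_GONE]])
        df = pd.DataFrame({
            "frame": frames,
            "emitter_id": emitter,
            "x_um": self.xy[..., 0].ravel(),
            "y_um": self.xy[..., 1].ravel(),
            "state": state_names[self.state.ravel()],
            "donor_bleached": self.donor_bleached.ravel(),
            "acceptor_bleached": self.acceptor_bleached.ravel(),
            "pathway": np.repeat(self.pathway, T),
        })
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.6f")


@dataclass
class Movie:
    """A two-channel image stack: left half donor, right half acceptor."""

    frames: np.ndarray  # (T, H, 2W) uint16
    config: SimulationConfig

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def channel_split(self) -> int:
        return self.config.field_size[1]

    def donor(self) -> np.ndarray:
        return self.frames[:, :, : self.channel_split]

    def acceptor(self) -> np.ndarray:
        return self.frames[:, :, self.channel_split:]

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.frames, photometric="minisblack")

    @classmethod
    def from_tiff(cls, path, config: SimulationConfig) -> "Movie":
        return cls(frames=np.asarray(tifffile.imread(path)), config=config)


# ---------------------------------------------------------------------------
# state simulation
# ---------------------------------------------------------------------------

def _reflect_disk(xy: np.ndarray, center: np.ndarray, radius_um: float) -> np.ndarray:
    """Reflect positions radially back into a disk of radius_um around center."""
    d = xy - center
    r = np.hypot(d[..., 0], d[..., 1])
    out = r > radius_um
    if np.any(out):
        # radial reflection r -> 2R - r (a second bounce is negligible for
        # per-frame steps much smaller than R, but clamp to stay inside)
        r_new = np.clip(2.0 * radius_um - r[out], 0.0, radius_um)
        scale = np.where(r[out] > 0, r_new / r[out], 0.0)
        d[out] *= scale[:, None]
    return center + d


def simulate_state_trajectories(config: SimulationConfig) -> SimulationTruth:
    """Draw emitter states and positions for every frame of one movie.

    Emitters are born at frame 0, monomeric or dimeric (``dimer_fraction``);
    association is not simulated.  Dimer dwell times are exponential with mean
    1/k_off, discretized to whole frames; dissociation takes pathway 2
    (internalization: both signals vanish) with probability ``p_internalize``,
    else pathway 1 (the donor-labeled receptor diffuses on as a monomer).
    Positions take Brownian steps with the current state's D (variance
    2*D*dt per axis), reflected at the confinement boundary when
    ``confinement_radius`` is set; emitters that leave the field are marked
    gone from that frame (never clipped or wrapped).
    """
    rng = np.random.default_rng(config.seed)
    T = config.n_frames
    dt = config.frame_interval
    h_um, w_um = config.field_um
    n = int(round(config.emitter_density * config.area_um2))

    xy = np.full((n, T, 2), np.nan)
    state = np.full((n, T), STATE_GONE, dtype=np.int8)
    donor_bleached = np.zeros((n, T), dtype=bool)
    acceptor_bleached = np.zeros((n, T), dtype=bool)
    dissociation_frame = np.full(n, -1, dtype=np.int64)
    pathway = np.zeros(n, dtype=np.int64)
    dwell_time_s = np.full(n, np.nan)

    born_dimer = rng.random(n) < config.dimer_fraction
    donor_only = born_dimer & (rng.random(n) < config.donor_only_dimer_fraction)
    has_acceptor = born_dimer & ~donor_only

    # continuous-time draws (recorded pre-discretization for oracle tests)
    if config.k_off > 0:
        dwell = rng.exponential(1.0 / config.k_off, size=n)
    else:
        dwell = np.full(n, np.inf)
    dwell_time_s[born_dimer] = dwell[born_dimer]
    internalize = rng.random(n) < config.p_internalize

    def _bleach_frames(rate: float) -> np.ndarray:
        if rate > 0:
            t = rng.exponential(1.0 / rate, size=n)
            return np.floor(t / dt).astype(np.int64)
        return np.full(n, np.iinfo(np.int64).max)

    donor_bleach_f = _bleach_frames(config.bleach_rate_donor)
    acceptor_bleach_f = _bleach_frames(config.bleach_rate_acceptor)

    # first frame in which a born-dimer emitter is monomeric (or gone)
    dwell_frames = np.floor(np.where(np.isfinite(dwell), dwell, 0.0) / dt)
    diss_f = np.where(born_dimer & np.isfinite(dwell),
                      np.maximum(1, dwell_frames.astype(np.int64)), T + 1)

    start = np.column_stack([rng.uniform(0, w_um, n), rng.uniform(0, h_um, n)])
    pos = start.copy()
    alive = np.ones(n, dtype=bool)
    R_um = None if config.confinement_radius is None else config.confinement_radius / 1000.0

    sd_mono = math.sqrt(2.0 * config.D_monomer * dt)
    sd_dim = math.sqrt(2.0 * config.D_dimer * dt)

    for t in range(T):
        if t > 0:
            is_dimer_now = born_dimer & (t < diss_f)
            sd = np.where(is_dimer_now, sd_dim, sd_mono)
            steps = rng.normal(0.0, 1.0, size=(n, 2)) * sd[:, None]
            pos = pos + steps
            if R_um is not None:
                pos = _reflect_disk(pos, start, R_um)
            left = (pos[:, 0] < 0) | (pos[:, 0] >= w_um) | (pos[:, 1] < 0) | (pos[:, 1] >= h_um)
            alive = alive & ~left

        # dissociation bookkeeping at the first monomeric frame
        newly_diss = born_dimer & (t == diss_f) & (dissociation_frame < 0)
        for i in np.nonzero(newly_diss)[0]:
            if alive[i]:
                dissociation_frame[i] = t
                pathway[i] = 2 if internalize[i] else 1

        gone_now = ~alive | ((pathway == 2) & (dissociation_frame >= 0) & (t >= dissociation_frame))
        visible = ~gone_now
        xy[visible, t] = pos[visible]
        st = np.where(born_dimer & (t < diss_f), STATE_DIMER, STATE_MONOMER).astype(np.int8)
        state[:, t] = np.where(visible, st, STATE_GONE)
        donor_bleached[:, t] = t >= donor_bleach_f
        acceptor_bleached[:, t] = (t >= acceptor_bleach_f) | ~has_acceptor

    # a dissociation that never happened inside the movie is not recorded
    off_movie = dissociation_frame >= T
    dissociation_frame[off_movie] = -1
    pathway[off_movie] = 0

    return SimulationTruth(
        xy=xy, state=state,
        donor_bleached=donor_bleached, acceptor_bleached=acceptor_bleached,
        dissociation_frame=dissociation_frame, pathway=pathway,
        has_acceptor=has_acceptor, born_dimer=born_dimer, dwell_time_s=dwell_time_s,
    )


# ---------------------------------------------------------------------------
# photon model
# ---------------------------------------------------------------------------

def expected_photons(truth: SimulationTruth, config: SimulationConfig,
                     frame: int) -> Tuple[np.ndarray, np.ndarray]:
    """Expected donor- and acceptor-channel photons per emitter in one frame.

    Photophysics (all under donor excitation):

    * FRET dimer:  I_DD = (1-E)*Q_D,
      I_AD = gamma*E*Q_D + alpha*I_DD + delta*Q_A
    * donor-only emitter (monomer, donor-only dimer, or acceptor bleached):
      I_DD = Q_D, I_AD = alpha*Q_D
    * donor bleached but acceptor present: I_AD = delta*Q_A only.
    """
    st = truth.state[:, frame]
    db = truth.donor_bleached[:, frame]
    ab = truth.acceptor_bleached[:, frame]
    visible = st != STATE_GONE

    Q_D, Q_A = config.photons_donor, config.photons_acceptor
    E, a, d, g = (config.E_true, config.leak_alpha_true,
                  config.direct_delta_true, config.gamma_true)

    fret_on = visible & (st == STATE_DIMER) & ~db & ~ab
    donor_on = visible & ~db
    acc_present = visible & ~ab

    mean_dd = np.where(donor_on, np.where(fret_on, (1 - E) * Q_D, Q_D), 0.0)
    sens = np.where(fret_on, g * E * Q_D, 0.0)
    mean_ad = sens + a * mean_dd + np.where(acc_present, d * Q_A, 0.0)
    return mean_dd, mean_ad


def _pixel_weights(coord_px: float, sigma_px: float, lo: int, hi: int) -> np.ndarray:
    """Integral of a unit 1-D Gaussian centred at coord_px over pixels lo..hi-1."""
    edges = np.arange(lo, hi + 1, dtype=float)
    z = (edges - coord_px) / (sigma_px * math.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(z))
    return np.diff(cdf)


def _stamp_spot(img: np.ndarray, x_px: float, y_px: float, mean_photons: float,
                sigma_px: float, rng: np.random.Generator, half: int) -> int:
    """Poisson-render one spot into img; return the realized photon count."""
    H, W = img.shape
    cx, cy = int(math.floor(x_px)), int(math.floor(y_px))
    x0, x1 = max(0, cx - half), min(W, cx + half + 1)
    y0, y1 = max(0, cy - half), min(H, cy + half + 1)
    if x0 >= x1 or y0 >= y1:
        return 0
    wx = _pixel_weights(x_px, sigma_px, x0, x1)
    wy = _pixel_weights(y_px, sigma_px, y0, y1)
    lam = mean_photons * np.outer(wy, wx)
    photons = rng.poisson(lam)
    img[y0:y1, x0:x1] += photons
    return int(photons.sum())


def render_movie(truth: SimulationTruth, config: SimulationConfig,
                 rng: Optional[np.random.Generator] = None) -> Movie:
    """Render a truth record into a two-channel camera movie.

    Each frame is ``(H, 2W)``: columns ``[0, W)`` are the donor channel,
    ``[W, 2W)`` the acceptor channel.  Per emitter and channel the expected
    photon count is spread over pixels as an integrated symmetric Gaussian of
    width ``psf_sigma`` and drawn pixel-wise from a Poisson law (so the
    realized in-window photon sum, recorded in the truth, is itself Poisson).
    A Poisson background is added everywhere, then counts are scaled by
    ``camera_gain`` and offset by ``camera_baseline`` into uint16 ADU.
    """
    if truth.n_frames != config.n_frames:
        raise ValueError("truth and config disagree on the number of frames")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    H, W = config.field_size
    px_um = config.pixel_size / 1000.0
    sigma_px = config.psf_sigma / config.pixel_size
    half = max(4, int(math.ceil(4.0 * sigma_px)))
    T = config.n_frames

    M = None
    if config.acceptor_misalignment is not None:
        a, b, tx, c, d, ty = config.acceptor_misalignment
        M = (np.array([[a, b], [c, d]]), np.array([tx, ty]))

    frames = np.empty((T, H, 2 * W), dtype=np.uint16)
    donor_photons = np.zeros((truth.n_emitters, T), dtype=np.int64)
    acceptor_photons = np.zeros((truth.n_emitters, T), dtype=np.int64)

    for t in range(T):
        img_d = np.zeros((H, W), dtype=np.int64)
        img_a = np.zeros((H, W), dtype=np.int64)
        mean_dd, mean_ad = expected_photons(truth, config, t)
        visible = np.nonzero(truth.state[:, t] != STATE_GONE)[0]
        for i in visible:
            x_um, y_um = truth.xy[i, t]
            x_px, y_px = x_um / px_um, y_um / px_um
            if mean_dd[i] > 0:
                donor_photons[i, t] = _stamp_spot(
                    img_d, x_px, y_px, mean_dd[i], sigma_px, rng, half)
            if mean_ad[i] > 0:
                if M is not None:
                    xa, ya = M[0] @ np.array([x_um, y_um]) + M[1]
                    xa_px, ya_px = xa / px_um, ya / px_um
                else:
                    xa_px, ya_px = x_px, y_px
                acceptor_photons[i, t] = _stamp_spot(
                    img_a, xa_px, ya_px, mean_ad[i], sigma_px, rng, half)
        full = np.concatenate([img_d, img_a], axis=1)
        if config.background_mean > 0:
            full = full + rng.poisson(config.background_mean, size=full.shape)
        adu = config.camera_baseline + config.camera_gain * full
        frames[t] = np.clip(np.rint(adu), 0, 65535).astype(np.uint16)

    truth.donor_photons = donor_photons
    truth.acceptor_photons = acceptor_photons
    return Movie(frames=frames, config=config)


def simulate_movie(config: SimulationConfig) -> Tuple[Movie, SimulationTruth]:
    """Convenience wrapper: states + rendering with one seed."""
    truth = simulate_state_trajectories(config)
    movie = render_movie(truth, config)
    return movie, truth


def simulate_bead_movie(config: SimulationConfig, n_beads: int = 12,
                        photons: float = 20000.0, n_frames: int = 20) -> Movie:
    """Stationary bright fiducials visible in both channels, for registration.

    Bead positions are uniform with a margin; the acceptor half applies
    ``config.acceptor_misalignment`` exactly as :func:`render_movie` does, so
    registration on this movie recovers the configured transform.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    H, W = config.field_size
    px_um = config.pixel_size / 1000.0
    h_um, w_um = config.field_um
    margin = 10 * px_um
    # beads are laid out with a minimum pairwise separation, as a usable
    # calibration field would be
    min_sep = 1.5
    pos_list: list = []
    while len(pos_list) < n_beads:
        p = np.array([rng.uniform(margin, w_um - margin),
                      rng.uniform(margin, h_um - margin)])
        if all(np.hypot(*(p - q)) >= min_sep for q in pos_list):
            pos_list.append(p)
    pos = np.array(pos_list)
    sigma_px = config.psf_sigma / config.pixel_size
    half = max(4, int(math.ceil(4.0 * sigma_px)))

    M = None
    if config.acceptor_misalignment is not None:
        a, b, tx, c, d, ty = config.acceptor_misalignment
        M = (np.array([[a, b], [c, d]]), np.array([tx, ty]))

    frames = np.empty((n_frames, H, 2 * W), dtype=np.uint16)
    for t in range(n_frames):
        img_d = np.zeros((H, W), dtype=np.int64)
        img_a = np.zeros((H, W), dtype=np.int64)
        for x_um, y_um in pos:
            _stamp_spot(img_d, x_um / px_um, y_um / px_um, photons, sigma_px, rng, half)
            if M is not None:
                xa, ya = M[0] @ np.array([x_um, y_um]) + M[1]
            else:
                xa, ya = x_um, y_um
            _stamp_spot(img_a, xa / px_um, ya / px_um, photons, sigma_px, rng, half)
        full = np.concatenate([img_d, img_a], axis=1)
        if config.background_mean > 0:
            full = full + rng.poisson(config.background_mean, size=full.shape)
        adu = config.camera_baseline + config.camera_gain * full
        frames[t] = np.clip(np.rint(adu), 0, 65535).astype(np.uint16)
    return Movie(frames=frames, config=config)


# ---------------------------------------------------------------------------
# trace-level simulation (no rendering) for vetting / segmentation tests
# ---------------------------------------------------------------------------

@dataclass
class TraceTruth:
    """Ground truth of one directly simulated intensity trace."""

    acceptor_loss_frame: int          # first frame after the (last) acceptor loss
    pathway: int                      # 1 or 2
    n_frames: int
    multi_step: bool = False
    loss_frames: Tuple[int, ...] = ()  # all acceptor loss frames (multi-step puncta)


def simulate_intensity_trace(
    rng: np.random.Generator,
    n_frames: int = 100,
    loss_frame: Optional[int] = None,
    pathway: int = 1,
    snr: float = 8.0,
    i_dd_fret: float = 300.0,
    i_ad_fret: float = 2900.0,
    i_dd_free: float = 3000.0,
    i_ad_free: float = 150.0,
    config: Optional[SimulationConfig] = None,
    xy0: Tuple[float, float] = (2.0, 2.0),
) -> Tuple[pd.DataFrame, TraceTruth]:
    """One candidate FRET trace (intensities + coordinates) with known truth.

    The acceptor drops from the FRET level to the leakage level at
    ``loss_frame``; in pathway 1 the donor rises to its unquenched level and
    keeps diffusing, in pathway 2 both signals fall to background.  ``snr``
    is each channel's own step height divided by that channel's additive
    noise sigma, so the donor response stays detectable at the stated
    signal-to-noise whichever pathway is drawn.
    """
    cfg = config or SimulationConfig()
    if loss_frame is None:
        loss_frame = int(rng.integers(n_frames // 4, 3 * n_frames // 4))
    frames = np.arange(n_frames)
    i_dd = np.where(frames < loss_frame, i_dd_fret,
                    i_dd_free if pathway == 1 else 0.0)
    i_ad = np.where(frames < loss_frame, i_ad_fret,
                    i_ad_free if pathway == 1 else 0.0)
    dd_post = i_dd_free if pathway == 1 else 0.0
    ad_post = i_ad_free if pathway == 1 else 0.0
    noise_d = max(abs(i_dd_fret - dd_post) / snr, 1.0)
    noise_a = max(abs(i_ad_fret - ad_post) / snr, 1.0)
    i_dd = i_dd + rng.normal(0, noise_d, n_frames)
    i_ad = i_ad + rng.normal(0, noise_a, n_frames)

    dt = cfg.frame_interval
    sd = np.where(frames[:-1] < loss_frame,
                  math.sqrt(2 * cfg.D_dimer * dt), math.sqrt(2 * cfg.D_monomer * dt))
    steps = rng.normal(0, 1, (n_frames - 1, 2)) * sd[:, None]
    xy = np.vstack([np.array(xy0), np.array(xy0) + np.cumsum(steps, axis=0)])
    # acceptor coordinates exist only while FRET is on; in pathway 2 the
    # whole complex disappears, donor coordinates included
    xa = np.where(frames < loss_frame, xy[:, 0], np.nan)
    ya = np.where(frames < loss_frame, xy[:, 1], np.nan)
    xd, yd = xy[:, 0].copy(), xy[:, 1].copy()
    if pathway == 2:
        xd[loss_frame:] = np.nan
        yd[loss_frame:] = np.nan

    df = pd.DataFrame({
        "frame": frames, "I_DD": i_dd, "I_AD": i_ad,
        "x_um": xd, "y_um": yd, "xa_um": xa, "ya_um": ya,
    })
    return df, TraceTruth(acceptor_loss_frame=loss_frame, pathway=pathway,
                          n_frames=n_frames)


def simulate_trace_set(
    n_traces: int,
    seed: int,
    multi_step: bool = False,
    snr: float = 8.0,
    n_frames: int = 100,
    p_internalize: float = 0.0,
    config: Optional[SimulationConfig] = None,
) -> list:
    """A batch of (trace DataFrame, TraceTruth) pairs.

    With ``multi_step=True`` each trace is a two-dimer punctum: two acceptors
    bleaching at distinct frames (staircase in the acceptor channel), the
    signature the vetting stage must reject.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_traces):
        if multi_step:
            f1 = int(rng.integers(n_frames // 5, n_frames // 2))
            f2 = int(rng.integers(f1 + max(10, n_frames // 5), n_frames - 5))
            df, tr = simulate_intensity_trace(
                rng, n_frames=n_frames, loss_frame=f2, pathway=1, snr=snr,
                config=config)
            step = (2900.0 - 150.0)
            extra_a = np.where(np.arange(n_frames) < f1, step, 0.0)
            extra_d = np.where(np.arange(n_frames) < f1, -150.0, 0.0)
            df["I_AD"] = df["I_AD"] + extra_a
            df["I_DD"] = df["I_DD"] + extra_d + 300.0  # second donor present throughout
            tr = TraceTruth(acceptor_loss_frame=f2, pathway=1, n_frames=n_frames,
                            multi_step=True, loss_frames=(f1, f2))
        else:
            pathway = 2 if rng.random() < p_internalize else 1
            df, tr = simulate_intensity_trace(
                rng, n_frames=n_frames, pathway=pathway, snr=snr, config=config)
        out.append((df, tr))
    return out
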