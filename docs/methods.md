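# Methods

## What the simulator emulates

The generator reproduces the statistical structure of a live-cell smFRET +
tracking experiment on membrane receptor dimers imaged by two-channel TIRF:

* **Geometry and timing.** One camera frame is 512×256 px split into two
  256×256 px emission channels (donor left, acceptor right), 159 nm
  effective pixel size, 40 ms frame interval. Field size and frame count
  are configurable; the analysis-scale studies use 160×160 px channels.
* **Kinetics.** Emitters are born at frame 0, monomeric or dimeric
  (`dimer_fraction`, default 0.5). Dimer dwell times are exponential with
  mean `1/k_off` (default 1.13 s), discretized to whole frames
  (`floor(t/Δt)`, at least one frame). At dissociation the complex takes
  pathway 2 (internalization — all signals vanish) with probability
  `p_internalize` (default 0.7, i.e. ~30 % of traces continue as donor-only
  monomers, pathway 1). Association is not simulated: the lifetime analysis
  starts at FRET appearance, so monomer→dimer transitions never occur
  within one emitter's record.
* **Motion.** Per-frame Brownian steps with the state's diffusion
  coefficient (defaults: dimer 0.066, monomer 0.109 µm²/s), variance
  `2DΔt` per axis. With `confinement_radius` set, steps reflect radially
  off a disk centred on the emitter's initial position. Emitters leaving
  the field are marked lost — never clipped or wrapped.
* **Photophysics.** Under donor excitation a FRET dimer emits
  `I_DD = (1−E)·Q_D` donor-channel photons and
  `I_AD = γ·E·Q_D + α·I_DD + δ·Q_A` acceptor-channel photons; a donor-only
  emitter gives `Q_D` and `α·Q_D`. Defaults: `Q_D = Q_A = 3000`
  photons/frame, E = 0.90, α = 0.05, δ = 0.02, γ = 1.1. Each dye bleaches
  in a single exponential step (0.03 s⁻¹ per dye): a no-dissociation
  control then shows a FRET-loss lifetime of ≈ 1/0.06 ≈ 17 s, about
  fifteenfold longer than the dimer lifetime, matching the relation between
  fixed-cell and live-cell FRET trace lengths that motivates treating the
  live-cell decay as dominated by dissociation. Blinking is not simulated.
* **Camera.** Expected photons are spread over pixels with an
  erf-integrated symmetric Gaussian PSF (σ = 150 nm) and drawn pixel-wise
  from a Poisson law; a Poisson background (10 photons/px) is added, then
  counts are scaled by the gain (2 ADU/photon) and offset by the baseline
  (100 ADU) into uint16. The realized in-window photon sum per emitter,
  channel and frame is recorded in the truth and is the oracle for
  photometry tests. No explicit EM-register excess noise is modelled; the
  linear-gain Poisson model keeps the truth-photon oracle exact while
  exercising detection and vetting at realistic shot noise.
* **Trace-level generator.** For vetting and segmentation tests a faster
  generator emits intensity/coordinate traces directly (no rendering):
  single dimers with one acceptor-loss step, pathway-2 traces with
  simultaneous loss, and two-dimer puncta with staircase bleaching. Its
  `snr` parameter is each channel's step height over that channel's
  additive noise sigma.

What the generator deliberately does **not** model: membrane topography and
apical-to-basal receptor exchange (sparse density is imposed directly),
EMCCD excess noise, dye blinking, association events, vesicle transport.
Tests passing on this synthetic data therefore validate the *analysis
machinery* — detection, linking, vetting, segmentation, estimators — not
the photophysical completeness of any real microscope.

## Analysis pipeline choices

* **Detection.** Difference-of-Gaussians band-pass (σ and 2.5σ), 8-connected
  local maxima above a robust threshold (median + 4·1.4826·MAD of the
  filtered frame). Candidates closer than 2.5 PSF sigmas are unresolvable:
  the dimmer is dropped (default) or the pair is fit as a two-Gaussian
  mixture (`overlap_mode="joint"`). After the first fitting round the
  fitted spots are subtracted and detection runs once more on the residual:
  a FRET-quenched donor sitting on a brighter neighbour's flank has no
  local maximum of its own in the first pass, and without the residual pass
  such donors drop out for many consecutive frames and fragment their
  trajectories. Fitted amplitudes must exceed 5× their shot-noise sigma
  (including, on the residual pass, the subtracted model's shot noise).
* **Fitting.** All candidates of a frame are fit in one batched, damped
  Gauss–Newton solve of a pixel-integrated Gaussian + constant background;
  the amplitude is then directly the integrated photon count. The PSF width
  is fit freely for the first 200 accepted spots and then frozen at their
  median (the "data-driven PSF radius" realization). Localization precision
  is the Mortensen formula from photons, background, PSF width and pixel
  size.
* **Registration.** Beads are localized per frame, averaged per bead by the
  across-frame median, matched across channels by mutual nearest neighbour,
  and a full 2-D affine is fit by least squares with one outlier-trim
  round (residual > 3× median). Typical residuals on synthetic beads are
  ~1 nm.
* **Tracking.** Per frame pair, squared-displacement costs capped at
  `max_disp` (default 1.1 µm = 4·√(4·D_max·Δt) at D_max = 0.5 µm²/s) are
  solved by the Hungarian algorithm with birth/death dummies; track ends
  and starts within 3 frames and `max_disp·√(gap+1)` are then merged.
  Gap frames carry no interpolated coordinates.
* **Pairing and photometry.** An acceptor trajectory pairs with the donor
  trajectory whose median distance over time-overlapping frames is below
  250 nm (one-to-one, nearest first, ties to the lower id). Intensity
  series are read from the movie by fixed-aperture photometry (radius 3 px,
  background from a 5–7 px annulus median) at the donor positions and
  their transform-mapped acceptor-channel counterparts, so the series
  continue through detection gaps and past trajectory ends.
* **Vetting.** Change points come from binary segmentation with penalty
  `3·σ²·ln n` (σ from the median absolute first difference — parameter-free
  on constant traces; minimum segment 3 frames). A trace is accepted iff
  the acceptor has exactly one downward step to below 30 % of its pre-step
  level, the donor has at most one downward step, the pre-loss acceptor
  signal exceeds 25 % of the donor signal (an "acceptor" at the ~5 %
  leakage level is a lone donor seen through crosstalk, not a FRET pair),
  and the donor responds at the loss: a rise of ≥ 2 noise sigmas within a
  5-frame window (dissociation), or a simultaneous drop of both channels to
  background within 3 frames. The simultaneous-loss clause is this
  package's rule: without it no pathway-2 trace could ever be accepted,
  yet both terminations are part of the analysis.
* **Correction factors.** α from donor-only traces (`⟨I_AD⟩/⟨I_DD⟩`),
  including paired traces rejected for a leakage-level acceptor; δ from
  acceptor-only traces under alternating excitation, else a configured
  fallback (live-cell movies have a single excitation colour); γ from the
  intensity steps across acceptor loss in accepted traces,
  `−ΔI_AD′/ΔI_DD` after α/δ correction; β (alternating excitation only)
  from `⟨I_AA⟩/(γ⟨I_DD⟩+⟨F_corr⟩)`. All tracewise, averaged for global use,
  with across-trace standard deviations.
* **Segmentation.** The intensity change point is the boundary authority;
  acceptor-channel detections after it are leakage. Donor and acceptor
  positions of the same frame merge by inverse-variance weighting within
  250 nm. The donor-only part must resume within `250 nm·√gap` of the last
  FRET position — otherwise the tracker grafted a different molecule onto a
  vanished complex and the trace is pathway 2.
* **Diffusion.** Time-averaged MSD uses all index pairs whose two end
  frames are present. D comes from a pair-count-weighted linear fit of
  lags 1–4; a negative intercept leaves D reported and σ_dyn "not
  estimable". The confined model `L²(1−exp(−t/τ_c)) + 4σ²` is fit over
  lags up to half the segment length.
* **Motion classification.** Confined iff the weighted mean shortfall of
  the MSD below the free-fit line over the last half of the lags exceeds
  both θ = 0.3 and 0.75× the single-track TA-MSD noise scale
  `√(2n/(3(N−n)))`. The noise gate is essential: without it ~30 % of
  genuinely free 20-frame segments classify as confined purely through MSD
  fluctuation; with it the false-confined rate is ≤ 15 % at 20 frames while
  strong confinement (L = 0.2 µm disks, 60-frame segments) is detected in
  ≥ 85 % of cases. θ and the gate are config-exposed and reported with
  every study summary.
* **Lifetime.** Durations are FRET-frame counts × Δt; durations > 10 s are
  excluded (aggregate-dominated), and pooled statistics drop durations
  below the 20-frame minimum trajectory length — below that cutoff a FRET
  segment is only observable when the donor survives long past it, a
  condition pathway-2 traces can never meet, so keeping them would bias
  both the dwell histogram and the pathway split. `A·exp(−t/τ)` is fit to
  the histogram counts (default) or to the empirical survival fraction;
  pooled studies use the survival mode with ~√n bins, which is unbiased and
  roughly twice as efficient on left-truncated samples of a few hundred
  dwells. The grid starts exactly at the shortest observed duration — the
  truncation point; padding the axis below it fakes a flat region of the
  decay and inflates τ. Memorylessness of the exponential makes the fit
  over the observed support unbiased despite the censoring.
* **Edge censoring.** A FRET segment ending within 1 µm of the field
  border may simply have diffused out of view — indistinguishable from a
  pathway-2 loss. Such traces are excluded from the pooled lifetime and
  pathway statistics (they still contribute diffusion and efficiency
  values); without this, field-exit events deflate the fitted lifetime by
  several percent at the simulated field sizes.
* **Bleach correction.** FRET loss is a competing-risk process:
  `1/τ_apparent = 1/τ_dissociation + 1/τ_bleach`. The study-level scripts
  estimate `τ_bleach` from a no-dissociation, immobile control batch
  (k_off = 0, D = 0, all emitters dimeric — the synthetic analogue of a
  fixed-cell control) without the 10 s exclusion, and report the corrected
  lifetime alongside the apparent one. At the default rates the correction
  is ≈ +7 %.
* **Group comparison.** Two-sided Mann–Whitney U with the usual
  significance bands (n.s. / * / ** / ***).

## Problem sizes

Unit and property tests run on small fields (64–128 px) and trace-level
batches of 500–1000. The study-level checks use 20 movies of 160×160 px
channels × 300 frames (tests) and 40 such movies plus 4 control movies of
1100 frames (`scripts/acceptance.py`), which yield ≈ 110 and ≈ 220 accepted
FRET traces respectively; these sizes were chosen so the lifetime fit's
sampling error (≈ τ/√n) sits well inside the recovery tolerances. All
randomness flows from explicit seeds; identical seeds reproduce movies and
all derived CSV/JSON output byte for byte.

## Known limitations

* The apparent pathway-1 fraction among accepted traces runs a few points
  above the generator probability because acceptor bleaching during the
  dimer phase mimics dissociation (donor rise) — an ambiguity intrinsic to
  single-colour-excitation data, shared with the real experiment.
* Median per-segment D on exponential-length (mean ≈ 28 frames) segments
  sits ~4–5 % below the generator value: the single-track D estimate is
  right-skewed, so its median undershoots while its mean is unbiased.
* The confined/free classifier trades power at short segments for a
  bounded false-confinement rate; moderately confined 20-frame segments
  are mostly called free.
* Densities well above ~0.1 /µm² would need genuine multi-emitter mixture
  fitting throughout; the residual pass plus drop-dimmer rule is adequate
  only in the sparse regime the experiment operates in.
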