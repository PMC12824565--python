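# fretspt

Combined single-molecule FRET (smFRET) and single-particle tracking (SPT)
analysis of membrane-receptor dimerization in live-cell TIRF movies — with a
ground-truthed simulator of the experiment so the entire pipeline is testable
without any microscope data.

## The problem

A receptor tyrosine kinase such as MET is activated when a ligand (here, the
bacterial ligand internalin B) crosslinks two receptors into a 2:2 complex.
With a donor dye on one ligand and an acceptor on the other, a dimer appears
as a single diffraction-limited spot that emits FRET-sensitized acceptor
fluorescence under donor excitation; dissociation or internalization ends the
FRET signal. From two-channel movies (donor emission left, acceptor emission
right, 159 nm pixels, 40 ms frames) the pipeline extracts:

* **dimer lifetime** — the FRET-segment durations follow an exponential
  decay `A·exp(−t/τ)`; τ is the apparent dimer lifetime, correctable for
  photobleaching via a no-dissociation control,
* **diffusion coefficients** — a weighted fit of the first four points of
  the time-averaged mean squared displacement,
  `MSD(t) = 4Dt + 4σ_dyn²`, separately for the FRET-active (dimer) and the
  donor-only (monomer) segment of each trajectory,
* **motion class** — confined vs free, from the long-lag shortfall of the
  MSD below the short-lag linear extrapolation,
* **jump angles** — the angle between consecutive displacement vectors;
  uniform for a random walk, biased toward 180° under confinement,
* **corrected FRET efficiency** — `E = F_corr / (γ·I_DD + F_corr)` with
  `F_corr = I_AD − α·I_DD − δ·I_AA`, where α is donor leakage, δ direct
  acceptor excitation, γ the detection/quantum-yield imbalance,
* **termination pathway** — donor persistence after acceptor loss means the
  dimer dissociated (pathway 1); simultaneous loss of both signals means the
  complex disappeared, e.g. by internalization (pathway 2).

## Layout

| module | contents |
| --- | --- |
| `fretspt.simulate` | two-channel movie generator with per-emitter truth; trace-level generator for vetting tests |
| `fretspt.localize` | band-pass detection, batched pixel-integrated Gaussian fitting, Mortensen precision, bead-based channel registration |
| `fretspt.track` | Hungarian frame-to-frame linking, gap closing (3 frames), minimum-length filter (20 frames) |
| `fretspt.fretscore` | donor/acceptor pairing (250 nm), aperture photometry, change-point vetting, correction factors, E and S |
| `fretspt.segment` | merge repeated localizations, split traces at acceptor loss, pathway call |
| `fretspt.dynamics` | MSD, diffusion fits, motion classification, jump angles, lifetime fit, Mann–Whitney comparison |
| `fretspt.pipeline` | one-call movie analysis and study-level pooling |

The package is used from Python; `examples/` holds one short script per
capability.

## Worked example

```bash
python examples/end_to_end_study.py
```

simulates eight movies (160×160 px channels, 300 frames) with the generator
defaults and runs the full chain; it prints

```
accepted FRET traces: 59
apparent dimer lifetime: 1.26 +- 0.05 s (n = 44)
median D (FRET segments): 0.061 um^2/s (generator 0.066)
median D (donor-only):    0.109 um^2/s (generator 0.109)
FRET efficiency peak: 0.900 +- 0.001 (generator 0.90)
Mann-Whitney FRET vs donor-only D: p = 2.01e-08 (***)
pathway 1 (dissociation) fraction: 0.16 (generator 0.30)
```

Dimeric receptors diffuse ~1.6× slower than monomers (the Mann–Whitney
test separates the two mobility populations decisively), the FRET peak
sits at the generator's efficiency, and with only ~50 traces the lifetime
and pathway fraction are still coarse. `scripts/acceptance.py` runs the
same computation at five times this scale, where each quantity converges
toward its generator setting.

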