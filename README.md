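# ulmkit

Super-resolution **ultrasound localization microscopy** (ULM) in Python:
the complete processing chain that turns contrast-enhanced ultrasound frame
ensembles into super-resolved microvascular maps, plus the evaluation layer
used to quantify those maps, plus a ground-truthed synthetic vascular-flow
simulator to exercise and validate everything end to end.

ULM reconstructs vasculature below the acoustic diffraction limit by
localizing intravascular microbubbles (MBs) — point scatterers whose image is
the system PSF — and linking the localizations into trajectories across
thousands of frames. The package is built around the question of how imaging
**frequency** and MB **concentration** interact: at tissue sound speed
c = 1540 m/s the wavelength λ = c/f shrinks with frequency, the MB PSF
(axial FWHM λ, lateral 2λ, area πλ²/2) shrinks quadratically, and the
maximum *resolvable* MB density — the optimal congruent-ellipse packing
fraction π/√12 divided by the PSF footprint — grows as f². A
higher-frequency probe can therefore localize more concurrent MBs, which
fills the vascular map faster and improves the reproducibility (hence
measured resolution) of the reconstruction.

## What is implemented

| stage | method |
|---|---|
| clutter rejection | per-ensemble Casorati SVD filter with adaptive low-order cutoff (log-slope rule); no high-order cutoff |
| noise handling | robust per-depth noise profile (median of medians, 2nd-order polynomial), divided out |
| de-overlapping | spatiotemporal Fourier quadrant filter splitting upward / downward axial motion |
| localization | cubic-spline interpolation to an isotropic λ/10 grid, zero-normalized cross-correlation against a 2D Gaussian MB template, threshold 0.6, non-max suppression within one lateral FWHM, 3×3 paraboloid sub-pixel refinement |
| tracking | frame-pair linear-assignment linking (birth/death cost = max-link²), no gap closing, 10-frame (10 ms) persistence floor, per-branch tracking with duplicate removal on pooling |
| maps | Bresenham accumulation of track polylines on a 2 μm grid (density and velocity) |
| resolution | Fourier ring correlation between two random track-half accumulations at 1 μm, ½-bit and 2-σ criteria, 5-split bootstrap |
| saturation | distinct-filled-pixel curve fit by S_inf(1 − e^(−t/τ)); 90% mapping time t90 = τ·ln 10 |
| theory | wavelength / PSF-ellipse / packing-limit calculators, FWHM of beam profiles, MB PSF measurement |
| simulator | Murray-branching vessel trees, Poisson MB transits with elevational slice weighting, PSF rendering + rank-5 slow tissue clutter (≥ 20 dB above MB) + depth-growing noise |

Probe presets ship for the three linear arrays compared throughout
(L22-14vX, L35-16vX, MS-550S; operating frequencies 15.625 / 23 / 31.25 MHz).

## Worked example

```bash
ulmkit theory
```

```
probe       f [MHz]   λ [μm]  λ/10 [μm]  PSF area [μm²]  max MB [1/mm²]
L22-14vX     15.625    98.56       9.86         15258.8            59.4
L35-16vX     23.000    66.96       6.70          7041.7           128.8
MS-550S      31.250    49.28       4.93          3814.7           237.7
```

Reading: at 15.625 MHz a single microbubble's image covers 15 259 μm², so at
most ~59 MBs/mm² remain individually resolvable; doubling the frequency
quarters the footprint and quadruples that ceiling.

An end-to-end synthetic run (simulate → filter → localize → track → map →
metrics), from Python:

```python
import ulmkit as u

result = u.run_condition("MS-550S", concentration_per_mm2=30.0,
                         seed=1, duration_s=6.0)
print(len(result.tracks), result.res_half_bit.mean_um, result.saturation.tau_s)
```

On the default 800×800 μm scene this prints 717 tracks, a ½-bit FRC
resolution of 39.2 μm and a saturation time constant τ ≈ 4.1 s. Running the
same scene at half the concentration (15 MB/mm²) yields 360 tracks and a
*worse* resolution of 47.1 μm — the high-frequency probe benefits from more
concentrated contrast — whereas the 15.625 MHz preset degrades from 57 μm to
77 μm over the same concentration step, because its 4×-larger PSF footprint
pushes it past its overlap limit. (Desk-scale resolutions from a few seconds
of data are far coarser than long-acquisition values; the orderings across
conditions, not the absolute numbers, carry the information.)

The same pipeline is scriptable from the shell, stage by stage:

```bash
ulmkit run --transducer MS-550S --concentration-per-mm2 30 \
           --duration-s 6 --seed 1 --out runs/ms550_high
ulmkit compare runs/* --out summary.csv
```

`docs/methods.md` documents the models, estimators, defaults and limitations.

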