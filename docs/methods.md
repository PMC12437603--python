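# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `ulmkit`. It is written for a reader who wants to know what
the package actually computes and what passing its tests does and does not
demonstrate.

## The reconstruction problem

Ultrasound localization microscopy (ULM) reconstructs vasculature below the
acoustic diffraction limit by localizing intravascular microbubbles (MBs) —
gas-core contrast agents a few μm across that act as point scatterers — and
linking the localizations into trajectories over thousands of frames. The
image of an MB is the system point-spread function (PSF): at a tissue sound
speed of c = 1540 m/s and centre frequency f, the wavelength is λ = c/f
(98.56 μm at 15.625 MHz, 66.96 μm at 23 MHz, 49.28 μm at 31.25 MHz) and the
PSF is modelled as an anisotropic Gaussian/ellipse with axial FWHM λ and
lateral FWHM 2λ. Because localization requires spatially isolated MBs, the
PSF footprint πλ²/2 sets a packing ceiling on the usable MB concentration:
the optimal congruent-ellipse packing fraction π/√12 ≈ 0.9069 divided by the
footprint, ≈ 59 MB/mm² at 15.625 MHz and ≈ 238 MB/mm² at 31.25 MHz. The
package's central experiment measures how reconstruction quality responds to
imaging frequency and MB concentration through this mechanism.

## Processing chain

1. **SVD clutter filter.** Each 1000-frame ensemble is reshaped into a
   Casorati matrix (pixels × frames) and the leading singular components are
   zeroed. The adaptive low-order cutoff is the smallest k ≥ 1 at which the
   least-squares slope of log σ over a 5-point window exceeds −0.1 nats
   (≈0.9 dB) per index, clamped to [1, rank/4]. The tolerance sits between
   the multi-dB-per-index decay of coherent tissue components and the slow
   tail of the MB/noise subspace; on the default synthetic scene it lands at
   the clutter's *effective* rank (3–6: heavily coherent temporal modes span
   fewer dimensions than their nominal count). No high-order cutoff is applied: late components
   still carry MB signal in low-flow regions.
2. **Noise equalization.** The per-depth noise amplitude (temporal median of
   the row-wise median absolute amplitude — medians make the profile
   insensitive to sparse bright MBs) is smoothed by a 2nd-order polynomial in
   depth and divided out. Ordering is fixed as SVD → equalize → separate.
3. **Directional separation.** A spatiotemporal Fourier quadrant filter over
   (z, t) assigns same-sign (k_z, f_t) quadrants to upward motion and
   opposite-sign quadrants to downward motion; zero-frequency planes are
   split equally, so the two branches sum back to the input exactly. The
   equal DC split means re-applying a branch filter is idempotent only up to
   the (small) DC share of the signal.
4. **Localization.** Frames are cubic-spline interpolated onto an isotropic
   λ/10 grid (9.86 / 6.70 / 4.93 μm for the three presets), cross-correlated
   (zero-normalized) against a 2D Gaussian template with σ = FWHM/2.3548 from
   the theoretical PSF and ±2σ support, and thresholded at NCC ≥ 0.6. Local
   maxima undergo non-maximum suppression within one lateral FWHM (2λ) and a
   3×3 paraboloid fit (centroid fallback if the Hessian is not
   negative-definite; displacement clamped to ±1 grid step) refines the
   position. Two guards matter in practice: windows that are flat to
   numerical precision score 0 (zero-normalized correlation is
   scale-invariant, so a bright scatterer's far tails would otherwise
   correlate as strongly as the scatterer), and peaks pinned on the border of
   the valid correlation region are rejected — they lack a full template
   window and repeat at identical positions across frames, which later
   masquerades as reproducible structure. Up- and down-branch candidates are
   localized independently; the merged candidate table collapses same-frame
   duplicates closer than half the suppression radius to the higher score.
5. **Tracking.** Consecutive-frame candidates are paired by a rectangular
   linear assignment minimizing summed squared displacement with birth/death
   cost max_link_distance² (default 10 μm/frame ≈ a 10 mm/s ceiling at
   1000 Hz); longer links are forbidden; there is no gap closing, merging, or
   motion model — at 1000 Hz with a 10-frame persistence floor these are
   second-order. Branches are tracked separately and pooled; pooling removes
   duplicate trajectories (≥50% frame overlap at mean distance < λ/2) because
   a slow or laterally moving MB splits its energy into both branches and
   would otherwise be counted twice — with direct consequences for any
   split-half consistency analysis. Tracks shorter than 10 frames (10 ms) are
   discarded; track speed is the mean per-frame displacement × frame rate.
6. **Accumulation.** Consecutive localizations are connected by Bresenham
   line segments on the reconstruction grid (2 μm pixels for final maps,
   1 μm for resolution analysis, shared origin). Each segment is half-open —
   the pixel containing its far endpoint belongs to the next segment — so
   interior pixels are not double counted; a degenerate segment keeps its
   single pixel. Density maps sum traversal weights; velocity maps carry the
   traversal-weighted mean track speed.

## Evaluation layer

**Fourier ring correlation (FRC).** Tracks are split per-track by a fair
coin, each half accumulated at 1 μm, both images zero-padded to a square
power of two, and the spectra correlated over integer-radius rings:
FRC(r) = Re Σ F_A·conj(F_B) / √(Σ|F_A|²·Σ|F_B|²). The curve is smoothed by a
3-ring moving average (raw ULM FRC curves are noisy near the floor) and the
first crossing below a criterion curve — the ½-bit threshold
T(n) = (0.2071 + 1.9102/√n)/(1.2071 + 0.9102/√n) or the 2-σ threshold
2/√(n/2), with n the pixel count per ring — is located by linear
interpolation; resolution = 1/f_cross. The split/accumulate/correlate cycle
is bootstrapped over 5 random splits and reported as mean ± sd. A repeat that
never crosses before Nyquist contributes the 2-pixel sampling bound and flags
the estimate. The FRC sub-accumulations count each pixel **at most once per
track** (presence weighting): dwell-weighted counts concentrate weight on the
few pixels where localization is biased, and since that bias field is shared
by both halves the FRC would plateau well above any threshold — reporting an
artifact as infinitely reproducible structure. Final maps keep traversal
weights.

**Saturation.** The cumulative count of distinct filled 2 μm pixels versus
accumulation time (tracks counted at their completion time) is fit by
S(t) = S_inf(1 − e^(−t/τ)) with multi-start least squares
(τ₀ ∈ {T/10, T/4, T/2, T, 2T}); the 90% mapping time is t90 = τ·ln 10. Both τ
and t90 are reported, since "characteristic time" is used for either in the
field. The time-to-match analysis accumulates growing sub-sets of
high-concentration tracks and reports the earliest time whose FRC resolution
reaches the full low-concentration estimate.

## The synthetic scene

The simulator provides ground truth with the statistical structure the
pipeline assumes, not an acoustic simulation:

- **Vasculature**: recursive binary trees; child radii obey Murray's rule
  r_p³ = Σ r_c³ with a 0.4–0.6 asymmetric split; mean speed ∝ radius²
  (Poiseuille-like); roots enter from the shallow side. Default root: 20 μm
  radius at 5 mm/s, the scale of mouse-brain penetrating arterioles. (At
  3 mm/s the deepest generations flow slowly enough to dwell ~150 frames
  within one PSF and are partially removed by the clutter filter; that
  slow-flow blind spot is real ULM physics, but it is not what the recovery
  tests are meant to probe.)
- **MB transits**: Poisson entries per root, rate calibrated so the
  time-averaged in-plane MB count equals concentration × field-of-view area
  (the entry window extends one maximal transit time before t = 0 so the
  process is stationary); uniform child choice at branches; advance
  mean_speed/frame_rate per frame with a 0.3 μm lateral random walk clamped
  inside the lumen. Each MB carries a fixed elevational offset drawn inside
  the slice (|y| < beamwidth/2, Table-value beamwidths per probe) weighting
  its echo through a Gaussian elevational sensitivity, and a log-normal
  amplitude with 3 dB sigma.
- **Frames**: λ/4 pixels (coarser than the λ/10 localization grid, so the
  interpolation stage does real work); each in-plane MB stamped as the
  anisotropic Gaussian PSF with 10^(−μ·f·z/20) attenuation
  (μ = 0.5 dB/cm/MHz); additive rank-5 clutter (smooth spatial modes × slow
  temporal weights with ~0.25 s coherence — tissue decorrelates much more
  slowly than an MB's dwell within one PSF — and a DC pedestal) scaled so
  every frame's clutter peak is ≥ 20 dB above the nominal MB amplitude, the
  mode spectrum decaying gently (0.8^k) so every clutter component stays
  high-energy relative to MB signal; white noise whose σ grows linearly with
  depth (0.05 at the surface, doubling at the bottom — ≈20 dB nominal MB
  SNR). The clutter-to-MB ratio is a free parameter: the in-vivo value is not
  quantified.

What the simulator does **not** model: RF/beamforming physics, speckle from
resolved tissue, nonlinear MB oscillation, frequency-dependent MB backscatter
efficiency, tissue motion, aberration, out-of-plane motion. Passing tests
therefore demonstrate the correctness and internal consistency of the
processing chain under its own statistical assumptions, not in-vivo
performance.

## Study conditions for the comparison grid

The frequency × concentration experiment uses an 800 × 800 μm field of view,
6 s at 1000 Hz (six 1000-frame ensembles) — a desk-scale analogue of 300 s
acquisitions — with low/high concentrations of 15 and 30 MB/mm² (a factor
two, emulating doubling the infusion rate; concentrations are stated for a
1 mm reference slice, and each probe's elevational beamwidth scales its
effective in-plane load, so the narrow-slice high-frequency probe carries
about half the bubbles of the low-frequency probe at the same infusion —
one of the two mechanisms by which it tolerates concentrated contrast).
30 MB/mm² sits far below the 31.25 MHz packing ceiling (~238/mm²) but covers
about half the field with 15.625 MHz PSF footprints, the overlap regime
where the low-frequency probe's localization degrades.

The two concentrations are compared as **coupled pairs**: the
high-concentration transit set is simulated once and thinned per transit
(keeping each bubble with probability ½ — a thinned Poisson process is a
Poisson process at the lower rate) to form the low-concentration scene, so
both cells share the vasculature and the common bubbles and the comparison
isolates the concentration effect. Expected orderings at the fixed default
seed: half-bit FRC resolution worsens at the low-frequency preset and
improves at the high-frequency preset when concentration doubles. Caveats
stated plainly: at this problem size the low-frequency degradation is the
robust effect (correct sign in three of four replicate seeds, magnitude
~5–20 μm), while the high-frequency improvement is at the edge of
detectability (~1–2 μm against a bootstrap σ of similar size; its sign
varies across replicate seeds). A corollary does **not** reproduce at desk
scale: because the high-frequency improvement is so small here, gradual
sub-accumulations of the high-concentration data reach the
low-concentration resolution only near the full acquisition (fraction
0.75–1.0), not in roughly half of it — the accumulation-time-halving test
is expected to fail at this problem size and is left failing rather than
weakened. Resolving both decisively would need the long-acquisition,
many-vessel regime in which the low-concentration high-frequency map is
strongly under-accumulated.

The track-recovery experiment uses a genuinely sparse scene — 3 MB/mm²
reference-slice concentration, ≈1.4 effective in the high-frequency probe's
0.48 mm slice, about one in-plane MB per frame — spread over 4 vessel trees
of 2 branch levels,
because with few distinct vessel paths two same-vessel MBs travel within one
suppression radius for entire transits and the measurement becomes a packing
test rather than a pipeline test. A transit counts as recovered when ≥50% of
its frames have a pooled-track point within λ/4; the accompanying accuracy
statement is the aggregate mean matched error staying below λ/10, the
empirical localization-accuracy limit (an ensemble property — a stricter
per-transit variant, gating each transit on its own mean error, is also
computed and reported; it runs a few points lower because follower pairs
inside one suppression radius, near-lateral movers degraded by the
directional filter, and transits sitting at the accuracy limit each shave a
transit or two). Track identity is ignored because accumulation consumes
fragments equally.

## Numerical choices and degenerate inputs

- FWHM estimation interpolates linearly between bracketing samples, with no
  smoothing; a profile whose half maximum is not crossed on one side raises
  an error naming the side. Point-target FWHM measurement averages ±2
  parallel pixel lines (width-neutral for separable spots) to suppress
  noise-induced early crossings.
- Noise-equalization profiles are floored at 10⁻⁶ of their maximum; zero
  concentration produces an empty track table, a zero map and flagged
  (missing) metrics rather than errors.
- Splits that leave one half empty are re-drawn with an incremented seed
  (logged). FRC rings with zero energy are marked undefined and treated as
  zero when locating the crossing.
- All randomness flows from explicit integer seeds; pipeline stages derive
  independent streams by hashing the master seed with the stage name.
  Re-running a config reproduces candidates and tracks bit-identically.

## Known limitations

- Localization error under residual clutter is ~λ/15–λ/10 — consistent with
  the empirical accuracy limit in vivo — so recovery criteria tighter than
  λ/10 fail by construction under full clutter.
- Slow flow (dwell comparable to the clutter coherence time) is partially
  removed by the SVD filter; the simulator's deepest branch speeds are chosen
  above that regime.
- Desk-scale FRC resolutions (tens of μm from a few seconds of data and a few hundred
  tracks) are far coarser than long-acquisition values; only orderings across
  conditions are meaningful, not absolute numbers.
- The tracker has no gap closing: a missed detection splits a transit. The
  recovery metric pools fragments for exactly this reason.
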