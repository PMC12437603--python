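"""Evaluation layer: Fourier-ring-correlation resolution and saturation-time
modelling.

**FRC resolution.**  Tracks are randomly split in half, each half accumulated
into its own 1 μm map, and the two spectra correlated over rings of increasing
spatial frequency.  The first crossing of the (3-ring-smoothed) FRC curve
below a criterion curve — the ½-bit information threshold or the 2-σ noise
threshold — defines the resolution as the inverse of the crossing frequency.
The split/accumulate/correlate cycle is bootstrapped over five random splits
and reported as mean ± standard deviation.

**Saturation.**  The cumulative count of distinct filled map pixels versus
accumulation time is fit with the exponential saturation model
``S(t) = S_inf · (1 − exp(−t/τ))``; the time to reach a 90% mapping is
``t90 = τ·ln 10``.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import DomainError, EstimationError, FitError
from .maps import ULMImage, accumulate, rasterize_track
from .tracking import Track

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Fourier ring correlation
# --------------------------------------------------------------------------

@dataclass
class FRCCurve:
    ring_freqs_per_um: np.ndarray  # cycles/μm, increasing from DC
    correlation: np.ndarray        # values in [−1, 1]; NaN marks empty rings
    n_per_ring: np.ndarray


@dataclass
class ResolutionEstimate:
    mean_um: float
    std_um: float
    criterion: str
    n_repeats: int
    values_um: np.ndarray = field(default_factory=lambda: np.array([]))
    bound_flagged: bool = False  # True when some repeat never crossed: value is an upper bound


@dataclass
class SaturationFit:
    s_inf: float
    tau_s: float
    residual_rms: float

    def __post_init__(self):
        if self.s_inf <= 0 or self.tau_s <= 0:
            raise DomainError("saturation parameters must be positive")

    @property
    def t90_s(self) -> float:
        return self.tau_s * math.log(10.0)


def split_tracks(
    tracks: Sequence[Track], seed: int
) -> tuple[list[Track], list[Track]]:
    """Fair-coin assignment of whole tracks to two sub-accumulations.

    Deterministic given ``seed``; if a draw leaves one half empty, the draw is
    repeated with an incremented seed (logged).
    """
    if len(tracks) < 2:
        raise DomainError("need at least 2 tracks to split")
    s = seed
    for _ in range(1000):
        coins = np.random.default_rng(s).integers(0, 2, len(tracks))
        if 0 < coins.sum() < len(tracks):
            a = [t for t, c in zip(tracks, coins) if c == 0]
            b = [t for t, c in zip(tracks, coins) if c == 1]
            return a, b
        logger.info("split_tracks: degenerate draw at seed %d, re-drawing", s)
        s += 1
    raise EstimationError("could not produce a non-degenerate track split")


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def frc(image_a: ULMImage, image_b: ULMImage) -> FRCCurve:
    """Fourier ring correlation between two equally-gridded maps.

    ``FRC(r) = Re Σ F_A·conj(F_B) / sqrt(Σ|F_A|² · Σ|F_B|²)`` over
    integer-radius rings of one frequency-pixel width, from DC to Nyquist.
    Images are zero-padded to a square power-of-two size; no spectral window.
    """
    if image_a.shape != image_b.shape:
        raise DomainError("FRC inputs must share a shape")
    if not np.isclose(image_a.pixel_um, image_b.pixel_um):
        raise DomainError("FRC inputs must share a pixel grid")
    n = _next_pow2(max(image_a.shape))
    a = np.zeros((n, n))
    b = np.zeros((n, n))
    a[: image_a.shape[0], : image_a.shape[1]] = image_a.counts
    b[: image_b.shape[0], : image_b.shape[1]] = image_b.counts
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    k = np.fft.fftfreq(n) * n
    radius = np.rint(np.hypot(k[:, None], k[None, :])).astype(int)
    flat = radius.ravel()
    num = np.bincount(flat, weights=(fa * np.conj(fb)).real.ravel())
    d_a = np.bincount(flat, weights=(np.abs(fa) ** 2).ravel())
    d_b = np.bincount(flat, weights=(np.abs(fb) ** 2).ravel())
    n_ring = np.bincount(flat)
    n_keep = n // 2 + 1
    num, d_a, d_b, n_ring = (arr[:n_keep] for arr in (num, d_a, d_b, n_ring))
    denom = np.sqrt(d_a * d_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / np.maximum(denom, 1e-300), np.nan)
    corr = np.clip(corr, -1.0, 1.0, out=corr, where=~np.isnan(corr))
    freqs = np.arange(n_keep) / (n * image_a.pixel_um)
    return FRCCurve(ring_freqs_per_um=freqs, correlation=corr, n_per_ring=n_ring)


def threshold_half_bit(n) -> np.ndarray:
    """½-bit information threshold as a function of ring pixel count."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise DomainError("ring pixel count must be >= 1")
    rn = np.sqrt(n)
    return (0.2071 + 1.9102 / rn) / (1.2071 + 0.9102 / rn)


def threshold_two_sigma(n) -> np.ndarray:
    """2-σ noise threshold ``2/sqrt(n/2)`` as a function of ring pixel count."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise DomainError("ring pixel count must be >= 1")
    return 2.0 / np.sqrt(n / 2.0)


_CRITERIA = {"half_bit": threshold_half_bit, "two_sigma": threshold_two_sigma}


def _smooth(values: np.ndarray, window: int = 3) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    padded = np.pad(values, window // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def frc_crossing_um(curve: FRCCurve, criterion: str = "half_bit",
                    smooth_window: int = 3) -> Optional[float]:
    """Resolution (μm) at the first crossing of the smoothed FRC curve below
    the criterion curve; None when no crossing occurs before Nyquist."""
    try:
        thr_fn = _CRITERIA[criterion]
    except KeyError:
        raise DomainError(f"unknown criterion '{criterion}'") from None
    corr = np.nan_to_num(curve.correlation, nan=0.0)
    sm = _smooth(corr, smooth_window)
    valid = curve.n_per_ring > 0
    thr = np.ones_like(sm)
    thr[valid] = thr_fn(np.maximum(curve.n_per_ring[valid], 1))
    g = sm - thr
    for r in range(1, len(g)):
        if g[r] < 0 <= g[r - 1]:
            f0, f1 = curve.ring_freqs_per_um[r - 1], curve.ring_freqs_per_um[r]
            f_cross = f0 + (f1 - f0) * g[r - 1] / (g[r - 1] - g[r])
            if f_cross > 0:
                return float(1.0 / f_cross)
    return None


def resolution(
    tracks: Sequence[Track],
    fov_um: tuple[float, float],
    pixel_um: float = 1.0,
    criterion: str = "half_bit",
    n_repeats: int = 5,
    seed: int = 0,
    smooth_window: int = 3,
) -> ResolutionEstimate:
    """Bootstrapped FRC resolution over ``n_repeats`` random track splits.

    Repeats that never cross the criterion before Nyquist contribute the
    ``2·pixel`` sampling bound and flag the estimate.
    """
    values = []
    flagged = False
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2 ** 31)
    for rep in range(n_repeats):
        half_a, half_b = split_tracks(tracks, int(sub_seeds[rep]))
        img_a = accumulate(half_a, pixel_um, fov_um, weighting="per_track")
        img_b = accumulate(half_b, pixel_um, fov_um, weighting="per_track")
        res = frc_crossing_um(frc(img_a, img_b), criterion, smooth_window)
        if res is None:
            res = 2.0 * pixel_um
            flagged = True
        values.append(res)
    values = np.asarray(values)
    return ResolutionEstimate(
        mean_um=float(values.mean()),
        std_um=float(values.std()),
        criterion=criterion,
        n_repeats=n_repeats,
        values_um=values,
        bound_flagged=flagged,
    )


# --------------------------------------------------------------------------
# saturation modelling
# --------------------------------------------------------------------------

def saturation_curve(
    tracks: Sequence[Track],
    pixel_um: float,
    fov_um: tuple[float, float],
    n_bins: int,
    frame_rate_hz: float,
    duration_s: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative count of distinct filled density pixels per time bin.

    A track's pixels are counted from the bin containing its completion time
    (its last frame) onward, so the curve is non-decreasing by construction.
    ``duration_s`` sets the binned acquisition window; it defaults to the
    latest track completion time.
    """
    if n_bins < 3:
        raise DomainError("need at least 3 time bins")
    shape = (int(math.ceil(fov_um[0] / pixel_um)), int(math.ceil(fov_um[1] / pixel_um)))
    if len(tracks) == 0:
        times = np.linspace(0, duration_s or 1.0, n_bins)
        return times, np.zeros(n_bins)
    completion = np.array([(t.end_frame + 1) / frame_rate_hz for t in tracks])
    t_max = duration_s if duration_s is not None else completion.max()
    edges = np.linspace(0.0, t_max, n_bins + 1)[1:]
    filled = np.zeros(shape, dtype=bool)
    counts = np.zeros(n_bins)
    order = np.argsort(completion)
    j = 0
    for i, edge in enumerate(edges):
        while j < len(order) and completion[order[j]] <= edge + 1e-12:
            rows, cols, _ = rasterize_track(tracks[order[j]], shape, pixel_um)
            filled[rows, cols] = True
            j += 1
        counts[i] = filled.sum()
    return edges, counts


def fit_saturation(times_s: np.ndarray, filled: np.ndarray) -> SaturationFit:
    """Least-squares fit of ``S(t) = S_inf (1 − exp(−t/τ))``.

    Multi-start over τ ∈ {T/10, T/4, T/2, T, 2T}; raises when no start
    converges.
    """
    times_s = np.asarray(times_s, dtype=float)
    filled = np.asarray(filled, dtype=float)
    if len(times_s) < 5:
        raise DomainError("need at least 5 points to fit the saturation model")
    if np.any(np.diff(filled) < -1e-9):
        raise DomainError("saturation curve must be non-decreasing")
    if filled.max() <= 0:
        raise FitError("saturation curve is identically zero")

    def model(t, s_inf, tau):
        return s_inf * (1.0 - np.exp(-t / tau))

    t_span = times_s.max()
    best = None
    for tau0 in (t_span / 10, t_span / 4, t_span / 2, t_span, 2 * t_span):
        try:
            popt, _ = curve_fit(
                model, times_s, filled,
                p0=(filled.max() * 1.05, tau0),
                bounds=((1e-12, 1e-12), (np.inf, np.inf)),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        resid = filled - model(times_s, *popt)
        sse = float((resid ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitError("saturation model fit did not converge from any start")
    sse, (s_inf, tau) = best
    return SaturationFit(s_inf=float(s_inf), tau_s=float(tau),
                         residual_rms=float(np.sqrt(sse / len(times_s))))


def accumulation_time_to_resolution(
    tracks: Sequence[Track],
    target_resolution_um: float,
    fov_um: tuple[float, float],
    frame_rate_hz: float,
    pixel_um: float = 1.0,
    criterion: str = "half_bit",
    n_fractions: int = 8,
    n_repeats: int = 3,
    seed: int = 0,
) -> Optional[float]:
    """Shortest accumulation time (s) whose gradual sub-accumulation reaches
    ``target_resolution_um`` under the given FRC criterion; None if even the
    full set does not reach it."""
    if not tracks:
        return None
    end_times = np.array([(t.end_frame + 1) / frame_rate_hz for t in tracks])
    t_total = end_times.max()
    for frac in np.linspace(1.0 / n_fractions, 1.0, n_fractions):
        subset = [t for t, e in zip(tracks, end_times) if e <= frac * t_total + 1e-12]
        if len(subset) < 2:
            continue
        est = resolution(subset, fov_um, pixel_um, criterion,
                         n_repeats=n_repeats, seed=seed)
        if not est.bound_flagged and est.mean_um <= target_resolution_um:
            return float(frac * t_total)
    return None
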