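"""Tissue-clutter rejection and microbubble signal conditioning.

Three stages, applied per acquisition ensemble:

1. **SVD clutter filter** — the stack is reshaped into a Casorati matrix
   (pixels × frames) and the leading singular components, which carry the
   high-energy temporally coherent tissue signal, are zeroed.  The low-order
   cutoff can be fixed or chosen adaptively from the singular-value curve.
   No high-order (noise) cutoff is applied: late singular components still
   carry microbubble signal in low-flow regions.
2. **Noise equalization** — the depth-dependent noise floor left by the filter
   is estimated robustly per depth row (temporal median of the row-wise median
   absolute amplitude), smoothed by a 2nd-order polynomial in depth, and
   divided out.
3. **Directional separation** — a spatiotemporal Fourier quadrant filter
   splits the stack into upward- and downward-moving components (axial
   velocity sign ↔ sign pairing of axial and temporal frequencies), which
   de-overlaps counter-flowing microbubbles.  The two branches sum back to the
   input exactly.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .core import FrameStack
from .errors import DomainError

DEFAULT_ENSEMBLE_FRAMES = 1000


@dataclass
class SingularSpectrum:
    singular_values: np.ndarray
    n_pixels: int
    n_frames: int

    def __post_init__(self):
        sv = np.asarray(self.singular_values, dtype=float)
        if len(sv) != min(self.n_pixels, self.n_frames):
            raise DomainError("spectrum length must equal min(n_pixels, n_frames)")
        if np.any(sv < -1e-12) or np.any(np.diff(sv) > 1e-9 * max(sv[0], 1.0)):
            raise DomainError("singular values must be non-negative and non-increasing")
        self.singular_values = sv

    @property
    def rank(self) -> int:
        return len(self.singular_values)


@dataclass
class FilterReport:
    low_cutoff: int
    high_cutoff: None = None
    noise_profile: Optional[np.ndarray] = None
    spectrum: Optional["SingularSpectrum"] = None  # kept for inspection plots


def casorati(stack: FrameStack) -> tuple[np.ndarray, tuple[int, int]]:
    """Reshape a stack into its (pixels × frames) Casorati matrix.

    Column ``t`` is frame ``t`` flattened in row-major order; the inverse
    reshaping is exact.
    """
    if stack.n_t < 2:
        raise DomainError("Casorati matrix needs at least 2 frames")
    mat = stack.data.reshape(stack.n_z * stack.n_x, stack.n_t)
    return mat, (stack.n_z, stack.n_x)


def uncasorati(matrix: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    n_z, n_x = shape
    return matrix.reshape(n_z, n_x, matrix.shape[1])


def svd_filter(
    stack: FrameStack,
    low_cutoff: Union[int, str] = "adaptive",
) -> tuple[FrameStack, SingularSpectrum, FilterReport]:
    """Remove the first ``low_cutoff`` singular components of the Casorati
    matrix (``"adaptive"`` selects the cutoff from the spectrum's log-slope)."""
    mat, shape = casorati(stack)
    mat64 = np.asarray(mat, dtype=np.float64)
    u, s, vt = np.linalg.svd(mat64, full_matrices=False)
    spectrum = SingularSpectrum(s, n_pixels=mat.shape[0], n_frames=mat.shape[1])
    if low_cutoff == "adaptive":
        k = adaptive_cutoff(spectrum)
    else:
        k = int(low_cutoff)
        if not 0 <= k < spectrum.rank:
            raise DomainError(f"cutoff {k} outside [0, rank={spectrum.rank})")
    if k == 0:
        filtered = stack.with_data(stack.data.copy())
    else:
        clutter = (u[:, :k] * s[:k]) @ vt[:k]
        filtered = stack.with_data(uncasorati(mat64 - clutter, shape).astype(stack.data.dtype))
    return filtered, spectrum, FilterReport(low_cutoff=k, spectrum=spectrum)


def adaptive_cutoff(
    spectrum: SingularSpectrum,
    slope_tol: float = 0.1,
    window: int = 5,
) -> int:
    """Low-order cutoff from the decay of the singular-value curve.

    Returns the smallest ``k ≥ 1`` at which the local least-squares slope of
    ``log σ`` over a ``window``-point window exceeds ``−slope_tol`` per index
    (the curve has flattened out of the steep tissue regime), clamped to
    ``[1, rank/4]``.  The default tolerance, 0.1 nats (≈0.9 dB) per index,
    sits between the multi-dB-per-index decay of coherent tissue components
    and the slow tail of the microbubble/noise subspace.
    """
    if spectrum.rank < 10:
        raise DomainError("need at least 10 singular values for adaptive cutoff")
    log_s = np.log(np.maximum(spectrum.singular_values, 1e-300))
    k_max = max(1, spectrum.rank // 4)
    xs = np.arange(window) - (window - 1) / 2.0
    denom = (xs ** 2).sum()
    for k in range(1, k_max + 1):
        seg = log_s[k:k + window]
        if len(seg) < window:
            break
        slope = (xs * (seg - seg.mean())).sum() / denom
        if slope > -slope_tol:
            return k
    return k_max


def noise_equalize(stack: FrameStack) -> tuple[FrameStack, np.ndarray]:
    """Flatten the depth-dependent noise floor.

    The per-depth-row noise amplitude is the temporal median of the row-wise
    median absolute amplitude — medians make the profile insensitive to sparse
    bright microbubbles — smoothed by a 2nd-order polynomial in depth; each
    row is divided by its profile value.
    """
    amp = np.abs(stack.data)
    row_median = np.median(amp, axis=1)          # (n_z, n_t)
    raw_profile = np.median(row_median, axis=1)  # (n_z,)
    z_idx = np.arange(stack.n_z, dtype=float)
    if stack.n_z >= 3:
        coeffs = np.polyfit(z_idx, raw_profile, deg=2)
        profile = np.polyval(coeffs, z_idx)
    else:
        profile = raw_profile.copy()
    floor = 1e-6 * max(profile.max(), raw_profile.max(), 1e-30)
    profile = np.maximum(profile, floor)
    out = stack.data / profile[:, None, None].astype(stack.data.dtype)
    return stack.with_data(out), profile


def directional_separation(stack: FrameStack) -> tuple[FrameStack, FrameStack]:
    """Split a stack into upward- (toward transducer) and downward-moving
    components by spatiotemporal Fourier quadrant filtering.

    A scatterer moving with ``dz/dt = −v`` (upward, v > 0) concentrates its
    energy where the axial and temporal frequencies share a sign; the opposite
    quadrants carry downward motion.  Zero-frequency planes are split equally,
    so ``up + down`` reconstructs the input exactly.
    """
    if stack.n_t < 8:
        raise DomainError("directional separation needs at least 8 frames")
    spec = np.fft.fftn(stack.data.astype(np.float64), axes=(0, 2))
    kz = np.fft.fftfreq(stack.n_z)[:, None, None]
    ft = np.fft.fftfreq(stack.n_t)[None, None, :]
    prod = np.sign(kz) * np.sign(ft)
    weight_up = np.where(prod > 0, 1.0, np.where(prod < 0, 0.0, 0.5))
    up = np.fft.ifftn(spec * weight_up, axes=(0, 2)).real
    down = stack.data.astype(np.float64) - up
    return (
        stack.with_data(up.astype(stack.data.dtype)),
        stack.with_data(down.astype(stack.data.dtype)),
    )


def filter_ensembles(
    stack: FrameStack,
    low_cutoff: Union[int, str] = "adaptive",
    ensemble_frames: int = DEFAULT_ENSEMBLE_FRAMES,
    equalize: bool = True,
    separate: bool = True,
) -> tuple[FrameStack, FrameStack, list[FilterReport]]:
    """Run SVD filter → noise equalization → directional separation on
    consecutive ``ensemble_frames``-frame chunks, independently per chunk, and
    concatenate the results.  Returns (up, down, per-ensemble reports); with
    ``separate=False`` both outputs are the same filtered stack."""
    ups, downs, reports = [], [], []
    for t0 in range(0, stack.n_t, ensemble_frames):
        chunk = stack.time_slice(t0, min(t0 + ensemble_frames, stack.n_t))
        if chunk.n_t < 2:
            break
        filtered, _, report = svd_filter(chunk, low_cutoff)
        if equalize:
            filtered, profile = noise_equalize(filtered)
            report.noise_profile = profile
        reports.append(report)
        if separate:
            up, down = directional_separation(filtered)
        else:
            up = down = filtered
        ups.append(up.data)
        downs.append(down.data)
    if not ups:
        raise DomainError("stack too short for ensemble filtering")
    up_stack = stack.with_data(np.concatenate(ups, axis=2))
    down_stack = stack.with_data(np.concatenate(downs, axis=2))
    return up_stack, down_stack, reports
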