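"""Sub-pixel microbubble localization.

Each clutter-filtered frame is cubic-spline interpolated onto an isotropic
λ/10 grid, cross-correlated (zero-normalized) against a 2D Gaussian
microbubble template, and thresholded at an NCC score of 0.6.  Local maxima
survive non-maximum suppression within one lateral FWHM, and a 3×3 paraboloid
fit around each surviving peak refines the position to sub-grid precision.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RectBivariateSpline
from skimage.feature import match_template

from .core import FrameStack
from .errors import DomainError
from .transducer import (
    FWHM_PER_SIGMA,
    SOUND_SPEED_TISSUE_M_S,
    TransducerSpec,
    wavelength,
)


@dataclass
class LocalizationConfig:
    """Localization parameters (all lengths in μm).

    ``interp_target_um`` is the isotropic interpolation grid (λ/10);
    template sigmas derive from the theoretical PSF (FWHM λ axial,
    2λ lateral); ``min_separation_um`` is the non-maximum-suppression radius,
    one lateral FWHM by default.
    """

    interp_target_um: float
    template_sigma_axial_um: float
    template_sigma_lateral_um: float
    min_separation_um: float
    ncc_threshold: float = 0.6

    def __post_init__(self):
        if not 0.0 < self.ncc_threshold < 1.0:
            raise DomainError("NCC threshold must lie in (0, 1)")
        if self.template_sigma_axial_um <= 0 or self.template_sigma_lateral_um <= 0:
            raise DomainError("template sigmas must be positive")
        if self.interp_target_um <= 0 or self.min_separation_um <= 0:
            raise DomainError("grid spacing and separation must be positive")

    @classmethod
    def for_transducer(
        cls,
        transducer: TransducerSpec,
        sound_speed_m_s: float = SOUND_SPEED_TISSUE_M_S,
        ncc_threshold: float = 0.6,
    ) -> "LocalizationConfig":
        lam = wavelength(sound_speed_m_s, transducer.center_frequency_mhz)
        return cls(
            interp_target_um=lam / 10.0,
            template_sigma_axial_um=lam / FWHM_PER_SIGMA,
            template_sigma_lateral_um=2.0 * lam / FWHM_PER_SIGMA,
            min_separation_um=2.0 * lam,
            ncc_threshold=ncc_threshold,
        )


@dataclass(frozen=True)
class MBCandidate:
    """One sub-pixel localization (scene μm coordinates)."""

    frame: int
    z_um: float
    x_um: float
    score: float
    branch: str = "all"


def upsample(
    frame: np.ndarray,
    dz_um: float,
    dx_um: float,
    target_um: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cubic-spline interpolation onto an isotropic grid of ``target_um``.

    Returns ``(frame_up, z_up, x_up)`` with coordinates in μm relative to the
    input frame's pixel (0, 0).  The interpolant passes through the original
    samples, so values at original nodes are preserved.
    """
    if target_um >= min(dz_um, dx_um):
        raise DomainError(
            f"target {target_um} μm must be finer than input spacing ({dz_um}, {dx_um})"
        )
    nz, nx = frame.shape
    z = np.arange(nz) * dz_um
    x = np.arange(nx) * dx_um
    kz = min(3, nz - 1)
    kx = min(3, nx - 1)
    spline = RectBivariateSpline(z, x, np.asarray(frame, dtype=np.float64), kx=kz, ky=kx, s=0)
    z_up = np.arange(0.0, z[-1] + 1e-9, target_um)
    x_up = np.arange(0.0, x[-1] + 1e-9, target_um)
    return spline(z_up, x_up), z_up, x_up


def gaussian_template(
    sigma_z_um: float,
    sigma_x_um: float,
    pixel_um: float,
) -> np.ndarray:
    """2D Gaussian MB template with ±2σ support, odd pixel counts."""
    hz = max(1, int(np.ceil(2.0 * sigma_z_um / pixel_um)))
    hx = max(1, int(np.ceil(2.0 * sigma_x_um / pixel_um)))
    zz = (np.arange(-hz, hz + 1) * pixel_um)[:, None]
    xx = (np.arange(-hx, hx + 1) * pixel_um)[None, :]
    return np.exp(-0.5 * ((zz / sigma_z_um) ** 2 + (xx / sigma_x_um) ** 2))


def ncc_map(frame: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Zero-normalized cross-correlation at every valid offset, in [−1, 1].

    ``map[i, j]`` scores the template whose top-left corner sits at
    ``(i, j)``.  A flat window under the template scores 0; windows that are
    flat to numerical precision (std below 1e-6 of the frame's dynamic range)
    are treated the same — zero-normalized correlation is scale invariant, so
    without this guard the far tails of a bright scatterer would correlate as
    strongly as the scatterer itself.
    """
    if template.shape[0] > frame.shape[0] or template.shape[1] > frame.shape[1]:
        raise DomainError("template must be smaller than the frame")
    frame = np.asarray(frame, dtype=np.float64)
    out = match_template(frame, np.asarray(template, dtype=np.float64))
    out = np.nan_to_num(out, nan=0.0, posinf=0.0, neginf=0.0)
    scale = float(np.ptp(frame))
    if scale > 0:
        local_mean = ndimage.uniform_filter(frame, size=template.shape)
        local_sq = ndimage.uniform_filter(frame ** 2, size=template.shape)
        local_std = np.sqrt(np.maximum(local_sq - local_mean ** 2, 0.0))
        hz, hx = template.shape[0] // 2, template.shape[1] // 2
        valid = local_std[hz:hz + out.shape[0], hx:hx + out.shape[1]]
        out[valid < 1e-6 * scale] = 0.0
    return np.clip(out, -1.0, 1.0)


def _paraboloid_offset(patch: np.ndarray) -> tuple[float, float]:
    """Sub-pixel peak offset from a 3×3 neighbourhood.

    Least-squares quadratic surface fit; falls back to an intensity centroid
    when the fitted Hessian is not negative-definite.  The returned
    displacement is clamped to ±1 grid step in each axis.
    """
    dz, dx = np.meshgrid([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0], indexing="ij")
    a = np.stack(
        [np.ones(9), dz.ravel(), dx.ravel(), dz.ravel() ** 2, dx.ravel() ** 2,
         (dz * dx).ravel()], axis=1
    )
    c = np.linalg.lstsq(a, patch.ravel(), rcond=None)[0]
    hess = np.array([[2 * c[3], c[5]], [c[5], 2 * c[4]]])
    if hess[0, 0] < 0 and np.linalg.det(hess) > 0:
        off = np.linalg.solve(hess, -np.array([c[1], c[2]]))
    else:
        w = patch - patch.min()
        tot = w.sum()
        if tot <= 0:
            return 0.0, 0.0
        off = np.array([(w * dz).sum() / tot, (w * dx).sum() / tot])
    off = np.clip(off, -1.0, 1.0)
    return float(off[0]), float(off[1])


def detect(
    ncc: np.ndarray,
    template_shape: tuple[int, int],
    grid_um: float,
    config: LocalizationConfig,
    frame_index: int = 0,
    branch: str = "all",
    origin_um: tuple[float, float] = (0.0, 0.0),
    frame_extent_um: tuple[float, float] | None = None,
) -> list[MBCandidate]:
    """Thresholded local maxima of an NCC map with non-maximum suppression and
    paraboloid sub-pixel refinement, as scene-coordinate candidates."""
    thr = config.ncc_threshold
    peaks = (ndimage.maximum_filter(ncc, size=3, mode="constant", cval=-2.0) == ncc) & (ncc >= thr)
    iz, ix = np.nonzero(peaks)
    if len(iz) == 0:
        return []
    order = np.argsort(ncc[iz, ix])[::-1]
    iz, ix = iz[order], ix[order]
    min_sep_px = config.min_separation_um / grid_um

    kept: list[tuple[int, int]] = []
    for z0, x0 in zip(iz, ix):
        if any((z0 - zk) ** 2 + (x0 - xk) ** 2 < min_sep_px ** 2 for zk, xk in kept):
            continue
        kept.append((int(z0), int(x0)))

    hz, hx = template_shape[0] // 2, template_shape[1] // 2
    out: list[MBCandidate] = []
    for z0, x0 in kept:
        if not (0 < z0 < ncc.shape[0] - 1 and 0 < x0 < ncc.shape[1] - 1):
            # a peak pinned on the valid-region border has no full template
            # window and no 3×3 neighbourhood: not a trustworthy localization
            continue
        dzs, dxs = _paraboloid_offset(ncc[z0 - 1:z0 + 2, x0 - 1:x0 + 2])
        z_um = origin_um[0] + (z0 + dzs + hz) * grid_um
        x_um = origin_um[1] + (x0 + dxs + hx) * grid_um
        if frame_extent_um is not None:
            if not (origin_um[0] <= z_um <= origin_um[0] + frame_extent_um[0]
                    and origin_um[1] <= x_um <= origin_um[1] + frame_extent_um[1]):
                continue
        out.append(MBCandidate(frame=frame_index, z_um=float(z_um), x_um=float(x_um),
                               score=float(ncc[z0, x0]), branch=branch))
    return out


def localize_frame(
    frame: np.ndarray,
    dz_um: float,
    dx_um: float,
    config: LocalizationConfig,
    frame_index: int = 0,
    branch: str = "all",
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> list[MBCandidate]:
    """Upsample → NCC → detect, for one frame."""
    frame_up, z_up, x_up = upsample(frame, dz_um, dx_um, config.interp_target_um)
    template = gaussian_template(
        config.template_sigma_axial_um, config.template_sigma_lateral_um,
        config.interp_target_um,
    )
    if template.shape[0] > frame_up.shape[0] or template.shape[1] > frame_up.shape[1]:
        return []
    corr = ncc_map(frame_up, template)
    return detect(
        corr, template.shape, config.interp_target_um, config,
        frame_index=frame_index, branch=branch, origin_um=origin_um,
        frame_extent_um=(z_up[-1], x_up[-1]),
    )


def localize_stack(
    stack: FrameStack,
    config: LocalizationConfig,
    branch: str = "all",
    frame_offset: int = 0,
) -> list[MBCandidate]:
    """Localize every frame of a (filtered) stack."""
    out: list[MBCandidate] = []
    for t in range(stack.n_t):
        out.extend(
            localize_frame(
                stack.frame(t), stack.pixel_dz_um, stack.pixel_dx_um, config,
                frame_index=frame_offset + t, branch=branch, origin_um=stack.origin_um,
            )
        )
    return out


def merge_candidates(
    candidates: list[MBCandidate],
    min_separation_um: float,
) -> list[MBCandidate]:
    """Merge candidate lists (e.g. from the up and down branches).

    Two candidates in the same frame closer than ``min_separation_um / 2``
    collapse to the higher-scoring one.
    """
    by_frame: dict[int, list[MBCandidate]] = {}
    for c in candidates:
        by_frame.setdefault(c.frame, []).append(c)
    radius2 = (min_separation_um / 2.0) ** 2
    merged: list[MBCandidate] = []
    for frame in sorted(by_frame):
        kept: list[MBCandidate] = []
        for c in sorted(by_frame[frame], key=lambda c: -c.score):
            if any((c.z_um - k.z_um) ** 2 + (c.x_um - k.x_um) ** 2 < radius2 for k in kept):
                continue
            kept.append(c)
        merged.extend(kept)
    return merged
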