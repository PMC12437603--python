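"""Ground-truthed synthetic vascular flow and contrast-enhanced frame stacks.

The generator emulates the statistical structure the reconstruction pipeline
assumes, at desk scale:

* a branching vessel tree (Murray-type radius splitting, Poiseuille-like
  ``speed ∝ radius²``) inside a rectangular imaging plane;
* microbubble (MB) transits entering the tree as a Poisson process, each MB
  carrying a fixed elevational offset inside the slice thickness and a
  log-normal amplitude;
* rendered frames in which every in-plane MB is stamped as an anisotropic
  Gaussian with the frequency-dependent PSF (axial FWHM λ, lateral 2λ), on top
  of a low-rank, slowly varying, high-energy tissue-clutter field, plus white
  noise whose standard deviation grows linearly with depth, with exponential
  frequency-dependent attenuation applied to the MB amplitudes.

All randomness is driven by explicit integer seeds; identical seeds reproduce
identical scenes bit-for-bit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import FrameStack
from .errors import DomainError, GenerationError
from .transducer import FWHM_PER_SIGMA, SOUND_SPEED_TISSUE_M_S, TransducerSpec, wavelength


# --------------------------------------------------------------------------
# vessel geometry
# --------------------------------------------------------------------------

@dataclass
class VesselSegment:
    """One straight centreline segment of the vascular tree (μm units)."""

    start: np.ndarray  # (z, x)
    end: np.ndarray
    radius_um: float
    mean_speed_um_s: float
    parent: Optional[int] = None
    children: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        if self.radius_um <= 0:
            raise DomainError("vessel radius must be positive")
        if self.mean_speed_um_s < 0:
            raise DomainError("mean speed must be non-negative")
        if np.allclose(self.start, self.end):
            raise DomainError("segment start and end coincide")

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(self.end - self.start))

    @property
    def direction(self) -> np.ndarray:
        d = self.end - self.start
        return d / np.linalg.norm(d)


@dataclass
class VesselTree:
    segments: list[VesselSegment]
    fov_um: tuple[float, float]  # (z extent, x extent)
    seed: int
    roots: list[int] = field(default_factory=list)

    def leaves(self) -> list[int]:
        return [i for i, s in enumerate(self.segments) if not s.children]

    def enumerate_paths(self, root: int) -> list[tuple[list[int], float]]:
        """All root→leaf segment index paths with their branch probabilities."""
        out: list[tuple[list[int], float]] = []

        def walk(idx, path, prob):
            seg = self.segments[idx]
            path = path + [idx]
            if not seg.children:
                out.append((path, prob))
                return
            p = prob / len(seg.children)
            for c in seg.children:
                walk(c, path, p)

        walk(root, [], 1.0)
        return out

    def lumen_mask(self, pixel_um: float, dilation_um: float = 0.0) -> np.ndarray:
        """Boolean raster of the vessel lumen on a grid of ``pixel_um`` spacing."""
        nz = int(math.ceil(self.fov_um[0] / pixel_um))
        nx = int(math.ceil(self.fov_um[1] / pixel_um))
        zz = (np.arange(nz) + 0.5) * pixel_um
        xx = (np.arange(nx) + 0.5) * pixel_um
        Z, X = np.meshgrid(zz, xx, indexing="ij")
        pts = np.stack([Z.ravel(), X.ravel()], axis=1)
        mask = np.zeros(pts.shape[0], dtype=bool)
        for seg in self.segments:
            d = _point_segment_distance(pts, seg.start, seg.end)
            mask |= d <= seg.radius_um + dilation_um
        return mask.reshape(nz, nx)


def _point_segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def generate_vessel_tree(
    seed: int,
    fov_um: tuple[float, float] = (1000.0, 1000.0),
    n_roots: int = 1,
    branch_levels: int = 3,
    root_radius_um: float = 20.0,
    root_speed_um_s: float = 5000.0,
    margin_um: Optional[float] = None,
) -> VesselTree:
    """Recursive binary branching tree inside ``fov_um``.

    Child radii follow a Murray-type rule ``r_parent³ = Σ r_child³`` with a
    mildly asymmetric split, and mean speeds scale as ``radius²``
    (Poiseuille-like).  Deterministic given ``seed``.
    """
    if fov_um[0] <= 0 or fov_um[1] <= 0:
        raise DomainError("field of view must be positive")
    if n_roots < 1:
        raise DomainError("need at least one root")
    if branch_levels < 0:
        raise DomainError("branch_levels must be >= 0")
    rng = np.random.default_rng(seed)
    if margin_um is None:
        margin_um = 0.08 * min(fov_um)
    lo = np.array([margin_um, margin_um])
    hi = np.array([fov_um[0] - margin_um, fov_um[1] - margin_um])
    base_len = (fov_um[0] - 2 * margin_um) / (branch_levels + 1)

    segments: list[VesselSegment] = []
    roots: list[int] = []

    def place(start, direction, length, radius, speed, parent, level):
        centre = (lo + hi) / 2.0
        for attempt in range(100):
            end = start + direction * length
            if np.all(end >= lo) and np.all(end <= hi):
                break
            # steer toward the interior and shrink
            to_centre = centre - start
            to_centre /= np.linalg.norm(to_centre)
            ang = rng.uniform(-0.3, 0.3)
            c, s = math.cos(ang), math.sin(ang)
            direction = np.array([c * to_centre[0] - s * to_centre[1],
                                  s * to_centre[0] + c * to_centre[1]])
            length *= 0.9
        else:
            raise GenerationError("could not place segment inside field of view after 100 attempts")
        idx = len(segments)
        segments.append(VesselSegment(start, end, radius, speed, parent=parent))
        if parent is not None:
            segments[parent].children.append(idx)
        if level < branch_levels:
            split = rng.uniform(0.4, 0.6)
            for frac, sign in ((split, 1.0), (1.0 - split, -1.0)):
                r_child = radius * frac ** (1.0 / 3.0)
                v_child = speed * (r_child / radius) ** 2
                ang = sign * rng.uniform(0.3, 0.7)
                c, s = math.cos(ang), math.sin(ang)
                d = segments[idx].direction
                d_child = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
                child_len = length * rng.uniform(0.75, 0.95)
                place(end.copy(), d_child, child_len, r_child, v_child, idx, level + 1)
        return idx

    for _ in range(n_roots):
        x0 = rng.uniform(lo[1], hi[1])
        start = np.array([margin_um, x0])
        theta = rng.uniform(-0.35, 0.35)  # mostly downward (+z)
        direction = np.array([math.cos(theta), math.sin(theta)])
        roots.append(
            place(start, direction, base_len * rng.uniform(0.9, 1.1),
                  root_radius_um, root_speed_um_s, None, 0)
        )
    return VesselTree(segments=segments, fov_um=tuple(fov_um), seed=seed, roots=roots)


# --------------------------------------------------------------------------
# microbubble transits
# --------------------------------------------------------------------------

@dataclass
class MBTrajectory:
    """One ground-truth microbubble transit through the vessel tree."""

    frames: np.ndarray        # strictly consecutive frame indices
    zs_um: np.ndarray
    xs_um: np.ndarray
    segment_ids: np.ndarray
    y_um: float               # fixed elevational offset within the slice
    amplitude: float          # rendered echo amplitude (elevational × log-normal)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of (frame, z, x)."""
        return np.stack([self.frames.astype(float), self.zs_um, self.xs_um], axis=1)


def simulate_mb_flow(
    tree: VesselTree,
    concentration_per_mm2: float,
    frame_rate_hz: float,
    duration_s: float,
    seed: int,
    elevational_beamwidth_mm: float = 1.0,
    lateral_jitter_um: float = 0.3,
    amplitude_sigma_db: float = 3.0,
) -> list[MBTrajectory]:
    """Poisson microbubble transits with the time-averaged in-plane count
    calibrated to ``concentration × field-of-view area``.

    Each MB enters at a root, picks children uniformly at random, advances by
    ``mean_speed/frame_rate`` per frame with a small lateral random walk, and
    exits at a leaf.  Elevational position is drawn uniformly inside the slice
    (``|y| < beamwidth/2``) and weights the echo amplitude through a Gaussian
    elevational sensitivity; amplitude variability is log-normal with
    ``amplitude_sigma_db`` spread.
    """
    if concentration_per_mm2 < 0:
        raise DomainError("concentration must be non-negative")
    if duration_s <= 0:
        raise DomainError("duration must be positive")
    if concentration_per_mm2 == 0:
        return []
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate_hz))
    fov_area_mm2 = tree.fov_um[0] * tree.fov_um[1] * 1e-6
    target_count = concentration_per_mm2 * fov_area_mm2
    bw_um = elevational_beamwidth_mm * 1000.0

    trajectories: list[MBTrajectory] = []
    for root in tree.roots:
        paths = tree.enumerate_paths(root)
        mean_transit = sum(
            p * sum(tree.segments[i].length_um / max(tree.segments[i].mean_speed_um_s, 1e-9)
                    for i in path)
            for path, p in paths
        )
        rate = target_count / (len(tree.roots) * mean_transit)  # entries per second
        # extend the entry window backwards by the longest transit so the
        # process is stationary over [0, duration): transits already in
        # progress at t = 0 are represented
        max_transit = max(
            sum(tree.segments[i].length_um / max(tree.segments[i].mean_speed_um_s, 1e-9)
                for i in path)
            for path, _ in paths
        )
        n_entries = rng.poisson(rate * (duration_s + max_transit))
        entry_times = np.sort(rng.uniform(-max_transit, duration_s, n_entries))
        for t0 in entry_times:
            traj = _propagate_mb(tree, root, t0, n_frames, frame_rate_hz, rng,
                                 bw_um, lateral_jitter_um, amplitude_sigma_db)
            if traj is not None:
                trajectories.append(traj)
    return trajectories


def _propagate_mb(tree, root, t0, n_frames, frame_rate, rng,
                  bw_um, jitter_um, amp_sigma_db) -> Optional[MBTrajectory]:
    # choose a path by uniform child selection
    path = [root]
    while tree.segments[path[-1]].children:
        path.append(int(rng.choice(tree.segments[path[-1]].children)))
    segs = [tree.segments[i] for i in path]
    seg_times = np.array([s.length_um / max(s.mean_speed_um_s, 1e-9) for s in segs])
    cum_t = np.concatenate([[0.0], np.cumsum(seg_times)])
    total_t = cum_t[-1]

    k0 = max(0, int(math.ceil(t0 * frame_rate)))
    k1 = min(int(math.floor((t0 + total_t) * frame_rate)), n_frames - 1)
    if k1 < k0:
        return None
    frames = np.arange(k0, k1 + 1)
    tau = frames / frame_rate - t0  # time inside the tree, in [0, total_t]
    idx = np.clip(np.searchsorted(cum_t, tau, side="right") - 1, 0, len(segs) - 1)

    starts = np.stack([s.start for s in segs])
    dirs = np.stack([s.direction for s in segs])
    speeds = np.array([s.mean_speed_um_s for s in segs])
    radii = np.array([s.radius_um for s in segs])
    s_in = (tau - cum_t[idx]) * speeds[idx]
    centre = starts[idx] + dirs[idx] * s_in[:, None]

    # lateral offset: fixed streamline fraction plus a small random walk,
    # clamped inside the lumen
    rho = rng.uniform(-0.8, 0.8)
    walk = np.cumsum(rng.normal(0.0, jitter_um, len(frames)))
    offset = np.clip(rho * radii[idx] + walk, -0.95 * radii[idx], 0.95 * radii[idx])
    normal = np.stack([-dirs[idx][:, 1], dirs[idx][:, 0]], axis=1)
    pos = centre + normal * offset[:, None]

    y = rng.uniform(-bw_um / 2.0, bw_um / 2.0)
    elev_gain = math.exp(-4.0 * math.log(2.0) * (y / bw_um) ** 2)
    amp = elev_gain * 10.0 ** (rng.normal(0.0, amp_sigma_db) / 20.0)
    return MBTrajectory(
        frames=frames,
        zs_um=pos[:, 0],
        xs_um=pos[:, 1],
        segment_ids=np.array([path[i] for i in idx]),
        y_um=float(y),
        amplitude=float(amp),
    )


def thin_trajectories(
    trajectories: Sequence[MBTrajectory],
    keep_fraction: float,
    seed: int,
) -> list[MBTrajectory]:
    """Independent per-transit thinning of a Poisson transit set.

    Keeping each transit with probability ``keep_fraction`` yields a transit
    set with exactly the statistics of a simulation at the proportionally
    lower concentration (thinning a Poisson process is a Poisson process),
    *coupled* to the original: the two scenes differ only by the dropped
    bubbles.  Paired concentration comparisons use this to remove
    scene-composition variance.
    """
    if not 0.0 <= keep_fraction <= 1.0:
        raise DomainError("keep fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return [t for t in trajectories if rng.random() < keep_fraction]


# --------------------------------------------------------------------------
# frame rendering
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Clutter/noise configuration for frame rendering.

    ``clutter_db`` sets how far the per-frame clutter peak sits above the
    nominal MB amplitude (None disables clutter); ``noise_std`` is the white
    noise standard deviation at the surface, growing linearly with depth by a
    factor ``1 + noise_depth_gain`` at the bottom of the field of view.
    """

    clutter_db: Optional[float] = 20.0
    clutter_rank: int = 5
    noise_std: float = 0.05
    noise_depth_gain: float = 1.0


def render_frame_stack(
    trajectories: Sequence[MBTrajectory],
    tree: VesselTree,
    transducer: TransducerSpec,
    frame_rate_hz: float,
    duration_s: Optional[float] = None,
    n_frames: Optional[int] = None,
    pixel_um: Optional[float] = None,
    noise: NoiseModel = NoiseModel(),
    attenuation_db_cm_mhz: float = 0.5,
    seed: int = 0,
    sound_speed_m_s: float = SOUND_SPEED_TISSUE_M_S,
) -> FrameStack:
    """Render ground-truth transits into a calibrated envelope frame stack.

    Every in-plane MB is stamped as an anisotropic Gaussian with FWHM
    (λ axial, 2λ lateral); a rank-≤``clutter_rank`` spatiotemporal clutter
    field and depth-growing white noise are added on top.  MB amplitudes decay
    with depth as ``10^(−μ·f·z/20)`` (``μ`` in dB/cm/MHz).  The default grid
    spacing is λ/4 — coarser than the λ/10 localization grid, so the
    interpolation stage downstream does real work.
    """
    lam = wavelength(sound_speed_m_s, transducer.center_frequency_mhz)
    if pixel_um is None:
        pixel_um = lam / 4.0
    if pixel_um > lam / 2.0:
        raise DomainError(f"pixel spacing {pixel_um:.2f} μm exceeds λ/2 = {lam / 2:.2f} μm")
    if n_frames is None:
        if duration_s is None:
            raise DomainError("provide duration_s or n_frames")
        n_frames = int(round(duration_s * frame_rate_hz))
    n_z = int(math.ceil(tree.fov_um[0] / pixel_um))
    n_x = int(math.ceil(tree.fov_um[1] / pixel_um))
    if n_z < 1 or n_x < 1:
        raise DomainError("empty field of view")

    data = np.zeros((n_z, n_x, n_frames), dtype=np.float32)
    sigma_z = lam / FWHM_PER_SIGMA
    sigma_x = 2.0 * lam / FWHM_PER_SIGMA
    hz = max(1, int(math.ceil(3.0 * sigma_z / pixel_um)))
    hx = max(1, int(math.ceil(3.0 * sigma_x / pixel_um)))
    dz_off = np.arange(-hz, hz + 1)[:, None] * pixel_um
    dx_off = np.arange(-hx, hx + 1)[None, :] * pixel_um
    atten_per_um = attenuation_db_cm_mhz * transducer.center_frequency_mhz / 1e4  # dB per μm

    for traj in trajectories:
        for k in range(len(traj)):
            t = int(traj.frames[k])
            if t < 0 or t >= n_frames:
                continue
            z, x = traj.zs_um[k], traj.xs_um[k]
            iz = int(round(z / pixel_um))
            ix = int(round(x / pixel_um))
            z0, z1 = max(0, iz - hz), min(n_z, iz + hz + 1)
            x0, x1 = max(0, ix - hx), min(n_x, ix + hx + 1)
            if z0 >= z1 or x0 >= x1:
                continue
            zz = (np.arange(z0, z1) * pixel_um - z)[:, None]
            xx = (np.arange(x0, x1) * pixel_um - x)[None, :]
            amp = traj.amplitude * 10.0 ** (-atten_per_um * z / 20.0)
            data[z0:z1, x0:x1, t] += (
                amp * np.exp(-0.5 * ((zz / sigma_z) ** 2 + (xx / sigma_x) ** 2))
            ).astype(np.float32)

    ss = np.random.SeedSequence(seed)
    rng_clutter, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]

    if noise.clutter_db is not None:
        data += _clutter_field(n_z, n_x, n_frames, noise.clutter_rank,
                               10.0 ** (noise.clutter_db / 20.0), frame_rate_hz, rng_clutter)
    if noise.noise_std > 0:
        depth_gain = 1.0 + noise.noise_depth_gain * np.arange(n_z) / max(n_z - 1, 1)
        data += (
            rng_noise.standard_normal((n_z, n_x, n_frames)).astype(np.float32)
            * (noise.noise_std * depth_gain)[:, None, None].astype(np.float32)
        )

    return FrameStack(
        data=data,
        pixel_dz_um=pixel_um,
        pixel_dx_um=pixel_um,
        frame_rate_hz=frame_rate_hz,
        transducer=transducer,
        origin_um=(0.0, 0.0),
        metadata={"seed": seed, "attenuation_db_cm_mhz": attenuation_db_cm_mhz},
    )


def _clutter_field(n_z, n_x, n_t, rank, target_amp, frame_rate, rng) -> np.ndarray:
    """Rank-``rank`` spatiotemporal tissue clutter: smooth spatial modes times
    slowly varying temporal weights, scaled so every frame's peak amplitude is
    at least ``target_amp``."""
    spatial = np.empty((n_z * n_x, rank), dtype=np.float64)
    for k in range(rank):
        f = rng.standard_normal((n_z, n_x))
        f = ndimage.gaussian_filter(f, sigma=(max(n_z, 2) / 6.0, max(n_x, 2) / 6.0))
        spatial[:, k] = (f / (np.abs(f).max() + 1e-12)).ravel()
    temporal = np.empty((rank, n_t), dtype=np.float64)
    # slow dynamics: tissue decorrelates over ~0.25 s — much slower than a
    # microbubble's dwell within one PSF — plus a DC pedestal on the first
    # mode so clutter energy dominates every frame
    smooth = max(2.0, 0.25 * frame_rate)
    for k in range(rank):
        v = ndimage.gaussian_filter1d(rng.standard_normal(n_t), sigma=smooth, mode="nearest")
        v /= np.abs(v).max() + 1e-12
        # gentle decay across modes: every clutter component stays high-energy
        # relative to the MB signal, as in tissue (no mode down at MB level)
        temporal[k] = v * (0.8 ** k)
    temporal[0] = 0.3 * temporal[0] + 1.0
    clutter = (spatial @ temporal).reshape(n_z, n_x, n_t)
    frame_peaks = np.abs(clutter).reshape(-1, n_t).max(axis=0)
    clutter *= target_amp / max(frame_peaks.min(), 1e-12)
    return clutter.astype(np.float32)
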