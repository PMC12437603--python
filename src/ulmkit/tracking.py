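"""Frame-to-frame microbubble track linking.

Candidates in consecutive frames are paired by solving a rectangular linear
assignment problem that minimizes total squared displacement, with a
birth/death cost of ``max_link_distance²`` (links longer than
``max_link_distance`` are forbidden outright).  There is no gap closing: a
missed detection terminates the track.  Tracks shorter than the persistence
floor (10 frames = 10 ms at 1000 Hz) are discarded, and per-track speed is
the mean consecutive-point displacement times the frame rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import DomainError
from .localize import MBCandidate

_FORBIDDEN = 1e12


@dataclass
class TrackingConfig:
    max_link_distance_um: float = 10.0
    min_persistence_frames: int = 10
    frame_rate_hz: float = 1000.0

    def __post_init__(self):
        if self.max_link_distance_um <= 0:
            raise DomainError("max link distance must be positive")
        if self.min_persistence_frames < 2:
            raise DomainError("minimum persistence must be at least 2 frames")
        if self.frame_rate_hz <= 0:
            raise DomainError("frame rate must be positive")


@dataclass
class Track:
    """A persistence-filtered sequence of localizations.

    ``points`` has one row per frame: ``(frame, z_um, x_um)`` with frame
    indices strictly increasing by 1.
    """

    points: np.ndarray
    branch: str = "all"
    id: int = 0
    scores: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise DomainError("track points must be an (n, 3) array of (frame, z, x)")
        if len(self.points) >= 2 and not np.all(np.diff(self.points[:, 0]) == 1):
            raise DomainError("track frame indices must increase strictly by 1")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def frames(self) -> np.ndarray:
        return self.points[:, 0].astype(int)

    @property
    def start_frame(self) -> int:
        return int(self.points[0, 0])

    @property
    def end_frame(self) -> int:
        return int(self.points[-1, 0])


def link(candidates: list[MBCandidate], config: TrackingConfig) -> list[Track]:
    """Assemble candidates into tracks by per-frame-pair optimal assignment.

    Deterministic; returns all tracks (before persistence filtering), each
    tagged with the branch of its first candidate.
    """
    by_frame: dict[int, list[MBCandidate]] = {}
    for c in candidates:
        by_frame.setdefault(c.frame, []).append(c)
    b = config.max_link_distance_um ** 2

    active: list[list[MBCandidate]] = []
    finished: list[list[MBCandidate]] = []
    prev_frame: int | None = None
    for f in sorted(by_frame):
        cands = by_frame[f]
        if prev_frame is not None and f == prev_frame + 1 and active:
            n, m = len(active), len(cands)
            ends = np.array([[tr[-1].z_um, tr[-1].x_um] for tr in active])
            pos = np.array([[c.z_um, c.x_um] for c in cands])
            d2 = ((ends[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
            cost = np.full((n + m, m + n), _FORBIDDEN)
            cost[:n, :m] = np.where(d2 <= b, d2, _FORBIDDEN)
            cost[np.arange(n), m + np.arange(n)] = b       # track death
            cost[n + np.arange(m), np.arange(m)] = b       # candidate birth
            cost[n:, m:] = 0.0                             # dummy-dummy
            rows, cols = linear_sum_assignment(cost)
            linked_tracks, linked_cands = set(), set()
            for r, c_ in zip(rows, cols):
                if r < n and c_ < m and cost[r, c_] < _FORBIDDEN:
                    active[r].append(cands[c_])
                    linked_tracks.add(r)
                    linked_cands.add(c_)
            next_active = [tr for i, tr in enumerate(active) if i in linked_tracks]
            finished.extend(tr for i, tr in enumerate(active) if i not in linked_tracks)
            next_active.extend([cands[j]] for j in range(m) if j not in linked_cands)
            active = next_active
        else:
            finished.extend(active)
            active = [[c] for c in cands]
        prev_frame = f
    finished.extend(active)

    tracks = []
    for i, chain in enumerate(finished):
        pts = np.array([[c.frame, c.z_um, c.x_um] for c in chain], dtype=float)
        tracks.append(Track(points=pts, branch=chain[0].branch, id=i,
                            scores=np.array([c.score for c in chain])))
    return tracks


def enforce_persistence(tracks: list[Track], config: TrackingConfig) -> list[Track]:
    """Drop tracks shorter than the persistence floor; survivors unchanged."""
    return [t for t in tracks if len(t) >= config.min_persistence_frames]


def track_speed(track: Track, frame_rate_hz: float) -> float:
    """Mean flow speed in μm/s: mean per-frame displacement × frame rate."""
    if len(track) < 2:
        raise DomainError("speed needs a track with at least 2 points")
    steps = np.linalg.norm(np.diff(track.points[:, 1:3], axis=0), axis=1)
    return float(steps.mean() * frame_rate_hz)


def deduplicate_tracks(tracks: list[Track], radius_um: float) -> list[Track]:
    """Remove duplicate trajectories of the same scatterer.

    A microbubble whose energy straddles both directional branches (slow or
    laterally moving) is localized and tracked twice; the copies coincide to
    within the localization error.  Tracks are kept longest-first; a track is
    dropped when at least half of its frames overlap a kept track with mean
    distance below ``radius_um``.
    """
    kept: list[Track] = []
    kept_points: list[dict[int, np.ndarray]] = []
    for t in sorted(tracks, key=len, reverse=True):
        mine = {int(f): np.array([z, x]) for f, z, x in t.points}
        duplicate = False
        for other in kept_points:
            shared = [f for f in mine if f in other]
            if len(shared) < 0.5 * len(mine):
                continue
            d = np.mean([np.linalg.norm(mine[f] - other[f]) for f in shared])
            if d < radius_um:
                duplicate = True
                break
        if not duplicate:
            kept.append(t)
            kept_points.append(mine)
    return kept


def track_candidates(
    candidates: list[MBCandidate],
    config: TrackingConfig,
    by_branch: bool = True,
    dedup_radius_um: float | None = None,
) -> list[Track]:
    """Link → persistence, tracking each directional branch separately and
    pooling the results (IDs reassigned to stay unique).

    ``dedup_radius_um`` enables cross-branch duplicate removal when pooling
    (see :func:`deduplicate_tracks`)."""
    if by_branch:
        branches = sorted({c.branch for c in candidates})
        tracks: list[Track] = []
        for br in branches:
            tracks.extend(
                enforce_persistence(link([c for c in candidates if c.branch == br], config),
                                    config)
            )
        if dedup_radius_um is not None:
            tracks = deduplicate_tracks(tracks, dedup_radius_um)
    else:
        tracks = enforce_persistence(link(candidates, config), config)
    for i, t in enumerate(tracks):
        t.id = i
    return tracks
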