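"""Ground-truth evaluation of reconstructed tracks.

Recovery is assessed per ground-truth transit against the pooled set of
persistence-filtered tracks: a transit counts as recovered when at least a
coverage fraction of its frames has a track point within the match radius and
the mean matched position error is below the error budget (λ/10 by default —
the empirical localization-accuracy limit).  Track identity is deliberately
ignored: accumulation consumes track fragments equally, so a transit split
into several tracks by missed detections is still recovered vasculature.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .simulate import MBTrajectory
from .tracking import Track


@dataclass
class TransitRecovery:
    n_frames: int
    covered_frames: int
    mean_error_um: float  # NaN when nothing matched

    @property
    def coverage(self) -> float:
        return self.covered_frames / self.n_frames


@dataclass
class RecoveryReport:
    per_transit: list[TransitRecovery]
    coverage_threshold: float
    error_budget_um: float

    @property
    def n_transits(self) -> int:
        return len(self.per_transit)

    @property
    def recovered_fraction(self) -> float:
        """Fraction of transits with at least the coverage-threshold share of
        frames matched by a track point.  The accompanying accuracy statement
        is the aggregate :attr:`mean_position_error_um` (the empirical
        accuracy limit is an ensemble property, not a per-transit
        guarantee)."""
        if not self.per_transit:
            return float("nan")
        ok = [t for t in self.per_transit if t.coverage >= self.coverage_threshold]
        return len(ok) / len(self.per_transit)

    @property
    def recovered_fraction_strict(self) -> float:
        """As :attr:`recovered_fraction`, but additionally requiring each
        transit's own mean matched error to stay below the error budget."""
        if not self.per_transit:
            return float("nan")
        ok = [
            t for t in self.per_transit
            if t.coverage >= self.coverage_threshold
            and np.isfinite(t.mean_error_um)
            and t.mean_error_um < self.error_budget_um
        ]
        return len(ok) / len(self.per_transit)

    @property
    def mean_position_error_um(self) -> float:
        errs = [t.mean_error_um for t in self.per_transit if np.isfinite(t.mean_error_um)]
        return float(np.mean(errs)) if errs else float("nan")


def track_recovery(
    trajectories: Sequence[MBTrajectory],
    tracks: Sequence[Track],
    lambda_um: float,
    min_transit_frames: int = 10,
    coverage_threshold: float = 0.5,
    match_radius_um: Optional[float] = None,
    error_budget_um: Optional[float] = None,
) -> RecoveryReport:
    """Match reconstructed tracks to ground-truth transits.

    ``match_radius_um`` defaults to λ/2 (a candidate farther than half the
    axial PSF extent is a different scatterer); ``error_budget_um`` defaults
    to λ/10.
    """
    if match_radius_um is None:
        match_radius_um = lambda_um / 2.0
    if error_budget_um is None:
        error_budget_um = lambda_um / 10.0

    by_frame: dict[int, list[tuple[float, float]]] = {}
    for tr in tracks:
        for f, z, x in tr.points:
            by_frame.setdefault(int(f), []).append((z, x))
    frame_arrays = {f: np.asarray(pts) for f, pts in by_frame.items()}

    per_transit: list[TransitRecovery] = []
    for g in trajectories:
        if len(g) < min_transit_frames:
            continue
        covered = 0
        errors: list[float] = []
        for f, z, x in zip(g.frames, g.zs_um, g.xs_um):
            pts = frame_arrays.get(int(f))
            if pts is None:
                continue
            d = np.hypot(pts[:, 0] - z, pts[:, 1] - x).min()
            if d < match_radius_um:
                covered += 1
                errors.append(float(d))
        per_transit.append(
            TransitRecovery(
                n_frames=len(g),
                covered_frames=covered,
                mean_error_um=float(np.mean(errors)) if errors else float("nan"),
            )
        )
    return RecoveryReport(per_transit=per_transit, coverage_threshold=coverage_threshold,
                          error_budget_um=error_budget_um)
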