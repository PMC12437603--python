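"""Shared containers: the calibrated image-stack type used by every stage.

Coordinate conventions (used package-wide):

* ``z`` is the axial coordinate, increasing with depth; ``x`` is lateral.
* Positions are in micrometres relative to the stack origin; pixel indices are
  0-based and a position refers to the pixel centre.
* Frame ``t`` covers the half-open time bin ``[t, t + 1/frame_rate)`` seconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DomainError
from .transducer import TransducerSpec


@dataclass
class FrameStack:
    """A beamformed contrast-enhanced image ensemble with calibration.

    Parameters
    ----------
    data:
        Real-amplitude array of shape ``(n_z, n_x, n_t)``.
    pixel_dz_um, pixel_dx_um:
        Axial / lateral pixel spacing in micrometres.
    frame_rate_hz:
        Post-compounding frame rate.
    transducer:
        Optional probe metadata attached to the acquisition.
    origin_um:
        Scene coordinates ``(z0, x0)`` of pixel ``(0, 0)``'s centre.
    """

    data: np.ndarray
    pixel_dz_um: float
    pixel_dx_um: float
    frame_rate_hz: float
    transducer: Optional[TransducerSpec] = None
    origin_um: tuple[float, float] = (0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DomainError(f"stack data must be 3D (n_z, n_x, n_t); got shape {self.data.shape}")
        if self.data.shape[2] < 1:
            raise DomainError("stack must contain at least one frame")
        if self.pixel_dz_um <= 0 or self.pixel_dx_um <= 0:
            raise DomainError("pixel spacings must be positive")
        if self.frame_rate_hz <= 0:
            raise DomainError("frame rate must be positive")

    @property
    def n_z(self) -> int:
        return self.data.shape[0]

    @property
    def n_x(self) -> int:
        return self.data.shape[1]

    @property
    def n_t(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_t / self.frame_rate_hz

    @property
    def z_coords_um(self) -> np.ndarray:
        """Axial pixel-centre coordinates in scene micrometres."""
        return self.origin_um[0] + np.arange(self.n_z) * self.pixel_dz_um

    @property
    def x_coords_um(self) -> np.ndarray:
        return self.origin_um[1] + np.arange(self.n_x) * self.pixel_dx_um

    def frame(self, t: int) -> np.ndarray:
        return self.data[:, :, t]

    def with_data(self, data: np.ndarray) -> "FrameStack":
        """A copy of this stack carrying new pixel data (same calibration)."""
        return replace(self, data=data)

    def time_slice(self, t0: int, t1: int) -> "FrameStack":
        return replace(self, data=self.data[:, :, t0:t1])
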