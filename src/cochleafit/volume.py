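"""Isotropic 3-D scalar volume with mm geometry.

Conventions, enforced everywhere: zero-based voxel indices, voxel-center
world mapping ``world = origin + index * spacing``, axial slices along the
third array axis (``data[:, :, k]`` is one axial slice in the (x, y) plane).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError


@dataclass
class Volume:
    data: np.ndarray
    spacing: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ParameterError("volume data must be 3-D")
        if not np.isfinite(self.spacing) or self.spacing <= 0:
            raise ParameterError(f"spacing must be positive, got {self.spacing}")
        if self.origin.shape != (3,):
            raise ParameterError("origin must be a 3-vector")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_extent(self) -> np.ndarray:
        """(2, 3) array of the voxel-center bounding box in mm."""
        lo = self.origin
        hi = self.origin + (np.array(self.shape) - 1) * self.spacing
        return np.stack([lo, hi])

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(idx, float) * self.spacing

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing, self.origin.copy())
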