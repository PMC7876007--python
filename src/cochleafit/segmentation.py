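"""Threshold segmentation: CT volume -> boundary point cloud.

The operator's single segmentation choice is a grayscale threshold; the
boundary is extracted slice by slice as sub-pixel iso-contours (marching
squares with linear interpolation), mirroring a contour-based clinical
workflow.  No morphology or hole filling is applied — regularization is the
model fit's job — so the cloud deliberately retains noisy, incomplete and
non-capsule boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import find_contours

from .errors import EmptyCloudError, ParameterError
from .volume import Volume


@dataclass(frozen=True)
class PointCloud:
    points: np.ndarray          # (N, 3) mm
    source_threshold: float

    def __post_init__(self):
        pts = np.asarray(self.points, float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ParameterError("point cloud must be (N, 3)")
        if not np.isfinite(pts).all():
            raise ParameterError("point cloud contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)


def roi_from_mesh(mesh, dilate_mm: float = 2.0) -> np.ndarray:
    """(2, 3) world-space box: mesh bounding box dilated by ``dilate_mm``."""
    b = np.asarray(mesh.bounds, float)
    return np.stack([b[0] - dilate_mm, b[1] + dilate_mm])


def extract_threshold_cloud(vol: Volume, threshold: float,
                            roi: np.ndarray | None = None) -> PointCloud:
    """Iso-contour the volume at ``threshold``, slice-wise, into world mm.

    ``roi`` is an optional (2, 3) world-coordinate box (min row, max row);
    typically the landmark-aligned template bounding box dilated by ~2 mm,
    which keeps clutter away from the fit.
    """
    lo_i, hi_i = float(vol.data.min()), float(vol.data.max())
    if not (lo_i <= threshold <= hi_i):
        raise ParameterError(
            f"threshold {threshold} outside volume intensity range "
            f"[{lo_i:.1f}, {hi_i:.1f}]")
    if roi is not None:
        roi = np.asarray(roi, float)

    pts = []
    for k in range(vol.shape[2]):
        z = vol.origin[2] + k * vol.spacing
        if roi is not None and not (roi[0, 2] <= z <= roi[1, 2]):
            continue
        for contour in find_contours(np.asarray(vol.data[:, :, k], float),
                                     threshold):
            world = np.column_stack([
                vol.origin[0] + contour[:, 0] * vol.spacing,
                vol.origin[1] + contour[:, 1] * vol.spacing,
                np.full(len(contour), z),
            ])
            pts.append(world)
    if not pts:
        raise EmptyCloudError(
            f"no iso-contours found at threshold {threshold}")
    points = np.vstack(pts)
    if roi is not None:
        keep = np.all((points >= roi[0]) & (points <= roi[1]), axis=1)
        points = points[keep]
    if len(points) < 3:
        raise EmptyCloudError(
            f"threshold {threshold} leaves fewer than 3 boundary points"
            + (" inside the ROI" if roi is not None else ""))
    return PointCloud(points=points, source_threshold=float(threshold))
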