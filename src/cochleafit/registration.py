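"""Rigid-family registration: landmark initialization and similarity ICP.

The fitting workflow mirrors a clinically practicable protocol: the operator
marks three landmarks (cochlear apex, oval-window centre, posterior-anterior
canal bifurcation), a closed-form similarity transform aligns the template's
predefined landmarks to them (optionally mirrored when the scan is the other
side), and iterative closest point with a similarity transform refines the
alignment against the thresholded point cloud.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .errors import EmptyCloudError, ParameterError
from .segmentation import PointCloud
from .transforms import SimilarityTransform, check_noncollinear, fit_similarity

LANDMARK_NAMES = ("apex", "oval_window", "canal_bifurcation")


@dataclass(frozen=True)
class LandmarkSet:
    apex: np.ndarray
    oval_window: np.ndarray
    canal_bifurcation: np.ndarray

    def __post_init__(self):
        for name in LANDMARK_NAMES:
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        check_noncollinear(self.as_array())

    def as_array(self) -> np.ndarray:
        return np.stack([np.asarray(getattr(self, n), float)
                         for n in LANDMARK_NAMES])

    @staticmethod
    def from_dict(d: dict) -> "LandmarkSet":
        return LandmarkSet(**{n: np.asarray(d[n], float) for n in LANDMARK_NAMES})


def landmark_similarity(src: LandmarkSet, dst: LandmarkSet,
                        allow_reflect: bool = False,
                        reflect: bool = False) -> SimilarityTransform:
    """Least-squares similarity mapping the source triad onto the target triad.

    Note that two mirror-image triangles are always directly congruent in 3-D,
    so for exactly three landmarks both chiralities reach (near-)zero residual
    and the landmark fit alone cannot decide whether the template must be
    mirrored.  ``reflect`` applies the operator's explicit mirror choice;
    ``allow_reflect`` picks the orientation-reversing solution automatically
    when it strictly lowers the residual (only decisive for noisy triads or
    larger point sets).
    """
    src_arr = src.as_array()
    dst_arr = dst.as_array()
    if reflect:
        tf = fit_similarity(src_arr * np.array([1.0, 1.0, -1.0]), dst_arr,
                            with_scale=True, allow_reflect=False)
        return SimilarityTransform(rotation=tf.rotation, scale=tf.scale,
                                   translation=tf.translation, reflect=True)
    return fit_similarity(src_arr, dst_arr, with_scale=True,
                          allow_reflect=allow_reflect)


def _as_points(cloud) -> np.ndarray:
    pts = cloud.points if isinstance(cloud, PointCloud) else np.asarray(cloud, float)
    if len(pts) == 0:
        raise EmptyCloudError("point cloud is empty")
    return pts


def pair_vertices(vertices: np.ndarray, tree: cKDTree,
                  trim_factor: float | None) -> tuple[np.ndarray, np.ndarray]:
    """Template-vertex -> nearest-cloud-point pairing with optional trimming.

    Pairs farther than ``trim_factor`` times the median pair distance are
    dropped (the cloud contains non-capsule clutter); at least 3 pairs are
    always kept.  Nearest-neighbour ties resolve to the lowest point index.
    """
    dist, idx = tree.query(vertices)
    if trim_factor is None:
        return np.arange(len(vertices)), idx
    cutoff = trim_factor * np.median(dist)
    keep = np.flatnonzero(dist <= cutoff)
    if len(keep) < 3:
        keep = np.argsort(dist)[:3]
    return keep, idx[keep]


class SimilarityICP(BaseEstimator):
    """Iterative closest point with a similarity transform (Besl & McKay).

    Alternates (a) pairing each transformed template vertex with its nearest
    cloud point and (b) a closed-form similarity update minimizing the summed
    squared pair distances.  Runs for ``n_iter`` iterations (50 by default)
    with an early stop when the mean pair distance changes by less than
    ``tol`` mm.

    Parameters
    ----------
    n_iter : fixed iteration budget.
    init : initial :class:`SimilarityTransform` (e.g. from landmarks); any
        reflection decided at initialization is kept fixed during ICP.
    trim_factor : pairs beyond this multiple of the median pair distance are
        excluded from the update; ``None`` disables trimming.
    tol : early-stop tolerance on the mean pair distance, mm.

    Attributes
    ----------
    transform_ : fitted :class:`SimilarityTransform` (includes ``init``).
    history_ : RMS (trimmed) pair distance after each iteration, mm
        (the quantity the closed-form update provably does not increase).
    n_iter_ : iterations actually run.
    """

    def __init__(self, n_iter: int = 50, init: SimilarityTransform | None = None,
                 trim_factor: float | None = 3.0, tol: float = 1e-6):
        self.n_iter = n_iter
        self.init = init
        self.trim_factor = trim_factor
        self.tol = tol

    def fit(self, X, y) -> "SimilarityICP":
        """Align source vertices ``X`` (N, 3) to target cloud ``y``."""
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ParameterError("X must be (N, 3) vertices")
        target = _as_points(y)
        if self.n_iter < 1:
            raise ParameterError("n_iter must be >= 1")
        init = self.init or SimilarityTransform()
        # the reflection decision is made at initialization and kept fixed:
        # mirror the source once, then iterate proper similarities
        reflect = init.reflect
        Xw = X * np.array([1.0, 1.0, -1.0]) if reflect else X
        transform = SimilarityTransform(rotation=init.rotation, scale=init.scale,
                                        translation=init.translation)
        tree = cKDTree(target)

        history = []
        prev = np.inf
        it = 0
        for it in range(1, self.n_iter + 1):
            cur = transform.apply(Xw)
            keep, idx = pair_vertices(cur, tree, self.trim_factor)
            transform = fit_similarity(Xw[keep], target[idx], with_scale=True)
            cur = transform.apply(Xw)
            d = np.linalg.norm(cur[keep] - target[idx], axis=1)
            mean_d = float(np.sqrt(np.mean(d * d)))
            history.append(mean_d)
            if abs(prev - mean_d) < self.tol:
                break
            prev = mean_d

        self.transform_ = SimilarityTransform(
            rotation=transform.rotation, scale=transform.scale,
            translation=transform.translation, reflect=reflect)
        self.history_ = np.asarray(history)
        self.n_iter_ = it
        return self

    def transform(self, X) -> np.ndarray:
        return self.transform_.apply(np.asarray(X, float))


def icp_similarity(vertices: np.ndarray, cloud, init: SimilarityTransform | None = None,
                   iters: int = 50, trim_factor: float | None = 3.0) -> SimilarityTransform:
    """Functional wrapper over :class:`SimilarityICP`."""
    est = SimilarityICP(n_iter=iters, init=init, trim_factor=trim_factor)
    est.fit(vertices, cloud)
    return est.transform_
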