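"""Point-based statistical shape model: Procrustes standardization + PCA,
and SSM-constrained ICP fitting.

Corresponded vertex sets are standardized for location, orientation and scale
(translated to a common origin, scaled to unit centroid size, rotated by
orthogonal Procrustes onto a reference — reflections never introduced).  PCA
of the standardized coordinates yields at most n-1 modes m_i with non-zero
eigenvalues; a shape is represented as

    X = X_mean + sum_i S_i m_i

with shape coefficients S_i.  Fitting to a point cloud proceeds within an ICP
framework: pair template vertices with nearest cloud points, solve the linear
least-squares problem for S over *all* modes (the method is parameter-free),
re-estimate the model-to-data similarity transform, and repeat.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .errors import CorrespondenceError, ParameterError
from .registration import _as_points, pair_vertices
from .transforms import SimilarityTransform, fit_similarity


def centroid_size(vertices: np.ndarray) -> float:
    """Root-sum-of-squared distances of the vertices to their centroid."""
    v = np.asarray(vertices, float)
    return float(np.sqrt(np.sum((v - v.mean(axis=0)) ** 2)))


def _standardize_one(verts: np.ndarray, ref: np.ndarray) -> np.ndarray:
    v = verts - verts.mean(axis=0)
    v = v / centroid_size(v)
    tf = fit_similarity(v, ref, with_scale=False, allow_reflect=False)
    return v @ tf.rotation.T


def procrustes_standardize(vertex_sets, reference: np.ndarray) -> list[np.ndarray]:
    """Standardize each vertex set for location, orientation and scale.

    Every set is centered, scaled to unit centroid size and rotated (proper
    rotation only) to minimize the summed squared distance to the reference,
    itself centered and scaled to unit size first.
    """
    ref = np.asarray(reference, float)
    ref = ref - ref.mean(axis=0)
    ref = ref / centroid_size(ref)
    out = []
    for i, vs in enumerate(vertex_sets):
        v = np.asarray(vs, float)
        if v.shape != ref.shape:
            raise CorrespondenceError(
                f"vertex set {i} has shape {v.shape}, reference {ref.shape}")
        out.append(_standardize_one(v, ref))
    return out


class StatisticalShapeModel(BaseEstimator):
    """Procrustes + PCA point-distribution model over corresponded shapes.

    ``fit`` takes an (n, V, 3) stack (or (n, 3V) matrix) of corresponded
    vertex sets; they are standardized against ``reference`` (default: the
    first set) and decomposed via the thin SVD of the centered data — the
    3V x 3V covariance is never formed.

    Attributes
    ----------
    mean_ : (3V,) mean shape in the normalized (unit-centroid-size) frame.
    components_ : (n_modes, 3V) orthonormal shape modes.
    eigenvalues_ : per-mode variances, descending.
    n_training_ : number of training shapes n.
    n_vertices_ : V.
    """

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = reference

    def fit(self, X, y=None) -> "StatisticalShapeModel":
        shapes = self._as_stack(X)
        n = len(shapes)
        if n < 2:
            raise ParameterError("need at least 2 training shapes")
        ref = shapes[0] if self.reference is None else np.asarray(self.reference, float)
        self.reference_used_ = ref
        std = procrustes_standardize(shapes, ref)
        data = np.stack([s.reshape(-1) for s in std])      # (n, 3V)
        mean = data.mean(axis=0)
        centered = data - mean
        # thin decomposition: n-1 non-trivial eigenpairs at most
        U, sv, Vt = np.linalg.svd(centered, full_matrices=False)
        eig = sv ** 2 / (n - 1)
        nz = min(n - 1, len(eig))
        self.mean_ = mean
        self.components_ = Vt[:nz]
        self.eigenvalues_ = eig[:nz]
        self.n_training_ = n
        self.n_vertices_ = shapes.shape[1]
        self.training_coefficients_ = centered @ self.components_.T
        return self

    @staticmethod
    def _as_stack(X) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim == 2:
            X = X.reshape(X.shape[0], -1, 3)
        if X.ndim != 3 or X.shape[2] != 3:
            raise ParameterError("training data must be (n, V, 3) or (n, 3V)")
        return X

    # -- shape <-> coefficient maps -----------------------------------------
    def transform(self, X) -> np.ndarray:
        """Project standardized shapes onto the modes -> coefficients (n, m).

        Standardization uses the same reference orientation as ``fit``, so
        training shapes project and reconstruct exactly.
        """
        shapes = self._as_stack(X)
        ref = getattr(self, "reference_used_", self.mean_.reshape(-1, 3))
        std = procrustes_standardize(shapes, ref)
        data = np.stack([s.reshape(-1) for s in std])
        return (data - self.mean_) @ self.components_.T

    def inverse_transform(self, S: np.ndarray) -> np.ndarray:
        """Coefficients (n, m) -> shapes (n, V, 3) in the normalized frame."""
        S = np.atleast_2d(np.asarray(S, float))
        flat = self.mean_ + S @ self.components_
        return flat.reshape(len(S), self.n_vertices_, 3)

    def shape_of(self, S: np.ndarray) -> np.ndarray:
        """Single-shape convenience: (m,) coefficients -> (V, 3) vertices."""
        return self.inverse_transform(S[None])[0]


class SSMRegistration(BaseEstimator):
    """SSM-constrained ICP: fit mode coefficients and a similarity to a cloud.

    Per iteration: (a) pair every current vertex with its nearest cloud point
    (trimmed); (b) solve the linear least-squares problem for the shape
    coefficients S over all modes given the current similarity; (c) re-fit
    the model-frame -> data-frame similarity (unless ``freeze_similarity``).
    The method is parameter-free in the sense that all available modes are
    used and the coefficients are unbounded.

    Attributes
    ----------
    coefficients_ : fitted shape coefficients S.
    transform_ : model-frame -> data-frame :class:`SimilarityTransform`.
    vertices_ : fitted surface vertices in the data frame.
    history_ : mean trimmed pair distance per iteration, mm.
    """

    def __init__(self, model: StatisticalShapeModel, n_iter: int = 50,
                 init: SimilarityTransform | None = None,
                 trim_factor: float | None = 3.0,
                 freeze_similarity: bool = False, tol: float = 1e-8):
        self.model = model
        self.n_iter = n_iter
        self.init = init
        self.trim_factor = trim_factor
        self.freeze_similarity = freeze_similarity
        self.tol = tol

    def fit(self, X, y=None) -> "SSMRegistration":
        """Fit the model to cloud ``X`` (an (N, 3) array or PointCloud)."""
        target = _as_points(X)
        model = self.model
        if self.n_iter < 1:
            raise ParameterError("n_iter must be >= 1")
        if self.init is None:
            # centroid/size-matched starting similarity: the model lives in
            # the unit-centroid-size frame, so an identity start would let the
            # free-scale update collapse the surface onto a single cloud point
            mean_pts = model.mean_.reshape(-1, 3)
            s0 = (np.sqrt(np.mean(np.sum((target - target.mean(0)) ** 2, 1)))
                  / np.sqrt(np.mean(np.sum((mean_pts - mean_pts.mean(0)) ** 2, 1))))
            tf = SimilarityTransform(
                scale=float(s0),
                translation=target.mean(0) - s0 * mean_pts.mean(0))
        else:
            tf = self.init
        reflect = tf.reflect
        mirror = np.array([1.0, 1.0, -1.0])
        tree = cKDTree(target)
        m = len(model.components_)
        modes = model.components_                     # (m, 3V)
        S = np.zeros(m)

        history = []
        prev = np.inf
        for _ in range(self.n_iter):
            model_pts = model.mean_.reshape(-1, 3) + (S @ modes).reshape(-1, 3)
            cur = tf.apply(model_pts)
            keep, idx = pair_vertices(cur, tree, self.trim_factor)
            part = target[idx]

            # solve for S given the similarity, working in the model frame
            # (the inverse transform undoes any mirror as well)
            back = tf.inverse().apply(part)           # partners in model frame
            mean_pts = model.mean_.reshape(-1, 3)
            rhs = (back - mean_pts[keep]).reshape(-1)
            cols = modes.reshape(m, -1, 3)[:, keep, :].reshape(m, -1)
            S, *_ = np.linalg.lstsq(cols.T, rhs, rcond=None)

            model_pts = model.mean_.reshape(-1, 3) + (S @ modes).reshape(-1, 3)
            if not self.freeze_similarity:
                src = model_pts[keep] * mirror if reflect else model_pts[keep]
                tf_new = fit_similarity(src, part, with_scale=True)
                tf = SimilarityTransform(rotation=tf_new.rotation,
                                         scale=tf_new.scale,
                                         translation=tf_new.translation,
                                         reflect=reflect)
            cur = tf.apply(model_pts)
            mean_d = float(np.linalg.norm(cur[keep] - part, axis=1).mean())
            history.append(mean_d)
            if abs(prev - mean_d) < self.tol:
                break
            prev = mean_d

        self.coefficients_ = S
        self.transform_ = tf
        self.vertices_ = tf.apply(
            model.mean_.reshape(-1, 3) + (S @ modes).reshape(-1, 3))
        self.history_ = np.asarray(history)
        return self


def build_ssm(vertex_sets, reference: np.ndarray | None = None) -> StatisticalShapeModel:
    """Functional wrapper over :class:`StatisticalShapeModel`."""
    return StatisticalShapeModel(reference=reference).fit(np.stack(
        [np.asarray(v, float) for v in vertex_sets]))


def ssm_fit(model: StatisticalShapeModel, cloud, init: SimilarityTransform | None = None,
            iters: int = 50, trim_factor: float | None = 3.0,
            freeze_similarity: bool = False):
    """Functional wrapper: returns (fitted vertices, coefficients, similarity)."""
    est = SSMRegistration(model, n_iter=iters, init=init, trim_factor=trim_factor,
                          freeze_similarity=freeze_similarity)
    est.fit(cloud)
    return est.vertices_, est.coefficients_, est.transform_
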