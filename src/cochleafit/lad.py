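"""Locally affine deformation (LAD): regularized nonrigid surface refinement.

Each template vertex k owns a neighbourhood N_k of vertices within a Euclidean
distance d (recomputed in the deformed configuration every iteration).  Per
iteration: every vertex is paired with its nearest cloud point (trimmed as in
ICP); for each vertex a least-squares *rigid* transform is fitted over the
neighbourhood's surviving pairs; the vertex then moves to the
proximity-weighted average of its images under the neighbourhood transforms.
``d`` is the algorithm's only substantive parameter — smaller values permit
more deformation, larger values favour smooth displacement fields.

All per-vertex Kabsch fits and the transform blending are evaluated in batch
through sparse neighbourhood matrices, so one iteration costs a KD-tree sweep
plus a batched 3x3 SVD.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from sklearn.base import BaseEstimator

from .errors import EmptyCloudError, ParameterError
from .registration import _as_points, pair_vertices


def _batched_kabsch(H: np.ndarray) -> np.ndarray:
    """Proper rotations from a batch of 3x3 cross-covariance matrices."""
    U, _, Vt = np.linalg.svd(H)
    R = U @ Vt
    neg = np.linalg.det(R) < 0
    if np.any(neg):
        U = U.copy()
        U[neg, :, -1] *= -1.0
        R[neg] = U[neg] @ Vt[neg]
    return R


def deformation_energy(vertices: np.ndarray, edges: np.ndarray,
                       displacement: np.ndarray) -> float:
    """Sum of squared displacement differences across mesh edges.

    A discrete smoothness (Dirichlet) energy of the displacement field: zero
    for any global translation, small for smooth fields, large for wrinkled
    ones.
    """
    diff = displacement[edges[:, 0]] - displacement[edges[:, 1]]
    return float(np.sum(diff * diff))


class LADRegistration(BaseEstimator):
    """Locally affine deformation fit of a pre-aligned template to a cloud.

    Parameters
    ----------
    d : neighbourhood radius in mm (default 5, a high degree of
        regularization suited to low-resolution noisy data).
    n_iter : iteration budget (default 50).
    trim_factor : pair-trimming multiple of the median pair distance;
        ``None`` disables trimming.
    weight_scale : proximity-weight length scale as a fraction of ``d``; the
        weight of neighbour j in the blend at vertex k is
        ``exp(-||v_j - v_k||^2 / (weight_scale * d)**2)``, truncated at d.

    Attributes
    ----------
    displacement_ : (N, 3) per-vertex displacement field, mm.
    vertices_ : deformed vertex positions (input + displacement).
    history_ : mean trimmed pair distance per iteration, mm.
    n_fallback_ : vertices that fell back to the global rigid transform
        because fewer than 3 neighbourhood pairs survived trimming
        (accumulated over iterations).
    """

    def __init__(self, d: float = 5.0, n_iter: int = 50,
                 trim_factor: float | None = 3.0, weight_scale: float = 0.5,
                 patience: int = 8):
        self.d = d
        self.n_iter = n_iter
        self.trim_factor = trim_factor
        self.weight_scale = weight_scale
        self.patience = patience

    def fit(self, X, y) -> "LADRegistration":
        """Deform vertices ``X`` (N, 3) toward target cloud ``y``."""
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ParameterError("X must be (N, 3) vertices")
        if self.d <= 0:
            raise ParameterError("neighbourhood radius d must be positive")
        if self.n_iter < 1:
            raise ParameterError("n_iter must be >= 1")
        target = _as_points(y)
        tree_target = cKDTree(target)

        V = len(X)
        cur = X.copy()
        history = []
        n_fallback = 0
        sigma2 = (self.weight_scale * self.d) ** 2
        best_res = np.inf
        best_cur = cur
        stall = 0

        for _ in range(self.n_iter):
            keep, idx = pair_vertices(cur, tree_target, self.trim_factor)
            part = target[idx]                     # partners of kept vertices

            tree_v = cKDTree(cur)
            # neighbourhood graph in the current (deformed) configuration,
            # assembled into CSR directly (row-sorted by construction)
            half = tree_v.query_pairs(self.d, output_type="ndarray")
            half_d = np.linalg.norm(cur[half[:, 0]] - cur[half[:, 1]], axis=1)
            rows = np.concatenate([half[:, 0], half[:, 1], np.arange(V)])
            cols = np.concatenate([half[:, 1], half[:, 0], np.arange(V)])
            dists = np.concatenate([half_d, half_d, np.zeros(V)])
            order = np.argsort(rows, kind="stable")
            rows, cols, dists = rows[order], cols[order], dists[order]
            indptr = np.searchsorted(rows, np.arange(V + 1))

            def nbr_matmul(data, dense):
                M = sparse.csr_matrix((data, cols, indptr), shape=(V, V))
                return M @ dense

            # -- per-vertex rigid fits over neighbourhood pairs -------------
            kept_mask = np.zeros(V, dtype=bool)
            kept_mask[keep] = True
            pmap = np.zeros((V, 3))
            pmap[keep] = part
            mdat = kept_mask[cols].astype(float)
            n_pairs = nbr_matmul(mdat, np.ones((V, 1))).ravel()
            ok = n_pairs >= 3

            sum_v = nbr_matmul(mdat, cur)
            sum_p = nbr_matmul(mdat, pmap)
            with np.errstate(divide="ignore", invalid="ignore"):
                mu_v = sum_v / n_pairs[:, None]
                mu_p = sum_p / n_pairs[:, None]
            outer = np.einsum("ni,nj->nij", cur, pmap).reshape(V, 9)
            sum_vp = nbr_matmul(mdat, outer).reshape(V, 3, 3)
            H = sum_vp - n_pairs[:, None, None] * np.einsum(
                "ni,nj->nij", mu_v, mu_p)
            # cross-covariance oriented source->target: rotate H^T
            Ht = np.transpose(H, (0, 2, 1))
            Ht[~ok] = np.eye(3)
            R = _batched_kabsch(Ht)

            # global rigid fallback for starved neighbourhoods
            if np.any(~ok):
                n_fallback += int(np.sum(~ok))
                mu_v_g = cur[keep].mean(axis=0)
                mu_p_g = part.mean(axis=0)
                Hg = (part - mu_p_g).T @ (cur[keep] - mu_v_g)
                Rg = _batched_kabsch(Hg[None])[0]
                R[~ok] = Rg
                mu_v[~ok] = mu_v_g
                mu_p[~ok] = mu_p_g

            # -- proximity-weighted blending of neighbourhood transforms ----
            # each rigid transform is expressed as a rotation about its own
            # neighbourhood centroid plus that centroid's displacement, then
            # blended: rotations as sign-aligned quaternion means (so the
            # blended map stays rigid) and the centroid/displacement parts as
            # weighted means.  Blending raw (R, t) pairs instead couples the
            # rotation spread to the world origin and drifts the surface.
            w = np.exp(-(dists ** 2) / sigma2)
            Q = Rotation.from_matrix(R).as_quat()
            sign = np.sign(np.einsum("ij,ij->i", Q[rows], Q[cols]))
            sign[sign == 0] = 1.0
            q_bar = nbr_matmul(w * sign, Q)
            q_bar /= np.linalg.norm(q_bar, axis=1, keepdims=True)
            R_bar = Rotation.from_quat(q_bar).as_matrix()
            wsum = nbr_matmul(w, np.ones((V, 1))).ravel()
            m_bar = nbr_matmul(w, mu_v) / wsum[:, None]
            delta_bar = nbr_matmul(w, mu_p - mu_v) / wsum[:, None]
            new = (np.einsum("nij,nj->ni", R_bar, cur - m_bar)
                   + m_bar + delta_bar)

            d_pairs = np.linalg.norm(cur[keep] - part, axis=1)
            res = float(d_pairs.mean())
            history.append(res)
            # convergence control: the update has no elastic memory of the
            # template, so once the data term stops improving further
            # iterations only let the surface drift.  The one-sided pair
            # distance alone can keep falling while the surface slides off
            # uncovered cloud regions, so the monitored objective is
            # symmetric: vertex->cloud plus cloud->vertex mean distance.
            # Keep the best iterate; stop after a patience window.
            obj = res + float(cKDTree(cur).query(target)[0].mean())
            if obj < best_res - 1e-9:
                best_res = obj
                best_cur = cur
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
            cur = new

        # evaluate the final iterate too
        keep, idx = pair_vertices(cur, tree_target, self.trim_factor)
        res = float(np.linalg.norm(cur[keep] - target[idx], axis=1).mean())
        history.append(res)
        obj = res + float(cKDTree(cur).query(target)[0].mean())
        if obj < best_res:
            best_res, best_cur = obj, cur

        self.displacement_ = best_cur - X
        self.vertices_ = best_cur
        self.history_ = np.asarray(history)
        self.objective_ = best_res
        self.n_fallback_ = n_fallback
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, float) + self.displacement_


def lad_fit(vertices: np.ndarray, cloud, d: float = 5.0, iters: int = 50,
            trim_factor: float | None = 3.0) -> np.ndarray:
    """Functional wrapper: returns the per-vertex displacement field."""
    est = LADRegistration(d=d, n_iter=iters, trim_factor=trim_factor)
    est.fit(vertices, cloud)
    return est.displacement_
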