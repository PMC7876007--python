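"""Similarity transforms (rotation + isotropic scale + translation, optional mirror).

The transform acts on mm coordinates as ``y = s * R @ (M @ x) + t`` where ``M``
is the fixed mirror ``diag(1, 1, -1)`` when ``reflect`` is set and the identity
otherwise.  Any orientation-reversing similarity can be written this way, so the
class closes under composition and inversion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateLandmarksError, ParameterError

_MIRROR = np.diag([1.0, 1.0, -1.0])


@dataclass(frozen=True)
class SimilarityTransform:
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    scale: float = 1.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    reflect: bool = False

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ParameterError("rotation must be 3x3 and translation length 3")
        if not np.isfinite(R).all() or not np.isfinite(t).all():
            raise ParameterError("non-finite transform parameters")
        if self.scale <= 0 or not np.isfinite(self.scale):
            raise ParameterError(f"scale must be positive, got {self.scale}")
        if abs(np.linalg.det(R) - 1.0) > 1e-6 or np.abs(R @ R.T - np.eye(3)).max() > 1e-6:
            raise ParameterError("rotation must be orthonormal with det +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- linear part including mirror and scale ------------------------------
    @property
    def linear(self) -> np.ndarray:
        L = self.scale * self.rotation
        return L @ _MIRROR if self.reflect else L

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.linear.T + self.translation

    def apply_direction(self, vec: np.ndarray) -> np.ndarray:
        """Map a direction (no translation, normalized back to unit length)."""
        v = np.asarray(vec, dtype=float) @ self.linear.T
        return v / np.linalg.norm(v)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform ``self ∘ other`` (apply ``other`` first)."""
        L = self.linear @ other.linear
        t = self.linear @ other.translation + self.translation
        return SimilarityTransform.from_linear(L, t)

    def inverse(self) -> "SimilarityTransform":
        Linv = np.linalg.inv(self.linear)
        return SimilarityTransform.from_linear(Linv, -Linv @ self.translation)

    @staticmethod
    def from_linear(L: np.ndarray, t: np.ndarray) -> "SimilarityTransform":
        det = np.linalg.det(L)
        if abs(det) < 1e-300:
            raise ParameterError("singular linear part")
        reflect = det < 0
        s = abs(det) ** (1.0 / 3.0)
        R = (L @ _MIRROR if reflect else L) / s
        # re-orthonormalize against accumulated round-off
        U, _, Vt = np.linalg.svd(R)
        R = U @ Vt
        return SimilarityTransform(rotation=R, scale=s, translation=np.asarray(t, float),
                                   reflect=bool(reflect))

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "scale": float(self.scale),
            "translation": self.translation.tolist(),
            "reflect": bool(self.reflect),
        }

    @staticmethod
    def from_dict(d: dict) -> "SimilarityTransform":
        return SimilarityTransform(
            rotation=np.asarray(d["rotation"], float),
            scale=float(d["scale"]),
            translation=np.asarray(d["translation"], float),
            reflect=bool(d.get("reflect", False)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def from_json(path) -> "SimilarityTransform":
        with open(path) as fh:
            return SimilarityTransform.from_dict(json.load(fh))


def fit_similarity(src: np.ndarray, dst: np.ndarray, *, with_scale: bool = True,
                   allow_reflect: bool = False,
                   weights: np.ndarray | None = None) -> SimilarityTransform:
    """Closed-form least-squares similarity aligning ``src`` onto ``dst``.

    Minimizes ``sum_i w_i || T(src_i) - dst_i ||^2`` over rotation, translation
    and (optionally) isotropic scale via the SVD of the weighted cross-covariance
    (Umeyama's construction).  With ``allow_reflect`` the orientation-reversing
    solution is returned when it strictly lowers the residual.
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ParameterError("src and dst must be matching (N, 3) arrays")
    n = src.shape[0]
    if n < 3:
        raise ParameterError("need at least 3 point pairs")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        w = w / w.sum()

    mu_s = w @ src
    mu_d = w @ dst
    xs = src - mu_s
    xd = dst - mu_d
    var_s = float(np.sum(w[:, None] * xs * xs))
    H = (w[:, None] * xd).T @ xs  # 3x3 cross-covariance (dst x src)
    U, sv, Vt = np.linalg.svd(H)

    def build(sign_flip: bool) -> tuple[SimilarityTransform, float]:
        D = np.ones(3)
        if sign_flip:
            D[-1] = -1.0
        R = U @ np.diag(D) @ Vt
        trace = float(sv @ D)
        s = trace / var_s if with_scale else 1.0
        if s <= 0:
            s = np.finfo(float).tiny
        t = mu_d - s * R @ mu_s
        # residual of the weighted objective
        res = float(np.sum(w[:, None] * (xd - s * xs @ R.T) ** 2))
        tf = SimilarityTransform.from_linear(s * R, t)
        return tf, res

    proper_needs_flip = np.linalg.det(U @ Vt) < 0
    tf_proper, res_proper = build(proper_needs_flip)
    if not allow_reflect:
        return tf_proper
    tf_improper, res_improper = build(not proper_needs_flip)
    return tf_improper if res_improper < res_proper else tf_proper


def check_noncollinear(points: np.ndarray, tol: float = 1e-9) -> None:
    """Raise if three (or more) points are collinear to within ``tol``."""
    pts = np.asarray(points, float)
    c = pts - pts.mean(axis=0)
    sv = np.linalg.svd(c, compute_uv=False)
    if len(sv) < 2 or sv[1] <= tol * max(sv[0], 1.0):
        raise DegenerateLandmarksError("points are collinear")
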