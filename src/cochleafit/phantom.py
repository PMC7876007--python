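"""Synthetic cochlea specimens: spiral duct meshes with analytic ground truth.

The outer (lateral) wall is a logarithmic spiral

    w(theta) = a * (exp(-b*theta) cos(theta), exp(-b*theta) sin(theta), zeta(theta))

with ``a`` the overall size (``spiral_scale``), ``b`` the radius decay per
radian and a cubic vertical profile ``z = c1*theta + c2*theta^2 + c3*theta^3``
(scaled with ``a`` so that all ground-truth measurements are exactly
proportional to ``spiral_scale``).  The duct is a tapering tube whose lateral
extremum coincides with ``w``; a torus-arc appendage mimics the semicircular
canals and carries the canal-bifurcation landmark.  Meshes produced for
different parameter draws share one vertex topology (identical theta/phi
sampling), giving native vertex correspondence across a cohort.

Ground truth is computed on a dense (2 * 10^4 sample) polyline of the analytic
outer-wall curve using the same measurement definitions as
:mod:`cochleafit.morphometry`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy import ndimage

from .errors import ParameterError
from .morphometry import measure_polyline
from .sdf import MeshDistance
from .volume import Volume

# fixed template topology: every specimen shares these sampling counts
N_THETA = 144
N_PHI = 8
N_CANAL = 36
N_CANAL_PHI = 8
N_ENV_AZ = 36       # envelope azimuth samples
N_ENV_POL = 17      # envelope polar rings (plus two pole vertices)
DENSE_SAMPLES = 20001

# number of vertices in the lumen (duct + canal) part of the capsule mesh;
# envelope vertices follow
N_LUMEN_VERTS = N_THETA * N_PHI + 2 + N_CANAL * N_CANAL_PHI + 2

BONE_SHELL = 2.0    # mm of capsule bone surrounding the duct union

REF_SCALE = 4.5  # mm; height profile coefficients are stated at this size

# canal-arc geometry (fixed shape; canal_offset shifts it horizontally)
_CANAL_DIR = np.array([-1.0, -0.6, 0.0]) / np.linalg.norm([-1.0, -0.6, 0.0])
_CANAL_RADIUS = 2.8
_CANAL_TUBE_RADIUS = 0.45
_CANAL_Z = 3.8
_CANAL_SPAN = (np.radians(-10.0), np.radians(140.0))

DEFAULT_INTENSITIES = {
    "inside": 90.0,    # perilymph/endolymph lumen
    "outside": 230.0,  # otic-capsule bone
    "tissue": 110.0,   # marrow/soft tissue surrounding the capsule
    "air": 20.0,       # beyond the bone margin (generic voxelization only)
    "air_margin": 4.0,  # mm of bone surrounding the ducts
    # the grayscale value taken ON the capsule surface at every interface, so
    # that segmenting at the central operator threshold recovers the geometry
    # unbiased and the neighbouring thresholds bracket it.  With tissue at
    # 110 the threshold is also the exact midpoint of the outer interface,
    # which keeps the level set unbiased under resolution blur.
    "surface_value": 170.0,
}


WINDOW_THETA = 5.2  # radians; roughly the first 270 degrees of turning


def height_coeffs_from_slopes(basal_slope: float, window_slope: float,
                              apex_height: float, total_turn: float,
                              theta_w: float = WINDOW_THETA) -> tuple[float, float, float]:
    """Cubic (c1, c2, c3) with z(0)=0, z'(0)=basal_slope, z'(theta_w)=window_slope
    and z(T)=apex_height.

    Pinning the slope at both ends of the basal window controls the curvature
    the basal-plane fit cannot absorb (hence non-planarity), while the apex
    height constraint keeps the overall rise physiological.  A negative
    ``basal_slope`` yields the down-then-up "rollercoaster" profile.
    """
    T = float(total_turn)
    c1 = float(basal_slope)
    A = np.array([[2 * theta_w, 3 * theta_w * theta_w], [T * T, T ** 3]])
    b = np.array([window_slope - c1, apex_height - c1 * T])
    c2, c3 = np.linalg.solve(A, b)
    return (c1, float(c2), float(c3))


_DEFAULT_HEIGHT = height_coeffs_from_slopes(-0.15, 0.25, 2.5, 2.5 * 2 * np.pi)


@dataclass(frozen=True)
class PhantomParams:
    spiral_scale: float = 4.5          # mm, outer-wall radius at the round window
    decay_rate: float = 0.082          # per radian
    total_turn: float = 2.5 * 2 * np.pi  # radians of coiling
    height_profile: tuple = _DEFAULT_HEIGHT  # cubic (c1, c2, c3) in mm at REF_SCALE
    apex_height: float = 2.5           # mm; used to derive c3 when it is None
    duct_radius_base: float = 0.82     # mm (fat basal scala, thin interscalar gap)
    duct_radius_apex: float = 0.27     # mm
    side: str = "left"
    canal_offset: float = 4.5          # mm, horizontal placement of the canal arc
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("spiral_scale", "total_turn", "duct_radius_base",
                     "duct_radius_apex"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and positive, got {v}")
        if not np.isfinite(self.decay_rate):
            raise ParameterError("decay_rate must be finite")
        if self.duct_radius_apex > self.duct_radius_base:
            raise ParameterError("duct radius must taper: base >= apex")
        if self.side not in ("left", "right"):
            raise ParameterError(f"side must be 'left' or 'right', got {self.side!r}")
        if len(self.height_profile) != 3:
            raise ParameterError("height_profile must be cubic coefficients (c1, c2, c3)")
        hp = [float(c) if c is not None else None for c in self.height_profile]
        if any(c is not None and not np.isfinite(c) for c in hp):
            raise ParameterError("height_profile coefficients must be finite")
        object.__setattr__(self, "height_profile", tuple(hp))

    @property
    def height_coeffs(self) -> np.ndarray:
        """Cubic coefficients (c1, c2, c3) with c3 derived from apex_height if None."""
        c1, c2, c3 = self.height_profile
        if c3 is None:
            T = self.total_turn
            c3 = (self.apex_height - c1 * T - c2 * T * T) / T ** 3
        return np.array([c1, c2, c3])


@dataclass(frozen=True)
class GroundTruth:
    centerline: np.ndarray           # dense outer-wall curve, mm
    non_planarity: float
    reach: float
    duct_length: float
    landmarks: dict                  # apex, oval_window, canal_bifurcation
    round_window: np.ndarray
    coiling_axis: np.ndarray
    axis_point: np.ndarray


@dataclass(frozen=True)
class Specimen:
    mesh: trimesh.Trimesh
    ground_truth: GroundTruth
    params: PhantomParams
    rings: np.ndarray = field(repr=False, default=None)  # (N_THETA, N_PHI) vertex ids

    def __iter__(self):
        yield self.mesh
        yield self.ground_truth


# ---------------------------------------------------------------------------
# analytic curves
# ---------------------------------------------------------------------------

def _height(params: PhantomParams, theta: np.ndarray) -> np.ndarray:
    c = params.height_coeffs
    z = c[0] * theta + c[1] * theta ** 2 + c[2] * theta ** 3
    return (params.spiral_scale / REF_SCALE) * z


def outer_wall_curve(params: PhantomParams, theta: np.ndarray) -> np.ndarray:
    """Analytic outer-wall curve w(theta) in mm, left-handed frame."""
    theta = np.asarray(theta, float)
    r = params.spiral_scale * np.exp(-params.decay_rate * theta)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), _height(params, theta)])
    if params.side == "right":
        pts = pts * np.array([1.0, -1.0, 1.0])
    return pts


def _size_factor(params: PhantomParams) -> float:
    """Overall size factor: the whole labyrinth co-varies with cochlear size,
    so every geometric element scales with ``spiral_scale`` and ground-truth
    measurements are exactly proportional to it."""
    return params.spiral_scale / REF_SCALE


def _duct_radius(params: PhantomParams, theta: np.ndarray) -> np.ndarray:
    u = np.asarray(theta, float) / params.total_turn
    rho = params.duct_radius_base + (params.duct_radius_apex
                                     - params.duct_radius_base) * u
    return _size_factor(params) * rho


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def _orient_outward(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    m = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    if m.volume < 0:
        return faces[:, ::-1]
    return faces


def _tube(centers: np.ndarray, frame_u: np.ndarray, frame_v: np.ndarray,
          radii: np.ndarray, n_phi: int) -> tuple[np.ndarray, np.ndarray]:
    """Capped tube: rings of ``n_phi`` vertices plus two cap-center vertices."""
    n = len(centers)
    phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    ring_pts = (centers[:, None, :]
                + radii[:, None, None] * (np.cos(phi)[None, :, None] * frame_u[:, None, :]
                                          + np.sin(phi)[None, :, None] * frame_v[:, None, :]))
    verts = ring_pts.reshape(-1, 3)
    faces = []
    for i in range(n - 1):
        for j in range(n_phi):
            a = i * n_phi + j
            b = i * n_phi + (j + 1) % n_phi
            c = (i + 1) * n_phi + j
            d = (i + 1) * n_phi + (j + 1) % n_phi
            faces.append([a, c, d])
            faces.append([a, d, b])
    base_center = len(verts)
    apex_center = len(verts) + 1
    verts = np.vstack([verts, centers[0], centers[-1]])
    for j in range(n_phi):
        # traverse boundary edges opposite to the adjacent strip triangles
        faces.append([base_center, j, (j + 1) % n_phi])
        faces.append([apex_center, (n - 1) * n_phi + (j + 1) % n_phi,
                      (n - 1) * n_phi + j])
    faces = np.asarray(faces, int)
    return verts, _orient_outward(verts, faces)


def _spiral_tube(params: PhantomParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = np.linspace(0.0, params.total_turn, N_THETA)
    r_wall = params.spiral_scale * np.exp(-params.decay_rate * theta)
    rho = _duct_radius(params, theta)
    e_r = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
    z_hat = np.tile([0.0, 0.0, 1.0], (N_THETA, 1))
    wall = np.column_stack([r_wall * np.cos(theta), r_wall * np.sin(theta),
                            _height(params, theta)])
    centers = wall - rho[:, None] * e_r
    verts, faces = _tube(centers, e_r, z_hat, rho, N_PHI)
    rings = np.arange(N_THETA * N_PHI).reshape(N_THETA, N_PHI)
    return verts, faces, rings


def _canal_tube(params: PhantomParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sf = _size_factor(params)
    psi = np.linspace(*_CANAL_SPAN, N_CANAL)
    u = _CANAL_DIR
    z = np.array([0.0, 0.0, 1.0])
    center = sf * (params.canal_offset * u + _CANAL_Z * z)
    n1 = np.cos(psi)[:, None] * u + np.sin(psi)[:, None] * z
    centers = center + sf * _CANAL_RADIUS * n1
    v = np.cross(u, z)
    n2 = np.tile(v, (N_CANAL, 1))
    radii = np.full(N_CANAL, sf * _CANAL_TUBE_RADIUS)
    verts, faces = _tube(centers, n1, n2, radii, N_CANAL_PHI)
    tip = center + sf * (_CANAL_RADIUS + _CANAL_TUBE_RADIUS) * z  # bifurcation landmark
    return verts, faces, tip


def _lumen_tube_samples(params: PhantomParams, n: int = 1200):
    """Dense (point, radius) samples of the duct + canal tube union, left frame."""
    theta = np.linspace(0.0, params.total_turn, n)
    r_wall = params.spiral_scale * np.exp(-params.decay_rate * theta)
    rho = _duct_radius(params, theta)
    e_r = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
    wall = np.column_stack([r_wall * np.cos(theta), r_wall * np.sin(theta),
                            _height(params, theta)])
    centers = wall - rho[:, None] * e_r
    sf = _size_factor(params)
    psi = np.linspace(*_CANAL_SPAN, n // 3)
    u, z = _CANAL_DIR, np.array([0.0, 0.0, 1.0])
    cc = sf * (params.canal_offset * u + _CANAL_Z * z
               + _CANAL_RADIUS * (np.cos(psi)[:, None] * u
                                  + np.sin(psi)[:, None] * z))
    pts = np.vstack([centers, cc])
    rad = np.concatenate([rho, np.full(len(cc), sf * _CANAL_TUBE_RADIUS)])
    return pts, rad


def _envelope_mesh(params: PhantomParams) -> tuple[np.ndarray, np.ndarray]:
    """Star-shaped outer bone-shell surface: the BONE_SHELL-offset of the duct
    union, sampled on a fixed spherical grid (shared across specimens)."""
    from scipy.spatial import cKDTree

    pts, rad = _lumen_tube_samples(params)
    sf = _size_factor(params)
    shell = sf * BONE_SHELL
    c0 = np.array([0.0, 0.0, float(pts[:, 2].mean())])
    psi = np.linspace(0.0, np.pi, N_ENV_POL + 2)[1:-1]
    alpha = np.linspace(0.0, 2 * np.pi, N_ENV_AZ, endpoint=False)
    A, P = np.meshgrid(alpha, psi, indexing="ij")
    dirs = np.column_stack([(np.sin(P) * np.cos(A)).ravel(),
                            (np.sin(P) * np.sin(A)).ravel(),
                            np.cos(P).ravel()])
    dirs = np.vstack([dirs, [0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])  # poles last

    # the offset solid is the union of spheres B(q_i, rad_i + BONE_SHELL)
    # along the tube centerlines; its star boundary seen from c0 has the
    # closed form r(dir) = max_i [ d_i cos(a_i) + sqrt(R_i^2 - d_i^2 sin^2 a_i) ]
    rel = pts - c0
    d_i = np.linalg.norm(rel, axis=1)                     # (nsamp,)
    R_i = rad + shell
    proj = dirs @ rel.T                                   # d_i * cos(a_i)
    h2 = d_i[None, :] ** 2 - proj ** 2                    # squared miss distance
    disc = R_i[None, :] ** 2 - h2
    reach = np.where(disc >= 0, proj + np.sqrt(np.clip(disc, 0, None)), 0.0)
    r = reach.max(axis=1)
    # central core: rays through the modiolar region can miss every tube
    # sphere; a bone core (kept clear of the lumen) removes the resulting
    # dimple, mimicking the solid modiolus
    core = float(np.clip((d_i - rad).min() - 0.15 * sf, 0.6 * sf, 2.5 * sf))
    r = np.maximum(r, core)
    # inflate by the worst chordal dip of the angular grid so the triangulated
    # surface never clips the tubes it is meant to enclose
    r = r + 0.15 * sf
    verts = c0 + r[:, None] * dirs

    na, np_ = N_ENV_AZ, N_ENV_POL
    faces = []
    for j in range(np_ - 1):
        for i in range(na):
            a = i * np_ + j
            b = ((i + 1) % na) * np_ + j
            faces.append([a, b, b + 1])
            faces.append([a, b + 1, a + 1])
    top = na * np_
    bot = na * np_ + 1
    for i in range(na):
        b = ((i + 1) % na) * np_
        # traverse boundary edges opposite to the adjacent strip triangles
        faces.append([top, b, i * np_])
        faces.append([bot, i * np_ + np_ - 1, b + np_ - 1])
    faces = np.asarray(faces, int)
    return verts, _orient_outward(verts, faces)


def generate_specimen(params: PhantomParams | None = None) -> Specimen:
    """Build one synthetic specimen: watertight mesh plus analytic ground truth.

    The mesh is the full capsule boundary: duct tube + canal appendage (the
    lumen walls, first ``N_LUMEN_VERTS`` vertices) followed by the outer
    bone-shell envelope.
    """
    params = params or PhantomParams()
    sv, sf, rings = _spiral_tube(params)
    cv, cf, canal_tip = _canal_tube(params)
    ev, ef = _envelope_mesh(params)
    verts = np.vstack([sv, cv, ev])
    faces = np.vstack([sf, cf + len(sv), ef + len(sv) + len(cv)])

    theta_dense = np.linspace(0.0, params.total_turn, DENSE_SAMPLES)
    left = replace(params, side="left")
    wall_dense = outer_wall_curve(left, theta_dense)
    theta_ow = 0.8
    ow_center = (outer_wall_curve(left, np.array([theta_ow]))[0]
                 - _duct_radius(params, theta_ow) * np.array(
                     [np.cos(theta_ow), np.sin(theta_ow), 0.0]))
    oval_window = ow_center + _duct_radius(params, theta_ow) * np.array([0, 0, 1.0])
    landmarks = {
        "apex": wall_dense[-1].copy(),
        "oval_window": oval_window,
        "canal_bifurcation": canal_tip,
    }
    round_window = wall_dense[0].copy()
    axis = np.array([0.0, 0.0, 1.0])
    axis_point = np.zeros(3)

    if params.side == "right":
        mirror = np.array([1.0, -1.0, 1.0])
        verts = verts * mirror
        faces = faces[:, ::-1]
        wall_dense = wall_dense * mirror
        landmarks = {k: v * mirror for k, v in landmarks.items()}
        round_window = round_window * mirror

    report = measure_polyline(wall_dense)
    gt = GroundTruth(
        centerline=wall_dense,
        non_planarity=report.non_planarity,
        reach=report.reach,
        duct_length=report.duct_length,
        landmarks=landmarks,
        round_window=round_window,
        coiling_axis=axis,
        axis_point=axis_point,
    )
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return Specimen(mesh=mesh, ground_truth=gt, params=params, rings=rings)


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

# Documented parameter ranges for cohort draws.  Chosen once so that the
# gold-standard duct length spans roughly 37-43 mm (a spread comparable to the
# 5 mm reported for human temporal-bone samples), reach sits near typical
# A-values (~8.5 mm), and non-planarity covers planar through rollercoaster
# vertical profiles.
COHORT_RANGES = {
    "spiral_scale": (4.25, 4.75),
    "decay_rate": (0.077, 0.087),
    "total_turn": (2.45 * 2 * np.pi, 2.55 * 2 * np.pi),
    "basal_slope": (-0.55, 0.30),    # z'(0), mm/radian: negative = rollercoaster
    "window_slope_delta": (-0.35, 0.55),  # z'(theta_w) - z'(0), mm/radian
    "apex_height": (1.8, 3.2),
    "duct_radius_base": (0.78, 0.86),
    "duct_radius_apex": (0.24, 0.30),
}


def sample_params(rng: np.random.Generator, mixed_sides: bool = True) -> PhantomParams:
    r = COHORT_RANGES
    u = {k: rng.uniform(*v) for k, v in r.items()}
    side = "right" if (mixed_sides and rng.uniform() < 0.5) else "left"
    height = height_coeffs_from_slopes(
        u["basal_slope"], u["basal_slope"] + u["window_slope_delta"],
        u["apex_height"], u["total_turn"])
    return PhantomParams(
        spiral_scale=u["spiral_scale"],
        decay_rate=u["decay_rate"],
        total_turn=u["total_turn"],
        height_profile=height,
        apex_height=u["apex_height"],
        duct_radius_base=u["duct_radius_base"],
        duct_radius_apex=u["duct_radius_apex"],
        side=side,
        rng_seed=int(rng.integers(2 ** 31 - 1)),
    )


def sample_cohort(n: int, seed: int, mixed_sides: bool = True) -> list[Specimen]:
    """Draw ``n`` independent specimens from the documented parameter ranges."""
    if n < 2:
        raise ParameterError(f"cohort size must be >= 2, got {n}")
    rng = np.random.default_rng(seed)
    return [generate_specimen(sample_params(rng, mixed_sides)) for _ in range(n)]


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def _inside_fraction(mesh: trimesh.Trimesh, spacing: float, origin: np.ndarray,
                     shape: tuple, level: float = 0.5) -> np.ndarray:
    """Flat per-voxel occupancy of a closed mesh: 1 deep inside, 0 outside,
    with a one-voxel-wide partial-volume ramp across the surface.

    Far-field classification uses a rasterized surface shell plus flood fill;
    voxels within two voxels of the surface get exact signed point-to-triangle
    distances, so the 0.5 iso-level tracks the mesh to sub-voxel accuracy.
    """
    # shell rasterization: subdivide so every surface point has a sample
    # within a quarter voxel, then mark the voxels those samples fall in
    sv, _ = trimesh.remesh.subdivide_to_size(
        np.asarray(mesh.vertices, float), np.asarray(mesh.faces, int),
        max_edge=spacing / 2.0)
    idx = np.rint((sv - origin) / spacing).astype(int)
    idx = idx[np.all((idx >= 0) & (idx < np.array(shape)), axis=1)]
    mark = np.zeros(shape, dtype=bool)
    mark[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    edt = ndimage.distance_transform_edt(~mark).astype(np.float32)
    band = edt <= 2.0

    # flood-fill classification: every voxel inherits the inside/outside vote
    # of its nearest shell-free voxel (robust where the surface folds back on
    # itself, unlike face-normal signing)
    free = edt > 1.0
    del edt
    labels, _ = ndimage.label(free)
    outside_label = labels[0, 0, 0]
    ind = ndimage.distance_transform_edt(~free, return_distances=False,
                                         return_indices=True)
    inside_vote = labels[ind[0], ind[1], ind[2]] != outside_label
    del free, labels, ind

    sgn = np.where(inside_vote.reshape(-1), np.float32(-1.0), np.float32(1.0))
    del inside_vote
    s = sgn * np.float32(10.0 * spacing)
    band_flat = np.flatnonzero(band.reshape(-1))
    del band
    dist = MeshDistance(mesh)
    for start in range(0, len(band_flat), 50_000):
        sel = band_flat[start:start + 50_000]
        ii, jj, kk = np.unravel_index(sel, shape)
        pts = origin + np.column_stack([ii, jj, kk]) * spacing
        s[sel] = sgn[sel] * dist.exact_unsigned(pts).astype(np.float32)
    # one-voxel ramp crossing ``level`` exactly on the surface
    return np.clip(-s / spacing + level, 0.0, 1.0)


def voxelize(mesh: trimesh.Trimesh, spacing: float, intensities: dict | None = None,
             *, origin: np.ndarray | None = None, shape: tuple | None = None,
             min_feature: float | None = None) -> Volume:
    """Rasterize a closed mesh into an intensity volume with a one-voxel
    partial-volume ramp across the surface.

    ``intensities`` maps ``inside``/``outside`` values and, optionally, an
    ``air`` value applied outside a bounding box ``air_margin`` mm beyond the
    mesh (the bony block embedding the capsule; the box boundary stays well
    away from any fitting region of interest).

    Inside/outside classification uses a rasterized surface shell plus flood
    fill; voxels within two voxels of the surface get exact signed
    point-to-triangle distances, so the mid-intensity iso-surface tracks the
    mesh to sub-voxel accuracy.
    """
    if not np.isfinite(spacing) or spacing <= 0:
        raise ParameterError(f"spacing must be positive, got {spacing}")
    if min_feature is not None and spacing > min_feature:
        raise ParameterError(
            f"spacing {spacing} mm exceeds the minimum feature size "
            f"{min_feature} mm: resolution is degenerate")
    inten = dict(DEFAULT_INTENSITIES)
    if intensities:
        inten.update(intensities)
    inside = float(inten["inside"])
    outside = float(inten["outside"])
    air = inten.get("air")
    air_margin = float(inten.get("air_margin", 4.0))

    if origin is None or shape is None:
        pad = (air_margin + 3 * spacing) if air is not None else 3 * spacing
        lo = mesh.bounds[0] - pad
        hi = mesh.bounds[1] + pad
        origin = lo
        shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)
    origin = np.asarray(origin, float)
    shape = tuple(int(s) for s in shape)

    frac_in = _inside_fraction(mesh, spacing, origin, shape)
    data = outside + (inside - outside) * frac_in
    del frac_in
    if air is not None:
        # analytic signed distance to the bone box (positive outside)
        center = (mesh.bounds[0] + mesh.bounds[1]) / 2
        half = (mesh.bounds[1] - mesh.bounds[0]) / 2 + air_margin
        ax = [np.abs(np.arange(n, dtype=np.float32) * spacing
                     + (origin[d] - center[d])) - half[d]
              for d, n in enumerate(shape)]
        qx = ax[0][:, None, None]
        qy = ax[1][None, :, None]
        qz = ax[2][None, None, :]
        pos = np.sqrt(np.clip(qx, 0, None) ** 2 + np.clip(qy, 0, None) ** 2
                      + np.clip(qz, 0, None) ** 2)
        neg = np.clip(np.maximum(np.maximum(qx, qy), qz), None, 0.0)
        frac_air = np.clip((pos + neg).reshape(-1) / w + 0.5, 0.0, 1.0)
        del pos, neg
        data = data + (float(air) - outside) * frac_air
    return Volume(data.reshape(shape).astype(np.float32), spacing, origin)


def split_capsule(mesh: trimesh.Trimesh) -> tuple[trimesh.Trimesh, trimesh.Trimesh]:
    """Split a capsule mesh into its lumen-wall and envelope components."""
    faces = np.asarray(mesh.faces, int)
    verts = np.asarray(mesh.vertices, float)
    lum = faces[np.all(faces < N_LUMEN_VERTS, axis=1)]
    env = faces[np.all(faces >= N_LUMEN_VERTS, axis=1)] - N_LUMEN_VERTS
    lumen = trimesh.Trimesh(vertices=verts[:N_LUMEN_VERTS], faces=lum,
                            process=False)
    envelope = trimesh.Trimesh(vertices=verts[N_LUMEN_VERTS:], faces=env,
                               process=False)
    return lumen, envelope


def voxelize_specimen(spec: Specimen, spacing: float = 0.05,
                      intensities: dict | None = None) -> Volume:
    """Micro-CT-surrogate volume of a specimen.

    Composes air outside the bone-shell envelope, bone in the shell and lumen
    inside the ducts, each interface carrying a one-voxel partial-volume ramp.
    Guards against spacing coarser than the narrowest duct.
    """
    if spacing > spec.params.duct_radius_apex:
        raise ParameterError(
            f"spacing {spacing} mm exceeds the apical duct radius "
            f"{spec.params.duct_radius_apex:.2f} mm: resolution is degenerate")
    inten = dict(DEFAULT_INTENSITIES)
    if intensities:
        inten.update(intensities)
    lumen, envelope = split_capsule(spec.mesh)
    pad = 3 * spacing + 0.5
    lo = spec.mesh.bounds[0] - pad
    hi = spec.mesh.bounds[1] + pad
    origin = lo
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int) + 1)
    tissue = float(inten["tissue"])
    bone = float(inten["outside"])
    lum_v = float(inten["inside"])
    sv = inten.get("surface_value")
    # shift each interface ramp so the iso-surface at ``surface_value`` lies
    # exactly on the mesh (the fraction at s=0 equals the calibrated level)
    f_at0_env = 0.5 if sv is None else (sv - tissue) / (bone - tissue)
    f_at0_lum = 0.5 if sv is None else 1.0 - (sv - lum_v) / (bone - lum_v)
    f_env = _inside_fraction(envelope, spacing, origin, shape,
                             level=f_at0_env)
    f_lum = _inside_fraction(lumen, spacing, origin, shape,
                             level=f_at0_lum)
    data = (tissue + (bone - tissue) * f_env + (lum_v - bone) * f_lum)
    return Volume(data.reshape(shape).astype(np.float32), spacing, origin)
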