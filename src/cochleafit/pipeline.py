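"""End-to-end experiment orchestration at phantom scale.

Reproduces the experimental design of the template-fitting study on synthetic
cohorts: sample a cohort of phantom specimens, rasterize each to a micro-CT
surrogate, degrade to pseudo-clinical CT at named presets, segment at one or
more grayscale thresholds, fit the template by similarity ICP followed by LAD
or (full / leave-one-out) SSM-constrained ICP, measure non-planarity, reach
and duct length on the fitted surface, and summarize mean absolute errors as
a percentage of the gold-standard sample range (max minus min over the
cohort).  The "unfitted" baseline measures the template after similarity
alignment only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import ctsim, phantom
from .errors import CochleaFitError, ParameterError
from .lad import LADRegistration
from .morphometry import (OuterWallContour, measure_contour,  # noqa: F401
                          trace_outer_wall)
from .registration import LandmarkSet, SimilarityICP, landmark_similarity
from .segmentation import PointCloud, extract_threshold_cloud
from .ssm import SSMRegistration, StatisticalShapeModel
from .transforms import SimilarityTransform, fit_similarity

log = logging.getLogger("cochleafit")

METRICS = ("non_planarity", "reach", "duct_length")
METHODS = ("full_ssm", "loo_ssm", "lad")


@dataclass(frozen=True)
class ExperimentConfig:
    cohort_size: int = 18
    presets: tuple = ("mdct",)
    thresholds: tuple = (170.0,)
    methods: tuple = ("lad",)
    lad_d: float = 5.0
    iters: int = 50
    seed: int = 0
    phantom_spacing: float = 0.15    # micro-CT-surrogate voxel pitch, mm
    degrade: bool = True             # False: fit directly to the surrogate
    roi_dilate: float = 2.0          # mm around the landmark-aligned template
    mixed_sides: bool = True

    def __post_init__(self):
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ParameterError(f"unknown methods {bad}; choose from {METHODS}")
        bad = [p for p in self.presets if p not in ctsim.PRESETS]
        if bad:
            raise ParameterError(f"unknown presets {bad}")


@dataclass
class FitResult:
    vertices: np.ndarray
    transform: SimilarityTransform
    report: object
    residual: float


@dataclass
class ErrorSummary:
    """Table-style summary plus the per-specimen measurement table."""
    summary: pd.DataFrame      # metric x method x preset x threshold
    per_specimen: pd.DataFrame
    gt_range: dict             # metric -> gold-standard max - min
    degenerate_range: bool
    failures: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# single-specimen fitting
# ---------------------------------------------------------------------------

def align_template(template: phantom.Specimen, cloud: PointCloud,
                   specimen_landmarks: dict, iters: int = 50) -> SimilarityICP:
    """Landmark initialization plus similarity ICP, resolving chirality.

    Both the direct and the mirrored landmark initializations are refined by
    a short ICP burn-in; the chirality with the lower residual wins and is
    then polished with the full iteration budget (the automatic analogue of
    the operator's optional template reflection).
    """
    src = LandmarkSet(**{k: template.ground_truth.landmarks[k]
                         for k in template.ground_truth.landmarks})
    dst = LandmarkSet(**specimen_landmarks)
    verts = np.asarray(template.mesh.vertices, float)

    candidates = []
    for refl in (False, True):
        init = landmark_similarity(src, dst, reflect=refl)
        probe = SimilarityICP(n_iter=10, init=init).fit(verts, cloud)
        candidates.append((probe.history_[-1], init))
    _, best_init = min(candidates, key=lambda c: c[0])
    return SimilarityICP(n_iter=iters, init=best_init).fit(verts, cloud)


_ANCHOR_CACHE: dict = {}


def template_contour_anchors(template: phantom.Specimen):
    """One-off outer-wall tracing on the template, stored as surface anchors.

    The contour is traced once on the undeformed template (ring extrema where
    the surface normal is perpendicular to the coiling axis) and each traced
    point is expressed in (face, barycentric) coordinates.  Carried through
    any vertex-preserving deformation, the anchors reproduce the contour on
    the fitted surface without re-detecting it — re-detection on a noisy
    fitted surface would inject per-specimen tracing noise.
    """
    key = id(template)
    if key in _ANCHOR_CACHE:
        return _ANCHOR_CACHE[key]
    import trimesh as _tm

    from .sdf import MeshDistance

    gt = template.ground_truth
    contour = trace_outer_wall(template.mesh, gt.landmarks["apex"],
                               gt.round_window, gt.coiling_axis,
                               rings=template.rings, axis_point=gt.axis_point,
                               n_points=len(template.rings))
    pts = contour.points
    md = MeshDistance(template.mesh)
    md.exact_unsigned(pts)
    face_ids = md._last_faces
    bary = _tm.triangles.points_to_barycentric(
        np.asarray(template.mesh.triangles)[face_ids], md._last_closest)
    bary = np.clip(bary, 0.0, 1.0)
    bary = bary / bary.sum(axis=1, keepdims=True)
    _ANCHOR_CACHE[key] = (np.asarray(face_ids, int), np.asarray(bary, float))
    return _ANCHOR_CACHE[key]


def measure_fitted(template: phantom.Specimen, vertices: np.ndarray,
                   transform: SimilarityTransform):
    """Measure the outer wall on deformed template vertices.

    The contour is the template's one-off traced contour carried through the
    deformation via its (face, barycentric) anchors.
    """
    face_ids, bary = template_contour_anchors(template)
    tris = np.asarray(vertices, float)[template.mesh.faces[face_ids]]
    poly = np.einsum("nk,nkj->nj", bary, tris)
    return measure_contour(OuterWallContour.from_polyline(poly, 101))


def fit_specimen(template: phantom.Specimen, cloud: PointCloud,
                 specimen_landmarks: dict, method: str,
                 cfg: ExperimentConfig,
                 ssm_model: StatisticalShapeModel | None = None) -> FitResult:
    """Fit the template to one segmented cloud with the requested method.

    ``method`` is one of ``unfitted`` (similarity alignment only), ``lad``,
    ``full_ssm`` or ``loo_ssm`` (the SSM variants differ only in the model
    passed in).
    """
    verts = np.asarray(template.mesh.vertices, float)
    icp = align_template(template, cloud, specimen_landmarks, iters=cfg.iters)
    aligned = icp.transform(verts)

    if method == "unfitted":
        fitted, tf = aligned, icp.transform_
        residual = float(icp.history_[-1])
    elif method == "lad":
        lad = LADRegistration(d=cfg.lad_d, n_iter=cfg.iters).fit(aligned, cloud)
        fitted, tf = lad.vertices_, icp.transform_
        residual = float(lad.history_[-1])
    elif method in ("full_ssm", "loo_ssm"):
        if ssm_model is None:
            raise ParameterError(f"method {method} requires a shape model")
        mean_pts = ssm_model.mean_.reshape(-1, 3)
        refl = icp.transform_.reflect
        src = mean_pts * [1.0, 1.0, -1.0] if refl else mean_pts
        bridge = fit_similarity(src, aligned, with_scale=True)
        init = SimilarityTransform(rotation=bridge.rotation, scale=bridge.scale,
                                   translation=bridge.translation, reflect=refl)
        ssm = SSMRegistration(ssm_model, n_iter=cfg.iters, init=init).fit(cloud)
        fitted, tf = ssm.vertices_, ssm.transform_
        residual = float(ssm.history_[-1])
    else:
        raise ParameterError(f"unknown method {method!r}")

    report = measure_fitted(template, fitted, tf)
    return FitResult(vertices=fitted, transform=tf, report=report,
                     residual=residual)


# ---------------------------------------------------------------------------
# cohort experiment
# ---------------------------------------------------------------------------

def make_template(cfg: ExperimentConfig) -> phantom.Specimen:
    """The template is the specimen at the documented default parameters."""
    return phantom.generate_specimen(phantom.PhantomParams())


def _side_normalized_vertices(spec: phantom.Specimen) -> np.ndarray:
    """Cohort vertices mirrored to a common (left) chirality for SSM training."""
    v = np.asarray(spec.mesh.vertices, float)
    if spec.params.side == "right":
        v = v * np.array([1.0, -1.0, 1.0])
    return v


def build_cohort_ssm(cohort, reference: np.ndarray,
                     leave_out: int | None = None) -> StatisticalShapeModel:
    """SSM from the cohort's gold-standard meshes (native correspondence)."""
    sets = [_side_normalized_vertices(s) for i, s in enumerate(cohort)
            if i != leave_out]
    return StatisticalShapeModel(reference=reference).fit(np.stack(sets))


def specimen_cloud(spec: phantom.Specimen, template: phantom.Specimen,
                   cfg: ExperimentConfig, preset: str, threshold: float,
                   rng_seed: int) -> PointCloud:
    """Voxelize, optionally degrade, and segment one specimen."""
    vol = phantom.voxelize_specimen(spec, cfg.phantom_spacing)
    if cfg.degrade:
        dcfg = ctsim.DegradeConfig.from_preset(preset, rng_seed=rng_seed)
        vol = ctsim.degrade_volume(vol, dcfg)
    src = LandmarkSet(**template.ground_truth.landmarks)
    dst = LandmarkSet(**spec.ground_truth.landmarks)
    roi = None
    # ROI: landmark-aligned template bounding box, dilated
    for refl in (False, True):
        tf = landmark_similarity(src, dst, reflect=refl)
        box = tf.apply(np.asarray(template.mesh.vertices, float))
        b = np.stack([box.min(axis=0) - cfg.roi_dilate,
                      box.max(axis=0) + cfg.roi_dilate])
        roi = b if roi is None else np.stack([np.minimum(roi[0], b[0]),
                                              np.maximum(roi[1], b[1])])
    return extract_threshold_cloud(vol, threshold, roi=roi)


def measure_template(template: phantom.Specimen):
    """The template's own measurements (the no-fitting baseline)."""
    gt = template.ground_truth
    contour = trace_outer_wall(template.mesh, gt.landmarks["apex"],
                               gt.round_window, gt.coiling_axis,
                               rings=template.rings, axis_point=gt.axis_point)
    return measure_contour(contour)


def run_experiment(cfg: ExperimentConfig | None = None) -> ErrorSummary:
    """Run the full cohort experiment and summarize errors Table-1 style.

    Per specimen/preset/threshold the table contains the requested fitting
    methods plus two baselines: ``template`` (the template measured directly,
    without any fitting to the individual) and ``unfitted`` (the template
    after landmark + similarity-ICP alignment only).
    """
    cfg = cfg or ExperimentConfig()
    cohort = phantom.sample_cohort(cfg.cohort_size, cfg.seed,
                                   mixed_sides=cfg.mixed_sides)
    template = make_template(cfg)
    ref = np.asarray(template.mesh.vertices, float)
    template_report = measure_template(template)

    models: dict = {}
    if "full_ssm" in cfg.methods:
        models["full_ssm"] = build_cohort_ssm(cohort, ref)
    if "loo_ssm" in cfg.methods:
        models.update({("loo_ssm", i): build_cohort_ssm(cohort, ref, leave_out=i)
                       for i in range(len(cohort))})

    rows = []
    failures = []
    rng = np.random.default_rng(cfg.seed + 1)

    def add_row(i, gt, preset, thr, method, report, residual):
        row = {"specimen": i, "preset": preset, "threshold": thr,
               "method": method, "residual": residual}
        for m in METRICS:
            row[m] = getattr(report, m)
            row[f"{m}_gt"] = getattr(gt, m)
            row[f"{m}_abs_err"] = abs(row[m] - row[f"{m}_gt"])
        rows.append(row)

    verts = np.asarray(template.mesh.vertices, float)
    for i, spec in enumerate(cohort):
        gt = spec.ground_truth
        for preset in cfg.presets:
            noise_seed = int(rng.integers(2 ** 31 - 1))
            for thr in cfg.thresholds:
                try:
                    cloud = specimen_cloud(spec, template, cfg, preset, thr,
                                           noise_seed)
                    icp = align_template(template, cloud, gt.landmarks,
                                         iters=cfg.iters)
                except CochleaFitError as exc:
                    failures.append({"specimen": i, "preset": preset,
                                     "threshold": thr, "stage": "align",
                                     "error": str(exc)})
                    continue
                aligned = icp.transform(verts)
                add_row(i, gt, preset, thr, "template", template_report,
                        np.nan)
                try:
                    rep_u = measure_fitted(template, aligned, icp.transform_)
                    add_row(i, gt, preset, thr, "unfitted", rep_u,
                            float(icp.history_[-1]))
                except CochleaFitError as exc:
                    failures.append({"specimen": i, "preset": preset,
                                     "threshold": thr, "stage": "unfitted",
                                     "error": str(exc)})
                for method in cfg.methods:
                    model = (models.get("full_ssm") if method == "full_ssm"
                             else models.get(("loo_ssm", i)))
                    try:
                        if method == "lad":
                            lad = LADRegistration(
                                d=cfg.lad_d, n_iter=cfg.iters).fit(aligned, cloud)
                            rep = measure_fitted(template, lad.vertices_,
                                                 icp.transform_)
                            residual = float(lad.history_[-1])
                        else:
                            mean_pts = model.mean_.reshape(-1, 3)
                            refl = icp.transform_.reflect
                            src = mean_pts * [1.0, 1.0, -1.0] if refl else mean_pts
                            bridge = fit_similarity(src, aligned, with_scale=True)
                            init = SimilarityTransform(
                                rotation=bridge.rotation, scale=bridge.scale,
                                translation=bridge.translation, reflect=refl)
                            ssm = SSMRegistration(model, n_iter=cfg.iters,
                                                  init=init).fit(cloud)
                            rep = measure_fitted(template, ssm.vertices_,
                                                 ssm.transform_)
                            residual = float(ssm.history_[-1])
                    except CochleaFitError as exc:
                        failures.append({"specimen": i, "preset": preset,
                                         "threshold": thr, "stage": method,
                                         "error": str(exc)})
                        continue
                    add_row(i, gt, preset, thr, method, rep, residual)
                    log.info("specimen %d %s thr %g %s: residual %.4f mm",
                             i, preset, thr, method, residual)

    per_specimen = pd.DataFrame(rows)
    gt_range = {m: float(np.ptp([getattr(s.ground_truth, m) for s in cohort]))
                for m in METRICS}
    degenerate = any(r == 0 for r in gt_range.values())

    summary_rows = []
    if len(per_specimen):
        for (method, preset, thr), grp in per_specimen.groupby(
                ["method", "preset", "threshold"]):
            for m in METRICS:
                mae = float(grp[f"{m}_abs_err"].mean())
                summary_rows.append({
                    "metric": m, "method": method, "preset": preset,
                    "threshold": thr, "mean_abs_error_mm": mae,
                    "pct_of_range": (np.nan if degenerate
                                     else 100.0 * mae / gt_range[m]),
                    "n": len(grp),
                })
    return ErrorSummary(summary=pd.DataFrame(summary_rows),
                        per_specimen=per_specimen, gt_range=gt_range,
                        degenerate_range=degenerate, failures=failures)


# ---------------------------------------------------------------------------
# sensitivity sweeps
# ---------------------------------------------------------------------------

SWEEP_VALUES = {
    "threshold": (160.0, 170.0, 180.0),
    "d": (2.5, 5.0, 10.0),
    "iters": (50, 100),
    "template": ("default", "alternative"),
}


def sensitivity_sweep(base_cfg: ExperimentConfig, vary: str,
                      values=None) -> pd.DataFrame:
    """Re-run the LAD pipeline over a varied parameter on the least- and
    most-nonplanar cohort members; returns per-value measurements."""
    if vary not in SWEEP_VALUES:
        raise ParameterError(f"vary must be one of {sorted(SWEEP_VALUES)}")
    values = values if values is not None else SWEEP_VALUES[vary]
    cohort = phantom.sample_cohort(base_cfg.cohort_size, base_cfg.seed,
                                   mixed_sides=base_cfg.mixed_sides)
    nps = [s.ground_truth.non_planarity for s in cohort]
    picks = {"least_nonplanar": int(np.argmin(nps)),
             "most_nonplanar": int(np.argmax(nps))}

    rows = []
    for value in values:
        cfg = base_cfg
        template = make_template(cfg)
        if vary == "threshold":
            cfg = replace(cfg, thresholds=(float(value),))
        elif vary == "d":
            cfg = replace(cfg, lad_d=float(value))
        elif vary == "iters":
            cfg = replace(cfg, iters=int(value))
        elif vary == "template" and value == "alternative":
            alt = phantom.PhantomParams(spiral_scale=4.62, decay_rate=0.079,
                                        duct_radius_base=0.52)
            template = phantom.generate_specimen(alt)
        preset = cfg.presets[0]
        thr = cfg.thresholds[0]
        for label, i in picks.items():
            spec = cohort[i]
            cloud = specimen_cloud(spec, template, cfg, preset, thr,
                                   rng_seed=cfg.seed + 17 * i)
            res = fit_specimen(template, cloud, spec.ground_truth.landmarks,
                               "lad", cfg)
            row = {"vary": vary, "value": value, "specimen": label}
            for m in METRICS:
                row[m] = getattr(res.report, m)
                row[f"{m}_gt"] = getattr(spec.ground_truth, m)
            rows.append(row)
    return pd.DataFrame(rows)
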