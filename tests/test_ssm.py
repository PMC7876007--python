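import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cochleafit.errors import CorrespondenceError, ParameterError
from cochleafit.sdf import MeshDistance
from cochleafit.ssm import (SSMRegistration, StatisticalShapeModel,
                            centroid_size, procrustes_standardize)
from cochleafit.transforms import SimilarityTransform


class TestProcrustes:
    def test_outputs_have_unit_centroid_size(self, small_cohort):
        sets = [np.asarray(s.mesh.vertices) for s in small_cohort]
        out = procrustes_standardize(sets, sets[0])
        for o in out:
            assert abs(centroid_size(o) - 1.0) < 1e-9

    def test_similarity_transformed_copy_standardizes_identically(self, small_cohort):
        ref = np.asarray(small_cohort[0].mesh.vertices)
        tf = SimilarityTransform(
            rotation=Rotation.from_rotvec([0.5, -0.3, 0.8]).as_matrix(),
            scale=1.8, translation=np.array([10.0, -4.0, 2.0]))
        a, b = procrustes_standardize([ref, tf.apply(ref)], ref)
        assert np.abs(a - b).max() < 1e-9

    def test_vertex_count_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(CorrespondenceError):
            procrustes_standardize([rng.normal(size=(5, 3))],
                                   rng.normal(size=(6, 3)))


class TestBuild:
    def test_identical_shapes_give_zero_eigenvalues(self, small_cohort):
        shape = np.asarray(small_cohort[0].mesh.vertices)
        model = StatisticalShapeModel().fit(np.stack([shape] * 4))
        assert np.all(model.eigenvalues_ < 1e-12)

    def test_three_shapes_give_exactly_two_nonzero_modes(self, small_cohort):
        stack = np.stack([np.asarray(s.mesh.vertices) for s in small_cohort[:3]])
        model = StatisticalShapeModel().fit(stack)
        eig = model.eigenvalues_
        assert len(eig) == 2
        assert eig[0] > 0 and eig[1] > 0 and eig[0] >= eig[1]

    def test_training_shapes_reconstructed_exactly(self, small_cohort):
        stack = np.stack([np.asarray(s.mesh.vertices) for s in small_cohort[:3]])
        model = StatisticalShapeModel().fit(stack)
        coeffs = model.transform(stack)
        std = procrustes_standardize(list(stack), model.reference_used_)
        for S, s_std in zip(coeffs, std):
            rec = model.shape_of(S)
            assert np.abs(rec - s_std).max() < 1e-8

    def test_modes_orthonormal_and_eigenvalues_sorted(self, small_cohort):
        stack = np.stack([np.asarray(s.mesh.vertices) for s in small_cohort])
        model = StatisticalShapeModel().fit(stack)
        gram = model.components_ @ model.components_.T
        assert np.abs(gram - np.eye(len(gram))).max() < 1e-8
        assert np.all(np.diff(model.eigenvalues_) <= 1e-15)

    def test_eigenvalue_sum_equals_total_variance(self, small_cohort):
        stack = np.stack([np.asarray(s.mesh.vertices) for s in small_cohort])
        model = StatisticalShapeModel().fit(stack)
        std = procrustes_standardize(list(stack), stack[0])
        data = np.stack([s.reshape(-1) for s in std])
        centered = data - data.mean(axis=0)
        total = np.sum(centered ** 2) / (len(stack) - 1)
        assert abs(model.eigenvalues_.sum() - total) / total < 1e-9

    def test_too_few_shapes_rejected(self, small_cohort):
        with pytest.raises(ParameterError):
            StatisticalShapeModel().fit(
                np.asarray(small_cohort[0].mesh.vertices)[None])


class TestFit:
    def test_mean_shape_cloud_gives_near_zero_coefficients(self, small_cohort):
        stack = np.stack([np.asarray(s.mesh.vertices) for s in small_cohort])
        model = StatisticalShapeModel().fit(stack)
        mesh = small_cohort[0].mesh.copy()
        mesh.vertices = model.mean_.reshape(-1, 3)
        cloud = np.asarray(mesh.sample(30000, seed=0))
        est = SSMRegistration(model, n_iter=20).fit(cloud)
        assert np.all(np.abs(est.coefficients_)
                      < 0.1 * np.sqrt(model.eigenvalues_))

    def test_training_shape_recovered(self, small_cohort):
        stack = np.stack([np.asarray(s.mesh.vertices) for s in small_cohort])
        model = StatisticalShapeModel().fit(stack)
        target = small_cohort[2]
        cloud = np.asarray(target.mesh.sample(40000, seed=1))
        est = SSMRegistration(model, n_iter=30).fit(cloud)
        d = MeshDistance(target.mesh).exact_unsigned(est.vertices_)
        assert d.mean() < 0.02

    def test_leave_one_out_residual_at_least_full_model(self, small_cohort):
        stack = np.stack([np.asarray(s.mesh.vertices) for s in small_cohort])
        full = StatisticalShapeModel().fit(stack)
        for i in range(len(small_cohort)):
            loo = StatisticalShapeModel().fit(np.delete(stack, i, axis=0))
            cloud = np.asarray(small_cohort[i].mesh.sample(20000, seed=2 + i))
            md = MeshDistance(small_cohort[i].mesh)
            d_full = md.exact_unsigned(
                SSMRegistration(full, n_iter=20).fit(cloud).vertices_).mean()
            d_loo = md.exact_unsigned(
                SSMRegistration(loo, n_iter=20).fit(cloud).vertices_).mean()
            assert d_loo >= d_full

    def test_objective_non_increasing_on_clean_cloud(self, small_cohort):
        stack = np.stack([np.asarray(s.mesh.vertices) for s in small_cohort])
        model = StatisticalShapeModel().fit(stack)
        cloud = np.asarray(small_cohort[1].mesh.sample(20000, seed=5))
        est = SSMRegistration(model, n_iter=25, trim_factor=None).fit(cloud)
        assert np.all(np.diff(est.history_) <= 1e-6)
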