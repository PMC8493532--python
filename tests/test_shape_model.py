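"""PCA point-distribution model: alignment, spectrum, sampling bounds."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles
from scipy.spatial.transform import Rotation

from echosynth.errors import ValidationError
from echosynth.phantoms import generate_phantom_cohort
from echosynth.shape_model import (
    align_cohort,
    expand_cohort,
    fit_pdm,
    load_pdm,
    reconstruct_from_coefficients,
    sample_shape,
    save_pdm,
)


def _rigidly_scattered(mesh, n, seed):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-30, 30, 3)
        out.append(mesh.with_vertices(mesh.vertices @ R.T + t))
    return out


def test_procrustes_removes_rigid_motion(phantom):
    cohort = _rigidly_scattered(phantom, 5, seed=1)
    aligned = align_cohort(cohort)
    ref = aligned[0].vertices
    for m in aligned[1:]:
        rmsd = np.sqrt(np.mean((m.vertices - ref) ** 2))
        assert rmsd < 1e-6


def test_alignment_is_idempotent_and_centers_the_mean(aligned):
    again = align_cohort(aligned)
    for a, b in zip(aligned, again):
        assert np.allclose(a.vertices, b.vertices, atol=1e-9)
    centroid = np.mean([m.vertices.mean(axis=0) for m in again], axis=0)
    assert np.abs(centroid).max() < 1e-9


def test_noncorresponded_cohort_is_rejected(cohort, phantom):
    import dataclasses

    broken = dataclasses.replace(phantom, faces=phantom.faces[:-1], face_labels=phantom.face_labels[:-1])
    with pytest.raises(ValidationError):
        align_cohort([cohort[0], broken])


def test_mode_count_follows_parametric_degrees_of_freedom():
    cohort = generate_phantom_cohort(12, seed=3, vary=["lv_long_axis", "lv_radius", "wall_thickness"])
    pdm = fit_pdm(align_cohort(cohort), 0.999)
    # 3 shape parameters (+ residual rigid-alignment noise) dominate
    assert pdm.k <= 3


def test_full_variance_target_retains_numerical_rank(aligned):
    pdm = fit_pdm(aligned, 1.0)
    assert pdm.k == len(pdm.all_variances) <= len(aligned) - 1


def test_modes_are_orthonormal_and_spectrum_conserves_variance(aligned, pdm):
    assert np.abs(pdm.modes.T @ pdm.modes - np.eye(pdm.k)).max() < 1e-8
    assert np.all(np.diff(pdm.mode_variances) <= 1e-12)
    X = np.stack([m.vertices.ravel() for m in aligned])
    total = ((X - X.mean(axis=0)) ** 2).sum() / (len(X) - 1)
    assert abs(pdm.all_variances.sum() - total) / total < 1e-8


def test_training_shape_reconstruction_identity(aligned):
    pdm = fit_pdm(aligned, 1.0)
    x = aligned[2].vertices.ravel()
    c = pdm.modes.T @ (x - pdm.mean_shape) / np.sqrt(pdm.mode_variances)
    rec = reconstruct_from_coefficients(pdm, c)
    assert np.sqrt(np.mean((rec.vertices - aligned[2].vertices) ** 2)) < 1e-6


def test_known_subspace_and_variances_are_recovered(pdm):
    rng = np.random.default_rng(0)
    dim = 300
    Q, _ = np.linalg.qr(rng.normal(size=(dim, 3)))
    lam = np.array([9.0, 4.0, 1.0])
    Z = rng.normal(size=(200, 3)) * np.sqrt(lam)
    X = rng.normal(size=dim) + Z @ Q.T
    template = pdm.template
    import dataclasses

    meshes = []
    for row in X:
        v = np.zeros((dim // 3, 3))
        meshes.append(dataclasses.replace(
            template,
            vertices=v,
            faces=np.array([[0, 1, 2]]),
            face_labels=np.array([1]),
            landmark_indices={"apex": 0, "mitral_valve_center": 1, "aortic_valve_center": 2},
        ).with_vertices(row.reshape(-1, 3)))
    fitted = fit_pdm(meshes, 0.99)
    assert fitted.k == 3
    angles = np.degrees(subspace_angles(fitted.modes, Q))
    assert angles.max() < 1.0
    # PCA recovers the empirical variances of this draw along the true modes
    emp = np.sort(Z.var(axis=0, ddof=1))[::-1]
    assert np.all(np.abs(fitted.mode_variances - emp) / emp < 0.10)


def test_zero_coefficients_reproduce_the_mean_shape(pdm):
    rec = reconstruct_from_coefficients(pdm, np.zeros(pdm.k))
    assert np.allclose(rec.vertices.ravel(), pdm.mean_shape, atol=1e-9)


def test_sampling_respects_two_sd_bound_and_mode_linearity(pdm):
    maxc = max(np.abs(sample_shape(pdm, s).coefficients).max() for s in range(500))
    assert maxc <= 2.0
    cp, cm = np.zeros(pdm.k), np.zeros(pdm.k)
    cp[0], cm[0] = 2.0, -2.0
    a = reconstruct_from_coefficients(pdm, cp).vertices.ravel()
    b = reconstruct_from_coefficients(pdm, cm).vertices.ravel()
    expected = 4.0 * np.sqrt(pdm.mode_variances[0]) * pdm.modes[:, 0]
    assert np.allclose(a - b, expected, atol=1e-9)


def test_expanded_cohort_is_deterministic_with_positive_volumes(pdm):
    a = expand_cohort(pdm, 10, seed=5)
    b = expand_cohort(pdm, 10, seed=5)
    assert len(a) == 10
    for ma, mb in zip(a, b):
        assert np.array_equal(ma.vertices, mb.vertices)
    for code in a[0].compartment_codes():
        assert a[0].compartment_volume(code) > 0
    with pytest.raises(ValidationError):
        expand_cohort(pdm, 0, seed=1)


def test_variance_target_validation(aligned):
    for bad in (0.0, -0.1, 1.5):
        with pytest.raises(ValidationError):
            fit_pdm(aligned, bad)


def test_pdm_roundtrip(tmp_path, pdm):
    save_pdm(pdm, tmp_path / "pdm.npz")
    back = load_pdm(tmp_path / "pdm.npz")
    assert np.allclose(back.mean_shape, pdm.mean_shape)
    assert np.allclose(back.modes, pdm.modes)
    s1 = sample_shape(pdm, 11).mesh.vertices
    s2 = sample_shape(back, 11).mesh.vertices
    assert np.allclose(s1, s2)
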