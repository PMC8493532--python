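"""Pseudo-ultrasound rendering: pairing, cone invariant, noise statistics."""

import numpy as np
import pytest

from conftest import TASK
from echosynth.errors import GenerationError, ValidationError
from echosynth.phantoms import generate_phantom_cohort
from echosynth.pseudo import (
    ConeGeometry,
    RenderConfig,
    add_noise_and_shadows,
    blur,
    compose_view,
    derive_task_labels,
    load_dataset,
    render_dataset,
    render_pair,
    structure_mask,
    write_dataset,
)

CFG = RenderConfig(H=128, W=128, pixel_spacing=1.2)


@pytest.fixture(scope="module")
def pair(a4c_slice):
    return render_pair(a4c_slice, TASK, CFG, seed=5)


def test_task_labels_nest_and_reject_unknown_structures(a4c_slice):
    tr = derive_task_labels(a4c_slice, TASK)
    endo = structure_mask(tr, "lv_endo", TASK)
    epi = structure_mask(tr, "lv_epi", TASK)
    assert np.all(epi[endo])
    assert 0.0 < endo.sum() / epi.sum() < 1.0
    with pytest.raises(ValidationError):
        derive_task_labels(a4c_slice, ("lv_endo", "spleen"))


def test_empty_slice_gives_empty_task_raster(a4c_slice):
    import dataclasses

    empty = dataclasses.replace(a4c_slice, raster=np.zeros_like(a4c_slice.raster))
    assert not derive_task_labels(empty, ("lv_endo",)).any()


def test_cone_invariant(pair):
    mask = pair.cone_mask()
    assert np.all(pair.image[~mask] == 0)
    assert np.all(pair.label[~mask] == 0)
    assert pair.image.shape == pair.label.shape


def test_same_seed_regenerates_bit_identical_pair(a4c_slice):
    a = render_pair(a4c_slice, TASK, CFG, seed=5)
    b = render_pair(a4c_slice, TASK, CFG, seed=5)
    assert np.array_equal(a.image, b.image)
    assert np.array_equal(a.label, b.label)
    from echosynth.metrics import dice

    assert dice(a.label > 0, b.label > 0) == 100.0


def test_both_crop_modes_occur_and_are_recorded(a4c_slice):
    modes = {render_pair(a4c_slice, TASK, CFG, seed=s).provenance["crop_mode"] for s in range(15)}
    assert modes == {"lv_focused", "whole_heart"}


def test_compose_rejects_slice_without_crop_target(a4c_slice):
    import dataclasses

    empty = dataclasses.replace(a4c_slice, raster=np.zeros_like(a4c_slice.raster))
    with pytest.raises(GenerationError):
        compose_view(empty, TASK, CFG.cone_geometry(), "lv_focused", 0, CFG)


def test_noise_and_shadows_never_touch_labels(pair):
    noisy = add_noise_and_shadows(pair, seed=1, noise_amplitude=0.1)
    assert noisy.label is pair.label or np.array_equal(noisy.label, pair.label)
    ident = add_noise_and_shadows(pair, seed=1, noise_amplitude=0.0, n_shadows=(0, 0))
    assert np.array_equal(ident.image, pair.image)
    with pytest.raises(ValidationError):
        add_noise_and_shadows(pair, seed=1, noise_amplitude=-0.1)


def test_uniform_noise_standard_deviation_matches_closed_form(pair):
    # constant 0.5 inside the cone: after U(-a, a) noise the pixel std is a/sqrt(3)
    import dataclasses

    a = 0.1
    flat = dataclasses.replace(pair, image=np.where(pair.cone_mask(), 0.5, 0.0))
    noisy = add_noise_and_shadows(flat, seed=2, noise_amplitude=a, n_shadows=(0, 0))
    sd = noisy.image[flat.cone_mask()].std()
    assert abs(sd - a / np.sqrt(3)) / (a / np.sqrt(3)) < 0.05


def test_blur_identity_and_flat_interior_preservation(pair):
    import dataclasses

    assert blur(pair, 0.0) is pair
    flat = dataclasses.replace(pair, image=np.where(pair.cone_mask(), 0.5, 0.0))
    blurred = blur(flat, 2.0)
    from scipy.ndimage import binary_erosion

    # erode past the truncated kernel's square support (4 sigma = 8 px)
    interior = binary_erosion(flat.cone_mask(), structure=np.ones((3, 3)), iterations=10)
    assert np.abs(blurred.image[interior] - 0.5).max() < 1e-6
    assert abs(blurred.image[interior].sum() - flat.image[interior].sum()) / flat.image[interior].sum() < 0.01


def test_noise_amplitude_monotonically_increases_deviation(pair):
    base = pair.image
    devs = []
    for a in (0.02, 0.06, 0.12):
        noisy = add_noise_and_shadows(pair, seed=3, noise_amplitude=a, n_shadows=(0, 0))
        devs.append(np.abs(noisy.image - base).mean())
    assert devs[0] < devs[1] < devs[2]


def test_dataset_count_is_exact_and_deterministic():
    cohort = generate_phantom_cohort(3, seed=1)
    a = render_dataset(cohort, "a4c", 2, 2, TASK, CFG, seed=9)
    b = render_dataset(cohort, "a4c", 2, 2, TASK, CFG, seed=9)
    assert len(a) == 3 * 2 * 2
    for pa, pb in zip(a, b):
        assert np.array_equal(pa.image, pb.image)
        assert np.array_equal(pa.label, pb.label)
    for p in a:
        assert {"model_id", "view", "crop_mode", "affine", "noise", "seed"} <= set(p.provenance)


def test_affine_chain_keeps_image_and_label_synchronized(a4c_slice):
    # fiducial check: make exactly one tissue bright, everything else dark;
    # the thresholded image and the label of that structure must coincide
    import dataclasses

    from echosynth.metrics import dice
    from echosynth.pseudo import GRAY_LEVELS

    cfg = dataclasses.replace(CFG, noise_amplitude=0.0, n_shadows=(0, 0), blur_sigma=0.0)
    import echosynth.pseudo as ps

    orig = dict(ps.GRAY_LEVELS)
    try:
        for code in list(ps.GRAY_LEVELS):
            ps.GRAY_LEVELS[code] = 1.0 if code == 1 else 0.0
        ps_bg = ps.BACKGROUND_LEVEL
        ps.BACKGROUND_LEVEL = 0.0
        pair = render_pair(a4c_slice, TASK, cfg, seed=11)
    finally:
        ps.GRAY_LEVELS.update(orig)
        ps.BACKGROUND_LEVEL = ps_bg
    fid_img = pair.image > 0.5
    fid_lbl = structure_mask(pair.label, "lv_endo", TASK)
    assert dice(fid_img, fid_lbl) > 98.0


def test_dataset_roundtrip_preserves_labels_exactly(tmp_path, a4c_slice):
    pairs = [render_pair(a4c_slice, TASK, CFG, seed=s) for s in (1, 2)]
    write_dataset(pairs, tmp_path)
    back = load_dataset(tmp_path)
    assert len(back) == 2
    for a, b in zip(pairs, back):
        assert np.array_equal(a.label, b.label)
        assert np.abs(a.image - b.image).max() <= 1.0 / 255.0 + 1e-9


def test_cone_geometry_validation():
    with pytest.raises(ValidationError):
        ConeGeometry(apex=(0, 64), opening_angle=200.0, radius=100)
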