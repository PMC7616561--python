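"""Shape, watertightness and determinism of the synthetic heart generator."""

import dataclasses

import numpy as np
import pytest

from echo2vox.heartgen import (
    STRUCTURES,
    HeartShapeParams,
    ParameterError,
    generate_cohort,
    generate_heart_mesh,
)


def test_all_structures_watertight_nondegenerate(default_mesh):
    assert set(default_mesh.structure_names()) == set(STRUCTURES)
    for name in STRUCTURES:
        tm = default_mesh.structure_mesh(name)
        assert tm.is_watertight, name
        assert tm.area_faces.min() > 1e-9, name
    assert np.isfinite(default_mesh.vertices).all()


def test_jittered_structures_stay_watertight():
    mesh = generate_heart_mesh(HeartShapeParams(jitter_sd=0.1, seed=11))
    for name in STRUCTURES:
        assert mesh.structure_mesh(name).is_watertight, name


def test_epi_vertices_on_exact_truncated_ellipsoid(default_mesh, default_params):
    """Jitter-free epicardium is an exact ellipsoid surface."""
    p = default_params
    b = p.lv_short_axis_mm / 2 + p.wall_thickness_base_mm
    a = p.lv_long_axis_mm / 2 + p.wall_thickness_apex_mm
    v = np.asarray(default_mesh.structure_mesh("LV_MYOCARDIUM_EPI").vertices)
    resid = (v[:, 0] / b) ** 2 + (v[:, 1] / b) ** 2 + (v[:, 2] / a) ** 2 - 1.0
    assert np.abs(resid).max() < 1e-6


def test_same_seed_bit_identical():
    p = HeartShapeParams(jitter_sd=0.07, seed=1)
    m1 = generate_heart_mesh(p)
    m2 = generate_heart_mesh(p)
    assert np.array_equal(m1.vertices, m2.vertices)
    assert np.array_equal(m1.faces, m2.faces)
    assert np.array_equal(m1.face_labels, m2.face_labels)


def test_seed_variation_nonzero_and_bounded():
    """Different seeds move vertices, but never more than 4*sd*long_axis."""
    sd = 0.05
    p = HeartShapeParams(jitter_sd=sd)
    m1 = generate_heart_mesh(dataclasses.replace(p, seed=1))
    m2 = generate_heart_mesh(dataclasses.replace(p, seed=2))
    disp = np.linalg.norm(m1.vertices - m2.vertices, axis=1)
    assert disp.max() > 0
    assert disp.max() < 4 * sd * p.lv_long_axis_mm


@pytest.mark.parametrize(
    "field,value",
    [
        ("lv_long_axis_mm", -1.0),
        ("wall_thickness_apex_mm", 15.0),  # >= base thickness
        ("jitter_sd", -0.1),
        ("chamber_scale_rv", 0.0),
    ],
)
def test_invalid_params_raise_named_error(field, value):
    with pytest.raises(ParameterError):
        generate_heart_mesh(dataclasses.replace(HeartShapeParams(), **{field: value}))


def test_cohort_reproducible_and_sized(small_params):
    p = dataclasses.replace(small_params, jitter_sd=0.06)
    c1 = generate_cohort(3, p, seed=9)
    c2 = generate_cohort(3, p, seed=9)
    assert len(c1) == 3
    for a, b in zip(c1, c2):
        assert np.array_equal(a.vertices, b.vertices)
    with pytest.raises(ParameterError):
        generate_cohort(0, p, seed=9)


def test_cohort_without_jitter_is_constant(small_params):
    cohort = generate_cohort(5, small_params, seed=4)
    for mesh in cohort[1:]:
        assert np.array_equal(mesh.vertices, cohort[0].vertices)


def test_mesh_roundtrip_ply(tmp_path, small_mesh):
    path = tmp_path / "heart.ply"
    small_mesh.save(path)
    loaded = type(small_mesh).load(path)
    assert np.allclose(loaded.vertices, small_mesh.vertices, atol=1e-6)
    assert np.array_equal(loaded.face_labels, small_mesh.face_labels)
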