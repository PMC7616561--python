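import dataclasses

import numpy as np
import pytest
import trimesh

from echo2vox.heartgen import STRUCTURE_IDS, HeartShapeParams, LabeledSurfaceMesh, generate_heart_mesh


@pytest.fixture(scope="session")
def default_params():
    return HeartShapeParams()


@pytest.fixture(scope="session")
def default_mesh(default_params):
    """Jitter-free heart at default resolution."""
    return generate_heart_mesh(default_params)


@pytest.fixture(scope="session")
def small_params():
    return HeartShapeParams(lv_n_theta=18, lv_n_phi=36, sphere_subdivisions=2)


@pytest.fixture(scope="session")
def small_mesh(small_params):
    return generate_heart_mesh(small_params)


@pytest.fixture(scope="session")
def default_landmarks(default_mesh):
    from echo2vox.viewslice import compute_landmarks

    return compute_landmarks(default_mesh)


def labeled_from_parts(parts):
    """Assemble a LabeledSurfaceMesh from (structure_name, trimesh) pairs."""
    verts, faces, labels = [], [], []
    offset = 0
    for name, tm in parts:
        verts.append(np.asarray(tm.vertices, dtype=np.float64))
        faces.append(np.asarray(tm.faces, dtype=np.int64) + offset)
        labels.append(np.full(len(tm.faces), STRUCTURE_IDS[name], dtype=np.int64))
        offset += len(tm.vertices)
    return LabeledSurfaceMesh(
        vertices=np.vstack(verts),
        faces=np.vstack(faces),
        face_labels=np.concatenate(labels),
        mesh_id="synthetic-fixture",
    )


@pytest.fixture(scope="session")
def concentric_shells():
    """LV endo/epi as concentric icospheres of radii 8 and 10 mm."""
    endo = trimesh.creation.icosphere(subdivisions=3, radius=8.0)
    epi = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    return labeled_from_parts([("LV_MYOCARDIUM_ENDO", endo), ("LV_MYOCARDIUM_EPI", epi)])
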