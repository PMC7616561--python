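"""Seeded generator of synthetic labeled heart-like surface meshes.

Each generated heart is a collection of closed, watertight triangle surfaces
with per-face anatomical labels: the left-ventricular myocardium as two
nested truncated ellipsoids (endocardium and epicardium, whose separation
tapers from a thick base to a thin apex), ellipsoidal right ventricle and
atria attached around the base, and disk-like valve bodies at the base
plane.  Shape variation across a cohort is a seeded combination of
multiplicative parameter jitter and a low-order spherical-harmonic radial
perturbation of every surface, so identical parameters and seed reproduce a
bit-identical mesh.

Coordinates are millimetres.  The long axis is ``z``; the apex points
toward ``-z`` and the valve plane toward ``+z``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "STRUCTURES",
    "STRUCTURE_IDS",
    "HeartShapeParams",
    "LabeledSurfaceMesh",
    "generate_heart_mesh",
    "generate_cohort",
]

# Anatomical label vocabulary; integer ids are stable across runs/files.
STRUCTURES = (
    "LV_MYOCARDIUM_EPI",
    "LV_MYOCARDIUM_ENDO",
    "RV",
    "LA",
    "RA",
    "MITRAL_VALVE",
    "AORTIC_VALVE",
    "PULMONARY_VALVE",
)
STRUCTURE_IDS = {name: i + 1 for i, name in enumerate(STRUCTURES)}


class ParameterError(ValueError):
    """A shape parameter violates its constraint; names the offending field."""


@dataclass(frozen=True)
class HeartShapeParams:
    """Shape parameters of one synthetic heart.

    All lengths in millimetres.  ``wall_thickness_apex_mm`` must be smaller
    than ``wall_thickness_base_mm`` so the thinnest wall locus is the apex.
    ``jitter_sd`` is the relative standard deviation of the shape variation
    (multiplicative parameter jitter, clipped at 2 sd, plus a degree-2
    spherical-harmonic surface perturbation); the intended range is
    roughly 0–0.15.
    """

    lv_long_axis_mm: float = 90.0
    lv_short_axis_mm: float = 50.0
    wall_thickness_base_mm: float = 12.0
    wall_thickness_apex_mm: float = 4.0
    chamber_scale_rv: float = 1.0
    chamber_scale_la: float = 1.0
    chamber_scale_ra: float = 1.0
    valve_radius_mitral_mm: float = 14.0
    valve_radius_aortic_mm: float = 10.0
    valve_radius_pulmonary_mm: float = 9.0
    jitter_sd: float = 0.0
    seed: int = 0
    # meshing resolution (config-exposed): latitude/longitude rings for the
    # LV surfaces, icosphere subdivisions for the other structures
    lv_n_theta: int = 24
    lv_n_phi: int = 48
    sphere_subdivisions: int = 3

    def validate(self) -> None:
        lengths = (
            "lv_long_axis_mm",
            "lv_short_axis_mm",
            "wall_thickness_base_mm",
            "wall_thickness_apex_mm",
            "valve_radius_mitral_mm",
            "valve_radius_aortic_mm",
            "valve_radius_pulmonary_mm",
        )
        for name in lengths:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("chamber_scale_rv", "chamber_scale_la", "chamber_scale_ra"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0")
        if not self.wall_thickness_apex_mm < self.wall_thickness_base_mm:
            raise ParameterError(
                "wall_thickness_apex_mm must be smaller than wall_thickness_base_mm"
            )
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be >= 0")
        if self.lv_n_theta < 4 or self.lv_n_phi < 8:
            raise ParameterError("lv_n_theta/lv_n_phi resolution too low")


@dataclass
class LabeledSurfaceMesh:
    """Triangle mesh with a per-face anatomical structure label."""

    vertices: np.ndarray  # (N, 3) float64, mm
    faces: np.ndarray  # (M, 3) int
    face_labels: np.ndarray  # (M,) int, values from STRUCTURE_IDS
    mesh_id: str = "heart"

    def structure_names(self) -> list[str]:
        present = set(np.unique(self.face_labels).tolist())
        return [s for s in STRUCTURES if STRUCTURE_IDS[s] in present]

    def structure_mesh(self, name: str) -> trimesh.Trimesh:
        """The closed surface of one labeled structure as a trimesh."""
        if name not in STRUCTURE_IDS:
            raise KeyError(f"unknown structure label: {name}")
        mask = self.face_labels == STRUCTURE_IDS[name]
        if not mask.any():
            raise KeyError(f"structure not present in mesh: {name}")
        faces = self.faces[mask]
        used, inverse = np.unique(faces, return_inverse=True)
        return trimesh.Trimesh(
            vertices=self.vertices[used],
            faces=inverse.reshape(-1, 3),
            process=False,
        )

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    # -- persistence: PLY geometry + JSON sidecar with the face labels -----
    def save(self, path: str | Path) -> None:
        path = Path(path)
        mesh = trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)
        mesh.export(path)
        sidecar = {
            "mesh_id": self.mesh_id,
            "label_map": STRUCTURE_IDS,
            "face_labels": self.face_labels.astype(int).tolist(),
        }
        path.with_suffix(".labels.json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "LabeledSurfaceMesh":
        path = Path(path)
        mesh = trimesh.load(path, process=False)
        sidecar = json.loads(path.with_suffix(".labels.json").read_text())
        return cls(
            vertices=np.asarray(mesh.vertices, dtype=np.float64),
            faces=np.asarray(mesh.faces, dtype=np.int64),
            face_labels=np.asarray(sidecar["face_labels"], dtype=np.int64),
            mesh_id=sidecar.get("mesh_id", path.stem),
        )


# -- surface construction ---------------------------------------------------

def _truncated_ellipsoid(semi: np.ndarray, z_cut: float, n_theta: int, n_phi: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed truncated ellipsoid: open bowl capped by a fan at ``z=z_cut``.

    Every vertex (including the cap ring, which carries no interior points)
    lies exactly on the ellipsoid, so analytic surface checks hold for the
    whole structure.
    """
    a, b, c = semi
    if not -c < z_cut < c:
        raise ParameterError("truncation plane outside the ellipsoid")
    theta_cut = np.arccos(z_cut / c)
    thetas = np.linspace(theta_cut, np.pi, n_theta)
    phis = np.linspace(0.0, 2.0 * np.pi, n_phi, endpoint=False)
    rings = []
    for th in thetas[:-1]:
        st, ct = np.sin(th), np.cos(th)
        rings.append(np.column_stack([a * st * np.cos(phis), b * st * np.sin(phis), np.full(n_phi, c * ct)]))
    verts = np.vstack(rings + [np.array([[0.0, 0.0, -c]])])
    pole = len(verts) - 1
    faces = []
    nring = n_theta - 1
    for r in range(nring - 1):
        i0 = r * n_phi
        i1 = (r + 1) * n_phi
        for j in range(n_phi):
            jn = (j + 1) % n_phi
            faces.append([i0 + j, i1 + j, i1 + jn])
            faces.append([i0 + j, i1 + jn, i0 + jn])
    last = (nring - 1) * n_phi
    for j in range(n_phi):
        jn = (j + 1) % n_phi
        faces.append([last + j, pole, last + jn])
    # cap: fan over the first (cut) ring, no interior vertices
    for j in range(1, n_phi - 1):
        faces.append([0, j, j + 1])
    return verts, np.asarray(faces, dtype=np.int64)


def _ellipsoid(semi: np.ndarray, center: np.ndarray, subdivisions: int) -> tuple[np.ndarray, np.ndarray]:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(ico.vertices) * np.asarray(semi) + np.asarray(center)
    return verts, np.asarray(ico.faces, dtype=np.int64)


def _real_sph_harm_basis(dirs: np.ndarray) -> np.ndarray:
    """Real spherical harmonics up to degree 2 on unit directions, (N, 8).

    The constant (l=0) mode is excluded: a uniform radial scale is already
    covered by the parameter jitter.
    """
    x, y, z = dirs.T
    return np.column_stack(
        [
            y,
            z,
            x,  # l=1
            x * y,
            y * z,
            3.0 * z**2 - 1.0,
            x * z,
            x**2 - y**2,  # l=2
        ]
    )


def _perturb_radial(verts: np.ndarray, center: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    rel = verts - center
    r = np.linalg.norm(rel, axis=1, keepdims=True)
    dirs = rel / np.maximum(r, 1e-12)
    bump = _real_sph_harm_basis(dirs) @ coeffs
    return center + rel * (1.0 + bump)[:, None]


def _jittered(params: HeartShapeParams, rng: np.random.Generator) -> dict[str, float]:
    """Multiplicative Gaussian jitter, clipped at 2 sd, on the shape fields."""
    sd = params.jitter_sd
    fields = (
        "lv_long_axis_mm",
        "lv_short_axis_mm",
        "wall_thickness_base_mm",
        "wall_thickness_apex_mm",
        "chamber_scale_rv",
        "chamber_scale_la",
        "chamber_scale_ra",
        "valve_radius_mitral_mm",
        "valve_radius_aortic_mm",
        "valve_radius_pulmonary_mm",
    )
    draws = np.clip(rng.normal(0.0, 1.0, size=len(fields)), -2.0, 2.0)
    return {f: getattr(params, f) * (1.0 + sd * d) for f, d in zip(fields, draws)}


def generate_heart_mesh(params: HeartShapeParams) -> LabeledSurfaceMesh:
    """Generate one watertight multi-structure heart mesh.

    Deterministic: identical ``params`` (including ``seed``) give a
    bit-identical mesh, and with ``jitter_sd = 0`` the seed is irrelevant.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    p = _jittered(params, rng)

    a = p["lv_long_axis_mm"] / 2.0  # long semi-axis
    b = p["lv_short_axis_mm"] / 2.0  # short semi-axis
    wtb = p["wall_thickness_base_mm"]
    wta = p["wall_thickness_apex_mm"]
    z_cut = 0.35 * a  # endocardial base plane
    z_cut_epi = z_cut + 0.5 * wtb

    nt, np_, sub = params.lv_n_theta, params.lv_n_phi, params.sphere_subdivisions
    parts: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []

    # LV myocardium: separation of the two exact ellipsoids tapers from
    # ~wall_thickness_base at the base to exactly wall_thickness_apex on axis
    ev, ef = _truncated_ellipsoid(np.array([b, b, a]), z_cut, nt, np_)
    parts.append(("LV_MYOCARDIUM_ENDO", ev, ef, np.zeros(3)))
    pv_, pf = _truncated_ellipsoid(np.array([b + wtb, b + wtb, a + wta]), z_cut_epi, nt, np_)
    parts.append(("LV_MYOCARDIUM_EPI", pv_, pf, np.zeros(3)))

    def add_ellipsoid(name: str, semi, center) -> None:
        v, f = _ellipsoid(np.asarray(semi, dtype=float), np.asarray(center, dtype=float), sub)
        parts.append((name, v, f, np.asarray(center, dtype=float)))

    add_ellipsoid(
        "RV",
        np.array([0.45 * b, 0.60 * b, 0.62 * a]) * p["chamber_scale_rv"],
        [-(b + wtb + 0.35 * b), -0.40 * b, -0.10 * a],
    )
    add_ellipsoid(
        "LA",
        np.array([0.55 * b, 0.55 * b, 0.45 * b]) * p["chamber_scale_la"],
        [0.25 * b, -0.10 * b, z_cut + 0.35 * a],
    )
    add_ellipsoid(
        "RA",
        np.array([0.50 * b, 0.50 * b, 0.45 * b]) * p["chamber_scale_ra"],
        [-0.90 * b, 0.55 * b, z_cut + 0.30 * a],
    )
    add_ellipsoid(
        "MITRAL_VALVE",
        [p["valve_radius_mitral_mm"], p["valve_radius_mitral_mm"], 2.5],
        [0.0, 0.0, z_cut + 2.5],
    )
    add_ellipsoid(
        "AORTIC_VALVE",
        [p["valve_radius_aortic_mm"], p["valve_radius_aortic_mm"], 2.5],
        [0.55 * b, 0.35 * b, z_cut + 0.13 * a],
    )
    add_ellipsoid(
        "PULMONARY_VALVE",
        [p["valve_radius_pulmonary_mm"], p["valve_radius_pulmonary_mm"], 2.5],
        [-(b + wtb + 0.1 * b), -0.30 * b, z_cut + 0.10 * a],
    )

    # seeded low-order surface perturbation, independent per structure
    sh_sd = 0.05 * params.jitter_sd
    all_v, all_f, all_l = [], [], []
    offset = 0
    for name, v, f, center in parts:
        coeffs = np.clip(rng.normal(0.0, 1.0, size=8), -2.0, 2.0) * sh_sd
        if params.jitter_sd > 0:
            v = _perturb_radial(v, center, coeffs)
        all_v.append(v)
        all_f.append(f + offset)
        all_l.append(np.full(len(f), STRUCTURE_IDS[name], dtype=np.int64))
        offset += len(v)

    return LabeledSurfaceMesh(
        vertices=np.vstack(all_v),
        faces=np.vstack(all_f),
        face_labels=np.concatenate(all_l),
        mesh_id=f"heart-seed{params.seed}",
    )


def generate_cohort(n: int, base_params: HeartShapeParams | None = None, seed: int = 0) -> list[LabeledSurfaceMesh]:
    """Generate ``n`` hearts with independent seeded shape variation."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    base_params = base_params or HeartShapeParams()
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31)
    out = []
    for i, s in enumerate(child_seeds):
        mesh = generate_heart_mesh(dataclasses.replace(base_params, seed=int(s)))
        mesh.mesh_id = f"heart-{i:04d}"
        out.append(mesh)
    return out
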