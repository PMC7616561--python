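"""Standard-view plane extraction, slicing and voxelization of heart meshes.

This module turns a labeled heart mesh into the inputs and targets of the
reconstruction networks:

* anatomical landmarks (area-weighted surface centroids plus the LV apex,
  located by ray casting from the mitral-valve centroid to the thinnest
  point of the LV wall);
* the nine standard echocardiographic view planes, each defined either by
  three landmarks or by two landmarks and a fractional position along the
  apex–mitral long axis;
* 2D segmentation masks rasterized from plane–mesh intersection contours
  (even–odd rule, pixel-center sampling);
* 3D binary occupancy grids of the solid heart (union of all structures)
  in a unit cube with a 5% margin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .heartgen import STRUCTURE_IDS, STRUCTURES, LabeledSurfaceMesh

__all__ = [
    "VIEW_NAMES",
    "LandmarkSet",
    "ViewPlane",
    "SegmentationImage",
    "VoxelGrid",
    "compute_landmarks",
    "find_lv_apex",
    "fit_view_plane",
    "slice_to_mask",
    "extract_all_views",
    "voxelize",
    "resample_voxels_on_plane",
]


class StructureNotFoundError(KeyError):
    pass


class DegenerateGeometryError(RuntimeError):
    pass


class DegenerateLandmarksError(RuntimeError):
    pass


class EmptySliceError(RuntimeError):
    pass


class VoxelizationError(RuntimeError):
    pass


# -- the nine standard views ------------------------------------------------
# Three-landmark views map view name -> landmark names; the three parasternal
# short-axis levels are defined by the apex -> mitral-centroid axis and a
# fractional level along it.
THREE_LANDMARK_VIEWS: dict[str, tuple[str, str, str]] = {
    "Right Ventricular Inflow": ("RV_CENTROID", "RA_CENTROID", "PULMONARY_VALVE_CENTROID"),
    "Left Ventricular Parasternal Long-Axis": ("LV_APEX", "MITRAL_VALVE_CENTROID", "AORTIC_VALVE_CENTROID"),
    "Parasternal Short-Axis Aortic Valve Level": ("LA_CENTROID", "RA_CENTROID", "AORTIC_VALVE_CENTROID"),
    "Apical 4 Chamber": ("LA_CENTROID", "RA_CENTROID", "LV_APEX"),
    "Apical 5 Chamber": ("LA_CENTROID", "AORTIC_VALVE_CENTROID", "LV_APEX"),
    "Apical 2 Chamber": ("LV_APEX", "MITRAL_VALVE_CENTROID", "RV_CENTROID"),
}

# conventional anatomical levels along the apex->mitral axis (config-exposed)
SHORT_AXIS_LEVELS: dict[str, float] = {
    "Parasternal Short-Axis Mitral Valve Level": 0.85,
    "Parasternal Short-Axis Papillary Muscle Level": 0.5,
    "Parasternal Short-Axis Apex Level": 0.2,
}

VIEW_NAMES: tuple[str, ...] = (
    "Right Ventricular Inflow",
    "Left Ventricular Parasternal Long-Axis",
    "Parasternal Short-Axis Aortic Valve Level",
    "Parasternal Short-Axis Mitral Valve Level",
    "Parasternal Short-Axis Papillary Muscle Level",
    "Parasternal Short-Axis Apex Level",
    "Apical 4 Chamber",
    "Apical 5 Chamber",
    "Apical 2 Chamber",
)

# label painting order for label-mode rasters: later entries overwrite
# earlier ones, so the endocardial blood pool and the valves sit on top of
# the epicardial silhouette
_PAINT_ORDER = (
    "LV_MYOCARDIUM_EPI",
    "RV",
    "LA",
    "RA",
    "LV_MYOCARDIUM_ENDO",
    "MITRAL_VALVE",
    "AORTIC_VALVE",
    "PULMONARY_VALVE",
)


@dataclass
class LandmarkSet:
    points: dict[str, np.ndarray]  # name -> (3,) mm
    lv_apex_wall_thickness_mm: float

    REQUIRED = (
        "MITRAL_VALVE_CENTROID",
        "AORTIC_VALVE_CENTROID",
        "PULMONARY_VALVE_CENTROID",
        "LA_CENTROID",
        "RA_CENTROID",
        "LV_CENTROID",
        "RV_CENTROID",
        "LV_APEX",
    )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.points[name]

    @property
    def long_axis(self) -> np.ndarray:
        """Unit vector from LV apex toward the mitral-valve centroid."""
        v = self["MITRAL_VALVE_CENTROID"] - self["LV_APEX"]
        return v / np.linalg.norm(v)


@dataclass
class ViewPlane:
    view_name: str
    origin: np.ndarray  # (3,) mm
    normal: np.ndarray  # unit
    u_axis: np.ndarray  # unit, in-plane
    v_axis: np.ndarray  # unit, in-plane

    def project(self, points: np.ndarray) -> np.ndarray:
        rel = np.atleast_2d(points) - self.origin
        return np.column_stack([rel @ self.u_axis, rel @ self.v_axis])

    def unproject(self, uv: np.ndarray) -> np.ndarray:
        uv = np.atleast_2d(uv)
        return self.origin + uv[:, :1] * self.u_axis + uv[:, 1:2] * self.v_axis


@dataclass
class SegmentationImage:
    pixels: np.ndarray  # (H, W) uint8; 0 background
    pixel_spacing_mm: tuple[float, float]  # (du, dv)
    view_name: str
    mesh_id: str
    plane: ViewPlane | None = None
    mode: str = "binary"

    def save(self, path: str | Path) -> None:
        import imageio.v3 as iio

        path = Path(path)
        img = self.pixels * 255 if self.mode == "binary" else self.pixels
        iio.imwrite(path, img.astype(np.uint8))
        meta = {
            "view_name": self.view_name,
            "mesh_id": self.mesh_id,
            "pixel_spacing_mm": list(self.pixel_spacing_mm),
            "mode": self.mode,
        }
        if self.plane is not None:
            meta["plane"] = {
                "origin": self.plane.origin.tolist(),
                "normal": self.plane.normal.tolist(),
                "u_axis": self.plane.u_axis.tolist(),
                "v_axis": self.plane.v_axis.tolist(),
            }
        path.with_suffix(".json").write_text(json.dumps(meta))


@dataclass
class VoxelGrid:
    values: np.ndarray  # (D, D, D), axis order (x, y, z)
    origin: np.ndarray  # (3,) mm corner of voxel (0,0,0)
    spacing_mm: float
    binary: bool = True

    SUPPORTED_DIMS = (16, 32, 64)

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path, self.values)
        meta = {"origin": self.origin.tolist(), "spacing_mm": self.spacing_mm, "binary": self.binary}
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "VoxelGrid":
        path = Path(path)
        values = np.load(path if path.suffix == ".npy" else path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(values, np.asarray(meta["origin"]), meta["spacing_mm"], meta["binary"])


# -- ray casting ------------------------------------------------------------

def ray_mesh_intersections(
    origin: np.ndarray,
    directions: np.ndarray,
    triangles: np.ndarray,
    eps: float = 1e-9,
    chunk: int = 256,
) -> list[np.ndarray]:
    """Möller–Trumbore intersection of rays from one origin with a triangle soup.

    Returns, per ray, the sorted positive distances (deduplicated within
    1e-9) at which the ray crosses the surface.  ``triangles`` is (T, 3, 3).
    """
    origin = np.asarray(origin, dtype=np.float64)
    directions = np.asarray(directions, dtype=np.float64)
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    tvec = origin - v0  # (T, 3)
    q = np.cross(tvec, e1)  # (T, 3)
    out: list[np.ndarray] = []
    for lo in range(0, len(directions), chunk):
        d = directions[lo : lo + chunk]  # (R, 3)
        p = np.cross(d[:, None, :], e2[None, :, :])  # (R, T, 3)
        det = np.einsum("rtk,tk->rt", p, e1)
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        u = np.einsum("rtk,tk->rt", p, tvec) * inv
        v = (d @ q.T) * inv
        t = np.einsum("tk,tk->t", e2, q)[None, :] * inv
        hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps) & (t > 1e-7)
        for r in range(len(d)):
            ts = np.sort(t[r, hit[r]])
            if len(ts) > 1:
                ts = ts[np.concatenate([[True], np.diff(ts) > 1e-9])]
            out.append(ts)
    return out


def find_lv_apex(mesh: LabeledSurfaceMesh, source: np.ndarray) -> tuple[np.ndarray, float]:
    """Locate the LV apex as the thinnest crossing of the LV wall.

    Rays are cast from ``source`` (the mitral-valve centroid) toward every
    LV face center; along each ray the first endocardial crossing that is
    immediately followed by an epicardial crossing bounds one traverse of
    the myocardial wall, and the shortest such traverse is returned as
    (midpoint, thickness).  Ties within 1e-9 mm resolve to the smallest
    face index.
    """
    source = np.asarray(source, dtype=np.float64)
    labels = mesh.face_labels
    endo_id = STRUCTURE_IDS["LV_MYOCARDIUM_ENDO"]
    epi_id = STRUCTURE_IDS["LV_MYOCARDIUM_EPI"]
    lv_mask = (labels == endo_id) | (labels == epi_id)
    if not lv_mask.any():
        raise StructureNotFoundError("LV_MYOCARDIUM_ENDO/LV_MYOCARDIUM_EPI")
    faces = mesh.faces[lv_mask]
    tris = mesh.vertices[faces]  # (T, 3, 3)
    is_epi = labels[lv_mask] == epi_id

    centers = tris.mean(axis=1)
    dirs = centers - source
    norms = np.linalg.norm(dirs, axis=1)
    dirs = dirs / norms[:, None]

    best = (np.inf, -1, None)  # thickness, ray index, midpoint
    v0 = tris[:, 0]
    e1 = tris[:, 1] - v0
    e2 = tris[:, 2] - v0
    tvec = source - v0
    q = np.cross(tvec, e1)
    t_e2q = np.einsum("tk,tk->t", e2, q)
    eps = 1e-9
    chunk = 256
    for lo in range(0, len(dirs), chunk):
        d = dirs[lo : lo + chunk]
        p = np.cross(d[:, None, :], e2[None, :, :])
        det = np.einsum("rtk,tk->rt", p, e1)
        ok = np.abs(det) > eps
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        u = np.einsum("rtk,tk->rt", p, tvec) * inv
        v = (d @ q.T) * inv
        t = t_e2q[None, :] * inv
        hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1.0 + eps) & (t > 1e-7)
        for r in range(len(d)):
            idx = np.flatnonzero(hit[r])
            if len(idx) < 2:
                continue
            order = np.argsort(t[r, idx], kind="stable")
            ts = t[r, idx][order]
            surf_epi = is_epi[idx][order]
            keep = np.concatenate([[True], np.diff(ts) > 1e-9])
            ts, surf_epi = ts[keep], surf_epi[keep]
            # first endo crossing immediately followed by an epi crossing
            for k in range(len(ts) - 1):
                if not surf_epi[k] and surf_epi[k + 1]:
                    thick = ts[k + 1] - ts[k]
                    mid = source + dirs[lo + r] * (0.5 * (ts[k] + ts[k + 1]))
                    if thick < best[0] - 1e-9:
                        best = (thick, lo + r, mid)
                    break
    if best[1] < 0:
        raise DegenerateGeometryError("no ray crossed both the endo- and epicardial wall")
    return best[2], float(best[0])


# -- landmarks --------------------------------------------------------------

def _surface_centroid(tm: trimesh.Trimesh) -> np.ndarray:
    areas = tm.area_faces
    centers = tm.triangles_center
    return (centers * areas[:, None]).sum(axis=0) / areas.sum()


def compute_landmarks(mesh: LabeledSurfaceMesh) -> LandmarkSet:
    """Area-weighted surface centroids of every structure plus the LV apex."""
    present = set(mesh.structure_names())
    for s in STRUCTURES:
        if s not in present:
            raise StructureNotFoundError(s)
    cent = {s: _surface_centroid(mesh.structure_mesh(s)) for s in STRUCTURES}
    lv_faces = (mesh.face_labels == STRUCTURE_IDS["LV_MYOCARDIUM_EPI"]) | (
        mesh.face_labels == STRUCTURE_IDS["LV_MYOCARDIUM_ENDO"]
    )
    lv_tm = trimesh.Trimesh(mesh.vertices, mesh.faces[lv_faces], process=False)
    points = {
        "MITRAL_VALVE_CENTROID": cent["MITRAL_VALVE"],
        "AORTIC_VALVE_CENTROID": cent["AORTIC_VALVE"],
        "PULMONARY_VALVE_CENTROID": cent["PULMONARY_VALVE"],
        "LA_CENTROID": cent["LA"],
        "RA_CENTROID": cent["RA"],
        "LV_CENTROID": _surface_centroid(lv_tm),
        "RV_CENTROID": cent["RV"],
    }
    apex, thickness = find_lv_apex(mesh, points["MITRAL_VALVE_CENTROID"])
    points["LV_APEX"] = apex
    return LandmarkSet(points=points, lv_apex_wall_thickness_mm=thickness)


# -- view planes ------------------------------------------------------------

def _in_plane_axes(normal: np.ndarray, long_axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic in-plane frame: u is the projected long axis (with
    fixed fallbacks when the plane is a short-axis plane), v = n x u."""
    candidates = [long_axis, np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])]
    for c in candidates:
        proj = c - (c @ normal) * normal
        n = np.linalg.norm(proj)
        if n > 1e-8:
            u = proj / n
            return u, np.cross(normal, u)
    raise DegenerateGeometryError("cannot construct in-plane axes")


def fit_view_plane(landmarks: LandmarkSet, view_name: str) -> ViewPlane:
    """Fit one of the nine standard view planes to the landmark set."""
    if view_name in THREE_LANDMARK_VIEWS:
        names = THREE_LANDMARK_VIEWS[view_name]
        p1, p2, p3 = (landmarks[n] for n in names)
        cr = np.cross(p2 - p1, p3 - p1)
        area = 0.5 * np.linalg.norm(cr)
        if area < 1e-9:
            raise DegenerateLandmarksError(f"collinear landmarks for view {view_name!r}")
        normal = cr / np.linalg.norm(cr)
        origin = (p1 + p2 + p3) / 3.0
    elif view_name in SHORT_AXIS_LEVELS:
        f = SHORT_AXIS_LEVELS[view_name]
        apex = landmarks["LV_APEX"]
        mv = landmarks["MITRAL_VALVE_CENTROID"]
        axis = mv - apex
        normal = axis / np.linalg.norm(axis)
        origin = apex + f * axis
    else:
        raise KeyError(f"unknown view name: {view_name!r}")
    u, v = _in_plane_axes(normal, landmarks.long_axis)
    return ViewPlane(view_name=view_name, origin=origin, normal=normal, u_axis=u, v_axis=v)


# -- slicing & rasterization ------------------------------------------------

def _plane_segments_uv(tm: trimesh.Trimesh, plane: ViewPlane) -> np.ndarray:
    """Plane–surface intersection as 2D segments (S, 2, 2) in (u, v)."""
    seg3 = trimesh.intersections.mesh_plane(tm, plane_normal=plane.normal, plane_origin=plane.origin)
    if len(seg3) == 0:
        return np.empty((0, 2, 2))
    flat = plane.project(seg3.reshape(-1, 3)).reshape(-1, 2, 2)
    return flat


def _even_odd_fill(segments: np.ndarray, px_u: np.ndarray, px_v: np.ndarray, chunk: int = 8192) -> np.ndarray:
    """Even–odd (crossing-parity) membership of pixel centers in a segment soup."""
    if len(segments) == 0:
        return np.zeros(px_u.shape, dtype=bool)
    u1, v1 = segments[:, 0, 0], segments[:, 0, 1]
    u2, v2 = segments[:, 1, 0], segments[:, 1, 1]
    du = u2 - u1
    dv = v2 - v1
    flat_u, flat_v = px_u.ravel(), px_v.ravel()
    inside = np.zeros(flat_u.shape, dtype=bool)
    for lo in range(0, len(flat_u), chunk):
        pu = flat_u[lo : lo + chunk, None]
        pv = flat_v[lo : lo + chunk, None]
        straddle = (v1[None, :] > pv) != (v2[None, :] > pv)
        with np.errstate(divide="ignore", invalid="ignore"):
            ucross = u1[None, :] + (pv - v1[None, :]) * du[None, :] / np.where(dv == 0, 1.0, dv)[None, :]
        crossings = (straddle & (pu < ucross)).sum(axis=1)
        inside[lo : lo + chunk] = (crossings % 2) == 1
    return inside.reshape(px_u.shape)


def default_fov_mm(mesh: LabeledSurfaceMesh, margin: float = 1.2) -> float:
    """Field of view: 1.2x the mesh bounding-sphere diameter (box-center sphere)."""
    center = mesh.bounds.mean(axis=0)
    radius = np.linalg.norm(mesh.vertices - center, axis=1).max()
    return float(2.0 * radius * margin)


def slice_to_mask(
    mesh: LabeledSurfaceMesh,
    plane: ViewPlane,
    image_size: int = 128,
    fov_mm: float | None = None,
    mode: str = "binary",
) -> SegmentationImage:
    """Rasterize the plane–mesh intersection into a segmentation image.

    A pixel is filled iff its center lies inside a structure's intersection
    contour by the even–odd rule.  Binary mode is the union of tissue
    regions, with the two LV surfaces filled jointly so the blood pool
    between endo- and epicardium rasterizes as an annulus; label mode paints
    structure ids in a fixed anatomical order (innermost last).  Pixel (row, col) = (v, u); centers sit at half-integer offsets
    on a grid of ``image_size`` px covering ``fov_mm`` centered on the
    plane origin.
    """
    if mode not in ("binary", "label"):
        raise ValueError(f"mode must be 'binary' or 'label', got {mode!r}")
    if fov_mm is None:
        fov_mm = default_fov_mm(mesh)
    n = int(image_size)
    if n < 2:
        raise ValueError("image_size must be >= 2")
    spacing = fov_mm / n
    coords = (np.arange(n) + 0.5) * spacing - fov_mm / 2.0
    px_u, px_v = np.meshgrid(coords, coords)  # row -> v, col -> u

    per_structure = {}
    total_segments = 0
    for name in _PAINT_ORDER:
        try:
            tm = mesh.structure_mesh(name)
        except KeyError:
            continue
        segs = _plane_segments_uv(tm, plane)
        total_segments += len(segs)
        per_structure[name] = segs
    if total_segments == 0:
        raise EmptySliceError(f"plane {plane.view_name!r} does not intersect the mesh")

    pixels = np.zeros((n, n), dtype=np.uint8)
    if mode == "binary":
        # the two LV surfaces jointly bound the myocardial tissue: their
        # contours are filled together by the even-odd rule (annulus, blood
        # pool excluded); every other closed structure fills solid
        groups: list[np.ndarray] = []
        lv = [per_structure.get(k) for k in ("LV_MYOCARDIUM_EPI", "LV_MYOCARDIUM_ENDO")]
        lv = [s for s in lv if s is not None and len(s)]
        if lv:
            groups.append(np.concatenate(lv))
        for name in _PAINT_ORDER:
            if name in ("LV_MYOCARDIUM_EPI", "LV_MYOCARDIUM_ENDO"):
                continue
            segs = per_structure.get(name)
            if segs is not None and len(segs):
                groups.append(segs)
        for segs in groups:
            pixels[_even_odd_fill(segs, px_u, px_v)] = 1
    else:
        for name in _PAINT_ORDER:
            segs = per_structure.get(name)
            if segs is None or len(segs) == 0:
                continue
            region = _even_odd_fill(segs, px_u, px_v)
            pixels[region] = STRUCTURE_IDS[name]
    if not pixels.any():
        raise EmptySliceError(f"plane {plane.view_name!r} intersection rasterized to an empty image")
    return SegmentationImage(
        pixels=pixels,
        pixel_spacing_mm=(spacing, spacing),
        view_name=plane.view_name,
        mesh_id=mesh.mesh_id,
        plane=plane,
        mode=mode,
    )


def extract_all_views(
    mesh: LabeledSurfaceMesh,
    image_size: int = 128,
    fov_mm: float | None = None,
    mode: str = "binary",
    landmarks: LandmarkSet | None = None,
) -> dict[str, SegmentationImage]:
    """All nine standard views of one mesh, keyed by view name."""
    if landmarks is None:
        landmarks = compute_landmarks(mesh)
    if fov_mm is None:
        fov_mm = default_fov_mm(mesh)
    out: dict[str, SegmentationImage] = {}
    for name in VIEW_NAMES:
        try:
            plane = fit_view_plane(landmarks, name)
            out[name] = slice_to_mask(mesh, plane, image_size=image_size, fov_mm=fov_mm, mode=mode)
        except Exception as exc:
            raise type(exc)(f"view {name!r}: {exc}") from exc
    return out


# -- voxelization -----------------------------------------------------------

# tiny irrational sampling offsets guard the column parity against exact
# edge/vertex hits on the axis-aligned construction
_NUDGE = (7.3e-8, 3.9e-8)


def _column_parity_occupancy(triangles: np.ndarray, dim: int) -> np.ndarray:
    """Solid occupancy of one closed surface on a dim^3 unit-cube grid.

    Casts the +z column through every (x, y) voxel-center position and
    accumulates surface-crossing parity below each voxel center.
    """
    d = dim
    centers = (np.arange(d) + 0.5) / d
    delta = np.zeros((d, d, d + 1), dtype=np.int64)
    v0, v1, v2 = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    for i in range(len(triangles)):
        a, b, c = v0[i], v1[i], v2[i]
        e1 = b - a
        e2 = c - a
        det = e1[0] * e2[1] - e1[1] * e2[0]
        if abs(det) < 1e-15:
            continue  # vertical triangle: grazes columns only
        xs = np.array([a[0], b[0], c[0]]) - _NUDGE[0]
        ys = np.array([a[1], b[1], c[1]]) - _NUDGE[1]
        ix0 = max(int(np.ceil(xs.min() * d - 0.5)), 0)
        ix1 = min(int(np.floor(xs.max() * d - 0.5)), d - 1)
        iy0 = max(int(np.ceil(ys.min() * d - 0.5)), 0)
        iy1 = min(int(np.floor(ys.max() * d - 0.5)), d - 1)
        if ix1 < ix0 or iy1 < iy0:
            continue
        gx = centers[ix0 : ix1 + 1] + _NUDGE[0]
        gy = centers[iy0 : iy1 + 1] + _NUDGE[1]
        px, py = np.meshgrid(gx, gy, indexing="ij")
        rx = px - a[0]
        ry = py - a[1]
        s = (rx * e2[1] - ry * e2[0]) / det
        t = (e1[0] * ry - e1[1] * rx) / det
        inside = (s >= 0.0) & (t >= 0.0) & (s + t <= 1.0)
        if not inside.any():
            continue
        z = a[2] + s * e1[2] + t * e2[2]
        # number of voxel centers strictly below the crossing
        m = np.clip(np.ceil(z * d - 0.5).astype(np.int64), 0, d)
        ii, jj = np.nonzero(inside)
        np.add.at(delta, (ii + ix0, jj + iy0, m[inside]), 1)
    below = np.cumsum(delta, axis=2)[:, :, :d]
    return (below % 2) == 1


def voxelize(mesh: LabeledSurfaceMesh, dim: int = 64) -> VoxelGrid:
    """Binary occupancy of the solid heart (union of all structures).

    The mesh is isotropically scaled and centered into the unit cube with a
    5% margin per side; a voxel is occupied iff its center at
    ``(i + 0.5)/dim`` per axis lies inside any structure's closed surface.
    """
    if dim not in VoxelGrid.SUPPORTED_DIMS:
        raise ValueError(f"dim must be one of {VoxelGrid.SUPPORTED_DIMS}")
    for name in mesh.structure_names():
        tm = mesh.structure_mesh(name)
        if not tm.is_watertight:
            raise VoxelizationError(f"structure {name!r} is not watertight")
    lo, hi = mesh.bounds
    center = (lo + hi) / 2.0
    extent = float((hi - lo).max())
    scale = 0.9 / extent
    occ = np.zeros((dim, dim, dim), dtype=bool)
    for name in mesh.structure_names():
        tm = mesh.structure_mesh(name)
        tris = (np.asarray(tm.triangles) - center) * scale + 0.5
        occ |= _column_parity_occupancy(tris, dim)
    spacing = (extent / 0.9) / dim
    origin = center - 0.5 * (extent / 0.9)
    return VoxelGrid(values=occ.astype(np.uint8), origin=origin, spacing_mm=spacing, binary=True)


def resample_voxels_on_plane(grid: VoxelGrid, plane: ViewPlane, image_size: int, fov_mm: float) -> np.ndarray:
    """Nearest-voxel resampling of an occupancy grid along a view plane."""
    n = image_size
    coords = (np.arange(n) + 0.5) * (fov_mm / n) - fov_mm / 2.0
    px_u, px_v = np.meshgrid(coords, coords)
    world = (
        plane.origin[None, :]
        + px_u.ravel()[:, None] * plane.u_axis
        + px_v.ravel()[:, None] * plane.v_axis
    )
    idx = np.floor((world - grid.origin) / grid.spacing_mm).astype(np.int64)
    ok = np.all((idx >= 0) & (idx < grid.dim), axis=1)
    out = np.zeros(n * n, dtype=np.uint8)
    out[ok] = grid.values[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    return out.reshape(n, n)
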