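"""Independent test oracles, deliberately implemented differently from the
package code paths they check."""

import numpy as np


def naive_ray_hits(origin, direction, triangles, eps=1e-12):
    """Ray-triangle intersection by plane hit + same-side barycentric test
    (a different formulation from the package's Möller–Trumbore caster).

    Returns sorted positive distances plus the triangle indices, ordered by
    distance.
    """
    origin = np.asarray(origin, float)
    d = np.asarray(direction, float)
    v0, v1, v2 = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    n = np.cross(v1 - v0, v2 - v0)
    denom = n @ d
    ok = np.abs(denom) > eps
    t = np.where(ok, ((v0 - origin) * n).sum(axis=1) / np.where(ok, denom, 1.0), -1.0)
    ok &= t > 1e-7
    p = origin + t[:, None] * d
    # same-side test against each edge
    for a, b in ((v0, v1), (v1, v2), (v2, v0)):
        c1 = np.cross(b - a, p - a)
        ok &= (c1 * n).sum(axis=1) >= -1e-9 * np.linalg.norm(n, axis=1)
    idx = np.flatnonzero(ok)
    order = np.argsort(t[idx], kind="stable")
    return t[idx][order], idx[order]


def fibonacci_sphere(n):
    """n nearly uniform unit directions."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def brute_force_min_wall(mesh, source, n_dirs=10_000):
    """Exhaustive direction sweep for the thinnest endo->epi wall traverse.

    Uses the naive intersector on every direction of a Fibonacci sphere and
    the same consecutive endo-then-epi pairing rule as the landmark search.
    Returns (min thickness, direction).
    """
    from echo2vox.heartgen import STRUCTURE_IDS

    labels = mesh.face_labels
    lv = (labels == STRUCTURE_IDS["LV_MYOCARDIUM_ENDO"]) | (labels == STRUCTURE_IDS["LV_MYOCARDIUM_EPI"])
    tris = mesh.vertices[mesh.faces[lv]]
    is_epi = labels[lv] == STRUCTURE_IDS["LV_MYOCARDIUM_EPI"]
    best = (np.inf, None)
    for d in fibonacci_sphere(n_dirs):
        ts, idx = naive_ray_hits(source, d, tris)
        if len(ts) < 2:
            continue
        keep = np.concatenate([[True], np.diff(ts) > 1e-9])
        ts, epi = ts[keep], is_epi[idx][keep]
        for k in range(len(ts) - 1):
            if not epi[k] and epi[k + 1]:
                if ts[k + 1] - ts[k] < best[0]:
                    best = (ts[k + 1] - ts[k], d)
                break
    return best


def winding_number_inside(points, triangles):
    """Generalized winding number point-in-mesh test (solid-angle sum),
    independent of the package's column-parity voxelizer."""
    points = np.asarray(points, float)
    out = np.zeros(len(points))
    a = triangles[:, 0][None] - points[:, None]
    b = triangles[:, 1][None] - points[:, None]
    c = triangles[:, 2][None] - points[:, None]
    la = np.linalg.norm(a, axis=2)
    lb = np.linalg.norm(b, axis=2)
    lc = np.linalg.norm(c, axis=2)
    num = np.einsum("ptk,ptk->pt", a, np.cross(b, c))
    den = la * lb * lc + np.einsum("ptk,ptk->pt", a, b) * lc + np.einsum("ptk,ptk->pt", b, c) * la + np.einsum("ptk,ptk->pt", c, a) * lb
    out = np.arctan2(num, den).sum(axis=1) / (2.0 * np.pi)
    return np.abs(out) > 0.5


def set_iou(pred_bin, gt_bin):
    """IoU via explicit coordinate-tuple sets."""
    p = {tuple(c) for c in np.argwhere(pred_bin)}
    g = {tuple(c) for c in np.argwhere(gt_bin)}
    union = p | g
    if not union:
        return 1.0
    return len(p & g) / len(union)
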