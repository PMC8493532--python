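"""Apical view planes and 2D label-slice rasterization.

The apical four-chamber (A4C) plane is defined by three anatomical landmarks:
the LV apex, the mitral-valve center and the aortic-valve center.  The apical
two-chamber (A2C) plane is obtained by rotating the A4C plane 70 degrees
counter-clockwise (viewed from the apex toward the base) about the LV long
axis, which lies in both planes.  Controlled random rotations about the LV
long and short axes emulate foreshortened / off-plane acquisitions.

Rasterization labels each pixel center by the tissue compartment containing
the corresponding 3D point.  For watertight compartments this containment
test restricted to the plane is evaluated exactly via the compartment's
plane cross-section polygons (even-odd rule), which is orders of magnitude
faster than general ray casting and agrees with it by construction.
Painting follows the precedence blood pools > myocardium > valve disk, so a
pixel inside the LV cavity is never labeled myocardium.

Raster convention: row 0 is the top of the image, on the apex side; the
in-plane axis v points from the apex toward the mitral valve (down the
image), u to the right; pixel centers sit at (index + 0.5) * spacing.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import trimesh
from PIL import Image
from skimage.measure import points_in_poly

from .errors import GeometryError, ValidationError
from .phantoms import PAINT_ORDER, LabeledMesh

__all__ = [
    "SlicePlane",
    "LabelSlice",
    "define_a4c_plane",
    "define_a2c_plane",
    "perturb_plane",
    "slice_mesh",
    "save_slice",
    "load_slice",
]

#: Margin above the apex at the top of the raster, as a fraction of height.
APEX_MARGIN_FRAC = 0.06


@dataclasses.dataclass
class SlicePlane:
    """Oriented cut plane with an orthonormal in-plane frame {u, v, normal}."""

    origin: np.ndarray
    normal: np.ndarray
    in_plane_u: np.ndarray
    in_plane_v: np.ndarray
    view: str = "a4c"
    perturbation: tuple[float, ...] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        M = np.stack([self.in_plane_u, self.in_plane_v, self.normal])
        if not np.allclose(M @ M.T, np.eye(3), atol=1e-9):
            raise ValidationError("plane frame {u, v, normal} is not orthonormal")

    def to_world(self, uu: np.ndarray, vv: np.ndarray) -> np.ndarray:
        """Map in-plane mm coordinates to 3D points."""
        return (
            self.origin
            + np.multiply.outer(uu, self.in_plane_u)
            + np.multiply.outer(vv, self.in_plane_v)
        )


@dataclasses.dataclass
class LabelSlice:
    """2D integer tissue-label raster on a sampled plane."""

    raster: np.ndarray          # (H, W) int
    pixel_spacing: float        # mm / pixel
    plane: SlicePlane
    model_id: str
    legend: dict[str, int]


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, dtype=float)
    return Rotation.from_rotvec(axis / np.linalg.norm(axis) * np.deg2rad(angle_deg)).as_matrix()


def define_a4c_plane(mesh: LabeledMesh) -> SlicePlane:
    """Plane through apex, mitral-valve center and aortic-valve center.

    v points apex -> mitral (down the image); the normal sign is fixed so the
    aortic valve lies on the +u side, making the frame deterministic.
    """
    p1 = mesh.landmarks["apex"]
    p2 = mesh.landmarks["mitral_valve_center"]
    p3 = mesh.landmarks["aortic_valve_center"]
    a, b = p2 - p1, p3 - p1
    n = np.cross(a, b)
    if np.linalg.norm(n) < 1e-9 * np.linalg.norm(a) * np.linalg.norm(b):
        raise GeometryError("landmarks are collinear; A4C plane undefined")
    n = n / np.linalg.norm(n)
    v = a / np.linalg.norm(a)
    u = np.cross(v, n)
    if np.dot(u, b) < 0:
        n, u = -n, -u
    return SlicePlane(origin=p1.copy(), normal=n, in_plane_u=u, in_plane_v=v, view="a4c")


def define_a2c_plane(mesh: LabeledMesh, rotation_deg: float = 70.0) -> SlicePlane:
    """A4C plane rotated about the LV long axis through the apex.

    Positive angles are counter-clockwise when viewed from the apex toward
    the base (right-handed about the apex->base long-axis direction).
    """
    a4c = define_a4c_plane(mesh)
    d = mesh.landmarks["lv_long_axis_direction"]
    R = _rotation_about(d, rotation_deg)
    apex = mesh.landmarks["apex"]
    return SlicePlane(
        origin=apex + R @ (a4c.origin - apex),
        normal=R @ a4c.normal,
        in_plane_u=R @ a4c.in_plane_u,
        in_plane_v=R @ a4c.in_plane_v,
        view="a2c",
    )


def perturb_plane(
    plane: SlicePlane,
    mesh: LabeledMesh,
    seed: int,
    ranges: tuple[float, float] = (10.0, 5.0),
) -> SlicePlane:
    """Random foreshortening: rotations about the LV long and short axes.

    One angle is drawn uniformly in +/-ranges[0] about the long axis and one
    in +/-ranges[1] about each of the two orthogonal short axes, all through
    the LV blood-pool centroid.  (0, 0) ranges leave the plane untouched.
    """
    if ranges[0] < 0 or ranges[1] < 0:
        raise ValidationError("perturbation ranges must be non-negative")
    rng = np.random.default_rng(seed)
    a_long = rng.uniform(-ranges[0], ranges[0]) if ranges[0] > 0 else 0.0
    a_short1 = rng.uniform(-ranges[1], ranges[1]) if ranges[1] > 0 else 0.0
    a_short2 = rng.uniform(-ranges[1], ranges[1]) if ranges[1] > 0 else 0.0
    d = mesh.landmarks["lv_long_axis_direction"]
    # the two short axes: in-plane u and the plane normal (both orthogonal
    # to the long axis by construction of the apical frame)
    R = (
        _rotation_about(plane.normal, a_short2)
        @ _rotation_about(plane.in_plane_u, a_short1)
        @ _rotation_about(d, a_long)
    )
    lv = mesh.compartment_mesh(mesh.legend["lv_blood_pool"])
    c = lv.vertices.mean(axis=0)
    return SlicePlane(
        origin=c + R @ (plane.origin - c),
        normal=R @ plane.normal,
        in_plane_u=R @ plane.in_plane_u,
        in_plane_v=R @ plane.in_plane_v,
        view=plane.view,
        perturbation=(a_long, a_short1, a_short2),
    )


# ---------------------------------------------------------------------------
# cross-section rasterization
# ---------------------------------------------------------------------------

def _section_polygons(tm: trimesh.Trimesh, plane: SlicePlane) -> list[np.ndarray]:
    """Closed 2D polygons (in-plane mm coords) of the mesh-plane section."""
    segs = trimesh.intersections.mesh_plane(
        tm, plane_normal=plane.normal, plane_origin=plane.origin
    )
    if len(segs) == 0:
        return []
    B = np.stack([plane.in_plane_u, plane.in_plane_v])  # (2, 3)
    q = (segs - plane.origin) @ B.T  # (m, 2, 2)
    # drop degenerate segments and exact duplicates
    lengths = np.linalg.norm(q[:, 0] - q[:, 1], axis=1)
    q = q[lengths > 1e-9]
    key = np.round(q, 6)
    key = np.array([tuple(sorted(map(tuple, k))) for k in key], dtype=float)
    if len(key):
        _, idx = np.unique(key.reshape(len(key), -1), axis=0, return_index=True)
        q = q[np.sort(idx)]
    # chain segments into closed loops by matching rounded endpoints
    def node(p):
        return (round(p[0], 5), round(p[1], 5))

    adj: dict[tuple, list[int]] = {}
    for i, s in enumerate(q):
        adj.setdefault(node(s[0]), []).append(i)
        adj.setdefault(node(s[1]), []).append(i)
    unused = set(range(len(q)))
    polys = []
    while unused:
        i = unused.pop()
        chain = [q[i][0], q[i][1]]
        while True:
            end = node(chain[-1])
            nxt = next((j for j in adj.get(end, []) if j in unused), None)
            if nxt is None:
                break
            unused.discard(nxt)
            s = q[nxt]
            chain.append(s[1] if node(s[0]) == end else s[0])
            if node(chain[-1]) == node(chain[0]):
                break
        poly = np.asarray(chain)
        if len(poly) >= 4:  # at least a triangle plus closure
            polys.append(poly)
    return polys


def _pixel_grid_mm(H: int, W: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    margin = APEX_MARGIN_FRAC * H * spacing
    uu = (np.arange(W) + 0.5 - W / 2) * spacing
    vv = (np.arange(H) + 0.5) * spacing - margin
    return uu, vv


def _polygons_mask(polys: list[np.ndarray], H: int, W: int, spacing: float) -> np.ndarray:
    """Even-odd containment of pixel centers in a set of polygons."""
    mask = np.zeros((H, W), dtype=bool)
    if not polys:
        return mask
    uu, vv = _pixel_grid_mm(H, W, spacing)
    for poly in polys:
        # crop to the polygon bounding box to keep the test cheap
        j0 = np.searchsorted(uu, poly[:, 0].min()) 
        j1 = np.searchsorted(uu, poly[:, 0].max())
        i0 = np.searchsorted(vv, poly[:, 1].min())
        i1 = np.searchsorted(vv, poly[:, 1].max())
        if j0 >= j1 or i0 >= i1:
            continue
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        pts = np.column_stack([uu[jj.ravel()], vv[ii.ravel()]])
        inside = points_in_poly(pts, poly)
        mask[ii.ravel()[inside], jj.ravel()[inside]] ^= True
    return mask


def slice_mesh(
    mesh: LabeledMesh,
    plane: SlicePlane,
    H: int = 256,
    W: int = 256,
    pixel_spacing: float = 0.6,
) -> LabelSlice:
    """Rasterize the tissue cross-section of ``mesh`` on ``plane``.

    Emits a warning and an all-background raster if the plane misses the
    mesh entirely.
    """
    if H <= 0 or W <= 0 or pixel_spacing <= 0:
        raise ValidationError("raster dimensions and pixel spacing must be positive")
    lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
    corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])])
    side = (corners - plane.origin) @ plane.normal
    raster = np.zeros((H, W), dtype=np.int64)
    if side.min() > 0 or side.max() < 0:
        warnings.warn(f"plane misses mesh bounding box for {mesh.model_id}; empty slice")
        return LabelSlice(raster, pixel_spacing, plane, mesh.model_id, dict(mesh.legend))
    present = set(mesh.compartment_codes())
    for code in PAINT_ORDER:
        if code not in present:
            continue
        polys = _section_polygons(mesh.compartment_mesh(code), plane)
        m = _polygons_mask(polys, H, W, pixel_spacing)
        raster[m] = code
    return LabelSlice(raster, pixel_spacing, plane, mesh.model_id, dict(mesh.legend))


# ---------------------------------------------------------------------------
# serialization: indexed PNG + JSON sidecar with plane provenance
# ---------------------------------------------------------------------------

_PALETTE = np.array(
    [
        [0, 0, 0],
        [140, 20, 20],
        [220, 160, 60],
        [60, 120, 220],
        [60, 180, 90],
        [160, 80, 200],
        [220, 60, 140],
        [200, 200, 200],
    ],
    dtype=np.uint8,
)


def save_slice(sl: LabelSlice, out_dir: str | Path, stem: str | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{sl.model_id}_{sl.plane.view}"
    img = Image.fromarray(sl.raster.astype(np.uint8), mode="P")
    pal = np.zeros((256, 3), dtype=np.uint8)
    pal[: len(_PALETTE)] = _PALETTE
    img.putpalette(pal.ravel().tolist())
    png_path = out_dir / f"{stem}.png"
    img.save(png_path)
    sidecar = {
        "model_id": sl.model_id,
        "pixel_spacing": sl.pixel_spacing,
        "legend": sl.legend,
        "plane": {
            "origin": sl.plane.origin.tolist(),
            "normal": sl.plane.normal.tolist(),
            "in_plane_u": sl.plane.in_plane_u.tolist(),
            "in_plane_v": sl.plane.in_plane_v.tolist(),
            "view": sl.plane.view,
            "perturbation": list(sl.plane.perturbation),
        },
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar))
    return png_path


def load_slice(png_path: str | Path) -> LabelSlice:
    png_path = Path(png_path)
    raster = np.asarray(Image.open(png_path), dtype=np.int64)
    sc = json.loads(png_path.with_suffix(".json").read_text())
    pl = sc["plane"]
    plane = SlicePlane(
        origin=np.array(pl["origin"]),
        normal=np.array(pl["normal"]),
        in_plane_u=np.array(pl["in_plane_u"]),
        in_plane_v=np.array(pl["in_plane_v"]),
        view=pl["view"],
        perturbation=tuple(pl["perturbation"]),
    )
    return LabelSlice(raster, float(sc["pixel_spacing"]), plane, sc["model_id"], {k: int(v) for k, v in sc["legend"].items()})
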