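"""Parametric labeled 3D heart phantoms.

Generates a cohort of corresponded, tissue-labeled surface meshes of the left
and right heart with named anatomical landmarks.  Each phantom is an assembly
of closed analytic compartments -- half-ellipsoid chambers, a concentric
myocardial shell, a tubular aorta and a flat mitral-valve disk -- built on a
fixed template topology so that every phantom in a cohort shares the same
vertex count and face connectivity (correspondence by construction).  The
cohort stands in for a set of CT-derived anatomical models and feeds the
statistical shape model, view slicing and pseudo-ultrasound rendering stages.

Coordinates are millimetres.  The LV long axis runs from the apex (origin,
before rigid jitter) toward the mitral-valve plane at z = lv_long_axis.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import trimesh

from .errors import ValidationError

#: Tissue label legend.  0 is reserved for background; the valve is modeled
#: as a flat disk, mirroring how anatomical heart models represent it.
LEGEND: dict[str, int] = {
    "background": 0,
    "lv_blood_pool": 1,
    "lv_myocardium": 2,
    "left_atrium": 3,
    "right_ventricle": 4,
    "right_atrium": 5,
    "aorta": 6,
    "valve_disk": 7,
}

#: Painting precedence for rasterization, least to most dominant:
#: myocardium (the solid epicardial compartment) first, then the valve disk,
#: then blood pools -- so no pixel inside a blood pool is ever labeled
#: myocardium or valve.
PAINT_ORDER: tuple[int, ...] = (2, 7, 3, 5, 4, 6, 1)

# Template discretization (fixed: correspondence depends on it).
_N_RINGS = 10
_N_SEG = 24
_N_AX = 6


@dataclasses.dataclass
class PhantomParams:
    """Shape parameters of a phantom, in mm, with plausible adult ranges."""

    lv_long_axis: float = 85.0       # apex to mitral-valve center
    lv_radius: float = 25.0          # endocardial radius at the base
    wall_thickness: float = 10.0     # LV myocardial wall
    la_radius: float = 24.0
    la_height: float = 36.0
    rv_radius: float = 22.0
    rv_length: float = 70.0
    ra_radius: float = 19.0
    ra_height: float = 28.0
    aorta_radius: float = 9.0
    aorta_length: float = 30.0
    valve_thickness: float = 3.0

    RANGES = {
        "lv_long_axis": (70.0, 100.0),
        "lv_radius": (20.0, 30.0),
        "wall_thickness": (6.0, 14.0),
        "la_radius": (18.0, 30.0),
        "la_height": (28.0, 45.0),
        "rv_radius": (16.0, 28.0),
        "rv_length": (55.0, 90.0),
        "ra_radius": (14.0, 24.0),
        "ra_height": (20.0, 36.0),
        "aorta_radius": (6.0, 12.0),
        "aorta_length": (20.0, 40.0),
        "valve_thickness": (1.0, 5.0),
    }

    def validate(self) -> None:
        for name, (lo, hi) in self.RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValidationError(
                    f"parameter {name}={v} outside plausible range [{lo}, {hi}]"
                )


@dataclasses.dataclass
class LabeledMesh:
    """Corresponded, tissue-labeled triangle mesh with anatomical landmarks.

    ``landmarks`` holds 3D points (``apex``, ``mitral_valve_center``,
    ``aortic_valve_center``) plus the unit vector ``lv_long_axis_direction``;
    ``landmark_indices`` maps the point landmarks to template vertex ids so
    they survive statistical resampling of the vertex coordinates.
    """

    vertices: np.ndarray          # (V, 3) float64, mm
    faces: np.ndarray             # (F, 3) int
    face_labels: np.ndarray       # (F,) int tissue codes
    landmarks: dict[str, np.ndarray]
    landmark_indices: dict[str, int]
    model_id: str
    legend: dict[str, int] = dataclasses.field(default_factory=lambda: dict(LEGEND))

    def compartment_codes(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.face_labels))

    def compartment_mesh(self, code: int) -> trimesh.Trimesh:
        """Closed sub-mesh of one tissue compartment (vertices re-indexed)."""
        faces = self.faces[self.face_labels == code]
        if len(faces) == 0:
            raise ValidationError(f"no faces with tissue code {code}")
        used = np.unique(faces)
        remap = np.zeros(len(self.vertices), dtype=np.int64)
        remap[used] = np.arange(len(used))
        return trimesh.Trimesh(
            vertices=self.vertices[used], faces=remap[faces], process=False
        )

    def compartment_volume(self, code: int) -> float:
        return float(self.compartment_mesh(code).volume)

    def with_vertices(self, vertices: np.ndarray, model_id: str | None = None) -> "LabeledMesh":
        """Same topology/labels with replaced vertex coordinates; landmarks
        re-derived from the landmark vertex indices."""
        vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
        if vertices.shape != self.vertices.shape:
            raise ValidationError("vertex array shape mismatch with template")
        lms = {k: vertices[i].copy() for k, i in self.landmark_indices.items()}
        ax = lms["mitral_valve_center"] - lms["apex"]
        lms["lv_long_axis_direction"] = ax / np.linalg.norm(ax)
        return LabeledMesh(
            vertices=vertices,
            faces=self.faces,
            face_labels=self.face_labels,
            landmarks=lms,
            landmark_indices=dict(self.landmark_indices),
            model_id=model_id if model_id is not None else self.model_id,
            legend=dict(self.legend),
        )


# ---------------------------------------------------------------------------
# analytic compartment builders (template topology is fixed by the constants)
# ---------------------------------------------------------------------------

def _half_ellipsoid(center, semi_xy, semi_z, direction, n_rings=_N_RINGS, n_seg=_N_SEG):
    """Closed half-ellipsoid: pole + rings + flat cap with a center vertex.

    ``direction`` is -1 for a lower half (pole below center, cap on top,
    e.g. a ventricle) or +1 for an upper half (an atrium).
    Returns (vertices, faces, pole_index, cap_center_index).
    """
    cx, cy, cz = center
    verts = [[cx, cy, cz + direction * semi_z]]  # pole
    # rings from near the pole to the equator
    thetas = np.linspace(0.0, np.pi / 2, n_rings + 1)[1:]
    phis = np.linspace(0.0, 2 * np.pi, n_seg, endpoint=False)
    for th in thetas:
        r = semi_xy * np.sin(th)
        z = cz + direction * semi_z * np.cos(th)
        for ph in phis:
            verts.append([cx + r * np.cos(ph), cy + r * np.sin(ph), z])
    cap_center = len(verts)
    verts.append([cx, cy, cz])
    faces = []
    # pole fan
    for j in range(n_seg):
        a, b = 1 + j, 1 + (j + 1) % n_seg
        faces.append([0, b, a] if direction < 0 else [0, a, b])
    # ring strips
    for i in range(n_rings - 1):
        r0, r1 = 1 + i * n_seg, 1 + (i + 1) * n_seg
        for j in range(n_seg):
            a, b = r0 + j, r0 + (j + 1) % n_seg
            c, d = r1 + j, r1 + (j + 1) % n_seg
            if direction < 0:
                faces += [[a, b, c], [b, d, c]]
            else:
                faces += [[a, c, b], [b, c, d]]
    # cap fan on the equator ring
    r_last = 1 + (n_rings - 1) * n_seg
    for j in range(n_seg):
        a, b = r_last + j, r_last + (j + 1) % n_seg
        faces.append([cap_center, a, b] if direction < 0 else [cap_center, b, a])
    return np.array(verts), np.array(faces, dtype=np.int64), 0, cap_center


def _tube(base, axis_dir, radius, length, n_ax=_N_AX, n_seg=_N_SEG):
    """Closed cylinder along ``axis_dir`` with capped ends.

    Returns (vertices, faces, base_center_index)."""
    d = np.asarray(axis_dir, dtype=float)
    d = d / np.linalg.norm(d)
    # orthonormal frame around the axis
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    base = np.asarray(base, dtype=float)
    phis = np.linspace(0.0, 2 * np.pi, n_seg, endpoint=False)
    verts = [base]  # base center
    for i in range(n_ax + 1):
        c = base + d * (length * i / n_ax)
        for ph in phis:
            verts.append(c + radius * (np.cos(ph) * u + np.sin(ph) * v))
    top_center = len(verts)
    verts.append(base + d * length)
    faces = []
    for j in range(n_seg):  # base cap (normal points -d)
        a, b = 1 + j, 1 + (j + 1) % n_seg
        faces.append([0, b, a])
    for i in range(n_ax):
        r0, r1 = 1 + i * n_seg, 1 + (i + 1) * n_seg
        for j in range(n_seg):
            a, b = r0 + j, r0 + (j + 1) % n_seg
            c, e = r1 + j, r1 + (j + 1) % n_seg
            faces += [[a, b, c], [b, e, c]]
    r_last = 1 + n_ax * n_seg
    for j in range(n_seg):  # top cap
        a, b = r_last + j, r_last + (j + 1) % n_seg
        faces.append([top_center, a, b])
    return np.array(verts), np.array(faces, dtype=np.int64), 0


def _build_template(p: PhantomParams):
    """Assemble all compartments; returns vertices, faces, labels, landmark ids."""
    L = p.lv_long_axis
    parts = []  # (verts, faces, code)
    lm_idx = {}
    offset = 0

    def add(verts, faces, code):
        nonlocal offset
        parts.append((verts, faces + offset, code))
        base = offset
        offset += len(verts)
        return base

    # LV endocardial blood pool: apex pole at origin
    v, f, pole, cap = _half_ellipsoid((0, 0, L), p.lv_radius, L, -1)
    base = add(v, f, LEGEND["lv_blood_pool"])
    lm_idx["apex"] = base + pole
    lm_idx["mitral_valve_center"] = base + cap
    # solid epicardial compartment (myocardium = this minus the pools)
    v, f, _, _ = _half_ellipsoid(
        (0, 0, L), p.lv_radius + p.wall_thickness, L + p.wall_thickness, -1
    )
    add(v, f, LEGEND["lv_myocardium"])
    # left atrium above the valve plane (small gap keeps the disk visible)
    v, f, _, _ = _half_ellipsoid((0, 0, L + 2.0), p.la_radius, p.la_height, +1)
    add(v, f, LEGEND["left_atrium"])
    # right ventricle beside the LV, cavity reaching mid-septum
    rv_cx = p.lv_radius + 0.5 * p.wall_thickness + p.rv_radius
    v, f, _, _ = _half_ellipsoid((rv_cx, 0, L), p.rv_radius, p.rv_length, -1)
    add(v, f, LEGEND["right_ventricle"])
    # right atrium
    v, f, _, _ = _half_ellipsoid((0.85 * rv_cx, 0, L + 1.0), p.ra_radius, p.ra_height, +1)
    add(v, f, LEGEND["right_atrium"])
    # aorta from the LV outflow tract, tilted away from the long axis
    ao_base = np.array([-0.35 * p.lv_radius, 0.0, L + 1.0])
    v, f, bc = _tube(ao_base, (-0.5, 0.0, 1.0), p.aorta_radius, p.aorta_length)
    base = add(v, f, LEGEND["aorta"])
    lm_idx["aortic_valve_center"] = base + bc
    # flat mitral-valve disk on the base plane
    v, f, _ = _tube((0, 0, L), (0, 0, 1.0), 1.05 * p.lv_radius, p.valve_thickness)
    add(v, f, LEGEND["valve_disk"])

    vertices = np.vstack([v for v, _, _ in parts])
    faces = np.vstack([f for _, f, _ in parts])
    labels = np.concatenate(
        [np.full(len(f), code, dtype=np.int64) for _, f, code in parts]
    )
    return vertices, faces, labels, lm_idx


def generate_phantom(
    seed: int,
    params: PhantomParams | None = None,
    model_id: str | None = None,
    rigid_jitter: bool = True,
) -> LabeledMesh:
    """Build one labeled phantom.

    ``seed`` drives a small rigid pose jitter (rotation up to ~3 deg,
    translation up to 2 mm) emulating inter-subject pose differences; shape is
    controlled entirely by ``params``.  Identical (seed, params) give a
    bit-identical mesh.
    """
    params = params or PhantomParams()
    params.validate()
    vertices, faces, labels, lm_idx = _build_template(params)
    if rigid_jitter:
        rng = np.random.default_rng(seed)
        angles = rng.uniform(-3.0, 3.0, size=3) * np.pi / 180.0
        t = rng.uniform(-2.0, 2.0, size=3)
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", angles).as_matrix()
        centroid = vertices.mean(axis=0)
        vertices = (vertices - centroid) @ R.T + centroid + t
    mesh = LabeledMesh(
        vertices=vertices,
        faces=faces,
        face_labels=labels,
        landmarks={},
        landmark_indices=lm_idx,
        model_id=model_id or f"phantom_{seed:04d}",
    )
    return mesh.with_vertices(vertices, model_id=mesh.model_id)


def generate_phantom_cohort(
    n: int = 19,
    seed: int = 7,
    base_params: PhantomParams | None = None,
    vary: list[str] | None = None,
    jitter_frac: float = 0.08,
) -> list[LabeledMesh]:
    """Cohort of ``n`` corresponded phantoms with jittered shape parameters.

    Each phantom's parameters are drawn uniformly within ``jitter_frac``
    (relative) of the base value, clipped to the documented plausible range;
    ``vary`` restricts jitter to a subset of parameter names (all by default).
    """
    if n < 2:
        raise ValidationError("cohort size n must be >= 2 (shape PCA needs >= 2)")
    base = base_params or PhantomParams()
    base.validate()
    names = vary if vary is not None else list(PhantomParams.RANGES)
    for nm in names:
        if nm not in PhantomParams.RANGES:
            raise ValidationError(f"unknown phantom parameter: {nm}")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        p = dataclasses.replace(base)
        for nm in names:
            lo, hi = PhantomParams.RANGES[nm]
            v = getattr(base, nm) * (1.0 + rng.uniform(-jitter_frac, jitter_frac))
            setattr(p, nm, float(np.clip(v, lo, hi)))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cohort.append(generate_phantom(sub_seed, p, model_id=f"phantom_{i:04d}"))
    return cohort


# ---------------------------------------------------------------------------
# serialization: ASCII PLY geometry + JSON sidecar with labels and landmarks
# ---------------------------------------------------------------------------

def _labels_to_runs(labels: np.ndarray) -> list[list[int]]:
    runs, prev, count = [], None, 0
    for v in labels.tolist():
        if v == prev:
            count += 1
        else:
            if prev is not None:
                runs.append([prev, count])
            prev, count = v, 1
    if prev is not None:
        runs.append([prev, count])
    return runs


def _runs_to_labels(runs) -> np.ndarray:
    return np.concatenate([np.full(c, v, dtype=np.int64) for v, c in runs])


def save_mesh(mesh: LabeledMesh, out_dir: str | Path) -> Path:
    """Write ``<model_id>.ply`` plus ``<model_id>.landmarks.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    ply_path = out_dir / f"{mesh.model_id}.ply"
    ply_path.write_bytes(tm.export(file_type="ply", encoding="ascii"))
    sidecar = {
        "model_id": mesh.model_id,
        "legend": mesh.legend,
        "face_label_runs": _labels_to_runs(mesh.face_labels),
        "landmarks": {k: np.asarray(v).tolist() for k, v in mesh.landmarks.items()},
        "landmark_indices": mesh.landmark_indices,
    }
    (out_dir / f"{mesh.model_id}.landmarks.json").write_text(json.dumps(sidecar))
    return ply_path


def load_mesh(ply_path: str | Path) -> LabeledMesh:
    ply_path = Path(ply_path)
    tm = trimesh.load(ply_path, process=False)
    sidecar = json.loads(ply_path.with_suffix(".landmarks.json").read_text())
    mesh = LabeledMesh(
        vertices=np.asarray(tm.vertices, dtype=np.float64),
        faces=np.asarray(tm.faces, dtype=np.int64),
        face_labels=_runs_to_labels(sidecar["face_label_runs"]),
        landmarks={k: np.asarray(v, dtype=np.float64) for k, v in sidecar["landmarks"].items()},
        landmark_indices={k: int(v) for k, v in sidecar["landmark_indices"].items()},
        model_id=sidecar["model_id"],
        legend={k: int(v) for k, v in sidecar["legend"].items()},
    )
    return mesh


def load_cohort(directory: str | Path) -> list[LabeledMesh]:
    return [load_mesh(p) for p in sorted(Path(directory).glob("*.ply"))]
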