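"""Pseudo-ultrasound rendering: label slice -> (image, task label) pair.

A tissue label slice is converted into a grayscale image that structurally
mimics ultrasound -- dark blood pools, bright myocardium -- then masked with
the scan-cone, cropped to either the whole heart or an LV-focused zoom,
affinely augmented (rotation / squeeze / translation), degraded with uniform
noise and angular shadow sectors cast from the cone apex, and Gaussian
blurred.  The task label raster goes through the *identical* affine chain
(nearest-neighbor resampled, since codes are categorical) and is never
touched by noise, shadows or blur, so image and labels stay exactly paired.

Every pixel outside the cone is zero in both image and label in every pair
emitted (the cone invariant).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import GenerationError, ValidationError
from .phantoms import LEGEND
from .slicing import LabelSlice

__all__ = [
    "ConeGeometry",
    "RenderConfig",
    "PseudoPair",
    "PROFILES",
    "derive_task_labels",
    "structure_mask",
    "compose_view",
    "add_noise_and_shadows",
    "blur",
    "render_pair",
    "render_dataset",
    "save_pair",
    "load_pair",
    "write_dataset",
    "load_dataset",
]

#: Task structures expressed as sets of tissue codes they cover.
STRUCTURES: dict[str, frozenset[int]] = {
    "lv_endo": frozenset({LEGEND["lv_blood_pool"]}),
    "lv_epi": frozenset({LEGEND["lv_blood_pool"], LEGEND["lv_myocardium"]}),
    "la": frozenset({LEGEND["left_atrium"]}),
    "rv": frozenset({LEGEND["right_ventricle"]}),
    "ra": frozenset({LEGEND["right_atrium"]}),
}

#: Gray level per tissue code for the pre-transform intensity proxy:
#: blood pools dark, myocardium bright, valve intermediate.
GRAY_LEVELS: dict[int, float] = {
    LEGEND["lv_blood_pool"]: 0.10,
    LEGEND["lv_myocardium"]: 0.70,
    LEGEND["left_atrium"]: 0.12,
    LEGEND["right_ventricle"]: 0.10,
    LEGEND["right_atrium"]: 0.12,
    LEGEND["aorta"]: 0.14,
    LEGEND["valve_disk"]: 0.55,
}

#: Background (non-tissue, inside cone) gray level: weak diffuse echo.
BACKGROUND_LEVEL = 0.30


@dataclasses.dataclass
class ConeGeometry:
    """Ultrasound sector: apex position (row, col), opening angle, radius (px)."""

    apex: tuple[float, float]
    opening_angle: float
    radius: float

    def __post_init__(self):
        if not (0.0 < self.opening_angle < 180.0):
            raise ValidationError("cone opening_angle must be in (0, 180) degrees")

    @classmethod
    def default(cls, H: int, W: int) -> "ConeGeometry":
        return cls(apex=(2.0, W / 2.0), opening_angle=75.0, radius=0.92 * H)

    def mask(self, H: int, W: int) -> np.ndarray:
        rr, cc = np.mgrid[:H, :W]
        dr = rr + 0.5 - self.apex[0]
        dc = cc + 0.5 - self.apex[1]
        dist = np.hypot(dr, dc)
        ang = np.degrees(np.arctan2(dc, dr))  # 0 = straight down
        return (dist <= self.radius) & (np.abs(ang) <= self.opening_angle / 2)

    def angles(self, H: int, W: int) -> np.ndarray:
        rr, cc = np.mgrid[:H, :W]
        return np.degrees(np.arctan2(cc + 0.5 - self.apex[1], rr + 0.5 - self.apex[0]))


@dataclasses.dataclass
class RenderConfig:
    """Extraction profile: raster geometry, augmentation and noise settings.

    The affine/noise/shadow defaults are package choices producing visible
    but non-pathological variation; all are configurable per profile.
    """

    H: int = 256
    W: int = 256
    pixel_spacing: float = 0.6           # mm/px of the source label slice
    cone: ConeGeometry | None = None     # default geometry if None
    lv_focused_prob: float = 0.5
    lv_span_frac: float = 0.70           # LV height / cone radius, lv_focused
    whole_span_frac: float = 0.80        # heart height / cone radius
    top_offset_frac: float = 0.10        # ROI top below cone apex
    rotation_range: float = 10.0         # deg, in-plane
    squeeze_range: tuple[float, float] = (0.9, 1.1)
    jitter_frac: float = 0.03            # translation jitter, fraction of W
    noise_amplitude: float = 0.08
    n_shadows: tuple[int, int] = (1, 3)
    shadow_width: tuple[float, float] = (5.0, 20.0)
    shadow_attenuation: tuple[float, float] = (0.3, 0.7)
    blur_sigma: float = 2.0
    max_retries: int = 20

    def cone_geometry(self) -> ConeGeometry:
        return self.cone if self.cone is not None else ConeGeometry.default(self.H, self.W)


#: Named per-dataset extraction profiles (crop-mix and depth differ slightly).
PROFILES: dict[str, RenderConfig] = {
    "camus": RenderConfig(lv_focused_prob=0.3, whole_span_frac=0.82),
    "echonet": RenderConfig(lv_focused_prob=0.8, lv_span_frac=0.72),
    "site_a": RenderConfig(lv_focused_prob=0.5),
}


@dataclasses.dataclass
class PseudoPair:
    """Aligned pseudo-ultrasound image and task-label raster with provenance."""

    image: np.ndarray            # (H, W) float in [0, 1]
    label: np.ndarray            # (H, W) int task codes
    cone: ConeGeometry
    provenance: dict

    def cone_mask(self) -> np.ndarray:
        return self.cone.mask(*self.image.shape)


def derive_task_labels(sl: LabelSlice, task: tuple[str, ...]) -> np.ndarray:
    """Task label raster from a tissue slice.

    Structures are painted from the largest tissue support to the smallest so
    nested structures (LV endocardium inside the epicardial region) keep
    their own code; the code of a structure is 1 + its index in ``task``.
    """
    for s in task:
        if s not in STRUCTURES:
            raise ValidationError(f"unknown task structure: {s}")
    out = np.zeros_like(sl.raster)
    order = sorted(task, key=lambda s: -len(STRUCTURES[s]))
    for s in order:
        code = 1 + list(task).index(s)
        out[np.isin(sl.raster, list(STRUCTURES[s]))] = code
    return out


def structure_mask(task_raster: np.ndarray, structure: str, task: tuple[str, ...]) -> np.ndarray:
    """Binary mask of one structure, re-uniting nested sub-structures."""
    if structure not in task:
        raise ValidationError(f"structure {structure} not in task {task}")
    sup = STRUCTURES[structure]
    codes = [1 + i for i, s in enumerate(task) if STRUCTURES[s] <= sup]
    return np.isin(task_raster, codes)


def _intensity_proxy(raster: np.ndarray) -> np.ndarray:
    img = np.full(raster.shape, BACKGROUND_LEVEL, dtype=np.float64)
    for code, level in GRAY_LEVELS.items():
        img[raster == code] = level
    img[raster == 0] = BACKGROUND_LEVEL
    return img


def compose_view(
    sl: LabelSlice,
    task: tuple[str, ...],
    cone: ConeGeometry,
    crop_mode: str | None,
    seed: int,
    config: RenderConfig,
) -> PseudoPair:
    """Cone-masked, cropped and affinely augmented (image, label) pair.

    The identical affine chain is applied to the intensity proxy (bilinear)
    and the task labels (nearest-neighbor).  The transform is redrawn up to
    ``config.max_retries`` times until every task-label pixel falls inside
    the cone; failure raises :class:`GenerationError`.
    """
    rng = np.random.default_rng(seed)
    if crop_mode is None:
        crop_mode = "lv_focused" if rng.uniform() < config.lv_focused_prob else "whole_heart"
    if crop_mode not in ("lv_focused", "whole_heart"):
        raise ValidationError(f"unknown crop_mode: {crop_mode}")
    task_raster = derive_task_labels(sl, task)
    if crop_mode == "lv_focused":
        roi = np.isin(sl.raster, list(STRUCTURES["lv_epi"]))
        span_frac = config.lv_span_frac
    else:
        roi = sl.raster > 0
        span_frac = config.whole_span_frac
    if not roi.any():
        raise GenerationError(f"slice of {sl.model_id} contains no crop target for {crop_mode}")
    img_src = _intensity_proxy(sl.raster)
    rows, cols = np.nonzero(roi)
    in_center = np.array([(rows.min() + rows.max()) / 2.0, (cols.min() + cols.max()) / 2.0])
    roi_height = max(rows.max() - rows.min() + 1, 1)
    roi_width = max(cols.max() - cols.min() + 1, 1)
    H, W = config.H, config.W
    mask = cone.mask(H, W)
    # fit by height, but never wider than the cone at the ROI's mid depth
    height_scale = span_frac * cone.radius / roi_height
    mid_depth = (config.top_offset_frac + span_frac / 2.0) * cone.radius
    half_width = min(mid_depth * np.tan(np.deg2rad(cone.opening_angle / 2)), W / 2.0)
    width_scale = 1.8 * half_width / roi_width
    scale = min(height_scale, width_scale)
    out_center_base = np.array(
        [cone.apex[0] + config.top_offset_frac * cone.radius + scale * roi_height / 2.0,
         cone.apex[1]]
    )
    last_err = None
    for attempt in range(config.max_retries):
        theta = np.deg2rad(rng.uniform(-config.rotation_range, config.rotation_range))
        sq = rng.uniform(*config.squeeze_range, size=2)
        jitter = rng.uniform(-config.jitter_frac, config.jitter_frac, size=2) * W
        # successive attempts pull the crop in slightly so a fit always exists
        shrink = 0.95 ** attempt
        A = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]) @ np.diag(scale * shrink * sq)
        out_center = out_center_base + jitter
        Ainv = np.linalg.inv(A)
        offset = in_center - Ainv @ out_center
        img = ndimage.affine_transform(img_src, Ainv, offset=offset, output_shape=(H, W), order=1, mode="constant", cval=0.0)
        lbl = ndimage.affine_transform(task_raster, Ainv, offset=offset, output_shape=(H, W), order=0, mode="constant", cval=0)
        if not lbl.any():
            last_err = "transformed labels fell fully outside the raster"
            continue
        if np.all(mask[lbl > 0]):
            img = np.clip(img, 0.0, 1.0) * mask
            lbl = lbl * mask
            prov = {
                "model_id": sl.model_id,
                "view": sl.plane.view,
                "crop_mode": crop_mode,
                "task": list(task),
                "plane_perturbation": list(sl.plane.perturbation),
                "affine": {
                    "rotation_deg": float(np.rad2deg(theta)),
                    "squeeze": [float(s) for s in sq],
                    "scale": float(scale),
                    "jitter_px": [float(j) for j in jitter],
                    "attempt": attempt,
                },
                "seed": int(seed),
            }
            return PseudoPair(image=img, label=lbl.astype(np.int64), cone=cone, provenance=prov)
        last_err = "region of interest extends outside the cone"
    raise GenerationError(
        f"could not fit {crop_mode} crop of {sl.model_id} inside the cone "
        f"after {config.max_retries} attempts ({last_err})"
    )


def add_noise_and_shadows(
    pair: PseudoPair,
    seed: int,
    noise_amplitude: float = 0.08,
    n_shadows: tuple[int, int] = (1, 3),
    shadow_width: tuple[float, float] = (5.0, 20.0),
    shadow_attenuation: tuple[float, float] = (0.3, 0.7),
) -> PseudoPair:
    """Uniform noise inside the cone plus multiplicative angular shadows.

    Shadows are sectors fanning out from the cone apex.  The label raster is
    returned bit-identical.
    """
    if noise_amplitude < 0:
        raise ValidationError("noise_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    H, W = pair.image.shape
    mask = pair.cone_mask()
    img = pair.image.copy()
    n_sh = int(rng.integers(n_shadows[0], n_shadows[1] + 1)) if n_shadows[1] > 0 else 0
    if n_sh > 0:
        ang = pair.cone.angles(H, W)
        half = pair.cone.opening_angle / 2
        shadows = []
        for _ in range(n_sh):
            width = rng.uniform(*shadow_width)
            center = rng.uniform(-half, half)
            atten = rng.uniform(*shadow_attenuation)
            sector = np.abs(ang - center) <= width / 2
            img[sector & mask] *= atten
            shadows.append({"center_deg": float(center), "width_deg": float(width), "attenuation": float(atten)})
    else:
        shadows = []
    if noise_amplitude > 0:
        noise = rng.uniform(-noise_amplitude, noise_amplitude, size=img.shape)
        img[mask] = img[mask] + noise[mask]
    img = np.clip(img, 0.0, 1.0) * mask
    prov = dict(pair.provenance)
    prov["noise"] = {"amplitude": float(noise_amplitude), "shadows": shadows, "seed": int(seed)}
    return PseudoPair(image=img, label=pair.label, cone=pair.cone, provenance=prov)


def blur(pair: PseudoPair, sigma_px: float = 2.0) -> PseudoPair:
    """Gaussian blur of the image only; the result is re-zeroed outside the cone."""
    if sigma_px < 0:
        raise ValidationError("sigma_px must be >= 0")
    if sigma_px == 0:
        return pair
    img = ndimage.gaussian_filter(pair.image, sigma_px) * pair.cone_mask()
    prov = dict(pair.provenance)
    prov["blur_sigma_px"] = float(sigma_px)
    return PseudoPair(image=img, label=pair.label, cone=pair.cone, provenance=prov)


def render_pair(sl: LabelSlice, task: tuple[str, ...], config: RenderConfig, seed: int) -> PseudoPair:
    """Full render chain: compose -> noise + shadows -> blur."""
    ss = np.random.SeedSequence(seed)
    s_compose, s_noise = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(2))
    pair = compose_view(sl, task, config.cone_geometry(), None, s_compose, config)
    pair = add_noise_and_shadows(
        pair, s_noise, config.noise_amplitude, config.n_shadows,
        config.shadow_width, config.shadow_attenuation,
    )
    return blur(pair, config.blur_sigma)


def render_dataset(
    models,
    view: str = "a4c",
    slices_per_model: int = 3,
    pseudo_per_slice: int = 3,
    task: tuple[str, ...] = ("lv_endo", "lv_epi", "la"),
    config: RenderConfig | None = None,
    seed: int = 0,
    perturb_ranges: tuple[float, float] = (10.0, 5.0),
) -> list[PseudoPair]:
    """Render |models| x slices_per_model x pseudo_per_slice pairs, exactly.

    Each slice comes from a freshly perturbed (foreshortened) view plane;
    failed renders are re-drawn with fresh sub-seeds so the count is exact.
    Deterministic for a fixed ``seed``.
    """
    from .slicing import define_a2c_plane, define_a4c_plane, perturb_plane, slice_mesh

    if len(models) == 0:
        raise ValidationError("need at least one model")
    if view not in ("a4c", "a2c"):
        raise ValidationError(f"unknown view: {view}")
    config = config or RenderConfig()
    root = np.random.SeedSequence(seed)
    pairs: list[PseudoPair] = []
    for mesh, mesh_ss in zip(models, root.spawn(len(models))):
        base_plane = define_a4c_plane(mesh) if view == "a4c" else define_a2c_plane(mesh)
        for slice_ss in mesh_ss.spawn(slices_per_model):
            s_perturb, s_render = slice_ss.spawn(2)
            plane = perturb_plane(
                base_plane, mesh, int(s_perturb.generate_state(1)[0] % (2**31 - 1)), perturb_ranges
            )
            sl = slice_mesh(mesh, plane, config.H, config.W, config.pixel_spacing)
            draws = iter(s_render.spawn(pseudo_per_slice * 50))
            made = 0
            while made < pseudo_per_slice:
                sub = int(next(draws).generate_state(1)[0] % (2**31 - 1))
                try:
                    pair = render_pair(sl, task, config, sub)
                except GenerationError:
                    continue
                pair.provenance["pair_index"] = len(pairs)
                pairs.append(pair)
                made += 1
    return pairs


# ---------------------------------------------------------------------------
# serialization: 8-bit grayscale image + indexed label PNG + provenance JSON
# ---------------------------------------------------------------------------

def save_pair(pair: PseudoPair, out_dir: str | Path, stem: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_dir / f"{stem}_img.png", (np.clip(pair.image, 0, 1) * 255).round().astype(np.uint8))
    lbl = Image.fromarray(pair.label.astype(np.uint8), mode="P")
    pal = np.zeros((256, 3), dtype=np.uint8)
    pal[:8] = np.array([[0, 0, 0], [200, 40, 40], [230, 170, 60], [70, 130, 220],
                        [70, 190, 100], [170, 90, 210], [230, 70, 150], [210, 210, 210]], dtype=np.uint8)
    lbl.putpalette(pal.ravel().tolist())
    lbl.save(out_dir / f"{stem}_lbl.png")
    prov = dict(pair.provenance)
    prov["cone"] = {"apex": list(pair.cone.apex), "opening_angle": pair.cone.opening_angle, "radius": pair.cone.radius}
    (out_dir / f"{stem}.json").write_text(json.dumps(prov))


def load_pair(out_dir: str | Path, stem: str) -> PseudoPair:
    out_dir = Path(out_dir)
    img = np.asarray(iio.imread(out_dir / f"{stem}_img.png"), dtype=np.float64) / 255.0
    lbl = np.asarray(Image.open(out_dir / f"{stem}_lbl.png"), dtype=np.int64)
    prov = json.loads((out_dir / f"{stem}.json").read_text())
    c = prov.pop("cone")
    cone = ConeGeometry(apex=tuple(c["apex"]), opening_angle=c["opening_angle"], radius=c["radius"])
    return PseudoPair(image=img, label=lbl, cone=cone, provenance=prov)


def write_dataset(pairs: list[PseudoPair], out_dir: str | Path) -> Path:
    """Write all pairs plus a manifest CSV; returns the manifest path."""
    import pandas as pd

    out_dir = Path(out_dir)
    rows = []
    for i, p in enumerate(pairs):
        stem = f"pair_{i:05d}"
        save_pair(p, out_dir, stem)
        rows.append({
            "stem": stem,
            "model_id": p.provenance.get("model_id"),
            "view": p.provenance.get("view"),
            "crop_mode": p.provenance.get("crop_mode"),
            "seed": p.provenance.get("seed"),
        })
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(out_dir: str | Path) -> list[PseudoPair]:
    import pandas as pd

    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "manifest.csv")
    return [load_pair(out_dir, stem) for stem in df["stem"]]
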