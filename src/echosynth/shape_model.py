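"""Point-distribution shape model (PDM) over a corresponded mesh cohort.

A classical statistical shape model: the cohort is rigidly aligned with
generalized Procrustes analysis (rotation + translation only -- overall heart
size is a genuine anatomical mode and is deliberately kept in the model),
then PCA decomposes the flattened vertex coordinates into orthonormal modes
of variation.  New anatomies are synthesized as

    x = x_mean + sum_i  c_i * sqrt(lambda_i) * mode_i

with per-mode coefficients ``c_i`` drawn within two standard deviations of
the mean shape.  The retained mode count is the smallest capturing a target
fraction of total variance (default 0.90).

PCA is computed through the thin SVD of the (n x 3V) centered data matrix,
which is the dual of the eigendecomposition of the 3V x 3V covariance and
exact for n << 3V.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.stats import truncnorm

from .errors import ValidationError
from .phantoms import LabeledMesh

__all__ = [
    "ShapeModelPDM",
    "ShapeSample",
    "align_cohort",
    "fit_pdm",
    "sample_shape",
    "expand_cohort",
    "mode_sweep",
    "save_pdm",
    "load_pdm",
]


@dataclasses.dataclass
class ShapeModelPDM:
    """Mean shape + orthonormal variation modes + per-mode variances."""

    mean_shape: np.ndarray        # (3V,) mm
    modes: np.ndarray             # (3V, k) orthonormal columns
    mode_variances: np.ndarray    # (k,) mm^2, non-increasing
    all_variances: np.ndarray     # full eigenvalue spectrum (rank entries)
    template: LabeledMesh         # topology, labels, landmark indices
    variance_target: float

    @property
    def k(self) -> int:
        return self.modes.shape[1]

    @property
    def variance_captured(self) -> float:
        total = float(self.all_variances.sum())
        return float(self.mode_variances.sum()) / total if total > 0 else 1.0


@dataclasses.dataclass
class ShapeSample:
    """One sampled anatomy: mode coefficients (in SD units) and its mesh."""

    coefficients: np.ndarray
    mesh: LabeledMesh
    source_seed: int


def _check_corresponded(cohort: list[LabeledMesh]) -> None:
    if len(cohort) < 2:
        raise ValidationError("cohort must contain >= 2 meshes")
    ref = cohort[0]
    for m in cohort[1:]:
        if m.vertices.shape != ref.vertices.shape or not np.array_equal(m.faces, ref.faces):
            raise ValidationError("cohort is not corresponded (topology mismatch)")


def _kabsch(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rigid (R, t) minimizing ||src @ R.T + t - dst||."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, dc - R @ sc


def align_cohort(cohort: list[LabeledMesh], max_iter: int = 100, tol: float = 1e-12) -> list[LabeledMesh]:
    """Generalized Procrustes alignment, rigid only (no scaling).

    Iterates alignment to the running mean shape until the mean stops moving
    (RMS change < ``tol`` mm), so re-aligning an aligned cohort is a no-op;
    the returned cohort has its mean centroid at the origin.
    """
    _check_corresponded(cohort)
    pts = [m.vertices.copy() for m in cohort]
    ref = np.mean([p - p.mean(axis=0) for p in pts], axis=0)
    ref = ref - ref.mean(axis=0)
    for _ in range(max_iter):
        aligned = []
        for p in pts:
            R, t = _kabsch(p, ref)
            aligned.append(p @ R.T + t)
        pts = aligned
        new_ref = np.mean(pts, axis=0)
        new_ref = new_ref - new_ref.mean(axis=0)
        moved = np.sqrt(np.mean((new_ref - ref) ** 2))
        ref = new_ref
        if moved < tol:
            break
    mean_centroid = np.mean([p.mean(axis=0) for p in pts], axis=0)
    pts = [p - mean_centroid for p in pts]
    return [m.with_vertices(p) for m, p in zip(cohort, pts)]


def fit_pdm(aligned: list[LabeledMesh], variance_target: float = 0.90) -> ShapeModelPDM:
    """PCA point-distribution model retaining the smallest mode count whose
    cumulative variance fraction reaches ``variance_target``."""
    if not (0.0 < variance_target <= 1.0):
        raise ValidationError(f"variance_target={variance_target} outside (0, 1]")
    _check_corresponded(aligned)
    X = np.stack([m.vertices.ravel() for m in aligned])  # (n, 3V)
    n = X.shape[0]
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = s**2 / (n - 1)
    # numerical rank cut: discard machine-noise modes
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    variances = variances[:rank]
    Vt = Vt[:rank]
    total = variances.sum()
    frac = np.cumsum(variances) / total
    k = int(np.searchsorted(frac, variance_target - 1e-12) + 1)
    k = min(k, rank)
    return ShapeModelPDM(
        mean_shape=mean,
        modes=Vt[:k].T.copy(),
        mode_variances=variances[:k].copy(),
        all_variances=variances.copy(),
        template=aligned[0],
        variance_target=variance_target,
    )


def _reconstruct(pdm: ShapeModelPDM, coeffs: np.ndarray) -> np.ndarray:
    disp = pdm.modes @ (coeffs * np.sqrt(pdm.mode_variances))
    return (pdm.mean_shape + disp).reshape(-1, 3)


def sample_shape(
    pdm: ShapeModelPDM,
    seed: int,
    distribution: str = "uniform",
    model_id: str | None = None,
) -> ShapeSample:
    """Draw one plausible anatomy with per-mode coefficients within +/-2 SD.

    ``distribution`` is ``uniform`` (i.i.d. uniform on [-2, 2], the default)
    or ``truncnorm`` (standard normal truncated at +/-2 SD).
    """
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        c = rng.uniform(-2.0, 2.0, size=pdm.k)
    elif distribution == "truncnorm":
        c = truncnorm.rvs(-2.0, 2.0, size=pdm.k, random_state=rng)
    else:
        raise ValidationError(f"unknown coefficient distribution: {distribution}")
    mesh = pdm.template.with_vertices(
        _reconstruct(pdm, c), model_id=model_id or f"pdm_sample_{seed}"
    )
    return ShapeSample(coefficients=c, mesh=mesh, source_seed=seed)


def reconstruct_from_coefficients(pdm: ShapeModelPDM, coeffs, model_id: str = "pdm_recon") -> LabeledMesh:
    """Deterministic reconstruction from explicit SD-unit coefficients."""
    c = np.asarray(coeffs, dtype=np.float64)
    if c.shape != (pdm.k,):
        raise ValidationError(f"expected {pdm.k} coefficients, got {c.shape}")
    return pdm.template.with_vertices(_reconstruct(pdm, c), model_id=model_id)


def expand_cohort(
    pdm: ShapeModelPDM, n_new: int = 99, seed: int = 0, distribution: str = "uniform"
) -> list[LabeledMesh]:
    """Sample ``n_new`` anatomies (the shape-extension step of the pipeline)."""
    if n_new <= 0:
        raise ValidationError("n_new must be positive")
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_new)):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        s = sample_shape(pdm, sub_seed, distribution, model_id=f"pdm_{i:04d}")
        out.append(s.mesh)
    return out


def mode_sweep(pdm: ShapeModelPDM, mode: int, sd_values=(-2.0, 0.0, 2.0)) -> list[LabeledMesh]:
    """Meshes varying a single mode (what mode-variation figures visualize)."""
    if not (0 <= mode < pdm.k):
        raise ValidationError(f"mode {mode} out of range [0, {pdm.k})")
    out = []
    for v in sd_values:
        c = np.zeros(pdm.k)
        c[mode] = v
        out.append(reconstruct_from_coefficients(pdm, c, model_id=f"mode{mode}_{v:+.1f}sd"))
    return out


def save_pdm(pdm: ShapeModelPDM, path: str | Path) -> Path:
    path = Path(path)
    t = pdm.template
    manifest = {
        "variance_target": pdm.variance_target,
        "model_id": t.model_id,
        "legend": t.legend,
        "landmark_indices": t.landmark_indices,
    }
    np.savez(
        path,
        mean_shape=pdm.mean_shape,
        modes=pdm.modes,
        mode_variances=pdm.mode_variances,
        all_variances=pdm.all_variances,
        faces=t.faces,
        face_labels=t.face_labels,
        template_vertices=t.vertices,
        manifest=json.dumps(manifest),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_pdm(path: str | Path) -> ShapeModelPDM:
    with np.load(path, allow_pickle=False) as z:
        manifest = json.loads(str(z["manifest"]))
        template = LabeledMesh(
            vertices=z["template_vertices"],
            faces=z["faces"],
            face_labels=z["face_labels"],
            landmarks={},
            landmark_indices={k: int(v) for k, v in manifest["landmark_indices"].items()},
            model_id=manifest["model_id"],
            legend={k: int(v) for k, v in manifest["legend"].items()},
        )
        template = template.with_vertices(template.vertices)
        return ShapeModelPDM(
            mean_shape=z["mean_shape"],
            modes=z["modes"],
            mode_variances=z["mode_variances"],
            all_variances=z["all_variances"],
            template=template,
            variance_target=float(manifest["variance_target"]),
        )
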