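"""U-Net segmentation training and simplicity-based checkpoint selection.

The segmenter shares the U-Net architecture of the translation generators
and is trained with pixelwise cross-entropy for 30 epochs (default) on
generated image/label pairs, producing one checkpoint per epoch.

Checkpoint selection deliberately avoids synthetic-validation Dice (which
overfits to the synthetic domain): each checkpoint predicts masks on an
*unlabeled* selection set and is scored by the median simplicity of its
predicted structure mask -- a label-free, shape-based quality proxy -- and
the checkpoint with the highest median simplicity wins.  The selection
interface receives images only, so reference labels cannot leak into the
choice.  Ties go to the later epoch (more training); an empty predicted
mask scores simplicity 0.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from . import nn
from .errors import ValidationError
from .metrics import simplicity
from .pseudo import PseudoPair

__all__ = [
    "SegTrainConfig",
    "CheckpointScore",
    "train_segmenter",
    "predict_mask",
    "select_by_simplicity",
    "save_checkpoints",
    "load_checkpoints",
]


@dataclasses.dataclass
class SegTrainConfig:
    """Training settings; the architecture mirrors the translation U-Net."""

    n_classes: int = 4              # background + task structures
    epochs: int = 30
    lr: float = 1e-3
    image_size: int = 256
    levels: int = 8
    base_channels: int = 16
    max_channels: int = 256
    batch_size: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.n_classes < 2:
            raise ValidationError("need background plus at least one class")
        if self.image_size % (2 ** self.levels) != 0:
            raise ValidationError(
                f"image_size {self.image_size} not divisible by 2^{self.levels}"
            )


@dataclasses.dataclass
class CheckpointScore:
    epoch: int
    median_simplicity: float
    per_image: list[float]


def _build_net(config: SegTrainConfig) -> nn.UNet:
    return nn.UNet(1, config.n_classes, config.levels, config.base_channels,
                   config.max_channels, config.image_size, final=None,
                   seed=config.seed)


def train_segmenter(
    pairs: list[PseudoPair], config: SegTrainConfig
) -> tuple[list[dict[str, np.ndarray]], list[float]]:
    """Train on image/label pairs; returns (per-epoch checkpoints, loss log).

    Images are consumed in their native [0, 1] intensity range (the output
    domain of the generation pipeline); no other preprocessing is applied.
    """
    config.validate()
    if not pairs:
        raise ValidationError("need at least one training pair")
    X = np.stack([p.image for p in pairs]).astype(np.float32)[:, None]
    Y = np.stack([p.label for p in pairs]).astype(np.int64)
    present = set(np.unique(Y).tolist())
    bad = present - set(range(config.n_classes))
    if bad:
        raise ValidationError(
            f"label classes {sorted(bad)} not covered by n_classes={config.n_classes}"
        )
    if X.shape[2:] != (config.image_size, config.image_size):
        raise ValidationError(
            f"pairs have size {X.shape[2:]}, config expects {config.image_size}"
        )
    net = _build_net(config)
    opt = nn.Adam(net.parameters(), config.lr, betas=(0.9, 0.999))
    rng = np.random.default_rng(config.seed)
    checkpoints, losses = [], []
    n = len(pairs)
    bs = max(1, config.batch_size)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total, count = 0.0, 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            logits = net(nn.Tensor(X[idx]))
            loss = nn.softmax_cross_entropy(logits, Y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data)
            count += 1
        losses.append(total / count)
        if not np.isfinite(losses[-1]):
            raise RuntimeError(f"non-finite training loss at epoch {epoch + 1}")
        checkpoints.append(net.state_dict())
    return checkpoints, losses


def predict_mask(
    checkpoint: dict[str, np.ndarray], images: np.ndarray, config: SegTrainConfig
) -> np.ndarray:
    """Argmax class raster(s) for one image (H, W) or a stack (N, H, W)."""
    images = np.asarray(images, dtype=np.float32)
    single = images.ndim == 2
    if single:
        images = images[None]
    if images.shape[1:] != (config.image_size, config.image_size):
        raise ValidationError(
            f"image size {images.shape[1:]} does not match training geometry "
            f"({config.image_size}, {config.image_size})"
        )
    net = _build_net(config)
    net.load_state_dict(checkpoint)
    with nn.no_grad():
        logits = net(nn.Tensor(images[:, None])).data
    masks = logits.argmax(axis=1).astype(np.int64)
    return masks[0] if single else masks


def select_by_simplicity(
    checkpoints: list[dict[str, np.ndarray]],
    selection_images: np.ndarray,
    config: SegTrainConfig,
    structure_codes: tuple[int, ...] = (1,),
) -> tuple[int, list[CheckpointScore]]:
    """Pick the checkpoint with the highest median predicted-mask simplicity.

    ``selection_images`` is an unlabeled (N, H, W) stack; for several
    structure codes the score is the mean of per-structure medians.  Returns
    (index of best checkpoint, all scores); ties resolve to the later epoch.
    """
    if not checkpoints:
        raise ValidationError("need at least one checkpoint")
    selection_images = np.asarray(selection_images, dtype=np.float32)
    if selection_images.ndim == 2:
        selection_images = selection_images[None]
    if len(selection_images) == 0:
        raise ValidationError("need at least one selection image")
    scores = []
    any_nonempty = False
    for ep, ckpt in enumerate(checkpoints):
        masks = predict_mask(ckpt, selection_images, config)
        per_structure = []
        per_image_all = []
        for code in structure_codes:
            vals = [simplicity(m == code) for m in masks]
            per_structure.append(float(np.median(vals)))
            per_image_all.extend(vals)
        if any(v > 0 for v in per_image_all):
            any_nonempty = True
        scores.append(CheckpointScore(
            epoch=ep + 1,
            median_simplicity=float(np.mean(per_structure)),
            per_image=per_image_all,
        ))
    if not any_nonempty:
        raise ValidationError(
            "all predictions empty for the selection structure at epochs "
            f"{[s.epoch for s in scores]}"
        )
    best = max(range(len(scores)), key=lambda i: (scores[i].median_simplicity, scores[i].epoch))
    return best, scores


def save_checkpoints(checkpoints: list[dict[str, np.ndarray]], out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, ckpt in enumerate(checkpoints):
        np.savez(out_dir / f"seg_epoch_{i + 1:03d}.npz", **ckpt)


def load_checkpoints(ckpt_dir: str | Path) -> list[dict[str, np.ndarray]]:
    files = sorted(Path(ckpt_dir).glob("seg_epoch_*.npz"))
    if not files:
        raise ValidationError(f"no checkpoints found in {ckpt_dir}")
    out = []
    for f in files:
        with np.load(f, allow_pickle=False) as z:
            out.append({k: z[k] for k in z.files})
    return out
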