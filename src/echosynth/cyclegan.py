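"""Unpaired pseudo-to-real image translation with a CycleGAN.

Two U-Net generators (pseudo -> real and real -> pseudo) and two patch
discriminators are trained jointly with least-squares adversarial losses, a
cycle-consistency L1 loss (weight lambda = 10) and an identity L1 loss
(weight 0.5 * lambda), the canonical published configuration; the generator
is a U-Net with 8 down-sampling levels by default.  Training runs 200 epochs
with Adam (lr 2e-4, betas 0.5/0.999) and a linear learning-rate decay over
the second half, saving checkpoints every 5 epochs.

Applying a trained transform replaces each pseudo image by the generator
output (re-masked to the scan cone) while copying its label raster
bit-identically -- the transformation never touches labels.

The full-scale defaults are faithful to that recipe; tests and desk
experiments exercise the same code at reduced size (smaller images, fewer
levels, fewer epochs), which the configuration supports directly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .errors import ValidationError
from .pseudo import PseudoPair

__all__ = [
    "CycleGANConfig",
    "TrainedTransform",
    "train_cyclegan",
    "init_from",
    "transform_dataset",
    "apply_generator",
    "save_transform",
    "load_transform",
]


@dataclasses.dataclass
class CycleGANConfig:
    """Architecture and optimization settings (defaults: full-scale recipe)."""

    image_size: int = 256
    levels: int = 8                 # generator U-Net down-sampling levels
    base_channels: int = 16
    max_channels: int = 256
    disc_base: int = 16
    disc_layers: int = 3
    lambda_cycle: float = 10.0
    lambda_identity: float = 0.5    # multiplies lambda_cycle
    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    epochs: int = 200
    checkpoint_every: int = 5
    seed: int = 0
    initial_state: dict | None = dataclasses.field(default=None, repr=False)

    def validate(self) -> None:
        if self.image_size % (2 ** self.levels) != 0:
            raise ValidationError(
                f"image_size {self.image_size} must be divisible by 2^{self.levels} "
                f"for {self.levels} down-sampling levels"
            )
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.checkpoint_every < 1:
            raise ValidationError("checkpoint_every must be >= 1")

    def arch_key(self) -> dict:
        return dict(image_size=self.image_size, levels=self.levels,
                    base_channels=self.base_channels, max_channels=self.max_channels,
                    disc_base=self.disc_base, disc_layers=self.disc_layers)


@dataclasses.dataclass
class TrainedTransform:
    """Trained pseudo -> real generator plus full state for warm starts."""

    generator_state: dict[str, np.ndarray]     # G pseudo->real
    full_state: dict[str, dict[str, np.ndarray]]
    config: CycleGANConfig
    log: list[dict]


def _build_models(config: CycleGANConfig):
    g_ab = nn.UNet(1, 1, config.levels, config.base_channels, config.max_channels,
                   config.image_size, final="tanh", seed=config.seed)
    g_ba = nn.UNet(1, 1, config.levels, config.base_channels, config.max_channels,
                   config.image_size, final="tanh", seed=config.seed + 1)
    d_a = nn.PatchDiscriminator(1, config.disc_base, config.disc_layers, seed=config.seed + 2)
    d_b = nn.PatchDiscriminator(1, config.disc_base, config.disc_layers, seed=config.seed + 3)
    return g_ab, g_ba, d_a, d_b


def _load_images(source, config: CycleGANConfig, name: str) -> np.ndarray:
    """Stack of (N, 1, H, W) images in [-1, 1] from arrays or a PNG directory."""
    import imageio.v3 as iio

    if isinstance(source, (str, Path)):
        files = sorted(Path(source).glob("*.png"))
        if not files:
            raise ValidationError(f"{name} directory {source} contains no PNG images")
        imgs = []
        for f in files:
            arr = np.asarray(iio.imread(f), dtype=np.float32)
            if arr.ndim == 3:
                arr = arr.mean(axis=2)
            if arr.shape != (config.image_size, config.image_size):
                raise ValidationError(
                    f"{name} image {f.name} has size {arr.shape}, expected "
                    f"{(config.image_size, config.image_size)}"
                )
            imgs.append(arr / 255.0)
        stack = np.stack(imgs)
    else:
        stack = np.asarray(source, dtype=np.float32)
        if stack.ndim != 3 or len(stack) == 0:
            raise ValidationError(f"{name} must be a non-empty (N, H, W) stack")
        if stack.shape[1:] != (config.image_size, config.image_size):
            raise ValidationError(
                f"{name} images have size {stack.shape[1:]}, expected "
                f"{(config.image_size, config.image_size)}"
            )
    return (stack[:, None] * 2.0 - 1.0).astype(np.float32)


def train_cyclegan(
    pseudo_images,
    real_images,
    config: CycleGANConfig,
    checkpoint_dir: str | Path | None = None,
) -> TrainedTransform:
    """Train the unpaired translation; returns the pseudo->real transform.

    ``pseudo_images`` / ``real_images`` are (N, H, W) arrays in [0, 1] or
    directories of grayscale PNGs.  Checkpoints (full four-network state) are
    written to ``checkpoint_dir`` every ``config.checkpoint_every`` epochs.
    """
    config.validate()
    A = _load_images(pseudo_images, config, "pseudo")
    B = _load_images(real_images, config, "real")
    g_ab, g_ba, d_a, d_b = _build_models(config)
    if config.initial_state is not None:
        for name, model in [("g_ab", g_ab), ("g_ba", g_ba), ("d_a", d_a), ("d_b", d_b)]:
            model.load_state_dict(config.initial_state[name])
    g_params = {f"ab.{k}": v for k, v in g_ab.parameters().items()}
    g_params.update({f"ba.{k}": v for k, v in g_ba.parameters().items()})
    opt_g = nn.Adam(g_params, config.lr, config.betas)
    opt_da = nn.Adam(d_a.parameters(), config.lr, config.betas)
    opt_db = nn.Adam(d_b.parameters(), config.lr, config.betas)
    rng = np.random.default_rng(config.seed)
    lam = config.lambda_cycle
    lam_idt = config.lambda_identity * lam
    log: list[dict] = []
    ckpt_dir = Path(checkpoint_dir) if checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    n_iter = max(len(A), len(B))
    for epoch in range(config.epochs):
        for opt in (opt_g, opt_da, opt_db):
            opt.set_epoch(epoch, config.epochs)
        ia = rng.permutation(len(A))
        ib = rng.permutation(len(B))
        sums = {"g_adv": 0.0, "g_cycle": 0.0, "g_idt": 0.0, "d_a": 0.0, "d_b": 0.0}
        for it in range(n_iter):
            a = nn.Tensor(A[ia[it % len(A)]][None])
            b = nn.Tensor(B[ib[it % len(B)]][None])
            # generator update
            fake_b = g_ab(a)
            fake_a = g_ba(b)
            rec_a = g_ba(fake_b)
            rec_b = g_ab(fake_a)
            l_adv = nn.add(nn.mse_loss(d_b(fake_b), 1.0), nn.mse_loss(d_a(fake_a), 1.0))
            l_cyc = nn.scale(nn.add(nn.l1_loss(rec_a, a.data), nn.l1_loss(rec_b, b.data)), lam)
            l_idt = nn.scale(
                nn.add(nn.l1_loss(g_ab(b), b.data), nn.l1_loss(g_ba(a), a.data)), lam_idt
            ) if lam_idt > 0 else None
            loss_g = nn.add(l_adv, l_cyc) if l_idt is None else nn.add(nn.add(l_adv, l_cyc), l_idt)
            opt_g.zero_grad(); opt_da.zero_grad(); opt_db.zero_grad()
            loss_g.backward()
            opt_g.step()
            # discriminator updates on detached fakes
            fb = nn.Tensor(fake_b.data.copy())
            fa = nn.Tensor(fake_a.data.copy())
            l_db = nn.scale(nn.add(nn.mse_loss(d_b(b), 1.0), nn.mse_loss(d_b(fb), 0.0)), 0.5)
            opt_db.zero_grad(); l_db.backward(); opt_db.step()
            l_da = nn.scale(nn.add(nn.mse_loss(d_a(a), 1.0), nn.mse_loss(d_a(fa), 0.0)), 0.5)
            opt_da.zero_grad(); l_da.backward(); opt_da.step()
            sums["g_adv"] += float(l_adv.data)
            sums["g_cycle"] += float(l_cyc.data) / lam
            sums["g_idt"] += float(l_idt.data) / lam_idt if l_idt is not None else 0.0
            sums["d_a"] += float(l_da.data)
            sums["d_b"] += float(l_db.data)
        entry = {"epoch": epoch + 1, **{k: v / n_iter for k, v in sums.items()}}
        if not all(np.isfinite(v) for v in entry.values()):
            raise RuntimeError(f"non-finite loss at epoch {epoch + 1}: {entry}")
        log.append(entry)
        if ckpt_dir and (epoch + 1) % config.checkpoint_every == 0:
            state = _full_state(g_ab, g_ba, d_a, d_b)
            _save_checkpoint(ckpt_dir / f"ckpt_epoch_{epoch + 1:03d}.npz", state, config, log)
    return TrainedTransform(
        generator_state=g_ab.state_dict(),
        full_state=_full_state(g_ab, g_ba, d_a, d_b),
        config=config,
        log=log,
    )


def _full_state(g_ab, g_ba, d_a, d_b):
    return {"g_ab": g_ab.state_dict(), "g_ba": g_ba.state_dict(),
            "d_a": d_a.state_dict(), "d_b": d_b.state_dict()}


def init_from(previous: TrainedTransform, epochs: int = 100, **overrides) -> CycleGANConfig:
    """Config warm-started from a trained transform (fine-tuning setup).

    The returned config carries the donor's full network state; architecture
    fields cannot be overridden (a mismatch would invalidate the weights).
    """
    cfg = dataclasses.replace(previous.config, epochs=epochs, initial_state=previous.full_state, **overrides)
    if cfg.arch_key() != previous.config.arch_key():
        raise ValidationError("architecture overrides are incompatible with the donor weights")
    return cfg


def apply_generator(transform: TrainedTransform, images: np.ndarray) -> np.ndarray:
    """Run the pseudo->real generator on an (N, H, W) stack in [0, 1]."""
    cfg = transform.config
    g = nn.UNet(1, 1, cfg.levels, cfg.base_channels, cfg.max_channels,
                cfg.image_size, final="tanh", seed=0)
    g.load_state_dict(transform.generator_state)
    out = []
    with nn.no_grad():
        for img in np.asarray(images, dtype=np.float32):
            y = g(nn.Tensor(img[None, None] * 2.0 - 1.0)).data[0, 0]
            out.append(np.clip((y + 1.0) / 2.0, 0.0, 1.0))
    return np.stack(out)


def transform_dataset(transform: TrainedTransform, pairs: list[PseudoPair]) -> list[PseudoPair]:
    """Replace each pair's image by the generator output, re-masked to its
    cone; label rasters are copied bit-identically."""
    out = []
    imgs = apply_generator(transform, np.stack([p.image for p in pairs])) if pairs else []
    for p, img in zip(pairs, imgs):
        prov = dict(p.provenance)
        prov["transformed"] = True
        out.append(PseudoPair(
            image=(img * p.cone_mask()).astype(np.float64),
            label=p.label.copy(),
            cone=p.cone,
            provenance=prov,
        ))
    return out


# ---------------------------------------------------------------------------
# checkpoint / transform serialization
# ---------------------------------------------------------------------------

def _config_json(config: CycleGANConfig) -> str:
    d = dataclasses.asdict(config)
    d.pop("initial_state")
    d["betas"] = list(d["betas"])
    return json.dumps(d)


def _save_checkpoint(path: Path, state: dict, config: CycleGANConfig, log: list[dict]) -> None:
    arrays = {}
    for model, sd in state.items():
        for k, v in sd.items():
            arrays[f"{model}/{k}"] = v
    np.savez(path, __config__=_config_json(config), __log__=json.dumps(log), **arrays)


def save_transform(transform: TrainedTransform, path: str | Path) -> Path:
    path = Path(path)
    _save_checkpoint(path, transform.full_state, transform.config, transform.log)
    return path


def load_transform(path: str | Path) -> TrainedTransform:
    with np.load(path, allow_pickle=False) as z:
        cfg_d = json.loads(str(z["__config__"]))
        cfg_d["betas"] = tuple(cfg_d["betas"])
        config = CycleGANConfig(**cfg_d)
        log = json.loads(str(z["__log__"]))
        state: dict[str, dict[str, np.ndarray]] = {}
        for key in z.files:
            if key.startswith("__"):
                continue
            model, pname = key.split("/", 1)
            state.setdefault(model, {})[pname] = z[key]
    return TrainedTransform(generator_state=state["g_ab"], full_state=state,
                            config=config, log=log)
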