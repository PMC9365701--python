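"""Training harness: patient-level splits, augmentation, fit loop.

The schedule is Adam at 1e-4 with a reduce-on-plateau rule (factor 0.1,
patience 10 epochs) and early stopping (patience 50), batch size 8, up to
200 epochs. The plateau and early-stop callbacks monitor validation loss
(the framework-default choice); best-weights selection monitors validation
dice. All of these are configurable for desk-scale runs.

Augmentation applies one random geometric transform per sample — horizontal
/ vertical flips, small rotation, small shift — identically to both image
channels and to the label; labels are resampled nearest-neighbour so they
stay binary.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import NeolesionError
from .loss import LossParams, dice_score, total_loss
from .model import UNet, save_checkpoint
from .nn import Adam, Tensor
from .slicer import SliceRecord
from .volio import LongitudinalCase


@dataclasses.dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    plateau_patience: int = 10
    plateau_factor: float = 0.1
    batch_size: int = 8
    max_epochs: int = 200
    early_stop_patience: int = 50
    rotation_deg: float = 10.0
    shift_frac: float = 0.10
    flip_prob: float = 0.5
    augment: bool = True
    min_delta: float = 1e-4
    seed: int = 0
    loss: LossParams = dataclasses.field(default_factory=LossParams)

    def __post_init__(self):
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must be in (0,1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def split_by_patient(cases: list[LongitudinalCase], n_train: int, n_val: int,
                     seed: int) -> tuple[list[LongitudinalCase],
                                         list[LongitudinalCase]]:
    """Disjoint patient-level split, deterministic given the seed."""
    if n_train + n_val > len(cases):
        raise NeolesionError(
            f"requested {n_train}+{n_val} cases but only {len(cases)} given")
    order = np.random.default_rng(seed).permutation(len(cases))
    train = [cases[i] for i in order[:n_train]]
    val = [cases[i] for i in order[n_train:n_train + n_val]]
    return train, val


def augment(record: SliceRecord, rng: np.random.Generator,
            rotation_deg: float = 10.0, shift_frac: float = 0.10,
            flip_prob: float = 0.5) -> SliceRecord:
    """One random geometric transform, shared by both channels and label."""
    image = record.image
    label = record.label
    flip_h = rng.random() < flip_prob
    flip_v = rng.random() < flip_prob
    angle = rng.uniform(-rotation_deg, rotation_deg) if rotation_deg else 0.0
    h, w = image.shape[:2]
    shift = (rng.uniform(-shift_frac, shift_frac) * h,
             rng.uniform(-shift_frac, shift_frac) * w) if shift_frac else (0., 0.)

    def geom(arr: np.ndarray, order: int) -> np.ndarray:
        out = arr
        if flip_h:
            out = out[:, ::-1]
        if flip_v:
            out = out[::-1, :]
        if angle:
            out = ndimage.rotate(out, angle, axes=(0, 1), reshape=False,
                                 order=order, mode="constant", cval=0.0)
        if shift != (0.0, 0.0):
            shift_nd = shift + (0.,) * (out.ndim - 2)
            out = ndimage.shift(out, shift_nd, order=order, mode="constant",
                                cval=0.0)
        return np.ascontiguousarray(out)

    new_image = geom(image, order=1).astype(image.dtype)
    new_label = None
    if label is not None:
        new_label = geom(label.astype(np.float32), order=0)
        new_label = (new_label > 0.5).astype(label.dtype)
    return dataclasses.replace(record, image=new_image, label=new_label)


def _pool_to_arrays(pool: list[SliceRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(N, C, H, W) images and (N, 1, H, W) labels, channel-first."""
    x = np.stack([rec.image.transpose(2, 0, 1) for rec in pool]).astype(
        np.float32)
    y = np.stack([rec.label[None] for rec in pool]).astype(np.float32)
    return x, y


def _validate(model: UNet, x: np.ndarray, y: np.ndarray, batch_size: int,
              loss_params: LossParams) -> tuple[float, float]:
    """(mean slice dice at threshold 0.5, mean loss) on a validation pool."""
    probs = model.predict(x, batch_size=batch_size)
    pred = probs >= 0.5
    dice = float(np.mean([dice_score(y[i], pred[i]) for i in range(len(x))]))
    loss = float(total_loss(y, probs, loss_params, batch_axis=0))
    return dice, loss


def fit(model: UNet, train_pool: list[SliceRecord],
        val_pool: list[SliceRecord], cfg: TrainConfig,
        run_dir=None) -> tuple[dict[str, np.ndarray], list[dict]]:
    """Train ``model``; returns (best weights state, per-epoch history).

    The model is left loaded with the best-validation-dice weights. If
    ``run_dir`` is given, a config snapshot, CSV history and the best
    checkpoint are written there.
    """
    if not train_pool or not val_pool:
        raise NeolesionError("training and validation pools must be non-empty")
    if any(rec.label is None for rec in train_pool + val_pool):
        raise NeolesionError("all pooled slices must carry labels")

    rng = np.random.default_rng(cfg.seed)
    x_train, y_train = _pool_to_arrays(train_pool)
    x_val, y_val = _pool_to_arrays(val_pool)

    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    best_dice = -np.inf
    best_loss = np.inf
    best_state = model.named_state()
    best_state = {k: v.copy() for k, v in best_state.items()}
    stalled = 0
    plateau_stalled = 0
    history: list[dict] = []

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(train_pool))
        epoch_losses = []
        train_dices = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if cfg.augment:
                recs = [augment(train_pool[i], rng, cfg.rotation_deg,
                                cfg.shift_frac, cfg.flip_prob) for i in idx]
                xb, yb = _pool_to_arrays(recs)
            else:
                xb, yb = x_train[idx], y_train[idx]
            model.zero_grad()
            pr = model.forward(xb, training=True)
            loss = total_loss(Tensor(yb), pr, cfg.loss, batch_axis=0)
            loss.backward()
            optimizer.step()
            epoch_losses.append(loss.item())
            pred = pr.data >= 0.5
            train_dices.append(np.mean([dice_score(yb[i], pred[i])
                                        for i in range(len(yb))]))

        val_dice, val_loss = _validate(model, x_val, y_val, cfg.batch_size,
                                       cfg.loss)
        history.append({
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "train_dice": float(np.mean(train_dices)),
            "val_loss": val_loss,
            "val_dice": val_dice,
            "lr": optimizer.lr,
        })

        # checkpoint selection tracks validation dice
        if val_dice > best_dice + cfg.min_delta:
            best_dice = val_dice
            best_state = {k: v.copy() for k, v in model.named_state().items()}
        # schedule callbacks track validation loss
        if val_loss < best_loss - cfg.min_delta:
            best_loss = val_loss
            stalled = 0
            plateau_stalled = 0
        else:
            stalled += 1
            plateau_stalled += 1
            if plateau_stalled >= cfg.plateau_patience:
                optimizer.lr *= cfg.plateau_factor
                plateau_stalled = 0
            if stalled >= cfg.early_stop_patience:
                break

    model.load_state(best_state)
    if run_dir is not None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        cfg_dict = dataclasses.asdict(cfg)
        (run_dir / "train_config.json").write_text(
            json.dumps(cfg_dict, indent=1))
        with open(run_dir / "history.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(history[0]))
            writer.writeheader()
            writer.writerows(history)
        save_checkpoint(model, run_dir / "best_model.npz")
    return best_state, history
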