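"""Base training and few-shot fine-tuning recipes.

The base recipe follows the published setup: AdamW (initial learning rate
2e-4, weight decay 1e-2), cosine annealing with warm restarts (W0 = 10
epochs, period multiplier F = 2) over 1,200 epochs, minibatches of 32, an
8:1:1 stratified train/validation/test split, and flip/rotation/contrast
augmentation.  The segmentation loss is applied only to full-worm samples
(only full worms carry ground-truth masks); the 3-way occupancy
classification loss is applied to every sample.

Few-shot fine-tuning mixes ``n_new`` samples of a shifted domain with an
equal number of original-domain samples (guarding against catastrophic
forgetting) and trains for 250 epochs under a one-cycle cosine schedule.
The published fine-tuning peak learning rate is 1e-6; it is exposed in
``TrainConfig.max_lr`` since appropriate peaks scale with model size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .nn import AdamW, Tensor
from .model import CLASS_INDEX, ModelOutput, WormSegNet
from .preprocess import InputTensor
from .synthetic_data import CLASS_LABELS

__all__ = [
    "TrainConfig", "LabeledSample", "stratified_split", "augment", "loss",
    "lr_schedule", "warm_restart_epochs", "train", "finetune_few_shot",
    "samples_from_records",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    epochs: int = 1200
    lr0: float = 2e-4
    weight_decay: float = 1e-2
    scheduler: str = "warm_restarts"      # or "one_cycle"
    warm_restart_period: int = 10         # W0
    warm_restart_mult: int = 2            # F
    lr_min_factor: float = 1000.0         # lr_min = lr0 / factor
    max_lr: float = 1e-6                  # one-cycle peak (fine-tuning)
    one_cycle_pct_start: float = 0.3
    split_ratio: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    loss_weights: tuple[float, float] = (1.0, 1.0)   # (segmentation, class)
    flip: bool = True
    rotate_deg: float = 5.0
    gamma_range: tuple[float, float] = (0.7, 1.3)

    def __post_init__(self):
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split_ratio must sum to 1")

    @classmethod
    def few_shot(cls, **overrides) -> "TrainConfig":
        kw = dict(scheduler="one_cycle", epochs=250)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class LabeledSample:
    """A network input with its class label and (for full worms) a mask."""

    input: InputTensor
    class_label: str
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if (self.mask is not None) != (self.class_label == "full"):
            raise ValueError(
                "mask must be present exactly for full-worm samples "
                f"(label={self.class_label!r}, mask "
                f"{'present' if self.mask is not None else 'absent'})"
            )


# ---------------------------------------------------------------------------
# data handling
# ---------------------------------------------------------------------------

def samples_from_records(records, n_planes: int = 1,
                         pad_to: int | None = None) -> list[LabeledSample]:
    """Build labeled network samples from generated/loaded channel records.

    Masks are attached for full-worm channels only (the annotation protocol
    segments full worms exclusively); masks are padded to match the network
    input width.
    """
    from .preprocess import assemble_input, default_pad_width

    samples = []
    for rec in records:
        width = rec.stack.volume.shape[-1]
        p = pad_to if pad_to is not None else default_pad_width(width)
        inp = assemble_input(rec.stack, t=0, n_planes=n_planes, pad_to=p)
        mask = None
        if rec.class_label == "full":
            mask = np.pad(rec.mask, ((0, 0), (inp.pad_left, inp.pad_right)))
        samples.append(LabeledSample(input=inp, class_label=rec.class_label,
                                     mask=mask))
    return samples


def stratified_split(
    samples: list,
    ratio: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    label_of=lambda s: s.class_label,
    classes=CLASS_LABELS,
) -> tuple[list, list, list]:
    """Class-stratified train/validation/test split.

    Within each class the samples are shuffled (seeded) and divided by the
    ratio with largest-remainder rounding, so per-class proportions in every
    split stay within one sample of the global proportions.  Splits are
    disjoint and deterministic for a fixed seed.  Raises if a required class
    has no samples (pass ``classes=None`` to stratify over observed labels).
    """
    by_class: dict[str, list] = {}
    for s in samples:
        by_class.setdefault(label_of(s), []).append(s)
    if classes is not None:
        for c in classes:
            if not by_class.get(c):
                raise ValueError(f"class {c!r} has no samples")
    rng = np.random.default_rng(seed)
    splits: tuple[list, list, list] = ([], [], [])
    exact_total = [0.0, 0.0, 0.0]
    for label in sorted(by_class):
        group = by_class[label]
        order = rng.permutation(len(group))
        n = len(group)
        exact = [r * n for r in ratio]
        counts = [math.floor(e) for e in exact]
        # distribute the remainder by largest fractional part, breaking
        # ties toward the split furthest below its exact cumulative size
        for _ in range(n - sum(counts)):
            frac = [e - c for e, c in zip(exact, counts)]
            deficit = [et + e - (len(s) + c)
                       for et, e, s, c in zip(exact_total, exact, splits,
                                              counts)]
            pick = max(range(3), key=lambda i: (round(frac[i], 9),
                                                round(deficit[i], 9), -i))
            counts[pick] += 1
        start = 0
        for si, cnt in enumerate(counts):
            splits[si].extend(group[i] for i in order[start : start + cnt])
            start += cnt
        for si in range(3):
            exact_total[si] += exact[si]
    return splits


def augment(sample: LabeledSample, rng: np.random.Generator,
            cfg: TrainConfig | None = None) -> LabeledSample:
    """Random flips, small rotation and gamma-contrast adjustment.

    Geometric transforms are applied identically to all image planes and to
    the mask; the class label never changes.  Rotation uses bilinear
    interpolation with edge replication for the images and nearest-neighbour
    for the mask, limited to ``±cfg.rotate_deg`` degrees.
    """
    cfg = cfg or TrainConfig()
    planes = sample.input.planes
    mask = sample.mask
    if cfg.flip:
        if rng.random() < 0.5:
            planes = planes[..., ::-1]
            mask = mask[..., ::-1] if mask is not None else None
        if rng.random() < 0.5:
            planes = planes[..., ::-1, :]
            mask = mask[..., ::-1, :] if mask is not None else None
    if cfg.rotate_deg > 0:
        angle = float(rng.uniform(-cfg.rotate_deg, cfg.rotate_deg))
        planes = ndimage.rotate(planes, angle, axes=(-2, -1), reshape=False,
                                order=1, mode="nearest")
        if mask is not None:
            mask = ndimage.rotate(mask.astype(np.uint8), angle, reshape=False,
                                  order=0, mode="constant").astype(bool)
    if cfg.gamma_range is not None:
        gamma = float(rng.uniform(*cfg.gamma_range))
        planes = np.clip(planes, 0.0, 1.0) ** gamma
    new_input = InputTensor(
        planes=np.ascontiguousarray(planes),
        focus_index=sample.input.focus_index,
        pad_left=sample.input.pad_left,
        pad_right=sample.input.pad_right,
        source=sample.input.source,
    )
    return LabeledSample(input=new_input, class_label=sample.class_label,
                         mask=np.ascontiguousarray(mask) if mask is not None
                         else None)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _class_log_probs(output: ModelOutput) -> Tensor | np.ndarray:
    if output.class_logits is not None:
        return output.class_logits.log_softmax(axis=-1)
    return np.log(np.clip(output.class_probs, 1e-30, 1.0))


def loss(output: ModelOutput, samples: list[LabeledSample],
         weights: tuple[float, float] = (1.0, 1.0)):
    """Total loss = w_seg * L_seg + w_cls * L_cls over a batch.

    ``L_cls`` is 3-way cross-entropy for every sample.  ``L_seg`` (soft-Dice
    plus per-pixel cross-entropy on the worm-class plane) is computed only
    over samples labeled full — other samples contribute exactly zero and no
    gradient reaches the decoder.  Non-negative; zero exactly when the
    prediction is perfect on a full-worm batch.
    """
    w_seg, w_cls = weights
    labels = np.array([CLASS_INDEX[s.class_label] for s in samples])
    logp = _class_log_probs(output)
    b = len(samples)
    if isinstance(logp, Tensor):
        onehot = np.zeros((b, logp.shape[-1]))
        onehot[np.arange(b), labels] = 1.0
        l_cls = -(logp * Tensor(onehot)).sum() * (1.0 / b)
    else:
        l_cls = Tensor(-logp[np.arange(b), labels].mean())

    full_idx = [i for i, s in enumerate(samples) if s.class_label == "full"]
    if full_idx:
        for i in full_idx:
            if samples[i].mask is None:
                raise ValueError(f"full-worm sample {i} is missing its mask")
        if output.seg_logits is not None:
            seg_lp = output.seg_logits[full_idx].log_softmax(axis=1)
            probs = seg_lp.exp()
        else:
            p = np.clip(output.soft_segmentation[full_idx], 1e-30, 1.0)
            probs = Tensor(p)
            seg_lp = Tensor(np.log(p))
        truth = np.stack([samples[i].mask for i in full_idx]).astype(float)
        tgt = np.stack([1.0 - truth, truth], axis=1)  # (n, 2, H, W)
        n_px = truth[0].size
        l_ce = -(seg_lp * Tensor(tgt)).sum() * (1.0 / (len(full_idx) * n_px))
        p_worm = probs[:, 1]
        t_worm = Tensor(truth)
        inter = (p_worm * t_worm).sum(axis=(1, 2))
        denom = p_worm.sum(axis=(1, 2)) + t_worm.sum(axis=(1, 2))
        eps = 1e-7
        dice = (inter * 2.0 + eps) / (denom + eps)
        l_dice = (1.0 - dice).mean()
        l_seg = l_ce + l_dice
    else:
        l_seg = Tensor(0.0)
    return l_seg * w_seg + l_cls * w_cls


# ---------------------------------------------------------------------------
# learning-rate schedules
# ---------------------------------------------------------------------------

def warm_restart_epochs(cfg: TrainConfig, through_epoch: int) -> list[int]:
    """Restart epochs 0, W0, W0(1+F), ... = W0 (F^k - 1)/(F - 1)."""
    out, e, period = [], 0, cfg.warm_restart_period
    while e <= through_epoch:
        out.append(e)
        e += period
        period *= cfg.warm_restart_mult
    return out


def lr_schedule(epoch: float, cfg: TrainConfig) -> float:
    """Learning rate at a (fractional) epoch.

    ``warm_restarts``: within each period of length W0*F^k the rate decays
    from lr0 to lr_min along a half cosine, then restarts.  ``one_cycle``:
    a single cosine rise to ``max_lr`` over the first ``pct_start`` of
    training followed by a cosine decay toward zero.
    """
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if cfg.scheduler == "warm_restarts":
        lr_min = cfg.lr0 / cfg.lr_min_factor
        period = cfg.warm_restart_period
        t = epoch
        while t >= period:
            t -= period
            period *= cfg.warm_restart_mult
        return lr_min + 0.5 * (cfg.lr0 - lr_min) * (
            1.0 + math.cos(math.pi * t / period)
        )
    if cfg.scheduler == "one_cycle":
        e_peak = cfg.one_cycle_pct_start * cfg.epochs
        lr_start = cfg.max_lr / 25.0
        if epoch <= e_peak:
            frac = epoch / e_peak if e_peak > 0 else 1.0
            return lr_start + 0.5 * (cfg.max_lr - lr_start) * (
                1.0 - math.cos(math.pi * frac)
            )
        frac = (epoch - e_peak) / max(cfg.epochs - e_peak, 1e-9)
        return 0.5 * cfg.max_lr * (1.0 + math.cos(math.pi * min(frac, 1.0)))
    raise ValueError(f"unknown scheduler {cfg.scheduler!r}")


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _validation_dice(model: WormSegNet, samples: list[LabeledSample],
                     threshold: float = 0.5) -> float:
    """Mean Dice over the full-worm samples of a validation set."""
    from .evaluation import dice as dice_score
    from .nn import no_grad

    vals = []
    with no_grad():
        for s in samples:
            if s.class_label != "full":
                continue
            out = model.forward(s.input)
            pred = out.soft_segmentation[0, 1] >= threshold
            vals.append(dice_score(pred, s.mask))
    return float(np.mean(vals)) if vals else float("nan")


def train(
    model: WormSegNet,
    samples: list[LabeledSample],
    cfg: TrainConfig,
    val_samples: list[LabeledSample] | None = None,
    use_augment: bool = True,
) -> tuple[WormSegNet, dict]:
    """Seeded minibatch training loop.

    Runs ``cfg.epochs`` epochs of shuffled minibatches with augmentation,
    the configured loss and learning-rate schedule.  Validation Dice is
    tracked per epoch when ``val_samples`` is given and the
    best-validation-Dice checkpoint is restored at the end; otherwise the
    final weights are returned.  Aborts with a diagnostic on NaN loss.
    Returns ``(model, history)`` with per-epoch losses, learning rates and
    validation Dice.
    """
    if cfg.epochs > 0 and not samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr0,
                weight_decay=cfg.weight_decay)
    history = {"epoch_loss": [], "val_dice": [], "lr": []}
    best = (-np.inf, None)
    n = len(samples)
    steps = max(1, math.ceil(n / cfg.batch_size))
    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        opt.lr = lr
        order = rng.permutation(n)
        epoch_losses = []
        for step in range(steps):
            idx = order[step * cfg.batch_size : (step + 1) * cfg.batch_size]
            if idx.size == 0:
                continue
            batch = [samples[i] for i in idx]
            if use_augment:
                batch = [augment(s, rng, cfg) for s in batch]
            out = model.forward([s.input for s in batch])
            total = loss(out, batch, cfg.loss_weights)
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"training diverged: loss={float(total.data)} at epoch "
                    f"{epoch}, lr={lr:.3g}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_losses.append(float(total.data))
        history["epoch_loss"].append(float(np.mean(epoch_losses)))
        history["lr"].append(lr)
        if val_samples:
            vd = _validation_dice(model, val_samples)
            history["val_dice"].append(vd)
            if vd >= best[0]:
                best = (vd, model.state_dict())
    if val_samples and best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


def finetune_few_shot(
    model: WormSegNet,
    new_samples: list[LabeledSample],
    old_samples: list[LabeledSample],
    n_new: int,
    cfg: TrainConfig | None = None,
    val_samples: list[LabeledSample] | None = None,
) -> tuple[WormSegNet, dict]:
    """Fine-tune on ``n_new`` shifted-domain samples mixed 1:1 with old ones.

    The training corpus is the first ``n_new`` new-domain samples plus an
    equal number of original-domain samples (seeded draw), trained under the
    one-cycle schedule.  ``n_new = 0`` returns the model unchanged.
    """
    cfg = cfg or TrainConfig.few_shot()
    if n_new > len(new_samples):
        raise ValueError(f"n_new={n_new} exceeds available new samples "
                         f"({len(new_samples)})")
    if n_new == 0:
        return model, {"epoch_loss": [], "val_dice": [], "lr": []}
    if n_new > len(old_samples):
        raise ValueError(
            f"need {n_new} old-domain samples for 1:1 mixing, have "
            f"{len(old_samples)}"
        )
    rng = np.random.default_rng(cfg.seed)
    old_pick = rng.choice(len(old_samples), size=n_new, replace=False)
    corpus = list(new_samples[:n_new]) + [old_samples[i] for i in old_pick]
    if cfg.scheduler != "one_cycle":
        cfg = replace(cfg, scheduler="one_cycle")
    return train(model, corpus, cfg, val_samples=val_samples)
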