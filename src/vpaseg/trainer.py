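"""Template-based training: learn a segmentation network from one image.

Every epoch draws fresh augmented pairs from the single template, forwards
them one at a time, and accumulates gradients of the mean-per-image MSE; the
optimizer (Adam) then takes exactly one step, so an epoch with n images is
equivalent to a batch of n.  Training proceeds in rounds with decreasing
learning rates and increasing per-epoch image counts (defaults: 1000 epochs x
8 images at lr 1e-3, then 2000 x 16 at 5e-4, then 2000 x 32 at 2.5e-4).

Because there is only one labeled example, convergence is tracked with two
surrogates rather than a held-out split: the *template error* — the loss on
the original, never-augmented template, evaluated without any backpropagation
— and, when an unseen subject pair is supplied, the *evaluation error*, which
is inflated slightly relative to a true test error whenever the subject's
label comes from an independent source.  Both are split into foreground
(label != 0) and background components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import unet3d
from .augment import AugmentConfig, RandomStream, augment_once
from .postprocess import brain_mask, clip_probs, argmax_label
from .unet3d import Adam, UNet3D, UNetSpec
from .volume_io import LabelVolume, N_TISSUES, ScalarVolume, TemplatePair


@dataclass
class RoundSpec:
    epochs: int
    images_per_epoch: int
    learning_rate: float


#: The full-scale three-round schedule.
DEFAULT_ROUNDS: list[RoundSpec] = [
    RoundSpec(1000, 8, 0.001),
    RoundSpec(2000, 16, 0.0005),
    RoundSpec(2000, 32, 0.00025),
]


@dataclass
class ErrorRecord:
    round: int
    epoch: int
    training_mse: float
    template_fg_mse: float | None = None
    template_bg_mse: float | None = None
    eval_fg_mse: float | None = None
    eval_bg_mse: float | None = None


def encode_onehot(label: LabelVolume | np.ndarray) -> np.ndarray:
    """One-hot tissue target: channel k-1 is 1 where label == k (k = 1..5).

    Background voxels encode as all-zero across the five channels, so the
    channel sum per voxel is 0 (background) or 1 (tissue).
    """
    data = label.data if isinstance(label, LabelVolume) else np.asarray(label)
    out = np.zeros((N_TISSUES,) + data.shape, dtype=np.float32)
    for k in range(1, N_TISSUES + 1):
        out[k - 1] = data == k
    return out


def train_epoch(
    model: UNet3D,
    template: TemplatePair,
    n_images: int,
    lr: float,
    rng: RandomStream,
    cfg: AugmentConfig,
    optimizer: Adam | None = None,
) -> float:
    """One accumulation epoch: n_images augmented draws, one optimizer step.

    Gradients of the per-image loss are averaged over the n_images (each
    image's gradient is scaled by 1/n), so the step matches a batch-mean
    update.  Returns the mean per-image training MSE.
    """
    if optimizer is None:
        optimizer = Adam(model.params(), lr=lr)
    optimizer.lr = lr
    model.zero_grad()
    losses = []
    for i in range(n_images):
        pair = augment_once(template, rng.child(i), cfg)
        target = encode_onehot(pair.label)
        pred = model.forward(pair.image.data, training=True)
        l_i = unet3d.loss(pred, target)
        if not np.isfinite(l_i):
            raise RuntimeError(
                f"non-finite training loss ({l_i}) at image {i}; "
                f"lr={lr}, n_images={n_images}")
        losses.append(l_i)
        model.backward(unet3d.loss_grad(pred, target) / n_images)
    optimizer.step()
    return float(np.mean(losses))


def template_error(model: UNet3D, template: TemplatePair) -> tuple[float, float]:
    """(foreground, background) MSE on the original, unaugmented template.

    The template is never trained on directly; this is a pure eval-mode
    forward pass with no gradient side effects.
    """
    pred = model.forward(template.image.data, training=False)
    target = encode_onehot(template.label)
    fg = template.label.data != 0
    diff2 = (pred.astype(np.float64) - target) ** 2
    fg_mse = float(diff2[:, fg].mean()) if fg.any() else 0.0
    bg = ~fg
    bg_mse = float(diff2[:, bg].mean()) if bg.any() else 0.0
    return fg_mse, bg_mse


def train_schedule(
    template: TemplatePair,
    rounds: list[RoundSpec],
    rng: RandomStream,
    cfg: AugmentConfig,
    eval_pair: TemplatePair | None = None,
    model: UNet3D | None = None,
    spec: UNetSpec | None = None,
    eval_every: int = 1,
    verbose: bool = False,
) -> tuple[UNet3D, list[ErrorRecord]]:
    """Run the multi-round schedule on one model; one ErrorRecord per epoch.

    Template (and optional evaluation) errors are computed on the first epoch,
    the last epoch, and every ``eval_every``-th epoch in between; skipped
    epochs carry None in those fields.  Epoch streams are derived by
    counter-based splitting, so any epoch is reproducible in isolation.
    """
    if model is None:
        model = unet3d.build(spec or UNetSpec(), seed=int(rng.child(0xBEEF).integers(2**31)))
    records: list[ErrorRecord] = []
    if not rounds:
        return model, records
    optimizer = Adam(model.params(), lr=rounds[0].learning_rate)
    total_epochs = sum(r.epochs for r in rounds)
    done = 0
    for ridx, rnd in enumerate(rounds):
        for epoch in range(rnd.epochs):
            ep_rng = rng.child(ridx, epoch)
            tr_mse = train_epoch(model, template, rnd.images_per_epoch,
                                 rnd.learning_rate, ep_rng, cfg, optimizer)
            rec = ErrorRecord(round=ridx, epoch=epoch, training_mse=tr_mse)
            done += 1
            if done == 1 or done == total_epochs or done % eval_every == 0:
                rec.template_fg_mse, rec.template_bg_mse = template_error(model, template)
                if eval_pair is not None:
                    rec.eval_fg_mse, rec.eval_bg_mse = template_error(model, eval_pair)
            records.append(rec)
            if verbose and (done % max(1, total_epochs // 20) == 0 or done == 1):
                print(f"[round {ridx}] epoch {epoch + 1}/{rnd.epochs} "
                      f"training_mse={tr_mse:.5f}", flush=True)
    return model, records


def label_template_with_model(
    model: UNet3D, new_template_image: ScalarVolume | np.ndarray
) -> LabelVolume:
    """Label a new template with an existing model (transfer labeling).

    This is how a model trained on one species' template can bootstrap
    training for a related species: run the full post-processing chain on the
    network output and use the resulting label as the new training target.
    """
    if isinstance(new_template_image, ScalarVolume):
        data = new_template_image.data
        spacing, affine = new_template_image.spacing, new_template_image.affine
    else:
        data = np.asarray(new_template_image)
        spacing, affine = (1.0, 1.0, 1.0), None
    probs = clip_probs(model.forward(data, training=False))
    mask = brain_mask(probs)
    if not mask.any():
        raise ValueError("transfer labeling produced an empty brain mask")
    lab = argmax_label(probs, mask)
    return LabelVolume(lab, spacing, affine)


def records_to_rows(records: list[ErrorRecord]) -> list[dict]:
    """Flatten ErrorRecords for CSV output."""
    return [
        {
            "round": r.round, "epoch": r.epoch, "training_mse": r.training_mse,
            "template_fg_mse": r.template_fg_mse, "template_bg_mse": r.template_bg_mse,
            "eval_fg_mse": r.eval_fg_mse, "eval_bg_mse": r.eval_bg_mse,
        }
        for r in records
    ]
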