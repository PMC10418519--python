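"""Error analysis and augmentation ablations at desk scale.

The central mechanistic question: does the full augmentation family close the
gap between template error (loss on the training template) and evaluation
error (loss on an unseen subject), where rigid motion alone overfits?  An
:class:`AblationArm` names the enabled augmentation step groups; every arm
keeps rigid motion as the common baseline.  Arms are trained on the same
phantom with pinned seeds and their per-epoch error curves are written to CSV
and log-scale plots.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentConfig, RandomStream
from .phantom import PhantomSpec, make_subject, make_template
from .trainer import RoundSpec, records_to_rows, train_schedule
from .volume_io import N_TISSUES, LabelVolume, TemplatePair

STEP_GROUPS = ("rigid", "camera", "reduction", "crop", "lighting", "textures")


@dataclass
class AblationArm:
    """A named subset of augmentation step groups; rigid motion is mandatory."""

    name: str
    steps: frozenset[str]

    def __post_init__(self) -> None:
        self.steps = frozenset(self.steps)
        unknown = self.steps - set(STEP_GROUPS)
        if unknown:
            raise ValueError(f"unknown augmentation steps: {sorted(unknown)}")
        if "rigid" not in self.steps:
            raise ValueError("every ablation arm keeps rigid motion enabled")


RIGID_ONLY = AblationArm("rigid_only", frozenset({"rigid"}))
ALL_STEPS = AblationArm(
    "all_augmentations",
    frozenset({"rigid", "camera", "reduction", "lighting", "textures"}),
)


def arm_config(arm: AblationArm, base: AugmentConfig | None = None) -> AugmentConfig:
    """Translate an arm's enabled step groups into an AugmentConfig.

    Disabled groups are degenerated to the identity (probability 0 / unit
    ranges) rather than removed, so the pipeline order is identical across
    arms.
    """
    cfg = base or AugmentConfig()
    updates: dict = {}
    if "camera" not in arm.steps:
        updates.update(scale_range=(1.0, 1.0), aspect_range=(1.0, 1.0),
                       perspective_range=(0.0, 0.0), distortion_max=0.0)
    if "reduction" not in arm.steps:
        updates.update(p_subsample_per_dim=0.0, p_noise=0.0)
    if "lighting" not in arm.steps:
        updates.update(p_each_light=0.0)
    if "textures" not in arm.steps:
        updates.update(p_each_texture=0.0)
    updates.update(crop_enabled="crop" in arm.steps)
    return replace(cfg, **updates)


def fg_bg_mse(pred: np.ndarray, target_onehot: np.ndarray,
              label: np.ndarray) -> tuple[float, float]:
    """MSE split over foreground (label != 0) and background (label == 0) voxels."""
    pred = np.asarray(pred, dtype=np.float64)
    target_onehot = np.asarray(target_onehot, dtype=np.float64)
    label = label.data if isinstance(label, LabelVolume) else np.asarray(label)
    if pred.shape != target_onehot.shape or pred.shape[1:] != label.shape:
        raise ValueError(
            f"dimension mismatch: pred {pred.shape}, target {target_onehot.shape}, "
            f"label {label.shape}")
    fg = label != 0
    if not fg.any():
        raise ValueError("empty foreground: no voxel has a nonzero label")
    diff2 = (pred - target_onehot) ** 2
    fg_mse = float(diff2[:, fg].mean())
    bg = ~fg
    bg_mse = float(diff2[:, bg].mean()) if bg.any() else 0.0
    return fg_mse, bg_mse


def dice(label_a: np.ndarray, label_b: np.ndarray, tissue: int) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) for one tissue; 1.0 when both empty."""
    a = (label_a.data if isinstance(label_a, LabelVolume) else np.asarray(label_a)) == tissue
    b = (label_b.data if isinstance(label_b, LabelVolume) else np.asarray(label_b)) == tissue
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def run_ablation(
    arms: list[AblationArm],
    phantom_spec: PhantomSpec | None = None,
    budget: RoundSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    eval_every: int = 10,
    subject_seed: int | None = None,
    verbose: bool = False,
) -> dict:
    """Train one seed-pinned model per arm on the same phantom; collect curves.

    Every arm sees the same template, the same unseen subject, the same model
    initialization, and the same per-epoch random streams — only the
    augmentation config differs.  Returns
    ``{"template", "subject", "arms": {name: {"model", "records", "curves"}}}``;
    with ``out_dir`` set, also writes ``curves.csv`` and one log-scale error
    plot per arm.
    """
    phantom_spec = phantom_spec or PhantomSpec()
    budget = budget or RoundSpec(epochs=300, images_per_epoch=1, learning_rate=1e-3)
    template = make_template(phantom_spec)
    subject = make_subject(template, seed=phantom_spec.seed + 1
                           if subject_seed is None else subject_seed)
    results: dict = {"template": template, "subject": subject, "arms": {}}
    frames = []
    for arm in arms:
        cfg = arm_config(arm)
        rng = RandomStream(seed)  # identical streams across arms by design
        model, records = train_schedule(
            template, [budget], rng, cfg, eval_pair=subject,
            eval_every=eval_every, verbose=verbose)
        curves = pd.DataFrame(records_to_rows(records))
        curves.insert(0, "arm", arm.name)
        frames.append(curves)
        results["arms"][arm.name] = {
            "model": model, "records": records, "curves": curves,
        }
    all_curves = pd.concat(frames, ignore_index=True)
    results["curves"] = all_curves
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        all_curves.to_csv(out_dir / "curves.csv", index=False)
        for arm in arms:
            _plot_curves(results["arms"][arm.name]["curves"],
                         out_dir / f"errors_{arm.name}.png", arm.name)
    return results


def overfit_gap(records) -> float:
    """Terminal evaluation-minus-template foreground error gap of one run."""
    evald = [r for r in records if r.eval_fg_mse is not None]
    if not evald:
        raise ValueError("no epochs carry evaluation errors")
    last = evald[-1]
    return last.eval_fg_mse - last.template_fg_mse


def _plot_curves(curves: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(curves)) + 1
    ax.plot(x, curves["training_mse"], color="gray", label="training")
    have = curves["template_fg_mse"].notna()
    ax.plot(x[have], curves.loc[have, "template_fg_mse"], color="tab:orange",
            label="template fg")
    ax.plot(x[have], curves.loc[have, "template_bg_mse"], color="saddlebrown",
            label="template bg")
    if curves["eval_fg_mse"].notna().any():
        ax.plot(x[have], curves.loc[have, "eval_fg_mse"], color="tab:blue",
                label="evaluation fg")
        ax.plot(x[have], curves.loc[have, "eval_bg_mse"], color="navy",
                label="evaluation bg")
    ax.set_yscale("log")
    ax.set_xlabel("epoch")
    ax.set_ylabel("MSE (log scale)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
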