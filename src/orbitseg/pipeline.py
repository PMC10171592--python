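"""Training, evaluation, and the repeated-split model-comparison protocol.

Training follows the stated experimental recipe: AdamW (learning rate 1e-3,
weight decay 1e-4), batch size 16, focal Tversky loss on sigmoid outputs,
a fixed number of epochs, and checkpoint selection by minimum validation
loss (earliest epoch on ties).  Evaluation binarizes probabilities at 0.5
and reports per-image Dice and IoU.

``run_comparison`` repeats the random 0.7/0.15/0.15 split, trains every
candidate network on the identical split within each repetition (so the
comparison is paired), and reports per-model mean +/- SD over repetitions
together with a two-sided paired t-test of every other model against the
best one, flagged at p < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as oio
from .metrics import binarize, confusion, dice, iou
from .net import Checkpoint, EncoderDecoderNet
from .nn.optim import AdamW
from .objective import TverskyParams, focal_tversky_grad, focal_tversky_loss
from .preprocess import SplitSpec, WindowSpec, apply_window, split_ids

__all__ = [
    "TrainConfig", "SliceSample", "load_samples", "make_pairs",
    "train", "evaluate", "EvalResult",
    "paired_t", "PairedTResult",
    "run_comparison", "EvalReport",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters."""

    batch_size: int = 16
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class SliceSample:
    """One slice with its ground-truth masks, in memory."""

    id: str
    plane: str
    image: np.ndarray            # HU, int
    masks: dict[str, np.ndarray]  # tissue -> bool


def load_samples(manifest, root=None) -> list[SliceSample]:
    """Materialize a manifest (path or DataFrame) into SliceSamples."""
    if not isinstance(manifest, pd.DataFrame):
        root = Path(root) if root is not None else Path(manifest).parent
        manifest = oio.read_manifest(manifest)
    elif root is None:
        raise ValueError("root directory required with a DataFrame manifest")
    root = Path(root)
    samples: dict[str, SliceSample] = {}
    for row in manifest.itertuples():
        if row.id not in samples:
            samples[row.id] = SliceSample(
                id=str(row.id), plane=str(row.plane),
                image=oio.read_image(root / row.image_path), masks={})
        samples[row.id].masks[row.tissue] = oio.read_mask_png(root / row.mask_path)
    return list(samples.values())


def make_pairs(samples: Sequence[SliceSample], tissue: str,
               window: WindowSpec = WindowSpec()) -> list[tuple[np.ndarray, np.ndarray]]:
    """Windowed-image / binary-target pairs for one tissue."""
    pairs = []
    for s in samples:
        if tissue not in s.masks:
            raise KeyError(f"sample {s.id} has no mask for {tissue!r}")
        pairs.append((apply_window(s.image, window),
                      s.masks[tissue].astype(np.float32)))
    return pairs


def _stack(pairs: Sequence[tuple[np.ndarray, np.ndarray]]):
    x = np.stack([p[0] for p in pairs])[..., None].astype(np.float32)
    y = np.stack([p[1] for p in pairs])[..., None].astype(np.float32)
    return x, y


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _validation_loss(net: EncoderDecoderNet, pairs, tversky: TverskyParams,
                     batch_size: int) -> float:
    """Focal Tversky loss with soft counts aggregated over the whole set."""
    tp = fp = fn = 0.0
    for i in range(0, len(pairs), batch_size):
        x, y = _stack(pairs[i:i + batch_size])
        p = net.predict_proba(x)
        tp += float(np.sum(p * y))
        fp += float(np.sum(p * (1.0 - y)))
        fn += float(np.sum((1.0 - p) * y))
    ti = (tp + tversky.epsilon) / (
        tp + tversky.alpha * fp + tversky.beta * fn + tversky.epsilon)
    return (1.0 - ti) ** tversky.gamma


def train(net: EncoderDecoderNet,
          train_set: Sequence[tuple[np.ndarray, np.ndarray]],
          val_set: Sequence[tuple[np.ndarray, np.ndarray]],
          config: TrainConfig = TrainConfig(),
          tversky: TverskyParams = TverskyParams()) -> Checkpoint:
    """Train and return the weights of the epoch with minimum validation loss.

    The per-epoch loss traces are kept in ``Checkpoint.meta`` so the
    selection rule is auditable after the fact.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = AdamW(net.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    train_trace: list[float] = []
    val_trace: list[float] = []
    best: tuple[float, int, dict] | None = None
    n = len(train_set)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            batch = [train_set[k] for k in order[i:i + config.batch_size]]
            x, y = _stack(batch)
            z = net.forward(x, training=True)
            p = _sigmoid(z)
            loss = focal_tversky_loss(p, y, tversky)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss}")
            dz = (focal_tversky_grad(p, y, tversky) * p * (1.0 - p)).astype(np.float32)
            opt.zero_grad()
            net.backward(dz)
            opt.step()
            losses.append(loss)
        train_trace.append(float(np.mean(losses)))
        vloss = _validation_loss(net, val_set, tversky, config.batch_size)
        if not np.isfinite(vloss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        val_trace.append(float(vloss))
        if best is None or vloss < best[0]:  # strict: earliest epoch on ties
            best = (float(vloss), epoch, net.state_dict())
    assert best is not None
    return Checkpoint(
        state=best[2], config=net.config, use_skips=net.use_skips,
        meta={"best_epoch": best[1], "best_val_loss": best[0],
              "train_loss": train_trace, "val_loss": val_trace,
              "train_config": {"batch_size": config.batch_size,
                               "learning_rate": config.learning_rate,
                               "weight_decay": config.weight_decay,
                               "epochs": config.epochs, "seed": config.seed},
              "tversky": {"alpha": tversky.alpha, "beta": tversky.beta,
                          "gamma": tversky.gamma}})


@dataclass
class EvalResult:
    dice_per_image: list[float]
    iou_per_image: list[float]

    @property
    def mean_dice(self) -> float:
        return float(np.mean(self.dice_per_image))

    @property
    def mean_iou(self) -> float:
        return float(np.mean(self.iou_per_image))


def evaluate(model, test_set: Sequence[tuple[np.ndarray, np.ndarray]],
             threshold: float = 0.5, batch_size: int = 16,
             predict=None) -> EvalResult:
    """Per-image Dice/IoU of a trained model on a held-out set.

    ``model`` is a network or Checkpoint; ``predict`` may override the
    probability function (useful for stubbed oracles in tests).
    """
    if predict is None:
        net = model.build_net() if isinstance(model, Checkpoint) else model
        predict = net.predict_proba
    dices, ious = [], []
    for i in range(0, len(test_set), batch_size):
        x, y = _stack(test_set[i:i + batch_size])
        p = predict(x)
        if p.shape != y.shape:
            raise ValueError(f"prediction shape {p.shape} != target {y.shape}")
        for k in range(x.shape[0]):
            c = confusion(binarize(p[k, ..., 0], threshold), y[k, ..., 0] >= 0.5)
            dices.append(dice(c))
            ious.append(iou(c))
    return EvalResult(dice_per_image=dices, iou_per_image=ious)


# ---------------------------------------------------------------------------
# Paired t-test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    df: int
    degenerate: bool = False


def paired_t(a: Sequence[float], b: Sequence[float]) -> PairedTResult:
    """Classical two-sided paired t-test on the differences a - b.

    Zero-variance differences are degenerate: identical samples give
    ``t = nan, p = 1``; a constant non-zero shift gives the limiting
    ``t = +/-inf, p = 0``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D sequences of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    mean = d.mean()
    sd = d.std(ddof=1)
    dof = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(t=float("nan"), p=1.0, df=dof, degenerate=True)
        return PairedTResult(t=float(np.sign(mean)) * float("inf"), p=0.0,
                             df=dof, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return PairedTResult(t=float(t), p=float(p), df=dof)


# ---------------------------------------------------------------------------
# Repeated-split comparison
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Raw per-repetition metrics plus the paired-test summary.

    ``raw`` has one row per (model, tissue, repetition) with the test-set
    mean Dice/IoU of that run.  ``summary_frame`` aggregates to
    mean +/- SD over repetitions and attaches, for every non-best model,
    the two-sided paired-t p-value against the best model of that
    (tissue, metric) block.
    """

    raw: pd.DataFrame
    repetitions: int
    alpha: float = 0.001

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for tissue, tdf in self.raw.groupby("tissue", sort=False):
            for metric in ("dice", "iou"):
                col = f"mean_{metric}"
                means = tdf.groupby("model", sort=False)[col].mean()
                best_model = means.idxmax()
                best_vals = tdf[tdf.model == best_model].sort_values("repetition")[col].to_numpy()
                for model, mdf in tdf.groupby("model", sort=False):
                    vals = mdf.sort_values("repetition")[col].to_numpy()
                    if model == best_model:
                        p = np.nan
                        degenerate = False
                    else:
                        res = paired_t(vals, best_vals)
                        p, degenerate = res.p, res.degenerate
                    rows.append({
                        "tissue": tissue, "metric": metric, "model": model,
                        "mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                        "best": model == best_model,
                        "p_vs_best": p,
                        "significant": (not np.isnan(p)) and p < self.alpha,
                        "degenerate_t": degenerate,
                    })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.summary_frame()
        lines = [f"Repeated-split comparison ({self.repetitions} repetitions, "
                 f"paired t-test vs best, alpha={self.alpha})"]
        for (tissue, metric), block in df.groupby(["tissue", "metric"], sort=False):
            lines.append(f"\n{tissue} — {metric}")
            for row in block.itertuples():
                star = " *" if row.significant else ""
                tag = "  (best)" if row.best else f"  p={row.p_vs_best:.4g}{star}"
                lines.append(f"  {row.model:<12} {100 * row.mean:6.1f} "
                             f"± {100 * row.sd:4.1f} %{tag}")
        return "\n".join(lines)


def run_comparison(model_builders: dict[str, Callable[[int], EncoderDecoderNet]],
                   samples: Sequence[SliceSample],
                   tissues: Sequence[str],
                   split_spec: SplitSpec = SplitSpec(),
                   train_config: TrainConfig = TrainConfig(),
                   tversky: TverskyParams = TverskyParams(),
                   window: WindowSpec = WindowSpec(),
                   threshold: float = 0.5) -> EvalReport:
    """Train every candidate on identical repeated splits and compare.

    Within each repetition all models see the same train/val/test partition,
    so per-repetition test means are paired across models.
    """
    if len(model_builders) < 2:
        raise ValueError("need at least two model builders to compare")
    by_id = {s.id: s for s in samples}
    ids = list(by_id)
    rows = []
    for r in range(split_spec.repetitions):
        tr_ids, va_ids, te_ids = split_ids(ids, split_spec, r)
        for t_i, tissue in enumerate(tissues):
            tr = make_pairs([by_id[i] for i in tr_ids], tissue, window)
            va = make_pairs([by_id[i] for i in va_ids], tissue, window)
            te = make_pairs([by_id[i] for i in te_ids], tissue, window)
            for m_i, (name, builder) in enumerate(model_builders.items()):
                net_seed = train_config.seed + 101 * r + 11 * m_i + t_i
                net = builder(net_seed)
                cfg = TrainConfig(batch_size=train_config.batch_size,
                                  learning_rate=train_config.learning_rate,
                                  weight_decay=train_config.weight_decay,
                                  epochs=train_config.epochs,
                                  seed=net_seed)
                ckpt = train(net, tr, va, cfg, tversky)
                net.load_state_dict(ckpt.state)
                res = evaluate(net, te, threshold, train_config.batch_size)
                rows.append({"model": name, "tissue": tissue, "repetition": r,
                             "mean_dice": res.mean_dice, "mean_iou": res.mean_iou})
    raw = pd.DataFrame(rows, columns=["model", "tissue", "repetition",
                                      "mean_dice", "mean_iou"])
    return EvalReport(raw=raw, repetitions=split_spec.repetitions)
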