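"""Training loop and segmentation metric suite.

Metrics
-------
The central score is the Dice coefficient between the predicted tumor mask
``S`` and the ground-truth mask ``G``,

.. math:: \\mathrm{Dice} = \\frac{2\\,|S \\cap G|}{|S| + |G|},

reported per case and aggregated as mean and variance.  The companion suite
follows the standard pixelwise confusion-matrix definitions — pixel accuracy
``(TP+TN)/total``, per-class mean pixel accuracy, sensitivity ``TP/(TP+FN)``,
specificity ``TN/(TN+FP)`` — plus the area under the pixelwise ROC curve
computed from pre-argmax tumor probabilities by the Mann–Whitney rank
statistic.  Conventions for degenerate inputs are explicit: Dice of two
empty masks is 1.0 (perfect prediction on a tumor-free slice is not
penalized), and a class absent from ``G`` scores 1.0 on its own accuracy.
Aggregate metrics come in both conventions, per-case-then-averaged
(``dice_mean``) and pooled over all pixels (``dice_pooled``).

Training
--------
Seeded mini-batch backpropagation with pixelwise cross-entropy on the
two-class softmax output, Adam optimizer, optional inverse-class-frequency
loss weighting and optional early stopping; the best-validation-Dice weights
are checkpointed and restored at the end.  Wavelet injection maps are
computed once per case before the first epoch and reused — the transform of
a fixed input never changes, so recomputing it every iteration would only
add time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata

from ._nn import Adam, softmax_cross_entropy
from .phantom_gen import MultimodalSlice, PhantomDataset
from .wfcn_arch import WfcnNetwork, compute_injection

__all__ = [
    "DataError",
    "TrainingError",
    "UndefinedMetricError",
    "TrainConfig",
    "TrainResult",
    "MetricsReport",
    "dice",
    "confusion_metrics",
    "auc",
    "train",
    "evaluate",
]


class DataError(ValueError):
    """Raised for unusable datasets (empty, or missing ground truth)."""


class TrainingError(RuntimeError):
    """Raised when optimization produces non-finite losses."""


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given input."""


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def _check_binary_pair(s: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(s)
    g = np.asarray(g)
    if s.shape != g.shape:
        raise ValueError(f"mask shapes differ: {s.shape} vs {g.shape}")
    for name, m in (("S", s), ("G", g)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} is not binary (values outside {{0,1}})")
    return s.astype(bool), g.astype(bool)


def dice(s: np.ndarray, g: np.ndarray) -> float:
    """Dice overlap 2|S∩G|/(|S|+|G|); 1.0 when both masks are empty."""
    s, g = _check_binary_pair(s, g)
    denom = int(s.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((s & g).sum()) / denom


def confusion_metrics(s: np.ndarray, g: np.ndarray
                      ) -> tuple[float, float, float, float]:
    """(pixel_accuracy, mean_pixel_accuracy, sensitivity, specificity).

    A class absent from ``G`` contributes accuracy 1.0 (nothing to miss).
    """
    s, g = _check_binary_pair(s, g)
    tp = int((s & g).sum())
    tn = int((~s & ~g).sum())
    npos = int(g.sum())
    nneg = g.size - npos
    pixel_accuracy = (tp + tn) / g.size
    sensitivity = tp / npos if npos else 1.0
    specificity = tn / nneg if nneg else 1.0
    mean_pixel_accuracy = (sensitivity + specificity) / 2.0
    return pixel_accuracy, mean_pixel_accuracy, sensitivity, specificity


def auc(prob_map: np.ndarray, g: np.ndarray) -> float:
    """Area under the pixelwise ROC curve via the Mann–Whitney rank statistic.

    Requires both classes present in ``G``; ties in the probabilities get
    averaged ranks, matching the trapezoidal all-thresholds ROC area.
    """
    p = np.asarray(prob_map, dtype=np.float64).ravel()
    gb = np.asarray(g).ravel()
    if not np.isin(gb, (0, 1)).all():
        raise ValueError("G is not binary")
    if p.shape != gb.shape:
        raise ValueError(f"shapes differ: {prob_map.shape} vs {g.shape}")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    npos = int(gb.sum())
    nneg = gb.size - npos
    if npos == 0 or nneg == 0:
        raise UndefinedMetricError(
            "AUC is undefined when G contains a single class")
    ranks = rankdata(p)
    return float((ranks[gb == 1].sum() - npos * (npos + 1) / 2) / (npos * nneg))


@dataclass
class MetricsReport:
    """Aggregate segmentation metrics over an evaluation set (fractions)."""

    dice_mean: float
    dice_variance: float
    dice_pooled: float
    pixel_accuracy: float
    mean_pixel_accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    per_case_dice: list[float]
    case_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.dice_mean - float(np.mean(self.per_case_dice))) > 1e-12:
            raise ValueError("dice_mean inconsistent with per_case_dice")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    def to_table(self, sep: str = ",") -> str:
        """Character-separated metric table (one metric per row)."""
        rows = [("metric", "value")]
        for f in ("dice_mean", "dice_variance", "dice_pooled",
                  "pixel_accuracy", "mean_pixel_accuracy", "sensitivity",
                  "specificity", "auc"):
            rows.append((f, repr(getattr(self, f))))
        return "\n".join(sep.join(r) for r in rows)


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    ``epochs`` defaults to 100, the full-scale protocol; scaled-down runs
    pass fewer.  ``class_weighting`` weights the cross-entropy by inverse
    class frequency of the training split, countering tumor sparsity.
    """

    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    early_stop_patience: int | None = None
    checkpoint_path: str | None = None
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainResult:
    """Per-epoch loss/metric history and the best-validation checkpoint."""

    history: dict[str, list[float]]
    best_epoch: int
    best_val_dice: float
    train_indices: list[int]
    val_indices: list[int]

    def history_table(self, sep: str = ",") -> str:
        keys = list(self.history)
        rows = [sep.join(["epoch"] + keys)]
        for i in range(len(self.history[keys[0]])):
            rows.append(sep.join([str(i + 1)]
                                 + [repr(self.history[k][i]) for k in keys]))
        return "\n".join(rows)


def _resolve_split(dataset, seed: int) -> tuple[list[MultimodalSlice], list[int], list[int]]:
    if isinstance(dataset, PhantomDataset):
        return list(dataset.slices), list(dataset.train_indices), list(dataset.val_indices)
    cases = list(dataset)
    n = len(cases)
    if n == 0:
        raise DataError("dataset is empty")
    perm = np.random.default_rng(seed).permutation(n)
    n_val = max(1, int(round(0.2 * n))) if n > 1 else 0
    return (cases, sorted(int(i) for i in perm[n_val:]),
            sorted(int(i) for i in perm[:n_val]))


def _case_tensors(model: WfcnNetwork, cases: Sequence[MultimodalSlice]
                  ) -> tuple[np.ndarray, np.ndarray, dict[int, np.ndarray]]:
    """Stack images, masks and per-case injection maps for a case list."""
    x = np.stack([c.stack() for c in cases]).astype(np.float32)
    y = np.stack([c.mask for c in cases]).astype(np.int64)
    inj_per_case = [compute_injection(c, model.config) for c in cases]
    inj = {k: np.stack([m[k] for m in inj_per_case])
           for k in model.config.injection_paths}
    return x, y, inj


def _batched_probs(model: WfcnNetwork, x, inj, batch_size: int = 8) -> np.ndarray:
    out = []
    for i in range(0, len(x), batch_size):
        bi = {k: v[i:i + batch_size] for k, v in inj.items()}
        out.append(model.predict_proba(x[i:i + batch_size], bi))
    return np.concatenate(out)


def train(model: WfcnNetwork, dataset, config: TrainConfig) -> TrainResult:
    """Train ``model`` in place; returns the loss history and split.

    ``dataset`` is a :class:`PhantomDataset` (its recorded split is used) or
    a plain sequence of slices (seeded 80/20 split).  The model is left with
    the best-validation-Dice weights; if ``config.checkpoint_path`` is set
    they are also written there.
    """
    cases, train_idx, val_idx = _resolve_split(dataset, config.seed)
    if not cases:
        raise DataError("dataset is empty")
    for c in cases:
        if c.mask is None:
            raise DataError(f"case {c.case_id!r} has no ground-truth mask")
    if not train_idx:
        raise DataError("training split is empty")

    train_cases = [cases[i] for i in train_idx]
    val_cases = [cases[i] for i in val_idx]
    x_tr, y_tr, inj_tr = _case_tensors(model, train_cases)
    if val_cases:
        x_va, y_va, inj_va = _case_tensors(model, val_cases)

    weights = None
    if config.class_weighting:
        pos = y_tr.mean()
        weights = np.array([0.5 / max(1 - pos, 1e-6), 0.5 / max(pos, 1e-6)])

    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [],
                                       "val_dice": []}
    best_dice, best_epoch, best_state = -1.0, 0, model.state_dict()
    stale = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_cases))
        losses, sizes = [], []
        for i in range(0, len(order), config.batch_size):
            sel = order[i:i + config.batch_size]
            bi = {k: v[sel] for k, v in inj_tr.items()}
            logits = model.forward_logits(x_tr[sel], bi)
            loss, grad = softmax_cross_entropy(logits, y_tr[sel], weights)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
            sizes.append(len(sel))
        history["train_loss"].append(
            float(np.average(losses, weights=sizes)))

        if val_cases:
            probs = _batched_probs(model, x_va, inj_va, config.batch_size)
            val_loss, _ = softmax_cross_entropy(
                np.log(np.clip(probs, 1e-12, None)), y_va, weights)
            if not np.isfinite(val_loss):
                raise TrainingError(f"non-finite validation loss at epoch {epoch}")
            pred = probs.argmax(axis=1)
            val_dice = float(np.mean([dice(pred[j], y_va[j])
                                      for j in range(len(val_cases))]))
            history["val_loss"].append(val_loss)
            history["val_dice"].append(val_dice)
            if val_dice > best_dice:
                best_dice, best_epoch, best_state = val_dice, epoch, model.state_dict()
                stale = 0
            else:
                stale += 1
                if (config.early_stop_patience is not None
                        and stale >= config.early_stop_patience):
                    break
        else:
            history["val_loss"].append(float("nan"))
            history["val_dice"].append(float("nan"))
            best_dice, best_epoch, best_state = 0.0, epoch, model.state_dict()

    model.load_state_dict(best_state)
    if config.checkpoint_path:
        model.save(config.checkpoint_path)
    return TrainResult(history=history, best_epoch=best_epoch,
                       best_val_dice=best_dice, train_indices=train_idx,
                       val_indices=val_idx)


def evaluate(model: WfcnNetwork, cases: Iterable[MultimodalSlice],
             batch_size: int = 8) -> MetricsReport:
    """Compute the full metric suite over ``cases``.

    Per-case predicted masks come from the argmax of the class
    probabilities; Dice is reported per case then averaged (and, separately,
    pooled over all pixels).  The confusion metrics are pooled over all
    pixels of the evaluation set, and AUC uses the pre-argmax tumor-class
    probabilities of every pixel.
    """
    cases = list(cases)
    if not cases:
        raise DataError("evaluation set is empty")
    for c in cases:
        if c.mask is None:
            raise DataError(f"case {c.case_id!r} has no ground-truth mask")
    x, y, inj = _case_tensors(model, cases)
    probs = _batched_probs(model, x, inj, batch_size)
    pred = probs.argmax(axis=1)

    per_case = [dice(pred[i], y[i]) for i in range(len(cases))]
    pa, mpa, sen, spe = confusion_metrics(pred, y)
    try:
        auc_val = auc(probs[:, 1], y)
    except UndefinedMetricError:
        auc_val = float("nan")
    return MetricsReport(
        dice_mean=float(np.mean(per_case)),
        dice_variance=float(np.var(per_case)),
        dice_pooled=dice(pred.ravel(), y.ravel()),
        pixel_accuracy=pa,
        mean_pixel_accuracy=mpa,
        sensitivity=sen,
        specificity=spe,
        auc=auc_val,
        per_case_dice=[float(d) for d in per_case],
        case_ids=[c.case_id for c in cases],
    )
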