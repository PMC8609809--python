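"""Metric suite against brute-force oracles; training loop contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wfcnseg.phantom_gen import PhantomParams, make_dataset
from wfcnseg.train_eval import (DataError, MetricsReport, TrainConfig,
                                UndefinedMetricError, auc, confusion_metrics,
                                dice, evaluate, train)
from wfcnseg.wfcn_arch import build_model, preset_config


# -- oracles ---------------------------------------------------------------

def brute_force_counts(s, g):
    tp = fp = fn = tn = 0
    for a, b in zip(np.ravel(s), np.ravel(g)):
        if a and b:
            tp += 1
        elif a and not b:
            fp += 1
        elif not a and b:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_force_auc(p, g):
    """All-thresholds trapezoidal ROC area."""
    p, g = np.ravel(p), np.ravel(g).astype(bool)
    thresholds = np.unique(np.concatenate([[-np.inf], np.sort(p), [np.inf]]))
    tpr, fpr = [], []
    npos, nneg = g.sum(), (~g).sum()
    for t in thresholds[::-1]:
        pred = p >= t
        tpr.append((pred & g).sum() / npos)
        fpr.append((pred & ~g).sum() / nneg)
    return float(np.trapezoid(tpr, fpr))


# -- dice ------------------------------------------------------------------

def test_dice_identity_disjoint_and_half_overlap():
    g = np.zeros((20, 20), int)
    g[:10] = 1
    assert dice(g, g) == 1.0
    assert dice(1 - g, g) == 0.0
    s = np.zeros_like(g)
    s[5:15] = 1  # |S|=|G|=200, overlap 100
    assert dice(s, g) == 0.5


def test_dice_empty_convention_and_errors():
    z = np.zeros((4, 4), int)
    assert dice(z, z) == 1.0
    with pytest.raises(ValueError, match="shapes"):
        dice(z, np.zeros((3, 3), int))
    with pytest.raises(ValueError, match="binary"):
        dice(z + 2, z)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_dice_symmetry_bounds_and_confusion_identity(seed):
    rng = np.random.default_rng(seed)
    s = rng.integers(0, 2, size=(8, 8))
    g = rng.integers(0, 2, size=(8, 8))
    d = dice(s, g)
    assert d == dice(g, s)
    assert 0.0 <= d <= 1.0
    tp, fp, fn, _ = brute_force_counts(s, g)
    if 2 * tp + fp + fn:
        assert abs(d - 2 * tp / (2 * tp + fp + fn)) < 1e-12


# -- confusion metrics -----------------------------------------------------

def test_confusion_metrics_toy_case():
    # 4x4 masks with TP=2, FP=1, FN=1, TN=12
    g = np.zeros((4, 4), int)
    g[0, :3] = 1
    s = np.zeros((4, 4), int)
    s[0, :2] = 1
    s[1, 0] = 1
    pa, mpa, sen, spe = confusion_metrics(s, g)
    assert pa == pytest.approx(0.875, abs=1e-12)
    assert sen == pytest.approx(2 / 3, abs=1e-12)
    assert spe == pytest.approx(12 / 13, abs=1e-12)
    assert mpa == pytest.approx((2 / 3 + 12 / 13) / 2, abs=1e-12)


def test_confusion_metrics_identity_and_complement():
    g = np.zeros((6, 6), int)
    g[2:4, 2:4] = 1
    assert confusion_metrics(g, g) == (1.0, 1.0, 1.0, 1.0)
    pa, mpa, sen, spe = confusion_metrics(1 - g, g)
    assert (pa, sen, spe) == (0.0, 0.0, 0.0)


def test_confusion_metrics_match_brute_force_counts(rng):
    for _ in range(100):
        s = rng.integers(0, 2, size=(8, 8))
        g = rng.integers(0, 2, size=(8, 8))
        tp, fp, fn, tn = brute_force_counts(s, g)
        pa, mpa, sen, spe = confusion_metrics(s, g)
        assert pa == pytest.approx((tp + tn) / 64, abs=1e-12)
        if tp + fn:
            assert sen == pytest.approx(tp / (tp + fn), abs=1e-12)
        if tn + fp:
            assert spe == pytest.approx(tn / (tn + fp), abs=1e-12)


# -- auc -------------------------------------------------------------------

def test_auc_perfect_and_chance():
    g = np.zeros((4, 4), int)
    g[:2] = 1
    assert auc(g.astype(float), g) == 1.0
    assert auc(np.full((4, 4), 0.5), g) == 0.5


def test_auc_single_class_is_undefined():
    with pytest.raises(UndefinedMetricError):
        auc(np.random.default_rng(0).random((4, 4)), np.zeros((4, 4), int))


def test_auc_matches_brute_force_trapezoid(rng):
    for _ in range(20):
        p = rng.random((8, 8))
        g = rng.integers(0, 2, size=(8, 8))
        if g.sum() in (0, g.size):
            continue
        assert auc(p, g) == pytest.approx(brute_force_auc(p, g), abs=1e-10)


# -- training --------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_dataset():
    return make_dataset(6, PhantomParams(side=32, seed=3,
                                         tumor_radius_range=(4, 7)))


def _tiny_model(seed=0, paths=frozenset({1})):
    cfg = preset_config("base", input_side=32, encoder_levels=3,
                        base_channels=4)
    import dataclasses
    cfg = dataclasses.replace(cfg, injection_paths=frozenset(paths))
    return build_model(cfg, seed=seed)


def test_one_epoch_smoke_history_finite(tiny_dataset):
    model = _tiny_model()
    res = train(model, tiny_dataset, TrainConfig(epochs=1, seed=0))
    assert len(res.history["train_loss"]) == 1
    assert np.isfinite(res.history["train_loss"][0])
    assert np.isfinite(res.history["val_loss"][0])


def test_training_is_deterministic_under_fixed_seed(tiny_dataset):
    h1 = train(_tiny_model(seed=1), tiny_dataset,
               TrainConfig(epochs=2, seed=7)).history
    h2 = train(_tiny_model(seed=1), tiny_dataset,
               TrainConfig(epochs=2, seed=7)).history
    assert h1 == h2


def test_single_step_decreases_loss(tiny_dataset):
    """Gradient flow: one small-step epoch lowers the training loss."""
    model = _tiny_model(seed=2)
    cfg = TrainConfig(epochs=2, batch_size=8, learning_rate=3e-4, seed=0)
    res = train(model, tiny_dataset, cfg)
    assert res.history["train_loss"][1] < res.history["train_loss"][0]


def test_empty_dataset_raises():
    with pytest.raises(DataError):
        train(_tiny_model(), [], TrainConfig(epochs=1))


def test_missing_ground_truth_raises(tiny_dataset):
    import dataclasses as dc

    cases = [dc.replace(tiny_dataset[0], mask=None)]
    with pytest.raises(DataError, match="ground-truth"):
        train(_tiny_model(), cases, TrainConfig(epochs=1))
    with pytest.raises(DataError, match="ground-truth"):
        evaluate(_tiny_model(), cases)


def test_best_checkpoint_written(tmp_path, tiny_dataset):
    model = _tiny_model()
    path = tmp_path / "best.npz"
    res = train(model, tiny_dataset,
                TrainConfig(epochs=2, seed=0, checkpoint_path=str(path)))
    assert path.exists() and res.best_epoch in (1, 2)


# -- evaluate --------------------------------------------------------------

class _OracleModel:
    """Stand-in predictor that returns the ground truth (or a constant).

    Cases are consumed in evaluation order, so a running cursor pairs each
    forwarded image with its mask.
    """

    def __init__(self, dataset, mode):
        from wfcnseg.wfcn_arch import WfcnConfig

        self.config = WfcnConfig(input_side=dataset[0].side,
                                 encoder_levels=3)
        self._masks = [c.mask for c in dataset]
        self._cursor = 0
        self.mode = mode

    def predict_proba(self, x, injections=None):
        out = []
        for _ in x:
            mask = self._masks[self._cursor % len(self._masks)].astype(float)
            self._cursor += 1
            p1 = mask if self.mode == "oracle" else np.zeros_like(mask)
            p1 = np.clip(p1, 1e-6, 1 - 1e-6)
            out.append(np.stack([1 - p1, p1]))
        return np.asarray(out)


def test_evaluate_oracle_model_scores_perfectly(tiny_dataset):
    rep = evaluate(_OracleModel(tiny_dataset, "oracle"), list(tiny_dataset))
    assert rep.dice_mean == 1.0 and rep.dice_variance == 0.0
    assert rep.sensitivity == 1.0 and rep.auc == 1.0


def test_evaluate_all_background_model_scores_zero_dice(tiny_dataset):
    rep = evaluate(_OracleModel(tiny_dataset, "background"), list(tiny_dataset))
    assert rep.dice_mean == 0.0
    assert rep.specificity == 1.0


def test_report_aggregation_consistency(tiny_dataset):
    rep = evaluate(_OracleModel(tiny_dataset, "oracle"), list(tiny_dataset))
    assert rep.dice_mean == pytest.approx(np.mean(rep.per_case_dice), abs=1e-12)
    assert rep.dice_variance == pytest.approx(np.var(rep.per_case_dice),
                                              abs=1e-12)
    # report serializes
    import json

    doc = json.loads(rep.to_json())
    assert set(doc) >= {"dice_mean", "dice_pooled", "auc", "per_case_dice"}
    assert "dice_mean" in rep.to_table()


def test_report_rejects_inconsistent_mean():
    with pytest.raises(ValueError, match="inconsistent"):
        MetricsReport(dice_mean=0.9, dice_variance=0.0, dice_pooled=0.5,
                      pixel_accuracy=1, mean_pixel_accuracy=1, sensitivity=1,
                      specificity=1, auc=1, per_case_dice=[0.5, 0.5])
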