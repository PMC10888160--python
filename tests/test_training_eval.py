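"""Dataset splitting, error metrics and the training loop contract."""

import numpy as np
import pytest

from massgrader.model import ModelConfig, build_massnet, predict_mass
from massgrader.synthetic_data import DatasetManifest, ManifestRecord
from massgrader.training_eval import (
    EvaluationSet,
    ImageSet,
    TrainConfig,
    evaluate,
    load_image_set,
    mape,
    rmse,
    split_dataset,
    train,
)


def _manifest(n):
    recs = [ManifestRecord(f"img_{i:04d}.png", 100.0 + i, 3) for i in range(n)]
    return DatasetManifest(records=recs)


# ---------------------------------------------------------------------------
# splitting


@pytest.mark.parametrize("n,ratio,expected_train", [(409, 0.8, 327), (10, 0.8, 8)])
def test_split_sizes(n, ratio, expected_train):
    train_m, val_m = split_dataset(_manifest(n), ratio, seed=0)
    assert len(train_m) == expected_train
    assert len(val_m) == n - expected_train


def test_split_disjoint_exhaustive_and_seeded():
    m = _manifest(50)
    t1, v1 = split_dataset(m, 0.8, seed=7)
    t2, v2 = split_dataset(m, 0.8, seed=7)
    names = lambda mm: [r.filename for r in mm.records]
    assert names(t1) == names(t2) and names(v1) == names(v2)
    assert set(names(t1)) | set(names(v1)) == set(names(m))
    assert not set(names(t1)) & set(names(v1))
    t3, _ = split_dataset(m, 0.8, seed=8)
    assert names(t3) != names(t1)


def test_split_tags_and_small_n():
    t, v = split_dataset(_manifest(5), 0.8, seed=0)
    assert all(r.split == "train" for r in t.records)
    assert all(r.split == "val" for r in v.records)
    with pytest.raises(ValueError):
        split_dataset(_manifest(1), 0.8, seed=0)


# ---------------------------------------------------------------------------
# metrics


def test_rmse_worked_examples():
    assert rmse(EvaluationSet([10, 6], [8, 8])) == pytest.approx(2.0)
    assert rmse(EvaluationSet([103], [100])) == pytest.approx(3.0)
    assert rmse(EvaluationSet([1, 2, 3], [1, 2, 3])) == 0.0


def test_mape_worked_examples():
    assert mape(EvaluationSet([103], [100])) == pytest.approx(3.0)
    assert mape(EvaluationSet([110, 90], [100, 100])) == pytest.approx(10.0)
    assert mape(EvaluationSet([5, 5], [5, 5])) == 0.0


def test_mape_requires_positive_actuals():
    with pytest.raises(ValueError):
        mape(EvaluationSet([1.0], [0.0]))


def test_empty_evaluation_set_rejected():
    with pytest.raises(ValueError):
        EvaluationSet([], [])


def test_metrics_match_bruteforce_loops():
    """Vectorized rmse/mape agree with element-by-element loops to 1e-9."""
    rng = np.random.default_rng(42)
    pred = rng.uniform(90, 260, 100)
    actual = rng.uniform(95, 250, 100)
    ev = EvaluationSet(pred, actual)

    acc = 0.0
    for p, a in zip(pred, actual):
        acc += (p - a) ** 2
    assert rmse(ev) == pytest.approx((acc / len(pred)) ** 0.5, abs=1e-9)

    acc = 0.0
    for p, a in zip(pred, actual):
        acc += abs(p - a) / a
    assert mape(ev) == pytest.approx(acc / len(pred) * 100.0, abs=1e-9)


# ---------------------------------------------------------------------------
# training loop


def _micro_sets(n_train=6, n_val=3, size=64, seed=0):
    rng = np.random.default_rng(seed)
    imgs = rng.integers(0, 255, (n_train + n_val, size, size, 3)).astype(np.uint8)
    masses = rng.uniform(100, 240, n_train + n_val)
    tr = ImageSet(imgs[:n_train], masses[:n_train], [f"t{i}.png" for i in range(n_train)])
    va = ImageSet(imgs[n_train:], masses[n_train:], [f"v{i}.png" for i in range(n_val)])
    return tr, va


def test_memorization_reduces_training_loss():
    tr = ImageSet(
        np.random.default_rng(1).integers(0, 255, (1, 64, 64, 3)).astype(np.uint8),
        np.array([180.0]),
        ["a.png"],
    )
    model = build_massnet(ModelConfig.desk(), seed=1)
    cfg = TrainConfig(epochs=50, learning_rate=1e-3, seed=1)
    _, history = train(model, tr, tr, cfg)
    assert history[-1]["train_mse"] < history[0]["train_mse"]


def test_best_validation_checkpoint_returned():
    """The returned weights reproduce the minimum validation MSE."""
    tr, va = _micro_sets()
    model = build_massnet(ModelConfig.desk(), seed=2)
    cfg = TrainConfig(epochs=8, learning_rate=1e-3, seed=2)
    model, history = train(model, tr, va, cfg)
    best = min(h["val_mse"] for h in history)
    val_pred = predict_mass(model, va.images)
    val_mse = float(np.mean((val_pred - va.masses) ** 2))
    assert val_mse == pytest.approx(best, rel=1e-5)
    assert len(history) == cfg.epochs


def test_training_deterministic_for_fixed_seed():
    tr, va = _micro_sets()
    hists = []
    for _ in range(2):
        model = build_massnet(ModelConfig.desk(), seed=3)
        _, history = train(model, tr, va, TrainConfig(epochs=3, seed=3))
        hists.append([h["val_mse"] for h in history])
    assert hists[0] == hists[1]


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(split_ratio=1.0)
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")


# ---------------------------------------------------------------------------
# evaluation harness


def test_evaluate_oracle_and_constant(tiny_dataset):
    test_set = load_image_set(tiny_dataset)

    # an oracle predictor: perfect recovery of true mass
    ev = EvaluationSet(test_set.masses, test_set.masses)
    assert rmse(ev) == 0.0 and mape(ev) == 0.0

    # a constant predictor at the mean: rmse equals the population sd
    const = EvaluationSet(
        np.full(len(test_set), test_set.masses.mean()), test_set.masses
    )
    assert rmse(const) == pytest.approx(test_set.masses.std(), rel=1e-9)


def test_evaluate_reports_n_and_rejects_overlap(tiny_dataset):
    test_set = load_image_set(tiny_dataset)
    model = build_massnet(ModelConfig.desk(), seed=5)
    report = evaluate(model, test_set)
    assert report.n == len(tiny_dataset)
    with pytest.raises(ValueError, match="overlap"):
        evaluate(model, test_set, train_filenames={test_set.filenames[0]})
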