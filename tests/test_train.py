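"""Training loop behaviour: seeding, splitting, early stopping, prediction."""

import numpy as np
import pytest

import smsegnet as sm
from smsegnet.estimator import save_classifier, load_classifier


def _toy_patches(n=10, side=8, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, side, side), dtype=np.float32)
    y = (X > 0.5).astype(np.int16) + (X > 0.8).astype(np.int16)
    return X, y


@pytest.fixture
def toy_clf(tiny_config):
    return sm.SMSegNetClassifier(config=tiny_config, epochs=2, batch_size=4,
                                 seed=0)


def test_fit_records_losses_and_parameters(toy_clf):
    X, y = _toy_patches()
    toy_clf.fit(X, y)
    rec = toy_clf.record_
    assert len(rec.train_losses) == 2 and len(rec.val_losses) == 2
    assert all(np.isfinite(rec.train_losses))
    assert rec.n_parameters == toy_clf.network_.n_parameters()
    assert rec.config["plan"]["encoder_expand"] == [2, 4]


def test_validation_split_8_train_2_val(tiny_config, monkeypatch):
    seen = {}
    orig = sm.SMSegNetClassifier._epoch_loss

    def spy(self, X, y, batch):
        seen["val"] = len(X)
        return orig(self, X, y, batch)

    monkeypatch.setattr(sm.SMSegNetClassifier, "_epoch_loss", spy)
    X, y = _toy_patches(n=10)
    sm.SMSegNetClassifier(config=tiny_config, epochs=1,
                          validation_split=0.2, seed=0).fit(X, y)
    assert seen["val"] == 2


def test_zero_learning_rate_leaves_parameters_unchanged(tiny_config):
    X, y = _toy_patches()
    clf = sm.SMSegNetClassifier(config=tiny_config, learning_rate=0.0,
                                epochs=2, early_stopping=False, seed=0)
    clf.fit(X, y)
    fresh = sm.SMSegNet(tiny_config, seed=0)
    for k, t in clf.network_.params.items():
        np.testing.assert_array_equal(t.data, fresh.params[k].data)


def test_training_reduces_loss(tiny_config):
    X, y = _toy_patches(n=16)
    clf = sm.SMSegNetClassifier(config=tiny_config, epochs=5,
                                early_stopping=False, batch_size=4, seed=0)
    clf.fit(X, y)
    losses = clf.record_.train_losses
    assert losses[-1] < losses[0]


def test_run_is_seed_deterministic(tiny_config):
    X, y = _toy_patches()
    runs = []
    for _ in range(2):
        clf = sm.SMSegNetClassifier(config=tiny_config, epochs=3, seed=5)
        clf.fit(X, y)
        runs.append((clf.record_.train_losses, clf.predict(X)))
    assert runs[0][0] == runs[1][0]
    np.testing.assert_array_equal(runs[0][1], runs[1][1])


def test_early_stopping_truncates_and_restores_best(tiny_config):
    X, y = _toy_patches()
    # zero learning rate: the monitored loss can never improve after the
    # first epoch, so patience must cut the run short
    clf = sm.SMSegNetClassifier(config=tiny_config, learning_rate=0.0,
                                epochs=50, patience=2, seed=0)
    clf.fit(X, y)
    assert clf.record_.stopped_early
    assert len(clf.record_.train_losses) < 50
    assert clf.record_.best_epoch == 0
    best = min(clf.record_.val_losses)
    assert clf.record_.val_losses[clf.record_.best_epoch] == best


def test_empty_and_mismatched_datasets_rejected(tiny_config):
    clf = sm.SMSegNetClassifier(config=tiny_config)
    with pytest.raises(ValueError):
        clf.fit(np.zeros((0, 8, 8)), np.zeros((0, 8, 8), dtype=int))
    with pytest.raises(ValueError):
        clf.fit(np.zeros((2, 8, 8)), np.zeros((2, 4, 4), dtype=int))
    with pytest.raises(ValueError):
        clf.fit(np.zeros((2, 16, 16)), np.zeros((2, 16, 16), dtype=int))


def test_predict_shapes_and_probabilities(toy_clf):
    X, y = _toy_patches()
    toy_clf.fit(X, y)
    probs = toy_clf.predict_proba(X)
    assert probs.shape == (10, 8, 8, 4)
    np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)
    labels = toy_clf.predict(X)
    assert labels.shape == (10, 8, 8)
    assert set(np.unique(labels)) <= {0, 1, 2, 3}


def test_sklearn_param_interface(tiny_config):
    from sklearn.base import clone
    clf = sm.SMSegNetClassifier(config=tiny_config, epochs=3, seed=7)
    params = clf.get_params()
    assert params["epochs"] == 3 and params["seed"] == 7
    cloned = clone(clf)
    assert cloned.get_params()["epochs"] == 3
    cloned.set_params(epochs=1)
    assert cloned.epochs == 1


def test_functional_train_wrapper(tiny_config):
    X, y = _toy_patches()
    clf, record = sm.train(X, y, sm.TrainConfig(epochs=1, batch_size=4),
                           config=tiny_config)
    assert record is clf.record_
    assert len(record.train_losses) == 1


def test_save_and_load_classifier(tmp_path, toy_clf):
    X, y = _toy_patches()
    toy_clf.fit(X, y)
    stem = tmp_path / "model"
    save_classifier(toy_clf, stem)
    loaded = load_classifier(stem)
    np.testing.assert_array_equal(loaded.predict(X), toy_clf.predict(X))
    assert loaded.n_parameters_ == toy_clf.n_parameters_


def test_predict_volume_end_to_end(tiny_config, small_phantom):
    vol, _ = small_phantom
    clf = sm.SMSegNetClassifier(config=tiny_config, epochs=1, seed=0)
    X, y = _toy_patches()
    clf.fit(X, y)
    lab = sm.predict_volume(clf, vol, patch_size=8, canvas=56,
                            slice_indices=[13])
    assert lab.shape == vol.shape
    assert set(np.unique(lab.data)) <= {0, 1, 2, 3}
    again = sm.predict_volume(clf, vol, patch_size=8, canvas=56,
                              slice_indices=[13])
    np.testing.assert_array_equal(lab.data, again.data)


def test_train_config_validation():
    with pytest.raises(ValueError):
        sm.TrainConfig(validation_split=0.0)
    with pytest.raises(ValueError):
        sm.TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        sm.TrainConfig(learning_rate=-1.0)
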