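"""Scikit-learn style estimator around the network, plus volume prediction.

:class:`SMSegNetClassifier` is a per-pixel tissue classifier: ``fit`` takes a
stack of 2D patches with integer label patches, trains with stochastic
gradient descent (momentum) on the mean per-pixel cross-entropy, holds out a
validation fraction, and optionally stops early; ``predict`` returns label
patches.  ``predict_volume`` composes the full pipeline — normalize, pad,
slice, patch, forward, reassemble, crop — to segment a whole volume, and
``audit_parameters`` renders the per-layer trainable-parameter manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator

from .config import SMSegNetConfig, reference_config, _config_to_dict
from ._nn.network import SMSegNet
from ._nn.optim import SGD
from ._nn import ops
from .pipeline import (normalize_intensity, pad_to_square, divide_patches,
                       reassemble)
from .volume import Volume, LabelMap
from .metrics import dice

__all__ = ["TrainConfig", "RunRecord", "SMSegNetClassifier",
           "train", "predict_volume", "ParameterAudit", "audit_parameters",
           "save_classifier", "load_classifier"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (defaults follow the published recipe)."""

    learning_rate: float = 0.001
    momentum: float = 0.99
    validation_split: float = 0.2
    epochs: int = 10
    batch_size: int = 16
    early_stopping: bool = True
    patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_split < 1.0):
            raise ValueError("validation split must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")


@dataclass
class RunRecord:
    """What one training run did: losses, counts, and the exact setup."""

    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    n_parameters: int = 0
    seed: int = 0
    best_epoch: int | None = None
    stopped_early: bool = False
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        import json
        return json.dumps(asdict(self))


class SMSegNetClassifier(BaseEstimator):
    """Per-pixel brain tissue classifier with an M-shaped fire-module network.

    Parameters mirror :class:`TrainConfig`; ``config`` fixes the network
    topology (defaults to the reference channel plan, with the input size
    taken from the training patches).  Fitted attributes carry a trailing
    underscore: ``network_``, ``config_``, ``record_``, ``classes_``,
    ``n_parameters_``.

    ``X`` is a float array of patches shaped (n, H, W) (or (n, H, W, 1)),
    ``y`` an integer array of label patches shaped (n, H, W).
    """

    def __init__(self, config: SMSegNetConfig | None = None, *,
                 learning_rate: float = 0.001, momentum: float = 0.99,
                 validation_split: float = 0.2, epochs: int = 10,
                 batch_size: int = 16, early_stopping: bool = True,
                 patience: int = 3, seed: int = 0, verbose: bool = False):
        self.config = config
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.validation_split = validation_split
        self.epochs = epochs
        self.batch_size = batch_size
        self.early_stopping = early_stopping
        self.patience = patience
        self.seed = seed
        self.verbose = verbose

    # -- helpers ------------------------------------------------------------

    def _validate_patches(self, X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 4 and X.shape[-1] == 1:
            X = X[..., 0]
        if X.ndim != 3:
            raise ValueError(f"X must be (n, H, W) patches, got {X.shape}")
        if y is not None:
            y = np.asarray(y)
            if y.shape != X.shape:
                raise ValueError(
                    f"label patches {y.shape} do not match X {X.shape}")
            if not np.issubdtype(y.dtype, np.integer):
                raise ValueError("y must be integer class labels")
        return X, y

    def _resolve_config(self, X) -> SMSegNetConfig:
        cfg = self.config
        if cfg is None:
            ref = reference_config()
            cfg = SMSegNetConfig(
                plan=ref.plan, num_classes=ref.num_classes,
                input_size=(X.shape[1], X.shape[2], 1),
                long_skips_enabled=ref.long_skips_enabled,
                combined_connections_enabled=ref.combined_connections_enabled)
        h, w, _c = cfg.input_size
        if (X.shape[1], X.shape[2]) != (h, w):
            raise ValueError(
                f"patches are {X.shape[1]}x{X.shape[2]} but the network "
                f"expects {h}x{w}")
        return cfg

    def _epoch_loss(self, X, y, batch_size) -> float:
        """Mean cross-entropy over a dataset without updating parameters."""
        total, n = 0.0, 0
        for i in range(0, len(X), batch_size):
            xb, yb = X[i:i + batch_size], y[i:i + batch_size]
            loss = ops.softmax_cross_entropy(
                self.network_.logits(xb[:, None]), yb)
            total += float(loss.data) * len(xb)
            n += len(xb)
        return total / n

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y):
        X, y = self._validate_patches(X, y)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty dataset")
        cfg = self._resolve_config(X)
        if y.min() < 0 or y.max() >= cfg.num_classes:
            raise ValueError(
                f"labels must lie in [0, {cfg.num_classes}), "
                f"found [{y.min()}, {y.max()}]")

        self.config_ = cfg
        self.network_ = SMSegNet(cfg, seed=self.seed)
        self.n_parameters_ = self.network_.n_parameters()
        self.classes_ = np.arange(cfg.num_classes)
        record = RunRecord(n_parameters=self.n_parameters_, seed=self.seed,
                           config=_config_to_dict(cfg))

        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(X))
        n_val = int(round(self.validation_split * len(X)))
        n_val = min(n_val, len(X) - 1)  # always keep at least one train item
        train_idx = order[:len(X) - n_val] if n_val else order
        val_idx = order[len(X) - n_val:] if n_val else order[:0]
        Xt, yt = X[train_idx], y[train_idx]
        Xv, yv = X[val_idx], y[val_idx]

        opt = SGD(self.network_.params, lr=self.learning_rate,
                  momentum=self.momentum)
        best_val, best_state, since_best = np.inf, None, 0
        batch = max(1, self.batch_size)
        for epoch in range(self.epochs):
            perm = rng.permutation(len(Xt))
            running, seen = 0.0, 0
            for i in range(0, len(Xt), batch):
                sel = perm[i:i + batch]
                xb, yb = Xt[sel], yt[sel]
                opt.zero_grad()
                loss = ops.softmax_cross_entropy(
                    self.network_.logits(xb[:, None]), yb)
                loss.backward()
                opt.step()
                running += float(loss.data) * len(xb)
                seen += len(xb)
            record.train_losses.append(running / seen)
            monitor = (self._epoch_loss(Xv, yv, batch) if len(Xv)
                       else record.train_losses[-1])
            record.val_losses.append(monitor)
            if self.verbose:
                print(f"epoch {epoch + 1}/{self.epochs}  "
                      f"train {record.train_losses[-1]:.4f}  val {monitor:.4f}")
            if monitor < best_val:
                best_val, since_best = monitor, 0
                record.best_epoch = epoch
                best_state = {k: t.data.copy()
                              for k, t in self.network_.params.items()}
            else:
                since_best += 1
                if self.early_stopping and since_best >= self.patience:
                    record.stopped_early = True
                    break
        if self.early_stopping and best_state is not None:
            for k, t in self.network_.params.items():
                t.data = best_state[k]
        self.record_ = record
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel class probabilities, shape (n, H, W, num_classes)."""
        X, _ = self._validate_patches(X)
        out = []
        batch = max(1, self.batch_size)
        for i in range(0, len(X), batch):
            p = self.network_.predict_proba(X[i:i + batch][:, None])
            out.append(p.transpose(0, 2, 3, 1))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=-1)

    def score(self, X, y) -> float:
        """Mean Dice over the foreground classes (not pixel accuracy)."""
        X, y = self._validate_patches(X, y)
        pred = self.predict(X)
        scores = [dice(y == c, pred == c)
                  for c in range(1, self.config_.num_classes)
                  if (y == c).any() or (pred == c).any()]
        return float(np.mean(scores)) if scores else float("nan")


def train(X, y, train_config: TrainConfig | None = None,
          config: SMSegNetConfig | None = None,
          verbose: bool = False):
    """Functional wrapper: fit a classifier, return (estimator, RunRecord)."""
    tc = train_config or TrainConfig()
    clf = SMSegNetClassifier(
        config=config, learning_rate=tc.learning_rate, momentum=tc.momentum,
        validation_split=tc.validation_split, epochs=tc.epochs,
        batch_size=tc.batch_size, early_stopping=tc.early_stopping,
        patience=tc.patience, seed=tc.seed, verbose=verbose)
    clf.fit(X, y)
    return clf, clf.record_


def predict_volume(clf: SMSegNetClassifier, vol: Volume, *,
                   patch_size: int | None = None, mode: str = "quadrant",
                   stride: int = 8, canvas: int = 256,
                   slice_indices=None, normalize: bool = True) -> LabelMap:
    """Segment a whole volume slice by slice.

    Composes normalize -> pad -> (selected or all) slices -> patch ->
    forward -> probability fusion -> crop.  Slices outside ``slice_indices``
    are labelled background.  The output is congruent with the input volume.
    """
    if not hasattr(clf, "network_"):
        raise ValueError("the classifier must be fitted (or loaded) first")
    h, w, s = vol.shape
    data = normalize_intensity(vol.data) if normalize else vol.data
    if patch_size is None:
        patch_size = clf.config_.input_size[0]
    indices = range(s) if slice_indices is None else slice_indices
    out = np.zeros((h, w, s), dtype=np.int16)
    for k in indices:
        padded, pad = pad_to_square(data[:, :, k], target=canvas)
        grid = divide_patches(padded, patch_size=patch_size, mode=mode,
                              stride=stride, slice_index=k, pad=pad,
                              original_shape=(h, w))
        probs = clf.predict_proba(grid.patches).transpose(0, 3, 1, 2)
        out[:, :, k] = reassemble(grid, probs)
    return LabelMap(data=out, plane=vol.plane, spacing=vol.spacing)


def save_classifier(clf: SMSegNetClassifier, stem) -> None:
    """Persist a fitted classifier: ``<stem>.npz`` (weights), ``<stem>.yaml``
    (network configuration) and ``<stem>.record.json`` (run record)."""
    from .config import save_config
    if not hasattr(clf, "network_"):
        raise ValueError("classifier is not fitted")
    clf.network_.save(f"{stem}.npz")
    save_config(clf.config_, f"{stem}.yaml")
    with open(f"{stem}.record.json", "w") as fh:
        fh.write(clf.record_.to_json())


def load_classifier(stem) -> SMSegNetClassifier:
    """Rebuild a classifier saved by :func:`save_classifier`."""
    from .config import load_config
    import json
    cfg = load_config(f"{stem}.yaml")
    clf = SMSegNetClassifier(config=cfg)
    clf.config_ = cfg
    clf.network_ = SMSegNet(cfg, seed=0)
    clf.network_.load(f"{stem}.npz")
    clf.n_parameters_ = clf.network_.n_parameters()
    clf.classes_ = np.arange(cfg.num_classes)
    try:
        with open(f"{stem}.record.json") as fh:
            clf.record_ = RunRecord(**json.load(fh))
    except FileNotFoundError:
        clf.record_ = RunRecord(n_parameters=clf.n_parameters_)
    return clf


@dataclass
class ParameterAudit:
    """Per-layer trainable-parameter manifest with a budget check."""

    rows: list[tuple[str, tuple[int, ...], int, int]]
    total: int
    closed_form_total: int
    budget: int
    within_budget: bool

    def format(self) -> str:
        lines = [f"{name:32s} {str(shape):22s} {count:>10d} {cum:>10d}"
                 for name, shape, count, cum in self.rows]
        lines.append(f"{'TOTAL':32s} {'':22s} {self.total:>10d}")
        lines.append(f"budget {self.budget}: "
                     f"{'within' if self.within_budget else 'EXCEEDED'}")
        return "\n".join(lines)


def audit_parameters(config: SMSegNetConfig | None = None,
                     budget: int = 1_000_000) -> ParameterAudit:
    """Count every trainable weight and bias, layer by layer.

    The framework total (sum of allocated array sizes) is cross-checked
    against the closed-form fire-module arithmetic; they must agree.
    """
    cfg = config or reference_config()
    net = SMSegNet(cfg, seed=0)
    total = net.n_parameters()
    closed = cfg.layout().n_parameters
    if total != closed:
        raise AssertionError(
            f"framework count {total} != closed-form count {closed}")
    return ParameterAudit(rows=net.parameter_manifest(), total=total,
                          closed_form_total=closed, budget=budget,
                          within_budget=total < budget)
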