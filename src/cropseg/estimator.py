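"""Scikit-learn-style estimator wrapping the two-branch segmentation network.

:class:`PatchSegmenter` follows the sklearn estimator contract: all
hyperparameters are constructor arguments mirrored as attributes (so
``get_params``/``set_params``/``clone`` work), ``fit`` learns from arrays and
stores fitted state in trailing-underscore attributes, and
``predict``/``predict_proba``/``score`` operate on held-out arrays.

Inputs are image stacks ``X`` of shape [n_patches, 4, S, S] and label stacks
``y`` of shape [n_patches, S, S] where ignored pixels carry ``ignore_value``.
Training minimises the summed two-branch loss with Adam, monitors a
validation metric each epoch when a validation set is supplied, stops early
after ``patience`` epochs without improvement, and restores the best-epoch
weights.  Everything is seeded: weight init and batch shuffling use separate
streams derived from ``seed``, so two identical runs produce identical
fitted models.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .losses import LossConfig, total_loss
from .metrics import overall_accuracy
from .model import CropSegNet, NetConfig


class EarlyStopping:
    """Track a monitored metric; ``update`` returns True when patience runs out."""

    def __init__(self, patience: int, mode: str = "max"):
        self.patience = patience
        self.sign = 1.0 if mode == "max" else -1.0
        self.best = -np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, value: float, epoch: int) -> bool:
        if self.sign * value > self.best:
            self.best = self.sign * value
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience

    @property
    def best_value(self) -> float:
        return self.sign * self.best


class PatchSegmenter(BaseEstimator):
    """Crop-type patch segmenter: attention U-Net + point refinement branch."""

    def __init__(self, *, in_bands=4, n_classes=4, base_width=64, eca_kernel=3,
                 eca_levels=4, activation="prelu", prelu_init=0.25,
                 cp_enabled=True, cp_k=8096, cp_source_level=2, cp_after_eca=True,
                 cp_hidden=(256, 256), ce_weight=0.0, dice_weight=1.0,
                 cp_weight=1.0, ignore_value=255, lr=0.0003, epochs=150,
                 batch_size=16, patience=20, monitor="val_oa", seed=0):
        self.in_bands = in_bands
        self.n_classes = n_classes
        self.base_width = base_width
        self.eca_kernel = eca_kernel
        self.eca_levels = eca_levels
        self.activation = activation
        self.prelu_init = prelu_init
        self.cp_enabled = cp_enabled
        self.cp_k = cp_k
        self.cp_source_level = cp_source_level
        self.cp_after_eca = cp_after_eca
        self.cp_hidden = cp_hidden
        self.ce_weight = ce_weight
        self.dice_weight = dice_weight
        self.cp_weight = cp_weight
        self.ignore_value = ignore_value
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.monitor = monitor
        self.seed = seed

    # -- config assembly ---------------------------------------------------

    def _net_config(self) -> NetConfig:
        return NetConfig.scaled(
            self.base_width, in_bands=self.in_bands, n_classes=self.n_classes,
            eca_kernel=self.eca_kernel, eca_levels=self.eca_levels,
            activation=self.activation, prelu_init=self.prelu_init,
            cp_enabled=self.cp_enabled, cp_k=self.cp_k,
            cp_source_level=self.cp_source_level, cp_after_eca=self.cp_after_eca,
            cp_hidden=tuple(self.cp_hidden))

    def _loss_config(self) -> LossConfig:
        return LossConfig(ce_weight=self.ce_weight, dice_weight=self.dice_weight,
                          cp_weight=self.cp_weight, ignore_value=self.ignore_value)

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 4 or y.ndim != 3:
            raise ValueError("X must be [n, bands, S, S] and y [n, S, S]")
        if self.patience >= self.epochs and X_val is not None:
            pass  # patience simply never triggers
        loss_cfg = self._loss_config()
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 1]))
        self.model_ = CropSegNet(self._net_config(), seed=int(
            np.random.SeedSequence([self.seed, 0]).generate_state(1)[0] % (2**31)))
        optimizer = nn.Adam(self.model_.parameters(), lr=self.lr)
        stopper = EarlyStopping(self.patience,
                                mode="max" if self.monitor == "val_oa" else "min")
        has_val = X_val is not None and len(X_val) > 0
        n = len(X)
        self.history_ = []
        best_state = None
        for epoch in range(self.epochs):
            self.model_.train()
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, yb = X[idx], y[idx]
                valid = yb != self.ignore_value
                pred = self.model_.forward(xb, valid=valid)
                point_labels = None
                if pred.selection is not None:
                    point_labels = np.take_along_axis(
                        yb.reshape(len(idx), -1), pred.selection.indices, axis=1)
                loss = total_loss(pred.probs_t, yb, pred.cp_logits_t,
                                  point_labels, loss_cfg)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: loss={loss.data}")
                self.model_.zero_grad()
                loss.backward()
                optimizer.step()
                epoch_loss += loss.item()
                n_batches += 1
            record = {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1)}
            if has_val:
                if self.monitor == "val_oa":
                    monitored = self._eval_oa(np.asarray(X_val, dtype=np.float32),
                                              np.asarray(y_val))
                    record["val_oa"] = monitored
                else:
                    monitored = self._eval_loss(np.asarray(X_val, dtype=np.float32),
                                                np.asarray(y_val), loss_cfg)
                    record["val_loss"] = monitored
                stop = stopper.update(monitored, epoch)
                if stopper.best_epoch == epoch:
                    best_state = self.model_.state_dict()
                if stop:
                    self.history_.append(record)
                    break
            self.history_.append(record)
        if has_val and best_state is not None:
            self.model_.load_state_dict(best_state)
            self.best_epoch_ = stopper.best_epoch
            self.best_score_ = stopper.best_value
        else:
            self.best_epoch_ = self.epochs - 1
            self.best_score_ = float("nan")
        self.classes_ = np.arange(self.n_classes)
        self.n_epochs_run_ = len(self.history_)
        return self

    # -- inference ---------------------------------------------------------

    def _batched(self, X):
        for start in range(0, len(X), self.batch_size):
            yield slice(start, start + self.batch_size)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        self.model_.eval()
        return np.concatenate([self.model_.forward(X[s]).label_map
                               for s in self._batched(X)], axis=0)

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        self.model_.eval()
        return np.concatenate([self.model_.forward(X[s]).master_probs
                               for s in self._batched(X)], axis=0)

    def score(self, X, y) -> float:
        """Overall accuracy (fraction in [0,1]) on non-ignored pixels."""
        return overall_accuracy(self.predict(X), np.asarray(y),
                                self.ignore_value) / 100.0

    # -- helpers -----------------------------------------------------------

    def _eval_oa(self, X, y) -> float:
        return overall_accuracy(self.predict(X), y, self.ignore_value)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint: hyperparameters plus model weights/buffers (npz)."""
        import json

        state = self.model_.state_dict()
        np.savez(path, __params__=json.dumps(self.get_params(), default=list),
                 **state)

    @classmethod
    def load(cls, path) -> "PatchSegmenter":
        import json

        with np.load(path, allow_pickle=False) as data:
            params = json.loads(str(data["__params__"]))
            state = {k: data[k] for k in data.files if k != "__params__"}
        for key in ("cp_hidden",):
            params[key] = tuple(params[key])
        est = cls(**params)
        est.model_ = CropSegNet(est._net_config(), seed=0)
        est.model_.load_state_dict(state)
        est.model_.eval()
        est.classes_ = np.arange(est.n_classes)
        return est

    def _eval_loss(self, X, y, loss_cfg) -> float:
        self.model_.eval()
        vals = []
        for s in self._batched(X):
            yb = y[s]
            pred = self.model_.forward(X[s], valid=yb != self.ignore_value)
            point_labels = None
            if pred.selection is not None:
                point_labels = np.take_along_axis(
                    yb.reshape(len(yb), -1), pred.selection.indices, axis=1)
            vals.append(total_loss(pred.probs_t, yb, pred.cp_logits_t,
                                   point_labels, loss_cfg).item())
        return float(np.mean(vals))
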