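"""Experiment harness: single-fold training, repeated-random-split
cross-validation, and the module-ablation switchboard.

"10-fold cross-validation" here means ten independent seeded random 8:1:1
splits of the retained patches (the protocol re-assigns the whole dataset at
random for every repetition), not ten disjoint folds.  Per fold the model is
re-initialised from a fold-specific seed, trained with early stopping on
validation overall accuracy, restored to its best epoch, and evaluated on
that fold's test split; fold metrics come from the fold's pooled confusion
matrix and are then averaged (mean +/- sd) across folds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
import pandas as pd

from .estimator import PatchSegmenter
from .losses import LossConfig
from .metrics import MetricsReport, accumulate, summarize
from .model import NetConfig
from .scene import IGNORE, Patch, SplitSpec, split


@dataclasses.dataclass
class TrainConfig:
    lr: float = 0.0003
    epochs: int = 150
    batch_size: int = 16
    patience: int = 20
    seed: int = 0
    monitor: str = "val_oa"

    def __post_init__(self):
        if self.patience >= self.epochs:
            raise ValueError("patience must be < epochs")
        if self.monitor not in ("val_oa", "val_loss"):
            raise ValueError("monitor must be 'val_oa' or 'val_loss'")


@dataclasses.dataclass
class FoldResult:
    fold: int
    best_epoch: int
    report: MetricsReport
    seed: int
    config_hash: str


def _config_hash(net_cfg: NetConfig, loss_cfg: LossConfig, train_cfg: TrainConfig) -> str:
    blob = json.dumps([dataclasses.asdict(net_cfg), dataclasses.asdict(loss_cfg),
                       dataclasses.asdict(train_cfg)], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_estimator(net_cfg: NetConfig, loss_cfg: LossConfig,
                    train_cfg: TrainConfig) -> PatchSegmenter:
    """Assemble the sklearn-style estimator from the three config objects."""
    base_width = net_cfg.encoder_channels[0]
    if tuple(net_cfg.encoder_channels) != tuple(base_width * 2 ** i for i in range(5)):
        raise ValueError("engine requires doubling encoder channels")
    return PatchSegmenter(
        in_bands=net_cfg.in_bands, n_classes=net_cfg.n_classes,
        base_width=base_width, eca_kernel=net_cfg.eca_kernel,
        eca_levels=net_cfg.eca_levels, activation=net_cfg.activation,
        prelu_init=net_cfg.prelu_init, cp_enabled=net_cfg.cp_enabled,
        cp_k=net_cfg.cp_k, cp_source_level=net_cfg.cp_source_level,
        cp_after_eca=net_cfg.cp_after_eca, cp_hidden=net_cfg.cp_hidden,
        ce_weight=loss_cfg.ce_weight, dice_weight=loss_cfg.dice_weight,
        cp_weight=loss_cfg.cp_weight, ignore_value=loss_cfg.ignore_value,
        lr=train_cfg.lr, epochs=train_cfg.epochs, batch_size=train_cfg.batch_size,
        patience=train_cfg.patience, monitor=train_cfg.monitor, seed=train_cfg.seed)


def stack_patches(patches: list[Patch], indices) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([patches[i].image for i in indices])
    y = np.stack([patches[i].labels for i in indices])
    return X, y


def evaluate(est: PatchSegmenter, patches: list[Patch], indices,
             n_classes: int = 4) -> MetricsReport:
    """Pooled confusion matrix over the given patches, summarised."""
    X, y = stack_patches(patches, indices)
    pred = est.predict(X)
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    for p, t in zip(pred, y):
        accumulate(p, t, IGNORE, confusion)
    return summarize(confusion)


def train(net_cfg: NetConfig, loss_cfg: LossConfig, train_cfg: TrainConfig,
          patches: list[Patch], splits, fold: int = 0) -> FoldResult:
    """Train one fold and evaluate on its test split."""
    train_idx, val_idx, test_idx = splits
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("train and validation splits must be nonempty")
    est = build_estimator(net_cfg, loss_cfg, train_cfg)
    X_tr, y_tr = stack_patches(patches, train_idx)
    X_va, y_va = stack_patches(patches, val_idx)
    est.fit(X_tr, y_tr, X_val=X_va, y_val=y_va)
    report = evaluate(est, patches, test_idx, net_cfg.n_classes)
    result = FoldResult(fold=fold, best_epoch=est.best_epoch_, report=report,
                        seed=train_cfg.seed,
                        config_hash=_config_hash(net_cfg, loss_cfg, train_cfg))
    result.estimator = est  # kept for downstream prediction / inspection
    return result


def cross_validate(patches: list[Patch], net_cfg: NetConfig, loss_cfg: LossConfig,
                   train_cfg: TrainConfig, n_folds: int = 10,
                   base_seed: int = 0):
    """Repeated random-subsampling validation with per-fold re-splitting."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    results = []
    for fold in range(n_folds):
        splits = split(patches, SplitSpec(seed=base_seed + fold))
        fold_train_cfg = dataclasses.replace(train_cfg, seed=base_seed + fold)
        results.append(train(net_cfg, loss_cfg, fold_train_cfg, patches,
                             splits, fold=fold))
    oa = np.array([r.report.oa for r in results])
    aa = np.array([r.report.aa for r in results])
    miou = np.array([r.report.miou for r in results])
    aggregate = {
        "oa_mean": float(oa.mean()), "oa_sd": float(oa.std(ddof=1)),
        "aa_mean": float(aa.mean()), "aa_sd": float(aa.std(ddof=1)),
        "miou_mean": float(miou.mean()), "miou_sd": float(miou.std(ddof=1)),
        "n_folds": n_folds,
    }
    return results, aggregate


def ablation_grid(base_width: int = 64) -> dict[str, tuple[NetConfig, LossConfig]]:
    """Named configurations of the module-ablation study.

    The baseline is the plain U-Net: ReLU activations, cross-entropy loss,
    no channel attention, no point branch.  Rows add PReLU, Dice loss, ECA
    and the point branch singly and in the studied combinations, including
    sourcing point features before vs after ECA.
    """
    def net(**kw):
        return NetConfig.scaled(base_width, activation=kw.pop("activation", "relu"),
                                eca_levels=kw.pop("eca_levels", 0),
                                cp_enabled=kw.pop("cp_enabled", False), **kw)

    ce = LossConfig(ce_weight=1.0, dice_weight=0.0)
    dice = LossConfig(ce_weight=0.0, dice_weight=1.0)
    return {
        "baseline": (net(), ce),
        "baseline+prelu": (net(activation="prelu"), ce),
        "baseline+dice": (net(), dice),
        "baseline+eca": (net(eca_levels=4), ce),
        "baseline+cp": (net(cp_enabled=True, cp_after_eca=False), ce),
        "baseline+dice+eca": (net(eca_levels=4), dice),
        "baseline+dice+prelu+eca": (net(activation="prelu", eca_levels=4), dice),
        "baseline+dice+eca+cp_after_eca": (
            net(eca_levels=4, cp_enabled=True, cp_after_eca=True), dice),
        "baseline+dice+prelu+eca+cp_before_eca": (
            net(activation="prelu", eca_levels=4, cp_enabled=True,
                cp_after_eca=False), dice),
        "baseline+dice+prelu+eca+cp_after_eca": (
            net(activation="prelu", eca_levels=4, cp_enabled=True,
                cp_after_eca=True), dice),
    }


def ablate(patches: list[Patch], grid: dict, train_cfg: TrainConfig,
           n_folds: int = 10, base_seed: int = 0) -> pd.DataFrame:
    """Cross-validate every named configuration; one table row per config."""
    rows = []
    for name, (net_cfg, loss_cfg) in grid.items():
        _, agg = cross_validate(patches, net_cfg, loss_cfg, train_cfg,
                                n_folds=n_folds, base_seed=base_seed)
        rows.append({"config": name, **agg})
    return pd.DataFrame(rows)
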