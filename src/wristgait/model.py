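"""Desk-scale SSL-pretrained convolutional gait regressor.

The architecture mirrors the two-stage wrist-gait transfer pattern: a 1-D
residual convolutional backbone feeding a three-layer fully connected
adapter that emits a 128-dimensional feature, topped by a shallow (0-3
layer) regression head per gait outcome. The backbone+adapter are first
trained with self-supervision on unlabeled windows via three binary pretext
tasks (time-reversal, axis-permutation and time-warp detection, each applied
with probability 0.5 per sample, losses summed); the whole model is then
fine-tuned end-to-end per outcome with an L1 loss, subject-grouped
validation split and early stopping (patience 5).

Stride length gets a second, kinematic estimate speed/(cadence/120); the
final prediction is the simple average of the direct and derived estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import GroupKFold, GroupShuffleSplit, StratifiedGroupKFold

from . import nn
from .errors import ConfigError, DataError

FEATURE_DIM = 128  # fixed adapter output dimension

_AXIS_PERMS = [(0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]

SSL_TASKS = ("reverse", "perm", "warp")


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    n_res_blocks: int = 3
    channels: tuple[int, ...] = (16, 32, 48)
    kernel_size: int = 9
    head_depth: int = 1
    head_width: int = 64
    dropout: float = 0.0
    freeze_backbone: bool = False

    def __post_init__(self) -> None:
        if self.n_res_blocks < 1:
            raise ConfigError("n_res_blocks must be >= 1")
        if len(self.channels) != self.n_res_blocks:
            raise ConfigError("channels must list one width per residual block")
        if self.head_depth not in (0, 1, 2, 3):
            raise ConfigError("head_depth must be in [0, 3]")


@dataclass
class TrainConfig:
    loss: str = "l1"
    patience: int = 5
    max_epochs: int = 40
    batch_size: int = 64
    lr: float = 1e-3
    seed: int = 0
    cv_folds: int = 5
    tuning_trials: int = 10

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ConfigError("patience must be >= 1")
        if self.loss != "l1":
            raise ConfigError("only the L1 loss is supported")


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

class GaitNet(nn.Module):
    """Backbone -> 128-d adapter -> named scalar heads."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        k = cfg.kernel_size
        # stem downsamples by 2 up front: gait content lives well below
        # 7.5 Hz, and halving the length early halves compute everywhere
        layers: list[nn.Module] = [
            nn.Conv1d(3, cfg.channels[0], k, 2, rng),
            nn.BatchNorm1d(cfg.channels[0]),
            nn.ReLU(),
        ]
        in_ch = cfg.channels[0]
        for ch in cfg.channels:
            layers.append(nn.ResBlock(in_ch, ch, k, 2, rng))
            in_ch = ch
        layers.append(nn.GlobalAvgPool())
        self.backbone = nn.Sequential(*layers)
        self.adapter = nn.Sequential(
            nn.Linear(in_ch, FEATURE_DIM, rng),
            nn.ReLU(),
            nn.Linear(FEATURE_DIM, FEATURE_DIM, rng),
            nn.ReLU(),
            nn.Linear(FEATURE_DIM, FEATURE_DIM, rng),
        )
        self.heads: dict[str, nn.Sequential] = {}
        self.cfg = cfg
        self.backbone_frozen = False
        self._rng = rng

    # -- structure ---------------------------------------------------------
    def add_head(self, name: str, depth: int = 0, width: int = 64,
                 dropout: float = 0.0) -> None:
        if depth not in (0, 1, 2, 3):
            raise ConfigError("head depth must be in [0, 3]")
        layers: list[nn.Module] = []
        d_in = FEATURE_DIM
        for _ in range(depth):
            layers += [nn.Linear(d_in, width, self._rng), nn.ReLU()]
            if dropout > 0:
                layers.append(nn.Dropout(dropout, self._rng))
            d_in = width
        layers.append(nn.Linear(d_in, 1, self._rng))
        self.heads[name] = nn.Sequential(*layers)

    def parameters(self):
        for comp in ("backbone", "adapter"):
            for name, p in getattr(self, comp).parameters():
                yield f"{comp}.{name}", p
        for hname, head in self.heads.items():
            for name, p in head.parameters():
                yield f"heads.{hname}.{name}", p

    def trainable_parameters(self):
        for name, p in self.parameters():
            if self.backbone_frozen and name.startswith("backbone."):
                continue
            yield name, p

    def freeze_backbone(self) -> None:
        self.backbone_frozen = True
        self._set_bn_frozen(self.backbone, True)

    def _set_bn_frozen(self, mod: nn.Module, flag: bool) -> None:
        for attr in vars(mod).values():
            if isinstance(attr, nn.BatchNorm1d):
                attr.frozen = flag
            elif isinstance(attr, nn.Module):
                self._set_bn_frozen(attr, flag)
            elif isinstance(attr, list):
                for item in attr:
                    if isinstance(item, nn.Module):
                        self._set_bn_frozen(item, flag)

    # -- compute -----------------------------------------------------------
    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, 3, L) signal -> (B, 128) feature."""
        return self.adapter.forward(self.backbone.forward(x, train), train)

    def forward_head(self, feat: np.ndarray, head: str, train: bool = False
                     ) -> np.ndarray:
        return self.heads[head].forward(feat, train)

    def predict(self, x: np.ndarray, head: str) -> np.ndarray:
        return self.forward_head(self.features(x, train=False), head)[:, 0]

    def backward_from_heads(self, head_grads: dict[str, np.ndarray]) -> None:
        """Backprop gradients from one or more heads through the trunk."""
        gfeat = None
        for name, g in head_grads.items():
            gh = self.heads[name].backward(g)
            gfeat = gh if gfeat is None else gfeat + gh
        gpool = self.adapter.backward(gfeat)
        if not self.backbone_frozen:
            self.backbone.backward(gpool)

    def backbone_checksum(self) -> str:
        return self.backbone.checksum()


def build_network(cfg: NetworkConfig, seed: int) -> GaitNet:
    """Deterministically initialized network for the given seed."""
    return GaitNet(cfg, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# SSL pretraining
# ---------------------------------------------------------------------------

def _time_warp(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth sinusoidal time warp of one (3, L) window."""
    L = x.shape[1]
    t = np.arange(L, dtype=float)
    a = rng.uniform(4.0, 10.0)
    phi = rng.uniform(0, 2 * np.pi)
    tw = np.clip(t + a * np.sin(2 * np.pi * t / L + phi), 0, L - 1)
    return np.stack([np.interp(tw, t, x[c]) for c in range(x.shape[0])])


def ssl_augment(
    X: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Apply each pretext transform with prob 0.5 per sample.

    Returns the augmented batch and one binary label vector per task.
    """
    Xa = X.copy()
    B = X.shape[0]
    labels = {t: rng.integers(0, 2, size=B).astype(float) for t in SSL_TASKS}
    rev = labels["reverse"] == 1
    Xa[rev] = Xa[rev, :, ::-1]
    for i in np.nonzero(labels["perm"] == 1)[0]:
        perm = _AXIS_PERMS[rng.integers(0, len(_AXIS_PERMS))]
        Xa[i] = Xa[i, perm, :]
    for i in np.nonzero(labels["warp"] == 1)[0]:
        Xa[i] = _time_warp(Xa[i], rng)
    return Xa, labels


def ssl_pretrain(
    net: GaitNet,
    X: np.ndarray,
    epochs: int = 10,
    seed: int = 0,
    batch_size: int = 64,
    lr: float = 1e-3,
) -> list[float]:
    """Multi-task self-supervised pretraining on unlabeled windows.

    ``X`` is (n, L, 3) or (n, 3, L); >= 100 windows required. Adds one
    linear head per pretext task; the joint loss is the sum of the three
    binary cross-entropies. Returns the epoch-wise mean loss trace.
    """
    if epochs <= 0:
        raise ConfigError("epochs must be > 0")
    X = _as_bcl(X)
    if X.shape[0] < 100:
        raise DataError("SSL pretraining needs >= 100 windows")
    rng = np.random.default_rng(seed)
    for task in SSL_TASKS:
        if f"ssl_{task}" not in net.heads:
            net.add_head(f"ssl_{task}", depth=0)
    opt = nn.Adam(list(net.trainable_parameters()), lr=lr)
    trace = []
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            Xa, labels = ssl_augment(X[idx], rng)
            feat = net.features(Xa, train=True)
            opt.zero_grad()
            grads, total = {}, 0.0
            for task in SSL_TASKS:
                logits = net.forward_head(feat, f"ssl_{task}", train=True)
                loss, g = nn.bce_with_logits(logits, labels[task][:, None])
                total += loss
                grads[f"ssl_{task}"] = g
            net.backward_from_heads(grads)
            opt.step()
            losses.append(total)
        trace.append(float(np.mean(losses)))
    return trace


def pretext_accuracy(
    net: GaitNet, X: np.ndarray, seed: int = 0
) -> dict[str, float]:
    """Held-out accuracy of each pretext head on freshly augmented windows.

    Missing pretext heads are added untrained, so calling this before
    :func:`ssl_pretrain` measures chance-level performance.
    """
    X = _as_bcl(X)
    for task in SSL_TASKS:
        if f"ssl_{task}" not in net.heads:
            net.add_head(f"ssl_{task}", depth=0)
    rng = np.random.default_rng(seed)
    Xa, labels = ssl_augment(X, rng)
    out = {}
    for task in SSL_TASKS:
        logits = net.predict(Xa, f"ssl_{task}")
        out[task] = float(np.mean((logits > 0) == (labels[task] == 1)))
    return out


def _as_bcl(X: np.ndarray) -> np.ndarray:
    """Accept (n, L, 3) or (n, 3, L); return contiguous (n, 3, L)."""
    X = np.asarray(X, dtype=nn.DTYPE)
    if X.ndim != 3:
        raise DataError("window tensor must be 3-D")
    if X.shape[1] == 3 and X.shape[2] != 3:
        return np.ascontiguousarray(X)
    if X.shape[2] == 3:
        return np.ascontiguousarray(np.transpose(X, (0, 2, 1)))
    raise DataError("one axis of the window tensor must have size 3")


# ---------------------------------------------------------------------------
# fine-tuning estimator
# ---------------------------------------------------------------------------

class ConvGaitRegressor(BaseEstimator, RegressorMixin):
    """Scalar gait-metric regressor over 10-s wrist windows.

    sklearn-compatible: ``fit(X, y, groups=...)`` / ``predict(X)`` with
    ``X`` of shape (n_windows, 300, 3). Training minimizes the mean
    absolute error on a standardized target, holds out a subject-grouped
    validation split, keeps the best-validation checkpoint and stops early
    after ``patience`` epochs without improvement.

    A network pretrained with :func:`ssl_pretrain` is passed via
    ``pretrained_state`` (the dict from ``GaitNet.state()``); otherwise the
    model trains from scratch, which is the fully supervised twin.
    """

    def __init__(
        self,
        n_res_blocks: int = 3,
        channels: tuple[int, ...] = (16, 32, 48),
        kernel_size: int = 9,
        head_depth: int = 1,
        head_width: int = 64,
        dropout: float = 0.0,
        freeze_backbone: bool = False,
        lr: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 40,
        patience: int = 5,
        val_fraction: float = 0.2,
        random_state: int = 0,
        pretrained_state: dict | None = None,
    ):
        self.n_res_blocks = n_res_blocks
        self.channels = channels
        self.kernel_size = kernel_size
        self.head_depth = head_depth
        self.head_width = head_width
        self.dropout = dropout
        self.freeze_backbone = freeze_backbone
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.pretrained_state = pretrained_state

    def _build(self) -> GaitNet:
        cfg = NetworkConfig(
            n_res_blocks=self.n_res_blocks,
            channels=tuple(self.channels),
            kernel_size=self.kernel_size,
            head_depth=self.head_depth,
            head_width=self.head_width,
            dropout=self.dropout,
            freeze_backbone=self.freeze_backbone,
        )
        net = build_network(cfg, self.random_state)
        if self.pretrained_state is not None:
            trunk = {
                k: v
                for k, v in self.pretrained_state.items()
                if k.startswith(
                    ("backbone.", "adapter.", "buf:backbone.", "buf:adapter.")
                )
            }
            partial = dict(net.state())
            partial.update(trunk)
            net.load_state(partial)
        net.add_head("reg", self.head_depth, self.head_width, self.dropout)
        if self.freeze_backbone:
            net.freeze_backbone()
        return net

    def fit(self, X, y, groups=None):
        X = _as_bcl(X)
        y = np.asarray(y, dtype=float)
        if not np.isfinite(y).all():
            raise DataError("targets contain non-finite values")
        if y.size == 0:
            raise DataError("no valid labels to fit on")
        rng = np.random.default_rng(self.random_state)
        net = self._build()

        self._y_mean = float(np.mean(y))
        self._y_std = float(np.std(y)) or 1.0
        yn = (y - self._y_mean) / self._y_std

        n = X.shape[0]
        if groups is not None and len(np.unique(groups)) >= 2:
            tr, va = next(
                GroupShuffleSplit(
                    n_splits=1, test_size=self.val_fraction,
                    random_state=self.random_state,
                ).split(X, yn, groups)
            )
        else:
            perm = rng.permutation(n)
            n_val = max(1, int(round(self.val_fraction * n)))
            va, tr = perm[:n_val], perm[n_val:]

        opt = nn.Adam(list(net.trainable_parameters()), lr=self.lr)
        best_mae, best_state, best_epoch = np.inf, None, 0
        trace = []
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(tr)
            ep_losses = []
            for lo in range(0, order.size, self.batch_size):
                idx = order[lo : lo + self.batch_size]
                feat = net.features(X[idx], train=True)
                pred = net.forward_head(feat, "reg", train=True)
                loss, g = nn.l1_loss(pred, yn[idx, None])
                opt.zero_grad()
                net.backward_from_heads({"reg": g})
                opt.step()
                ep_losses.append(loss)
            val_mae = float(
                np.mean(np.abs(self._predict_norm(net, X[va]) - yn[va]))
            )
            trace.append({"epoch": epoch, "train_l1": float(np.mean(ep_losses)),
                          "val_mae": val_mae})
            if val_mae < best_mae - 1e-6:
                best_mae, best_epoch = val_mae, epoch
                best_state = net.state()
            elif epoch - best_epoch >= self.patience:
                break
        if best_state is not None:
            net.load_state(best_state)
        self.net_ = net
        self.loss_trace_ = pd.DataFrame(trace)
        self.best_epoch_ = best_epoch
        self.stopped_epoch_ = trace[-1]["epoch"]
        self.best_val_mae_ = best_mae * self._y_std
        return self

    def _predict_norm(self, net: GaitNet, X: np.ndarray) -> np.ndarray:
        out = []
        for lo in range(0, X.shape[0], 256):
            out.append(net.predict(X[lo : lo + 256], "reg"))
        return np.concatenate(out) if out else np.empty(0)

    def predict(self, X):
        X = _as_bcl(X)
        return self._predict_norm(self.net_, X) * self._y_std + self._y_mean


def finetune(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray | None = None,
    net_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    pretrained_state: dict | None = None,
) -> ConvGaitRegressor:
    """Functional wrapper: fine-tune one outcome head end-to-end."""
    ncfg = net_cfg or NetworkConfig()
    tcfg = train_cfg or TrainConfig()
    est = ConvGaitRegressor(
        n_res_blocks=ncfg.n_res_blocks,
        channels=ncfg.channels,
        kernel_size=ncfg.kernel_size,
        head_depth=ncfg.head_depth,
        head_width=ncfg.head_width,
        dropout=ncfg.dropout,
        freeze_backbone=ncfg.freeze_backbone,
        lr=tcfg.lr,
        batch_size=tcfg.batch_size,
        max_epochs=tcfg.max_epochs,
        patience=tcfg.patience,
        random_state=tcfg.seed,
        pretrained_state=pretrained_state,
    )
    return est.fit(X, y, groups=groups)


# ---------------------------------------------------------------------------
# stride-length fusion
# ---------------------------------------------------------------------------

def fuse_stride_length(direct_cm, speed_cms, cadence_spm):
    """Average the direct stride-length estimate with speed/(cadence/120).

    cadence/120 is strides per second, so 120 x speed / cadence is the
    kinematically derived stride length in cm. The fused value is the simple
    average and therefore always lies between the two estimates.
    """
    direct = np.asarray(direct_cm, dtype=float)
    speed = np.asarray(speed_cms, dtype=float)
    cadence = np.asarray(cadence_spm, dtype=float)
    if np.any(cadence <= 0):
        raise DataError("cadence must be > 0 to derive stride length")
    derived = 120.0 * speed / cadence
    fused = 0.5 * (direct + derived)
    if fused.ndim == 0:
        return float(fused)
    return fused


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def tune_hyperparameters(
    search_space: dict[str, list],
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    strata: np.ndarray | None = None,
    trials: int = 10,
    seed: int = 0,
    cv_folds: int = 5,
    base_params: dict | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Pure random search under grouped (optionally stratified) K-fold CV.

    Samples ``trials`` configurations uniformly from ``search_space`` (a
    dict of candidate lists over ConvGaitRegressor parameters), scores each
    by mean validation MAE across folds grouped by subject (stratified by
    ``strata``, e.g. clinical cohort, when provided), and returns the argmin
    along with the full trial log.
    """
    if not search_space:
        raise ConfigError("search space is empty")
    if trials < 1:
        raise ConfigError("trials must be >= 1")
    X = _as_bcl(X)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    keys = sorted(search_space)
    configs = []
    for _ in range(trials):
        configs.append({k: search_space[k][rng.integers(0, len(search_space[k]))]
                        for k in keys})
    if strata is not None:
        splitter = StratifiedGroupKFold(n_splits=cv_folds)
        splits = list(splitter.split(X, strata, groups))
    else:
        splitter = GroupKFold(n_splits=cv_folds)
        splits = list(splitter.split(X, y, groups))
    log_rows = []
    for i, cfg in enumerate(configs):
        maes = []
        for tr, va in splits:
            params = dict(base_params or {})
            params.update(cfg)
            params.setdefault("random_state", seed + i)
            est = ConvGaitRegressor(**params)
            est.fit(X[tr], y[tr], groups=np.asarray(groups)[tr])
            maes.append(float(np.mean(np.abs(est.predict(X[va]) - y[va]))))
        log_rows.append({**cfg, "trial": i, "mean_val_mae": float(np.mean(maes))})
    log = pd.DataFrame(log_rows)
    best = log.loc[log["mean_val_mae"].idxmin()]
    best_params = {k: best[k] for k in keys}
    return best_params, log
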