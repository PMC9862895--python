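"""3D CNN ligandability classifier: architecture, sampling and training protocol.

The classifier maps an 8-channel 19x19x19 property cube to a two-class
probability vector (non-ligandable, ligandable).  The feature extractor has
four convolutions and two max-poolings, each conv/dense output passing
through ReLU and batch normalization, with one dropout layer before the
classifier head.

Training follows a cluster-aware protocol: a batch draws nc clusters, one
chain per cluster and np surface points per chain (nc*np samples), with
ligandable points oversampled so the two classes are fed to the model in
equal expected proportion.  The learning rate follows a one-cycle schedule.
Dataset splits for cross-validation are made at cluster granularity so that
similar chains never straddle the train/test boundary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .featurize import GRID_SIZE, N_CHANNELS, SurfacePointSet, compute_grids

logger = logging.getLogger(__name__)

TESTED_NC_NP = ((16, 32), (32, 16), (64, 8), (128, 4))


@dataclass
class NetConfig:
    """Architecture hyperparameters (defaults favour width over depth)."""

    conv_channels: tuple = (32, 64, 64, 128)
    dense_widths: tuple = (256, 2)
    dropout_rate: float = 0.3
    kernel: int = 3
    in_channels: int = N_CHANNELS
    grid_size: int = GRID_SIZE


@dataclass
class TrainConfig:
    """Training protocol parameters."""

    epochs: int = 40
    clusters_per_epoch: int = 1024
    nc: int = 64          # clusters per batch
    np_points: int = 8    # surface points per chain; batch = nc * np_points
    max_lr: float = 1e-3
    seed: int = 0

    @property
    def batch_size(self) -> int:
        return self.nc * self.np_points

    @property
    def steps_per_epoch(self) -> int:
        return max(1, math.ceil(self.clusters_per_epoch / self.nc))


class LigandabilityNet:
    """Wrapper pairing the layer stack with softmax output semantics."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c = cfg.in_channels
        layers = []
        size = cfg.grid_size
        for i, out_c in enumerate(cfg.conv_channels):
            layers += [nn.Conv3d(c, out_c, cfg.kernel, rng=rng),
                       nn.ReLU(), nn.BatchNorm(out_c)]
            c = out_c
            if i in (1, 3):  # pool after conv blocks 2 and 4
                layers.append(nn.MaxPool3d())
                size //= 2
        layers.append(nn.Flatten())
        n_flat = c * size ** 3
        layers.append(nn.Dropout(cfg.dropout_rate))
        widths = cfg.dense_widths
        n_in = n_flat
        for i, w in enumerate(widths):
            layers.append(nn.Dense(n_in, w, rng=rng))
            if i < len(widths) - 1:
                layers += [nn.ReLU(), nn.BatchNorm(w)]
            n_in = w
        if widths[-1] != 2:
            raise ValueError("output layer must have 2 classes")
        self.net = nn.Sequential(layers)

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def forward_train(self, x, rng):
        logits = self.net.forward(x.astype(nn.F32), train=True, rng=rng)
        return nn.softmax(logits)

    def predict_proba(self, x, batch: int = 256) -> np.ndarray:
        """Class probabilities in evaluation mode, (n, 2) rows summing to 1."""
        x = np.asarray(x, dtype=nn.F32)
        if x.ndim == 4:
            x = x[None]
        expected = (self.cfg.in_channels,) + (self.cfg.grid_size,) * 3
        if x.shape[1:] != expected:
            raise ValueError(f"input shape {x.shape[1:]} != {expected}")
        out = [nn.softmax(self.net.forward(x[lo:lo + batch], train=False))
               for lo in range(0, len(x), batch)]
        return np.concatenate(out, axis=0)


def build_network(cfg: NetConfig | None = None, seed: int = 0) -> LigandabilityNet:
    return LigandabilityNet(cfg or NetConfig(), seed=seed)


@dataclass
class FeaturizedChain:
    """Pre-computed training material for one chain: a pool of surface points
    with labels and their property grids."""

    chain_ref: str
    cluster_id: int
    grids: np.ndarray          # (n_pool, 8, s, s, s) float32
    labels: np.ndarray         # bool (n_pool,)
    pool_indices: np.ndarray = None  # indices into the full surface point set

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.pool_indices is None:
            self.pool_indices = np.arange(len(self.labels))


def _sample_chain_points(chain: FeaturizedChain, np_points: int, rng) -> np.ndarray:
    """Indices of np_points pool points, ligandable half oversampled."""
    pos = np.flatnonzero(chain.labels)
    neg = np.flatnonzero(~chain.labels)
    if len(pos) == 0:
        logger.debug("chain %s has no ligandable points; sampling negatives only",
                     chain.chain_ref)
        return rng.choice(neg, size=np_points, replace=True)
    if len(neg) == 0:
        return rng.choice(pos, size=np_points, replace=True)
    n_pos = np_points // 2
    return np.concatenate([
        rng.choice(pos, size=n_pos, replace=True),
        rng.choice(neg, size=np_points - n_pos, replace=True),
    ])


def sample_batch(chains_by_cluster: dict, nc: int, np_points: int, rng) -> tuple:
    """One training batch: nc clusters, one chain each, np_points per chain."""
    cluster_ids = sorted(chains_by_cluster)
    if len(cluster_ids) < nc:
        raise ValueError(f"need >= {nc} clusters, have {len(cluster_ids)}")
    chosen = rng.choice(len(cluster_ids), size=nc, replace=False)
    xs, ys = [], []
    for ci in chosen:
        chains = chains_by_cluster[cluster_ids[ci]]
        chain = chains[rng.integers(len(chains))]
        idx = _sample_chain_points(chain, np_points, rng)
        xs.append(chain.grids[idx])
        ys.append(chain.labels[idx])
    return np.concatenate(xs, axis=0), np.concatenate(ys, axis=0).astype(int)


def one_cycle_lr(step: int, total_steps: int, max_lr: float,
                 warmup_frac: float = 0.3, start_div: float = 25.0,
                 final_div: float = 1000.0) -> float:
    """Piecewise-linear one-cycle schedule: rise from max_lr/start_div to
    max_lr over the first warmup fraction, then descend to max_lr/final_div."""
    if not 0 <= step <= total_steps:
        raise ValueError("step outside schedule")
    peak = warmup_frac * total_steps
    if total_steps == 0:
        return max_lr
    if step <= peak:
        f = step / peak if peak > 0 else 1.0
        return max_lr / start_div + f * (max_lr - max_lr / start_div)
    f = (step - peak) / (total_steps - peak)
    return max_lr + f * (max_lr / final_div - max_lr)


@dataclass
class CvSplit:
    fold_id: int
    train_clusters: set
    validation_clusters: set
    test_clusters: set


def make_cv_splits(clusters: list, n_folds: int = 10, rng=None) -> list:
    """Cluster-granular splits: shuffle once, use block i as the fold's test
    set and the next block as validation, so the n test sets are pairwise
    disjoint and jointly cover all clusters (80/10/10 up to rounding)."""
    clusters = list(clusters)
    if len(clusters) < n_folds:
        raise ValueError(f"need >= {n_folds} clusters, have {len(clusters)}")
    rng = rng or np.random.default_rng(0)
    order = list(rng.permutation(len(clusters)))
    blocks = np.array_split(order, n_folds)
    splits = []
    for i in range(n_folds):
        test = {clusters[j] for j in blocks[i]}
        val = {clusters[j] for j in blocks[(i + 1) % n_folds]}
        train = set(clusters) - test - val
        splits.append(CvSplit(i, train, val, test))
    return splits


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)   # per step
    epoch_train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)     # per epoch

    def last5_val_mean(self) -> float:
        if not self.val_loss:
            return math.nan
        return float(np.mean(self.val_loss[-5:]))


def _eval_loss(model: LigandabilityNet, chains: list, rng,
               max_points: int = 512) -> float:
    xs, ys = [], []
    for ch in chains:
        idx = np.arange(len(ch.labels))
        if len(idx) > max_points // max(1, len(chains)):
            idx = rng.choice(idx, size=max_points // len(chains), replace=False)
        xs.append(ch.grids[idx])
        ys.append(ch.labels[idx])
    x = np.concatenate(xs, axis=0)
    y = np.concatenate(ys, axis=0).astype(int)
    return nn.cross_entropy(model.predict_proba(x), y)


def train(model: LigandabilityNet, train_chains: dict, cfg: TrainConfig,
          val_chains: dict | None = None) -> TrainHistory:
    """Train with cluster-aware sampling, one-cycle LR and Adam.

    `train_chains` / `val_chains` map cluster id -> list of FeaturizedChain.
    Raises on divergence (NaN loss).
    """
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.net.params, lr=cfg.max_lr)
    total_steps = cfg.epochs * cfg.steps_per_epoch
    hist = TrainHistory()
    step = 0
    val_list = ([c for cl in val_chains.values() for c in cl]
                if val_chains else None)
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for _ in range(cfg.steps_per_epoch):
            x, y = sample_batch(train_chains, cfg.nc, cfg.np_points, rng)
            probs = model.forward_train(x, rng)
            loss = nn.cross_entropy(probs, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at step {step} (loss={loss}); "
                    f"lower max_lr={cfg.max_lr}")
            model.net.backward(nn.softmax_ce_backward(probs, y))
            opt.lr = one_cycle_lr(step, max(1, total_steps - 1), cfg.max_lr)
            opt.step(model.net.grads)
            hist.train_loss.append(loss)
            epoch_losses.append(loss)
            step += 1
        hist.epoch_train_loss.append(float(np.mean(epoch_losses)))
        if val_list:
            hist.val_loss.append(_eval_loss(model, val_list, rng))
    return hist


def config_hash(cfg: NetConfig) -> str:
    """Short stable digest of the architecture configuration."""
    blob = json.dumps(asdict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def save_model(model: LigandabilityNet, path,
               train_cfg: TrainConfig | None = None) -> None:
    """Checkpoint: npz of all weights plus a JSON header with the config
    and its hash (batch-norm running statistics included)."""
    meta = {"net": asdict(model.cfg), "config_hash": config_hash(model.cfg)}
    if train_cfg is not None:
        meta["train"] = asdict(train_cfg)
    arrays = {"__meta__": np.frombuffer(
        json.dumps(meta, default=list).encode(), dtype=np.uint8)}
    for i, layer in enumerate(model.net.layers):
        for j, p in enumerate(layer.params):
            arrays[f"p{i}_{j}"] = p
        if isinstance(layer, nn.BatchNorm):
            arrays[f"bn{i}_mean"] = layer.running_mean
            arrays[f"bn{i}_var"] = layer.running_var
    np.savez(path, **arrays)


def load_model(path) -> LigandabilityNet:
    """Rebuild a checkpointed network; raises if weights and config clash."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        net_meta = {k: tuple(v) if isinstance(v, list) else v
                    for k, v in meta["net"].items()}
        model = LigandabilityNet(NetConfig(**net_meta))
        if meta["config_hash"] != config_hash(model.cfg):
            raise ValueError("checkpoint config hash mismatch")
        for i, layer in enumerate(model.net.layers):
            for j, p in enumerate(layer.params):
                stored = data[f"p{i}_{j}"]
                if stored.shape != p.shape:
                    raise ValueError(f"weight p{i}_{j} shape mismatch")
                p[...] = stored
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = data[f"bn{i}_mean"]
                layer.running_var = data[f"bn{i}_var"]
    return model


def write_history_csv(history: TrainHistory, path) -> None:
    """Per-epoch training log (epoch, train_loss, val_loss)."""
    with open(path, "w") as fh:
        fh.write("epoch,train_loss,val_loss\n")
        for e, tl in enumerate(history.epoch_train_loss):
            vl = (history.val_loss[e] if e < len(history.val_loss) else "")
            fh.write(f"{e},{tl:.6f},{vl if vl == '' else f'{vl:.6f}'}\n")


def predict_points(model: LigandabilityNet, typed_atoms: list,
                   points: SurfacePointSet, spacing: float = 1.0,
                   batch: int = 256) -> SurfacePointSet:
    """Per-point ligandability probability for every surface point."""
    grids = compute_grids(typed_atoms, points.points, spacing=spacing,
                          size=model.cfg.grid_size)
    probs = model.predict_proba(grids, batch=batch)
    return SurfacePointSet(points.points, points.is_ligandable,
                           probs[:, 1], points.chain_ref)
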