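"""PTV2-Fr network assembly, training loop and inference.

The backbone is a compact U-shaped point-transformer encoder-decoder:
per-stage attention blocks over k-NN neighborhoods, grid (voxel) pooling
between stages, and skip connections on the way up.  The attention block
is either MRDCA or a plain scaled dot-product fallback (the ablation
baseline); the decoder output optionally passes through PG-InvFR before
the segmentation head.  All three contributions (MRDCA, PG-InvFR, EL loss)
toggle independently.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .cloud import LabeledCloud
from .losses import LossConfig, el_loss, weighted_cross_entropy
from .metrics import ConfusionCounts, confusion_counts, metric_report
from .mrdca import MRDCA, MultiRadiusConfig, build_knn_graph
from .nn import (AdamW, Linear, Module, ModuleList, MultiStepLR, PointBN,
                 Tensor, gather_rows, segment_max)
from .pg_invfr import PGInvFR, PGInvFRConfig
from .sampling import AugmentConfig, augment, fps_indices


@dataclass
class PTV2FrConfig:
    channels: tuple[int, ...] = (32, 64, 128, 256)
    grid_base: float = 0.02           # meters; doubles per stage
    num_classes: int = 3
    in_dim: int = 6                   # centered xyz + normalized rgb
    use_mrdca: bool = True
    use_pg_invfr: bool = True
    use_el_loss: bool = True
    mrdca: MultiRadiusConfig = field(default_factory=MultiRadiusConfig)
    pg_invfr: PGInvFRConfig = field(default_factory=PGInvFRConfig)
    baseline_k: int = 16              # fallback attention neighborhood
    seed: int = 0

    @classmethod
    def mini(cls, **kw) -> "PTV2FrConfig":
        """Reduced profile for CPU-scale experiments and tests."""
        defaults = dict(channels=(24, 48), grid_base=0.02,
                        mrdca=MultiRadiusConfig(k=(8, 16, 24), branch_channels=8),
                        pg_invfr=PGInvFRConfig(k=8, hidden=16))
        defaults.update(kw)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return {
            "channels": list(self.channels), "grid_base": self.grid_base,
            "num_classes": self.num_classes, "in_dim": self.in_dim,
            "use_mrdca": self.use_mrdca, "use_pg_invfr": self.use_pg_invfr,
            "use_el_loss": self.use_el_loss, "seed": self.seed,
            "baseline_k": self.baseline_k,
            "mrdca": {"k": list(self.mrdca.k),
                      "branch_channels": self.mrdca.branch_channels,
                      "fusion": self.mrdca.fusion},
            "pg_invfr": {"k": self.pg_invfr.k, "residual": self.pg_invfr.residual,
                         "aux_head_weight": self.pg_invfr.aux_head_weight,
                         "iterations": self.pg_invfr.iterations,
                         "hidden": self.pg_invfr.hidden},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PTV2FrConfig":
        d = dict(d)
        if "mrdca" in d:
            m = dict(d["mrdca"])
            if "k" in m:
                m["k"] = tuple(m["k"])
            d["mrdca"] = MultiRadiusConfig(**m)
        if "pg_invfr" in d:
            d["pg_invfr"] = PGInvFRConfig(**d["pg_invfr"])
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return cls(**d)


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 100
    lr: float = 0.001
    weight_decay: float = 0.05
    milestones: tuple[int, ...] = (60, 80)
    gamma: float = 0.05
    seed: int = 0
    max_steps: int | None = None      # optional hard cap on optimizer steps
    train_points: int | None = None   # FPS subsample size for training clouds
    resample_each_step: bool = False  # fresh subsample every step (slower)
    augment: AugmentConfig | None = None
    eval_every: int = 1               # epochs between validation passes

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.lr <= 0:
            raise ValueError("batch size, epochs and lr must be positive")
        if any(m >= self.epochs for m in self.milestones) and self.max_steps is None:
            raise ValueError("milestones must precede the final epoch")


@dataclass
class SegmentationOutput:
    logits: np.ndarray
    probabilities: np.ndarray
    labels: np.ndarray


class BaselineAttention(Module):
    """Scaled dot-product attention over a k-NN graph (ablation baseline,
    standing in for the original grouped vector attention)."""

    def __init__(self, dim: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k = k
        self.scale = 1.0 / np.sqrt(dim)
        self.w_q = Linear(dim, dim, rng)
        self.w_k = Linear(dim, dim, rng)
        self.w_v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)
        self.bn = PointBN(dim)

    def forward(self, features: Tensor, coords: np.ndarray) -> Tensor:
        graph = build_knn_graph(coords, self.k)
        n, c = features.shape
        q = self.w_q(features)
        kf = self.w_k(features)
        v = self.w_v(features)
        kj = gather_rows(kf, graph.idx)
        vj = gather_rows(v, graph.idx)
        scores = (q.reshape(n, 1, c) * kj).sum(axis=2) * self.scale
        w = scores.softmax(axis=1)
        agg = (w.reshape(n, graph.k, 1) * vj).sum(axis=1)
        return self.bn(self.out(agg)).relu()


class _Block(Module):
    """Residual attention block at fixed width."""

    def __init__(self, dim: int, cfg: PTV2FrConfig, rng: np.random.Generator):
        super().__init__()
        if cfg.use_mrdca:
            self.attn = MRDCA(dim, dim, rng, cfg.mrdca)
        else:
            self.attn = BaselineAttention(dim, cfg.baseline_k, rng)

    def forward(self, f: Tensor, coords: np.ndarray) -> Tensor:
        return f + self.attn(f, coords)


def _grid_segments(coords: np.ndarray, cell: float) -> tuple[np.ndarray, int]:
    keys = np.floor(coords / cell).astype(np.int64)
    uniq, inv = np.unique(keys, axis=0, return_inverse=True)
    return inv.ravel(), len(uniq)


class PTV2Fr(Module):
    def __init__(self, config: PTV2FrConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        ch = config.channels
        s = len(ch)
        self.stem = Linear(config.in_dim, ch[0], rng)
        self.stem_bn = PointBN(ch[0])
        self.enc_blocks = ModuleList([_Block(ch[i], config, rng) for i in range(s)])
        self.down = ModuleList([Linear(ch[i], ch[i + 1], rng) for i in range(s - 1)])
        self.down_bn = ModuleList([PointBN(ch[i + 1]) for i in range(s - 1)])
        self.up = ModuleList([Linear(ch[i + 1], ch[i], rng) for i in range(s - 1)])
        self.up_bn = ModuleList([PointBN(ch[i]) for i in range(s - 1)])
        self.dec_blocks = ModuleList([_Block(ch[i], config, rng) for i in range(s - 1)])
        if config.use_pg_invfr:
            self.refiner = PGInvFR(ch[0], config.num_classes, rng, config.pg_invfr)
        else:
            self.refiner = None
        self.head = Linear(ch[0], config.num_classes, rng)

    def forward(self, coords: np.ndarray, features: np.ndarray | Tensor):
        """Returns (logits (N, C) Tensor, aux logits Tensor or None)."""
        cfg = self.config
        x = features if isinstance(features, Tensor) else Tensor(features)
        if x.shape[1] != cfg.in_dim:
            raise ValueError(f"expected {cfg.in_dim} input channels, got {x.shape[1]}")
        f = self.stem_bn(self.stem(x)).relu()
        skips, seg_maps, coord_stack = [], [], [coords]
        cur_coords = coords
        for i, block in enumerate(self.enc_blocks):
            f = block(f, cur_coords)
            if i < len(self.down):
                skips.append(f)
                seg, n_seg = _grid_segments(cur_coords, cfg.grid_base * 2 ** i)
                f = segment_max(self.down_bn[i](self.down[i](f)).relu(), seg, n_seg)
                cur_coords = np.zeros((n_seg, 3))
                np.add.at(cur_coords, seg, coord_stack[-1])
                cur_coords /= np.maximum(np.bincount(seg, minlength=n_seg), 1)[:, None]
                seg_maps.append(seg)
                coord_stack.append(cur_coords)
        for i in reversed(range(len(self.dec_blocks))):
            f = gather_rows(f, seg_maps[i])
            f = self.up_bn[i](self.up[i](f)).relu() + skips[i]
            f = self.dec_blocks[i](f, coord_stack[i])
        aux = None
        if self.refiner is not None:
            f, aux = self.refiner(f, coords)
        return self.head(f), aux


def build_model(config: PTV2FrConfig) -> PTV2Fr:
    if len(config.channels) < 2:
        raise ValueError("need at least 2 stages")
    if any(c < 1 for c in config.channels):
        raise ValueError("channel widths must be positive")
    return PTV2Fr(config)


def cloud_features(cloud: LabeledCloud) -> tuple[np.ndarray, np.ndarray]:
    """(coords, input features): centered xyz plus RGB scaled to [-0.5, 0.5]."""
    coords = cloud.points
    centered = coords - coords.mean(axis=0)
    rgb = cloud.colors.astype(np.float64) / 255.0 - 0.5
    return coords, np.concatenate([centered, rgb], axis=1)


def _forward_loss(model: PTV2Fr, cloud: LabeledCloud, loss_cfg: LossConfig):
    coords, feats = cloud_features(cloud)
    logits, aux = model(coords, feats)
    cfg = model.config
    if cfg.use_el_loss:
        loss = el_loss(logits, cloud.labels, loss_cfg)
    else:
        loss = weighted_cross_entropy(logits, cloud.labels, None,
                                      loss_cfg.ignore_label)
    if aux is not None:
        loss = loss + cfg.pg_invfr.aux_head_weight * weighted_cross_entropy(
            aux, cloud.labels, loss_cfg.class_weights, loss_cfg.ignore_label)
    return loss, logits


def predict(model: PTV2Fr, cloud: LabeledCloud,
            crop_max: int | None = None) -> SegmentationOutput:
    """Full-cloud inference; clouds larger than ``crop_max`` are processed
    as a union of sliding sphere crops so every point is labeled once."""
    model.eval()
    n = len(cloud)
    if crop_max is None or n <= crop_max:
        coords, feats = cloud_features(cloud)
        logits, _ = model(coords, feats)
        logits = logits.data
    else:
        logits = np.zeros((n, model.config.num_classes))
        covered = np.zeros(n, dtype=bool)
        while not covered.all():
            center = cloud.points[np.flatnonzero(~covered)[0]]
            d2 = ((cloud.points - center) ** 2).sum(axis=1)
            take = np.sort(np.argsort(d2, kind="stable")[:crop_max])
            sub = cloud.select(take)
            coords, feats = cloud_features(sub)
            out, _ = model(coords, feats)
            fresh = take[~covered[take]]
            pos = np.searchsorted(take, fresh)
            logits[fresh] = out.data[pos]
            covered[take] = True
    z = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)
    return SegmentationOutput(logits=logits, probabilities=probs,
                              labels=logits.argmax(axis=1))


def evaluate(model: PTV2Fr, clouds: list[LabeledCloud]) -> ConfusionCounts:
    total = None
    for cloud in clouds:
        out = predict(model, cloud)
        cc = confusion_counts(out.labels, cloud.labels, model.config.num_classes)
        total = cc if total is None else ConfusionCounts(total.matrix + cc.matrix)
    return total


def train(model: PTV2Fr, train_clouds: list[LabeledCloud],
          val_clouds: list[LabeledCloud] | None,
          train_config: TrainConfig | None = None,
          loss_config: LossConfig | None = None,
          log_path=None, checkpoint_path=None) -> list[dict]:
    """Train with AdamW + MultiStepLR; returns the per-epoch metric log.

    Each optimizer step averages gradients over a batch of clouds; the
    best-validation-mIoU state is kept (and written to ``checkpoint_path``
    if given).  Deterministic for a fixed seed.
    """
    if not train_clouds:
        raise ValueError("empty training split")
    cfg = train_config or TrainConfig()
    loss_cfg = loss_config or LossConfig()
    if loss_cfg.class_weights is None and model.config.use_el_loss:
        loss_cfg = replace(loss_cfg, class_weights=_auto_weights(train_clouds,
                                                                 model.config.num_classes))
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = MultiStepLR(opt, list(cfg.milestones), cfg.gamma)
    history, best = [], (-1.0, None)
    steps = 0
    fixed = None
    if cfg.train_points is not None and not cfg.resample_each_step:
        # one deterministic subsample per cloud; fixed coordinates let the
        # k-NN graph cache amortize graph construction across epochs
        fixed = [c.select(np.sort(fps_indices(c.points, cfg.train_points,
                                              seed=cfg.seed + i)))
                 if len(c) > cfg.train_points else c
                 for i, c in enumerate(train_clouds)]
    for epoch in range(1, cfg.epochs + 1):
        sched.set_epoch(epoch)
        model.train()
        order = rng.permutation(len(train_clouds))
        losses = []
        t0 = time.time()
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            opt.zero_grad()
            batch_loss = 0.0
            for j in batch:
                cloud = fixed[j] if fixed is not None else train_clouds[j]
                if cfg.augment is not None:
                    cloud = augment(cloud, cfg.augment, rng)
                if (cfg.resample_each_step and cfg.train_points is not None
                        and len(cloud) > cfg.train_points):
                    cloud = cloud.select(np.sort(fps_indices(
                        cloud.points, cfg.train_points,
                        seed=int(rng.integers(2 ** 31)))))
                loss, _ = _forward_loss(model, cloud, loss_cfg)
                (loss * (1.0 / len(batch))).backward()
                batch_loss += float(loss.data) / len(batch)
            opt.step()
            losses.append(batch_loss)
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                break
        entry = {"epoch": epoch, "lr": opt.lr, "steps": steps,
                 "train_loss": float(np.mean(losses)),
                 "seconds": round(time.time() - t0, 3)}
        done = cfg.max_steps is not None and steps >= cfg.max_steps
        if epoch % cfg.eval_every == 0 or epoch == cfg.epochs or done:
            eval_clouds = val_clouds if val_clouds else train_clouds
            rep = metric_report(evaluate(model, eval_clouds))
            entry.update(val_miou=rep.mean_iou, val_precision=rep.mean_precision,
                         val_recall=rep.mean_recall, val_f1=rep.mean_f1)
            if entry["val_miou"] > best[0]:
                best = (entry["val_miou"], model.state_dict())
        history.append(entry)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")
        if done:
            break
    if best[1] is not None:
        model.load_state_dict(best[1])
        if checkpoint_path is not None:
            save_checkpoint(model, checkpoint_path)
    return history


def _auto_weights(clouds: list[LabeledCloud], num_classes: int) -> np.ndarray:
    from .losses import class_weights_from_frequency
    return class_weights_from_frequency([c.labels for c in clouds], num_classes)


def save_checkpoint(model: PTV2Fr, path) -> None:
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        yaml.safe_dump(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> PTV2Fr:
    archive = np.load(path)
    config = PTV2FrConfig.from_dict(
        yaml.safe_load(archive["__config__"].tobytes().decode()))
    model = build_model(config)
    model.load_state_dict({k: archive[k] for k in archive.files if k != "__config__"})
    return model
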