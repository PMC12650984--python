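"""CA-CNN, SA-CNN and MA-CNN assembly and training.

The spectral branch consumes 3x3xB patches through three stride-1 kernel-3
convolutions (batch norm, activation, channel attention after each block,
pool size/stride 2) and global average pooling; the spatial branch consumes
31x31xB patches through kernels 3/5/7 (spatial attention per block, 3x3 max
pooling at stride 2) and global average pooling.  The branch outputs are
concatenated and regressed onto the (min-max scaled) SSC label by two fully
connected layers with a linear output neuron.  Training minimises mean squared
error with the configured optimizer.

All parameter initialisation is keyed on (seed, component, layer) so the
convolutional weights are identical whether attention blocks are present,
frozen, or absent — which is what makes the frozen-attention network exactly
equal to the plain CNN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .attention import ChannelAttentionLayer, SpatialAttentionLayer
from .preprocess import PatchPair

__all__ = [
    "BranchConfig",
    "ModelSpec",
    "TrainedModel",
    "TrainingDivergenceError",
    "build_model",
    "train",
    "predict_sample",
    "predict_per_fruit",
    "count_trainable_parameters",
    "save_model",
    "load_model",
]

KINDS = ("ca-cnn", "sa-cnn", "ma-cnn")


class TrainingDivergenceError(RuntimeError):
    pass


@dataclass
class BranchConfig:
    """One feature-extraction branch: three conv blocks, each batch-normalised."""

    n_filters: tuple[int, int, int]
    kernel_sizes: tuple[int, int, int]
    pool_size: int
    pool_stride: int
    activation: str = "relu"

    @classmethod
    def spectral_default(cls, filters=(32, 64, 128), activation="relu") -> "BranchConfig":
        return cls(tuple(filters), (3, 3, 3), 2, 2, activation)

    @classmethod
    def spatial_default(cls, filters=(64, 128, 56), activation="relu") -> "BranchConfig":
        return cls(tuple(filters), (3, 5, 7), 3, 2, activation)


@dataclass
class ModelSpec:
    kind: str
    spectral_branch: BranchConfig | None = None
    spatial_branch: BranchConfig | None = None
    fc_neurons: tuple[int, int] = (83, 51)
    learning_rate: float = 1e-3
    batch_size: int = 32
    optimizer: str = "adam"
    epochs: int = 30
    fc_activation: str = "relu"
    attention: bool = True

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        needs_spec = self.kind in ("ca-cnn", "ma-cnn")
        needs_spat = self.kind in ("sa-cnn", "ma-cnn")
        if needs_spec and self.spectral_branch is None:
            raise ValueError(f"{self.kind} requires a spectral branch")
        if needs_spat and self.spatial_branch is None:
            raise ValueError(f"{self.kind} requires a spatial branch")
        if not needs_spec and self.spectral_branch is not None:
            raise ValueError(f"{self.kind} must not define a spectral branch")
        if not needs_spat and self.spatial_branch is not None:
            raise ValueError(f"{self.kind} must not define a spatial branch")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        for key in ("spectral_branch", "spatial_branch"):
            if d.get(key) is not None:
                b = dict(d[key])
                b["n_filters"] = tuple(b["n_filters"])
                b["kernel_sizes"] = tuple(b["kernel_sizes"])
                d[key] = BranchConfig(**b)
        d["fc_neurons"] = tuple(d["fc_neurons"])
        return cls(**d)


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, *tags])


class _Branch:
    """Three conv blocks with optional attention, threaded cross-layer state."""

    def __init__(
        self,
        cfg: BranchConfig,
        n_bands: int,
        attention_kind: str | None,
        seed: int,
        branch_tag: int,
        frozen: bool = False,
        dtype=np.float64,
    ):
        self.cfg = cfg
        self.attention_kind = attention_kind
        self.blocks = []
        c_in = n_bands
        for i in range(3):
            c_out = cfg.n_filters[i]
            conv = nn.Conv2d(c_in, c_out, cfg.kernel_sizes[i], _rng(seed, branch_tag, i, 0),
                             name=f"b{branch_tag}.conv{i}", dtype=dtype)
            bn = nn.BatchNorm(c_out, name=f"b{branch_tag}.bn{i}", dtype=dtype)
            act = nn.make_activation(cfg.activation)
            attn = None
            if attention_kind == "channel":
                attn = ChannelAttentionLayer(
                    c_out, _rng(seed, branch_tag, i, 1),
                    c_prev=None if i == 0 else cfg.n_filters[i - 1],
                    name=f"b{branch_tag}.ca{i}", dtype=dtype,
                )
                attn.frozen = frozen
            elif attention_kind == "spatial":
                attn = SpatialAttentionLayer(
                    _rng(seed, branch_tag, i, 1), first_layer=(i == 0),
                    name=f"b{branch_tag}.sa{i}", dtype=dtype,
                )
                attn.frozen = frozen
            pool = nn.MaxPool2d(cfg.pool_size, cfg.pool_stride)
            self.blocks.append((conv, bn, act, attn, pool))
            c_in = c_out
        self.gap = nn.GlobalAvgPool()
        self.out_dim = cfg.n_filters[-1]

    def params(self) -> list[nn.Param]:
        out = []
        for conv, bn, _act, attn, _pool in self.blocks:
            out += conv.params() + bn.params()
            if attn is not None:
                out += attn.params()
        return out

    def bn_layers(self) -> list[nn.BatchNorm]:
        out = []
        for _conv, bn, _act, attn, _pool in self.blocks:
            out.append(bn)
            if isinstance(attn, ChannelAttentionLayer) and attn.c_prev is not None:
                out.append(attn.w0_bn)
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        state = None
        for i, (conv, bn, act, attn, pool) in enumerate(self.blocks):
            x = act.forward(bn.forward(conv.forward(x, training), training), training)
            if attn is not None:
                x, state = attn.forward(x, None if i == 0 else state, training)
            x = pool.forward(x, training)
        return self.gap.forward(x, training)

    def backward(self, dvec: np.ndarray) -> np.ndarray:
        dx = self.gap.backward(dvec)
        dstate = None
        for i in range(2, -1, -1):
            conv, bn, act, attn, pool = self.blocks[i]
            dx = pool.backward(dx)
            if attn is not None:
                dx, dprev = attn.backward(dx, dstate)
                dstate = dprev
            dx = conv.backward(bn.backward(act.backward(dx)))
        return dx


class Model:
    """An assembled (possibly trained) CA/SA/MA network."""

    def __init__(self, spec: ModelSpec, n_bands: int, seed: int = 0,
                 frozen_attention: bool = False, dtype=np.float64):
        self.spec = spec
        self.n_bands = n_bands
        self.seed = seed
        self.dtype = dtype
        self.frozen_attention = frozen_attention
        attention = spec.attention
        self.spectral = self.spatial = None
        feat_dim = 0
        if spec.spectral_branch is not None:
            self.spectral = _Branch(
                spec.spectral_branch, n_bands,
                "channel" if attention else None, seed, 1, frozen=frozen_attention,
                dtype=dtype,
            )
            feat_dim += self.spectral.out_dim
        if spec.spatial_branch is not None:
            self.spatial = _Branch(
                spec.spatial_branch, n_bands,
                "spatial" if attention else None, seed, 2, frozen=frozen_attention,
                dtype=dtype,
            )
            feat_dim += self.spatial.out_dim
        fc1, fc2 = spec.fc_neurons
        r = _rng(seed, 3)
        self.head = [
            nn.Dense(feat_dim, fc1, r, name="head.fc1", dtype=dtype),
            nn.make_activation(spec.fc_activation),
            nn.Dense(fc1, fc2, r, name="head.fc2", dtype=dtype),
            nn.make_activation(spec.fc_activation),
            nn.Dense(fc2, 1, r, name="head.out", dtype=dtype),
        ]
        self.label_scaler: tuple[float, float] | None = None
        self.history: list[dict] = []

    def params(self) -> list[nn.Param]:
        out = []
        for br in (self.spectral, self.spatial):
            if br is not None:
                out += br.params()
        for layer in self.head:
            out += layer.params()
        return out

    def bn_layers(self) -> list[nn.BatchNorm]:
        out = []
        for br in (self.spectral, self.spatial):
            if br is not None:
                out += br.bn_layers()
        return out

    def _ctx_holders(self) -> list:
        """Every object owning a backprop context stack."""
        out = []
        for br in (self.spectral, self.spatial):
            if br is None:
                continue
            for conv, bn, act, attn, pool in br.blocks:
                out += [conv, bn, act, pool]
                if attn is not None:
                    out.append(attn)
                    if hasattr(attn, "mlp"):
                        out += [attn.mlp.fc1, attn.mlp.act, attn.mlp.fc2]
                        if attn.c_prev is not None:
                            out += [attn.w0, attn.w0_bn, attn.w0_act]
                    else:
                        out.append(attn.ws)
                        if not attn.first_layer:
                            out.append(attn.wl)
            out.append(br.gap)
        out += self.head
        return out

    def clear_caches(self) -> None:
        for layer in self._ctx_holders():
            if hasattr(layer, "_ctx"):
                layer._ctx.clear()

    def refresh_bn_stats(self, xs: np.ndarray | None, xp: np.ndarray | None,
                         batch_size: int = 64) -> None:
        """Re-estimate batch-norm statistics over a full dataset pass.

        The EMA kept during optimisation reflects only the last few minibatches
        and can shift eval-mode predictions by a constant; averaging batch
        statistics over the whole calibration set removes that bias.
        """
        bns = self.bn_layers()
        for bn in bns:
            bn.start_stat_collection()
        n = (xs if xs is not None else xp).shape[0]
        for lo in range(0, n, batch_size):
            hi = min(lo + batch_size, n)
            if hi - lo < 2:
                continue
            self.forward(
                None if xs is None else xs[lo:hi],
                None if xp is None else xp[lo:hi],
                training=True,
            )
            self.clear_caches()
        for bn in bns:
            bn.finish_stat_collection()

    def forward(self, xs: np.ndarray | None, xp: np.ndarray | None, training: bool = False) -> np.ndarray:
        feats = []
        if self.spectral is not None:
            feats.append(self.spectral.forward(np.asarray(xs, dtype=np.float64), training))
        if self.spatial is not None:
            feats.append(self.spatial.forward(np.asarray(xp, dtype=np.float64), training))
        h = np.concatenate(feats, axis=1)
        self._feat_split = [f.shape[1] for f in feats]
        for layer in self.head:
            h = layer.forward(h, training)
        return h[:, 0]

    def backward(self, dy: np.ndarray) -> None:
        dh = dy[:, None]
        for layer in reversed(self.head):
            dh = layer.backward(dh)
        splits = np.cumsum(self._feat_split)[:-1]
        parts = np.split(dh, splits, axis=1)
        i = 0
        if self.spectral is not None:
            self.spectral.backward(parts[i]); i += 1
        if self.spatial is not None:
            self.spatial.backward(parts[i])

    def predict_scaled(self, xs: np.ndarray | None, xp: np.ndarray | None,
                       batch_size: int = 256) -> np.ndarray:
        n = (xs if xs is not None else xp).shape[0]
        out = np.empty(n)
        for lo in range(0, n, batch_size):
            hi = min(lo + batch_size, n)
            out[lo:hi] = self.forward(
                None if xs is None else xs[lo:hi],
                None if xp is None else xp[lo:hi],
                training=False,
            )
        return out

    def predict_brix(self, xs: np.ndarray | None, xp: np.ndarray | None) -> np.ndarray:
        if self.label_scaler is None:
            raise RuntimeError("model has no label scaler; train it first")
        lo, hi = self.label_scaler
        return self.predict_scaled(xs, xp) * (hi - lo) + lo


@dataclass
class TrainedModel:
    """A trained network plus its training history and label scaling."""

    model: Model
    training_history: list[dict]
    label_scaler: tuple[float, float]

    def predict_brix(self, xs, xp) -> np.ndarray:
        return self.model.predict_brix(xs, xp)


def build_model(spec: ModelSpec, n_bands: int, seed: int = 0, frozen_attention: bool = False,
                dtype=np.float64) -> Model:
    """Assemble an untrained network for ``n_bands``-band patch pairs.

    ``dtype=np.float32`` roughly halves training time and memory; float64 is
    the default so small-tensor checks are exact.
    """
    if spec.kind == "ma-cnn" and (spec.spectral_branch is None or spec.spatial_branch is None):
        raise ValueError("ma-cnn requires both branches")  # also enforced by ModelSpec
    return Model(spec, n_bands, seed=seed, frozen_attention=frozen_attention, dtype=dtype)


def count_trainable_parameters(model: Model | TrainedModel) -> int:
    """Total learnable scalar count (conv/dense weights, BN affine, lambdas, attention convs)."""
    if isinstance(model, TrainedModel):
        model = model.model
    return int(sum(p.size for p in model.params()))


def train(
    model: Model,
    xs: np.ndarray | None,
    xp: np.ndarray | None,
    labels_brix: np.ndarray,
    spec: ModelSpec | None = None,
    seed: int = 0,
    val: tuple | None = None,
    label_scaler: tuple[float, float] | None = None,
) -> TrainedModel:
    """Train on patch pairs with MSE loss; labels are min-max scaled internally.

    ``val`` is an optional (xs, xp, y_brix) triple whose patch-level R² is
    recorded per epoch.  The history always has exactly ``epochs`` entries.
    """
    spec = spec or model.spec
    y = np.asarray(labels_brix, dtype=np.float64)
    n = y.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if label_scaler is None:
        lo, hi = float(y.min()), float(y.max())
        if hi == lo:
            hi = lo + 1.0
        label_scaler = (lo, hi)
    model.label_scaler = label_scaler
    lo, hi = label_scaler
    y_scaled = (y - lo) / (hi - lo)
    opt = nn.make_optimizer(spec.optimizer, model.params(), spec.learning_rate)
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    history = []
    bs = max(2, min(spec.batch_size, n))
    for epoch in range(spec.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = perm[start : start + bs]
            if idx.size < 2:
                continue  # batch norm needs at least two samples
            opt.zero_grad()
            pred = model.forward(
                None if xs is None else xs[idx],
                None if xp is None else xp[idx],
                training=True,
            )
            err = pred - y_scaled[idx]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"loss became non-finite at epoch {epoch}; "
                    f"learning rate {spec.learning_rate} may be too large"
                )
            model.backward(2.0 * err / idx.size)
            opt.step()
            losses.append(loss)
        if epoch == spec.epochs - 1:
            model.refresh_bn_stats(xs, xp, batch_size=bs)
        entry = {"epoch": epoch, "loss": float(np.mean(losses)) if losses else float("nan")}
        if val is not None:
            vxs, vxp, vy = val
            vpred = model.predict_brix(vxs, vxp)
            vy = np.asarray(vy, dtype=np.float64)
            ss_tot = float(np.sum((vy - vy.mean()) ** 2))
            entry["val_r2"] = 1.0 - float(np.sum((vy - vpred) ** 2)) / ss_tot if ss_tot else float("nan")
        else:
            entry["val_r2"] = float("nan")
        history.append(entry)
    model.history = history
    return TrainedModel(model=model, training_history=history, label_scaler=label_scaler)


def _stack_pairs(pairs: list[PatchPair]) -> tuple[np.ndarray, np.ndarray]:
    xs = np.stack([p.spectral_patch for p in pairs])
    xp = np.stack([p.spatial_patch for p in pairs])
    return xs, xp


def predict_sample(model: TrainedModel | Model, patch_pairs: list[PatchPair]) -> float:
    """Per-fruit SSC (°Brix): mean of per-patch predictions, inverse-scaled."""
    if len(patch_pairs) == 0:
        raise ValueError("need at least one patch pair")
    m = model.model if isinstance(model, TrainedModel) else model
    xs, xp = _stack_pairs(patch_pairs)
    preds = m.predict_brix(
        xs if m.spectral is not None else None,
        xp if m.spatial is not None else None,
    )
    return float(preds.mean())


def predict_per_fruit(
    model: TrainedModel | Model,
    xs: np.ndarray | None,
    xp: np.ndarray | None,
    patch_ids: list[str],
) -> tuple[list[str], np.ndarray]:
    """Aggregate patch predictions to one °Brix value per fruit id."""
    m = model.model if isinstance(model, TrainedModel) else model
    preds = m.predict_brix(
        xs if m.spectral is not None else None,
        xp if m.spatial is not None else None,
    )
    order: list[str] = []
    sums: dict[str, list[float]] = {}
    for pid, p in zip(patch_ids, preds):
        if pid not in sums:
            sums[pid] = []
            order.append(pid)
        sums[pid].append(float(p))
    return order, np.array([np.mean(sums[pid]) for pid in order])


def save_model(trained: TrainedModel, path: str | Path) -> Path:
    """Write parameters (npz) plus a JSON sidecar (spec, scaler, param count)."""
    path = Path(path)
    m = trained.model
    arrays = {}
    for i, p in enumerate(m.params()):
        arrays[f"p{i:04d}"] = p.value
    for i, bn in enumerate(m.bn_layers()):
        arrays[f"bn{i:04d}_mean"] = bn.running_mean
        arrays[f"bn{i:04d}_var"] = bn.running_var
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {
        "spec": m.spec.to_dict(),
        "n_bands": m.n_bands,
        "seed": m.seed,
        "label_scaler": list(trained.label_scaler),
        "n_trainable_parameters": count_trainable_parameters(m),
        "training_history": trained.training_history,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec = ModelSpec.from_dict(sidecar["spec"])
    model = build_model(spec, sidecar["n_bands"], seed=sidecar["seed"])
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(model.params()):
        p.value[...] = data[f"p{i:04d}"]
    for i, bn in enumerate(model.bn_layers()):
        bn.running_mean[...] = data[f"bn{i:04d}_mean"]
        bn.running_var[...] = data[f"bn{i:04d}_var"]
    model.label_scaler = tuple(sidecar["label_scaler"])
    model.history = sidecar["training_history"]
    return TrainedModel(model=model, training_history=model.history,
                        label_scaler=model.label_scaler)
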