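"""Light-attention binary classifier over per-residue embeddings.

A fast repeat/non-repeat pre-filter: two 1D convolutions over the sequence
axis produce attention logits and feature maps; per-channel softmax attention
weights the features, and the attention-weighted sum is concatenated with a
per-channel max-pool into a fixed-size vector (2*channels, independent of
sequence length) feeding a linear head with a sigmoid.  The channel-mean of
the raw attention logits gives a per-residue attention profile that localizes
the regions driving the prediction.

The model is small enough that it is implemented directly in numpy with
hand-derived gradients (im2col convolution, softmax/BCE backward pass, Adam),
keeping training fully deterministic under a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embeddings import InputError, ParameterError, ResidueEmbedding


@dataclass(frozen=True)
class ClassifierConfig:
    filter_size: int = 9
    channels: int = 1024
    dropout_rate: float = 0.25
    learning_rate: float = 1e-6
    patience: int = 20
    max_epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    train_fraction: float = 0.9

    def validate(self) -> None:
        if self.filter_size % 2 == 0 or self.filter_size < 1:
            raise ParameterError("filter_size must be odd and positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("dropout_rate must lie in [0, 1)")
        if not 0.0 < self.train_fraction < 1.0:
            raise ParameterError("train_fraction must lie in (0, 1)")


def small_config(**overrides) -> ClassifierConfig:
    """Small configuration for synthetic data (32 channels, lr 1e-3)."""
    defaults = dict(channels=32, learning_rate=1e-3)
    defaults.update(overrides)
    return ClassifierConfig(**defaults)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0


@dataclass
class AttentionProfile:
    """Per-residue attention scores (channel-mean of raw attention logits)."""

    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.scores)

    def mean_over(self, spans: list[tuple[int, int]]) -> float:
        vals = np.concatenate([self.scores[s:e] for s, e in spans])
        return float(vals.mean())


def prf_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R);
    zero denominators give 0 by convention."""
    precision = c.TP / (c.TP + c.FP) if c.TP + c.FP else 0.0
    recall = c.TP / (c.TP + c.FN) if c.TP + c.FN else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


# ---------------------------------------------------------------------------
# Model state
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """All learnable parameters; conv weights are (channels, D*filter_size)."""

    config: ClassifierConfig
    dim: int
    w_att: np.ndarray
    b_att: np.ndarray
    w_feat: np.ndarray
    b_feat: np.ndarray
    w_out: np.ndarray
    b_out: float

    def params(self) -> dict[str, np.ndarray]:
        return {"w_att": self.w_att, "b_att": self.b_att,
                "w_feat": self.w_feat, "b_feat": self.b_feat,
                "w_out": self.w_out,
                "b_out": np.atleast_1d(np.float64(self.b_out))}

    def copy(self) -> "ModelState":
        return ModelState(self.config, self.dim, self.w_att.copy(),
                          self.b_att.copy(), self.w_feat.copy(),
                          self.b_feat.copy(), self.w_out.copy(),
                          float(self.b_out))


def init_model(config: ClassifierConfig, dim: int) -> ModelState:
    """Seeded Glorot init for the convolutions; the linear head starts at
    zero, so an untrained model outputs probability exactly 0.5."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fan_in = dim * config.filter_size
    scale = np.sqrt(2.0 / (fan_in + config.channels))
    shape = (config.channels, fan_in)
    return ModelState(
        config, dim,
        w_att=rng.normal(0.0, scale, shape),
        b_att=np.zeros(config.channels),
        w_feat=rng.normal(0.0, scale, shape),
        b_feat=np.zeros(config.channels),
        w_out=np.zeros(2 * config.channels),
        b_out=0.0,
    )


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(L, D) -> (L, D*k) patches with zero 'same' padding."""
    L, d = x.shape
    h = k // 2
    xp = np.zeros((L + 2 * h, d))
    xp[h:h + L] = x
    idx = np.arange(L)[:, None] + np.arange(k)[None, :]
    return xp[idx].reshape(L, d * k)


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def forward(e: ResidueEmbedding, model: ModelState,
            dropout_rng: np.random.Generator | None = None
            ) -> tuple[float, AttentionProfile, np.ndarray, dict]:
    """Forward pass for one embedding.

    Returns (probability, attention profile, pooled vector of length
    2*channels, cache for the backward pass).  Dropout is active only when a
    generator is supplied (training mode).
    """
    cfg = model.config
    if e.dim != model.dim:
        raise InputError(f"embedding dim {e.dim} != model dim {model.dim}")
    if e.length < cfg.filter_size:
        raise InputError(f"sequence length {e.length} below filter size "
                         f"{cfg.filter_size}")
    patches = _im2col(e.values, cfg.filter_size)          # (L, D*k)
    att_logits = patches @ model.w_att.T + model.b_att     # (L, C)
    feats = patches @ model.w_feat.T + model.b_feat        # (L, C)
    if dropout_rng is not None and cfg.dropout_rate > 0:
        mask = (dropout_rng.random(feats.shape) >= cfg.dropout_rate)
        feats_d = feats * mask / (1.0 - cfg.dropout_rate)
    else:
        mask = None
        feats_d = feats
    att = _softmax(att_logits, axis=0)                     # over length, per channel
    weighted = (att * feats_d).sum(axis=0)                 # (C,)
    argmax = feats_d.argmax(axis=0)
    pooled = np.concatenate([weighted, feats_d.max(axis=0)])  # (2C,)
    logit = float(pooled @ model.w_out + model.b_out)
    prob = float(1.0 / (1.0 + np.exp(-logit)))
    profile = AttentionProfile(att_logits.mean(axis=1))
    cache = {"patches": patches, "att": att, "feats_d": feats_d,
             "mask": mask, "pooled": pooled, "argmax": argmax, "prob": prob}
    return prob, profile, pooled, cache


def _backward(model: ModelState, cache: dict, y: float) -> dict[str, np.ndarray]:
    """Gradients of the BCE loss for one sample (sigmoid folded in)."""
    cfg = model.config
    C = cfg.channels
    dlogit = cache["prob"] - y
    dpooled = dlogit * model.w_out
    grads = {"w_out": dlogit * cache["pooled"],
             "b_out": np.atleast_1d(np.float64(dlogit))}
    att, feats_d, patches = cache["att"], cache["feats_d"], cache["patches"]
    dweighted, dmax = dpooled[:C], dpooled[C:]
    datt = dweighted[None, :] * feats_d                    # (L, C)
    dfeats_d = dweighted[None, :] * att
    dfeats_d[cache["argmax"], np.arange(C)] += dmax
    # softmax over length, per channel
    datt_logits = att * (datt - (datt * att).sum(axis=0, keepdims=True))
    if cache["mask"] is not None:
        dfeats = dfeats_d * cache["mask"] / (1.0 - cfg.dropout_rate)
    else:
        dfeats = dfeats_d
    grads["w_att"] = datt_logits.T @ patches
    grads["b_att"] = datt_logits.sum(axis=0)
    grads["w_feat"] = dfeats.T @ patches
    grads["b_feat"] = dfeats.sum(axis=0)
    return grads


def _bce(prob: float, y: float, eps: float = 1e-12) -> float:
    p = min(max(prob, eps), 1.0 - eps)
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(dataset: list[tuple[ResidueEmbedding, int]],
          config: ClassifierConfig | None = None
          ) -> tuple[ModelState, list[dict], dict]:
    """Train with Adam on binary cross-entropy; early stopping on held-out loss.

    The dataset is split train/held-out at ``train_fraction`` (seeded
    shuffle); training halts when the held-out loss has not improved for
    ``patience`` epochs and the best state is restored.  Returns the model,
    the per-epoch history, and precision/recall/F1 on the held-out split.
    """
    config = config or ClassifierConfig()
    config.validate()
    labels = {y for _, y in dataset}
    if labels != {0, 1}:
        raise InputError("training needs examples of both classes")
    if len(dataset) < 4:
        raise InputError("dataset too small")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(dataset))
    n_train = int(round(config.train_fraction * len(dataset)))
    train_idx, val_idx = order[:n_train], order[n_train:]
    if len(val_idx) == 0 or len({dataset[i][1] for i in train_idx}) < 2:
        raise InputError("degenerate train/validation split")

    dim = dataset[0][0].dim
    model = init_model(config, dim)
    params = model.params()
    opt = _Adam(params, config.learning_rate)
    drop_rng = np.random.default_rng(config.seed + 1)

    def val_loss_and_counts() -> tuple[float, ConfusionCounts]:
        losses, tp = [], [0, 0, 0, 0]  # TP FP FN TN
        for i in val_idx:
            e, y = dataset[i]
            prob, _, _, _ = forward(e, model)
            losses.append(_bce(prob, y))
            pred = prob >= 0.5
            if pred and y:
                tp[0] += 1
            elif pred and not y:
                tp[1] += 1
            elif not pred and y:
                tp[2] += 1
            else:
                tp[3] += 1
        return float(np.mean(losses)), ConfusionCounts(*tp)

    history: list[dict] = []
    best_loss = np.inf
    best_state = model.copy()
    best_epoch = -1
    for epoch in range(config.max_epochs):
        perm = rng.permutation(train_idx)
        batch_losses = []
        for b0 in range(0, len(perm), config.batch_size):
            batch = perm[b0:b0 + config.batch_size]
            acc = {k: np.zeros_like(v) for k, v in params.items()}
            for i in batch:
                e, y = dataset[i]
                prob, _, _, cache = forward(e, model, dropout_rng=drop_rng)
                batch_losses.append(_bce(prob, y))
                for k, g in _backward(model, cache, float(y)).items():
                    acc[k] += g
            for k in acc:
                acc[k] /= len(batch)
            opt.step(params, acc)
            model.b_out = float(params["b_out"][0])
        vloss, _ = val_loss_and_counts()
        history.append({"epoch": epoch,
                        "train_loss": float(np.mean(batch_losses)),
                        "val_loss": vloss})
        if vloss < best_loss - 1e-12:
            best_loss = vloss
            best_state = model.copy()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break

    model = best_state
    # recompute metrics with the restored best weights
    saved = model
    probs_counts = _evaluate(saved, dataset, val_idx)
    precision, recall, f1 = prf_metrics(probs_counts)
    metrics = {"precision": precision, "recall": recall, "f1": f1,
               "best_epoch": best_epoch, "val_loss": best_loss,
               "n_val": int(len(val_idx))}
    return model, history, metrics


def _evaluate(model: ModelState, dataset, idx) -> ConfusionCounts:
    tp = [0, 0, 0, 0]
    for i in idx:
        e, y = dataset[i]
        prob, _, _, _ = forward(e, model)
        pred = prob >= 0.5
        if pred and y:
            tp[0] += 1
        elif pred and not y:
            tp[1] += 1
        elif not pred and y:
            tp[2] += 1
        else:
            tp[3] += 1
    return ConfusionCounts(*tp)


def classify_batch(embeddings: list[ResidueEmbedding], model: ModelState,
                   threshold: float = 0.5) -> list[tuple[float, int]]:
    """Stateless, order-preserving classification: label = prob >= threshold."""
    out = []
    for e in embeddings:
        prob, _, _, _ = forward(e, model)
        out.append((prob, int(prob >= threshold)))
    return out


# ---------------------------------------------------------------------------
# Serialization (single-file model state)
# ---------------------------------------------------------------------------

def save_model(model: ModelState, path) -> None:
    cfg = model.config
    np.savez(str(path),
             w_att=model.w_att, b_att=model.b_att, w_feat=model.w_feat,
             b_feat=model.b_feat, w_out=model.w_out,
             b_out=np.float64(model.b_out), dim=np.int64(model.dim),
             config=np.array([cfg.filter_size, cfg.channels, cfg.dropout_rate,
                              cfg.learning_rate, cfg.patience, cfg.max_epochs,
                              cfg.batch_size, cfg.seed, cfg.train_fraction]))


def load_model(path) -> ModelState:
    with np.load(str(path)) as z:
        c = z["config"]
        cfg = ClassifierConfig(filter_size=int(c[0]), channels=int(c[1]),
                               dropout_rate=float(c[2]),
                               learning_rate=float(c[3]), patience=int(c[4]),
                               max_epochs=int(c[5]), batch_size=int(c[6]),
                               seed=int(c[7]), train_fraction=float(c[8]))
        return ModelState(cfg, int(z["dim"]), z["w_att"], z["b_att"],
                          z["w_feat"], z["b_feat"], z["w_out"],
                          float(z["b_out"]))


__all__ = [
    "ClassifierConfig", "ConfusionCounts", "AttentionProfile", "ModelState",
    "prf_metrics", "init_model", "forward", "train", "classify_batch",
    "save_model", "load_model", "small_config",
]
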