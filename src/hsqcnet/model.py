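"""Multi-task convolutional network: HSQC image -> chemical properties.

A single convolutional trunk (strided 3x3 conv / batch-norm / ReLU stages,
global max pooling, dropout) feeds four fully connected heads:

* fingerprint — 6144 sigmoid outputs, binary cross-entropy loss;
* class — softmax over the compound-class vocabulary, sparse categorical
  cross-entropy;
* molecular weight — softplus-positive scalar in daltons, mean absolute
  percentage error (MAPE);
* glycoside — single sigmoid, binary cross-entropy.

Separate networks are trained for normal (1-channel) and multiplicity-edited
(2-channel) input; they share code but no weights.  The estimator follows
scikit-learn conventions: hyperparameters in ``__init__``, fitted state in
trailing-underscore attributes, ``fit``/``predict``.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import nn
from .chem import FINGERPRINT_DIM, MoleculeRecord
from .peaks import GRID_SIZE, HSQCImage, SpectrumBounds

__all__ = [
    "ModelConfig",
    "TrainingConfig",
    "Prediction",
    "HSQCNet",
    "multitask_loss",
    "build_model",
    "train",
    "predict",
    "stack_dataset",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``conv_stack`` is a sequence of ``(filters, kernel, stride)`` stages.
    The default — four stages doubling from 32 to 256 filters with 3x3
    kernels and stride-2 downsampling — is a conventional stack for a
    128x128 input; it is fully configurable.
    """

    channels: int = 1
    conv_stack: tuple[tuple[int, int, int], ...] = (
        (32, 3, 2),
        (64, 3, 2),
        (128, 3, 2),
        (256, 3, 2),
    )
    embedding_dim: int = 256
    n_classes: int = 2
    fingerprint_dim: int = FINGERPRINT_DIM
    loss_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.channels not in (1, 2):
            raise ValueError("channels must be 1 (normal) or 2 (edited)")
        if self.fingerprint_dim != FINGERPRINT_DIM:
            raise ValueError(f"fingerprint_dim must be {FINGERPRINT_DIM}")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be nonnegative")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization hyperparameters (Adam)."""

    learning_rate: float = 1e-5
    decay: float = 1e-6
    batch_size: int = 16
    dropout: float = 0.2
    epochs: int = 10
    seed: int = 0
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class Prediction:
    """Model output bundle for one spectrum."""

    fingerprint: np.ndarray
    class_probs: np.ndarray
    mw: float
    glycoside_prob: float

    def __post_init__(self) -> None:
        fp = np.asarray(self.fingerprint, dtype=np.float64)
        cp = np.asarray(self.class_probs, dtype=np.float64)
        if fp.shape != (FINGERPRINT_DIM,):
            raise ValueError(f"fingerprint must have length {FINGERPRINT_DIM}")
        if (fp < 0).any() or (fp > 1).any():
            raise ValueError("fingerprint probabilities must lie in [0, 1]")
        if abs(cp.sum() - 1.0) > 1e-5:
            raise ValueError("class_probs must sum to 1")
        if self.mw <= 0:
            raise ValueError("predicted molecular weight must be positive")
        if not 0 <= self.glycoside_prob <= 1:
            raise ValueError("glycoside_prob must lie in [0, 1]")
        object.__setattr__(self, "fingerprint", fp)
        object.__setattr__(self, "class_probs", cp)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


def _softplus_inv(y: float) -> float:
    # inverse of log(1+exp(z)); for y > ~30 this is y to machine precision
    return float(y + np.log(-np.expm1(-y))) if y < 30 else float(y)


def _bce(p: np.ndarray, t: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean())


def multitask_loss(
    pred: Prediction,
    truth: MoleculeRecord,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
) -> float:
    """Weighted sum of the four head losses for a single example.

    ``w_fp * BCE(fingerprint) + w_class * CCE(class) + w_mw * MAPE(mw)
    + w_gly * BCE(glycoside)``, each term mean-reduced.  MAPE is
    ``100 * |mw_pred - mw_true| / mw_true`` on the dalton scale.
    """
    if truth.mw <= 0:
        raise ValueError("true molecular weight must be positive")
    w_fp, w_class, w_mw, w_gly = weights
    loss = 0.0
    if w_fp:
        loss += w_fp * _bce(pred.fingerprint, truth.fingerprint.astype(np.float64))
    if w_class:
        p = np.clip(pred.class_probs[truth.class_label], _EPS, 1.0)
        loss += w_class * float(-np.log(p))
    if w_mw:
        loss += w_mw * 100.0 * abs(pred.mw - truth.mw) / truth.mw
    if w_gly:
        loss += w_gly * _bce(
            np.asarray([pred.glycoside_prob]), np.asarray([float(truth.glycoside)])
        )
    return loss


class _Network:
    """The layer graph; parameters live in the layers."""

    def __init__(self, cfg: ModelConfig, dropout: float, rng: np.random.Generator):
        self.cfg = cfg
        self.stages: list[tuple[nn.Conv2d, nn.BatchNorm2d, nn.ReLU]] = []
        in_ch = cfg.channels
        for filters, kernel, stride in cfg.conv_stack:
            self.stages.append(
                (
                    nn.Conv2d(in_ch, filters, kernel=kernel, stride=stride, rng=rng),
                    nn.BatchNorm2d(filters),
                    nn.ReLU(),
                )
            )
            in_ch = filters
        self.pool = nn.GlobalMaxPool()
        self.trunk = nn.Dense(in_ch, cfg.embedding_dim, rng=rng)
        self.trunk_act = nn.ReLU()
        self.drop = nn.Dropout(dropout, rng=rng)
        d = cfg.embedding_dim
        self.head_fp = nn.Dense(d, cfg.fingerprint_dim, rng=rng)
        self.head_class = nn.Dense(d, cfg.n_classes, rng=rng)
        self.head_mw = nn.Dense(d, 1, rng=rng)
        self.head_gly = nn.Dense(d, 1, rng=rng)

    def params(self) -> list[nn.Param]:
        out: list[nn.Param] = []
        for conv, bn, _ in self.stages:
            out += conv.params() + bn.params()
        out += self.trunk.params()
        out += self.head_fp.params() + self.head_class.params()
        out += self.head_mw.params() + self.head_gly.params()
        return out

    def buffers(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for _, bn, _ in self.stages:
            out += [bn.running_mean, bn.running_var]
        return out

    def forward(self, x: np.ndarray, training: bool) -> dict[str, np.ndarray]:
        h = x
        for conv, bn, act in self.stages:
            h = act.forward(bn.forward(conv.forward(h, training), training), training)
        emb = self.drop.forward(
            self.trunk_act.forward(self.trunk.forward(self.pool.forward(h, training), training), training),
            training,
        )
        return {
            "fp_logits": self.head_fp.forward(emb, training),
            "class_logits": self.head_class.forward(emb, training),
            "mw_logit": self.head_mw.forward(emb, training),
            "gly_logit": self.head_gly.forward(emb, training),
        }

    def backward(self, grads: dict[str, np.ndarray]) -> None:
        gemb = (
            self.head_fp.backward(grads["fp_logits"])
            + self.head_class.backward(grads["class_logits"])
            + self.head_mw.backward(grads["mw_logit"])
            + self.head_gly.backward(grads["gly_logit"])
        )
        g = self.pool.backward(self.trunk.backward(self.trunk_act.backward(self.drop.backward(gemb))))
        for conv, bn, act in reversed(self.stages):
            g = conv.backward(bn.backward(act.backward(g)))


def _as_nchw(X, channels: int) -> np.ndarray:
    """Accept (n,128,128,C) arrays or lists of HSQCImage; return NCHW float32."""
    if isinstance(X, HSQCImage):
        X = [X]
    if isinstance(X, (list, tuple)) and X and isinstance(X[0], HSQCImage):
        X = np.stack([im.grid for im in X])
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 3:
        X = X[None]
    if X.ndim != 4 or X.shape[1:3] != (GRID_SIZE, GRID_SIZE):
        raise ValueError(f"expected (n, {GRID_SIZE}, {GRID_SIZE}, C) input, got {X.shape}")
    if X.shape[3] != channels:
        raise ValueError(
            f"input has {X.shape[3]} channel(s) but the model expects {channels}"
        )
    return np.ascontiguousarray(X.transpose(0, 3, 1, 2))


def _as_targets(y, n: int) -> dict[str, np.ndarray]:
    if isinstance(y, (list, tuple)) and y and isinstance(y[0], MoleculeRecord):
        y = {
            "fingerprint": np.stack([r.fingerprint for r in y]),
            "class_label": np.array([r.class_label for r in y]),
            "mw": np.array([r.mw for r in y]),
            "glycoside": np.array([float(r.glycoside) for r in y]),
        }
    t = {
        "fingerprint": np.asarray(y["fingerprint"], dtype=np.float32),
        "class_label": np.asarray(y["class_label"], dtype=np.int64),
        "mw": np.asarray(y["mw"], dtype=np.float64),
        "glycoside": np.asarray(y["glycoside"], dtype=np.float32),
    }
    if t["fingerprint"].shape != (n, FINGERPRINT_DIM):
        raise ValueError("fingerprint targets must be (n, 6144)")
    if (t["mw"] <= 0).any():
        raise ValueError("all true molecular weights must be positive")
    return t


class HSQCNet(BaseEstimator):
    """Multi-task CNN estimator mapping HSQC images to chemical properties.

    Parameters follow the training defaults used for corpus-scale runs
    (Adam, lr 1e-5 with 1e-6 inverse-time decay, batch 16, dropout 0.2);
    small synthetic datasets need a larger learning rate (e.g. 1e-3) to
    move within a few dozen epochs.

    Attributes set by :meth:`fit`:

    ``net_`` — the underlying layer graph; ``history_`` — per-epoch
    DataFrame of training/validation losses; ``n_iter_`` — optimizer steps
    taken.
    """

    def __init__(
        self,
        channels: int = 1,
        conv_stack: tuple = ((32, 3, 2), (64, 3, 2), (128, 3, 2), (256, 3, 2)),
        embedding_dim: int = 256,
        n_classes: int = 2,
        loss_weights: tuple = (1.0, 1.0, 1.0, 1.0),
        learning_rate: float = 1e-5,
        decay: float = 1e-6,
        batch_size: int = 16,
        dropout: float = 0.2,
        epochs: int = 10,
        seed: int = 0,
        validation_fraction: float = 0.1,
    ):
        self.channels = channels
        self.conv_stack = conv_stack
        self.embedding_dim = embedding_dim
        self.n_classes = n_classes
        self.loss_weights = loss_weights
        self.learning_rate = learning_rate
        self.decay = decay
        self.batch_size = batch_size
        self.dropout = dropout
        self.epochs = epochs
        self.seed = seed
        self.validation_fraction = validation_fraction

    # -- config plumbing -------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            channels=self.channels,
            conv_stack=tuple(tuple(s) for s in self.conv_stack),
            embedding_dim=self.embedding_dim,
            n_classes=self.n_classes,
            loss_weights=tuple(self.loss_weights),
        )

    def _training_config(self) -> TrainingConfig:
        return TrainingConfig(
            learning_rate=self.learning_rate,
            decay=self.decay,
            batch_size=self.batch_size,
            dropout=self.dropout,
            epochs=self.epochs,
            seed=self.seed,
            validation_fraction=self.validation_fraction,
        )

    # -- training --------------------------------------------------------
    def fit(self, X, y, validation_indices: np.ndarray | None = None) -> "HSQCNet":
        """Train on images ``X`` and targets ``y``.

        ``X``: (n, 128, 128, C) array or list of :class:`HSQCImage`;
        ``y``: list of :class:`MoleculeRecord` or dict with keys
        ``fingerprint``, ``class_label``, ``mw``, ``glycoside``.
        A random seeded ``validation_fraction`` split is held out unless
        explicit ``validation_indices`` are given.
        """
        cfg = self._model_config()
        tcfg = self._training_config()
        Xn = _as_nchw(X, cfg.channels)
        n = Xn.shape[0]
        if n == 0:
            raise ValueError("cannot train on an empty dataset")
        t = _as_targets(y, n)
        if int(t["class_label"].max(initial=0)) >= cfg.n_classes:
            raise ValueError("class label outside the configured vocabulary size")

        rng = np.random.default_rng(tcfg.seed)
        net = _Network(cfg, tcfg.dropout, rng)

        if validation_indices is not None:
            val_idx = np.asarray(validation_indices, dtype=np.int64)
            train_idx = np.setdiff1d(np.arange(n), val_idx)
        else:
            perm = rng.permutation(n)
            n_val = int(round(n * tcfg.validation_fraction))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
        if train_idx.size == 0:
            raise ValueError("validation split left no training examples")

        # GLM-style intercept initialization from training-split marginals:
        # sigmoid/softmax heads start at the class-prior / bit-frequency
        # baseline and the softplus MW head at the mean training MW, so the
        # optimizer spends its steps on per-example signal rather than on
        # dragging thousands of biases to sparse-target logits.
        eps0 = 1.0 / (2.0 * train_idx.size)
        p_fp = np.clip(t["fingerprint"][train_idx].mean(axis=0), eps0, 1 - eps0)
        net.head_fp.bias.value[...] = np.log(p_fp / (1 - p_fp))
        p_cl = np.bincount(t["class_label"][train_idx], minlength=cfg.n_classes) + 0.5
        net.head_class.bias.value[...] = np.log(p_cl / p_cl.sum())
        p_g = float(np.clip(t["glycoside"][train_idx].mean(), eps0, 1 - eps0))
        net.head_gly.bias.value[0] = np.log(p_g / (1 - p_g))
        net.head_mw.bias.value[0] = _softplus_inv(float(t["mw"][train_idx].mean()))

        opt = nn.Adam(net.params(), lr=tcfg.learning_rate, decay=tcfg.decay)
        w = cfg.loss_weights
        shuffle_rng = np.random.default_rng(tcfg.seed + 1)
        rows = []
        for epoch in range(tcfg.epochs):
            order = shuffle_rng.permutation(train_idx)
            losses = []
            for start in range(0, order.size, tcfg.batch_size):
                idx = order[start : start + tcfg.batch_size]
                loss = self._train_step(net, opt, Xn[idx], t, idx, w)
                losses.append(loss)
            row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if val_idx.size:
                row.update(self._evaluate(net, Xn[val_idx], t, val_idx, w))
            rows.append(row)
        self.net_ = net
        self.config_ = cfg
        self.history_ = pd.DataFrame(rows)
        self.n_iter_ = opt.t
        return self

    @staticmethod
    def _head_losses(
        out: dict[str, np.ndarray], t: dict[str, np.ndarray], idx: np.ndarray
    ) -> tuple[dict[str, float], dict[str, np.ndarray]]:
        """Per-head mean losses and gradients w.r.t. the head logits."""
        nb = idx.size
        fp_t = t["fingerprint"][idx]
        p_fp = _sigmoid(out["fp_logits"])
        z = out["fp_logits"]
        bce_fp = float((np.maximum(z, 0) - z * fp_t + np.log1p(np.exp(-np.abs(z)))).mean())
        g_fp = (p_fp - fp_t) / (nb * fp_t.shape[1])

        labels = t["class_label"][idx]
        p_cl = _softmax(out["class_logits"])
        cce = float(-np.log(np.clip(p_cl[np.arange(nb), labels], _EPS, 1.0)).mean())
        g_cl = p_cl.copy()
        g_cl[np.arange(nb), labels] -= 1.0
        g_cl /= nb

        mw_t = t["mw"][idx]
        zmw = out["mw_logit"][:, 0].astype(np.float64)
        mw_p = _softplus(zmw)
        mape = float((100.0 * np.abs(mw_p - mw_t) / mw_t).mean())
        g_mw = (100.0 * np.sign(mw_p - mw_t) / mw_t / nb * _sigmoid(zmw))[:, None]

        gly_t = t["glycoside"][idx]
        zg = out["gly_logit"][:, 0]
        bce_g = float((np.maximum(zg, 0) - zg * gly_t + np.log1p(np.exp(-np.abs(zg)))).mean())
        g_g = ((_sigmoid(zg) - gly_t) / nb)[:, None]

        losses = {"fp_bce": bce_fp, "class_cce": cce, "mape": mape, "gly_bce": bce_g}
        grads = {"fp_logits": g_fp, "class_logits": g_cl, "mw_logit": g_mw, "gly_logit": g_g}
        return losses, grads

    def _train_step(self, net, opt, xb, t, idx, w) -> float:
        out = net.forward(xb, training=True)
        losses, grads = self._head_losses(out, t, idx)
        wmap = dict(zip(("fp_bce", "class_cce", "mape", "gly_bce"), w))
        total = sum(wmap[k] * v for k, v in losses.items())
        gkeys = {"fp_bce": "fp_logits", "class_cce": "class_logits", "mape": "mw_logit", "gly_bce": "gly_logit"}
        scaled = {
            gkeys[k]: (wmap[k] * grads[gkeys[k]]).astype(np.float32) for k in losses
        }
        opt.zero_grad()
        net.backward(scaled)
        opt.step()
        return total

    def _evaluate(self, net, xv, t, idx, w, batch: int = 64) -> dict[str, float]:
        parts: list[dict[str, float]] = []
        sizes = []
        for start in range(0, xv.shape[0], batch):
            sl = slice(start, start + batch)
            out = net.forward(xv[sl], training=False)
            losses, _ = self._head_losses(out, t, idx[sl])
            parts.append(losses)
            sizes.append(idx[sl].size)
        tot = np.asarray(sizes, dtype=float)
        agg = {
            f"val_{k}": float(sum(p[k] * s for p, s in zip(parts, tot)) / tot.sum())
            for k in parts[0]
        }
        agg["val_loss"] = float(
            sum(wi * agg[f"val_{k}"] for wi, k in zip(w, ("fp_bce", "class_cce", "mape", "gly_bce")))
        )
        return agg

    # -- inference -------------------------------------------------------
    def predict_arrays(self, X, batch: int = 64) -> dict[str, np.ndarray]:
        """Batched inference; returns arrays keyed by head name."""
        if not hasattr(self, "net_"):
            raise RuntimeError("model is not fitted")
        Xn = _as_nchw(X, self.config_.channels)
        outs = {"fingerprint": [], "class_probs": [], "mw": [], "glycoside_prob": []}
        for start in range(0, Xn.shape[0], batch):
            o = self.net_.forward(Xn[start : start + batch], training=False)
            outs["fingerprint"].append(_sigmoid(o["fp_logits"]))
            outs["class_probs"].append(_softmax(o["class_logits"]))
            outs["mw"].append(_softplus(o["mw_logit"][:, 0].astype(np.float64)))
            outs["glycoside_prob"].append(_sigmoid(o["gly_logit"][:, 0]))
        return {k: np.concatenate(v) for k, v in outs.items()}

    def predict(self, X) -> list[Prediction]:
        """Predictions as :class:`Prediction` bundles, one per spectrum."""
        arrs = self.predict_arrays(X)
        return [
            Prediction(
                fingerprint=arrs["fingerprint"][i],
                class_probs=arrs["class_probs"][i],
                mw=float(max(arrs["mw"][i], _EPS)),
                glycoside_prob=float(arrs["glycoside_prob"][i]),
            )
            for i in range(len(arrs["mw"]))
        ]

    def predict_one(self, image: HSQCImage) -> Prediction:
        return self.predict([image])[0]


# -- functional wrappers over the estimator ------------------------------


def build_model(cfg: ModelConfig, tcfg: TrainingConfig | None = None) -> HSQCNet:
    """Instantiate an (unfitted) estimator from config dataclasses."""
    tcfg = tcfg or TrainingConfig()
    return HSQCNet(
        channels=cfg.channels,
        conv_stack=cfg.conv_stack,
        embedding_dim=cfg.embedding_dim,
        n_classes=cfg.n_classes,
        loss_weights=cfg.loss_weights,
        learning_rate=tcfg.learning_rate,
        decay=tcfg.decay,
        batch_size=tcfg.batch_size,
        dropout=tcfg.dropout,
        epochs=tcfg.epochs,
        seed=tcfg.seed,
        validation_fraction=tcfg.validation_fraction,
    )


def train(
    model: HSQCNet,
    dataset: list[tuple[HSQCImage, MoleculeRecord]],
    tcfg: TrainingConfig | None = None,
) -> tuple[HSQCNet, pd.DataFrame]:
    """Fit ``model`` on (image, record) pairs; returns (model, history)."""
    if not dataset:
        raise ValueError("cannot train on an empty dataset")
    if tcfg is not None:
        model.set_params(
            learning_rate=tcfg.learning_rate,
            decay=tcfg.decay,
            batch_size=tcfg.batch_size,
            dropout=tcfg.dropout,
            epochs=tcfg.epochs,
            seed=tcfg.seed,
            validation_fraction=tcfg.validation_fraction,
        )
    images, records = zip(*dataset)
    model.fit(list(images), list(records))
    return model, model.history_


def predict(model: HSQCNet, image: HSQCImage) -> Prediction:
    return model.predict_one(image)


def stack_dataset(
    dataset: list[tuple[HSQCImage, MoleculeRecord]]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Stack (image, record) pairs into fit-ready arrays."""
    images, records = zip(*dataset)
    X = np.stack([im.grid for im in images])
    y = _as_targets(list(records), len(records))
    return X, y


# -- checkpointing -------------------------------------------------------


def save_checkpoint(
    model: HSQCNet,
    path: str,
    vocabulary: tuple[str, ...] | None = None,
    bounds: SpectrumBounds | None = None,
) -> None:
    """Write a self-describing single-file checkpoint (weights + config)."""
    if not hasattr(model, "net_"):
        raise RuntimeError("cannot checkpoint an unfitted model")
    meta = {
        "params": model.get_params(),
        "vocabulary": list(vocabulary) if vocabulary else None,
        "bounds": asdict(bounds) if bounds else None,
    }
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.net_.params())}
    arrays.update({f"buffer_{i}": b for i, b in enumerate(model.net_.buffers())})
    with open(path, "wb") as fh:  # write to the exact path, no .npz suffixing
        np.savez(fh, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str) -> tuple[HSQCNet, tuple[str, ...] | None, SpectrumBounds | None]:
    """Restore a fitted estimator; returns (model, vocabulary, bounds)."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        model = HSQCNet(**{k: (tuple(map(tuple, v)) if k == "conv_stack" else (tuple(v) if isinstance(v, list) else v)) for k, v in meta["params"].items()})
        cfg = model._model_config()
        net = _Network(cfg, model.dropout, np.random.default_rng(model.seed))
        for i, p in enumerate(net.params()):
            p.value[...] = data[f"param_{i}"]
        for i, b in enumerate(net.buffers()):
            b[...] = data[f"buffer_{i}"]
    model.net_ = net
    model.config_ = cfg
    model.history_ = pd.DataFrame()
    vocab = tuple(meta["vocabulary"]) if meta["vocabulary"] else None
    bounds = SpectrumBounds(**meta["bounds"]) if meta["bounds"] else None
    return model, vocab, bounds
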