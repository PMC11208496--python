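"""Variance-aware multiple-instance learning (VarMIL) bag classifier.

A whole-slide image is modeled as a *bag* of patch embeddings with a single
slide-level label.  The bag representation is the concatenation of an
attention-weighted mean and an attention-weighted, bias-corrected variance of
the patch embeddings:

    a_j  = softmax_j( W^T tanh(V z_j) )
    zbar = sum_j a_j z_j
    zvar = k/(k-1) * sum_j a_j (z_j - zbar)^2
    z    = zbar (+) zvar          ((+) = concatenation)

A small MLP head maps ``z`` to class probabilities over {NSMP, p53abn}.
The feature extractor that produces the embeddings is deliberately outside
this module: embeddings are frozen inputs and only the attention and head
parameters are trained (cross-entropy, Adam, decoupled weight decay).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PatchBag",
    "AttentionParams",
    "BagRepresentation",
    "VarMILModel",
    "TrainConfig",
    "attention_weights",
    "weighted_mean",
    "weighted_variance",
    "bag_representation",
    "predict",
    "train",
    "RandomProjectionFeaturizer",
]

CLASSES = ("NSMP", "p53abn")


@dataclass
class PatchBag:
    """One slide's set of patch embeddings.

    Z has shape (k, d): one row per patch.  ``positions`` optionally carries
    the (x, y) tile anchors the embeddings came from.
    """

    Z: np.ndarray
    slide_id: str
    patient_id: str
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=np.float64)
        if self.Z.ndim != 2 or self.Z.shape[0] < 1:
            raise ValueError("bag must contain >=1 patch")
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("bag embeddings must be finite")

    @property
    def k(self) -> int:
        return self.Z.shape[0]

    @property
    def d(self) -> int:
        return self.Z.shape[1]


@dataclass
class AttentionParams:
    """Attention parameters: V in R^{q x d}, W in R^q."""

    V: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=np.float64)
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.V.ndim != 2 or self.W.ndim != 1 or self.V.shape[0] != self.W.shape[0]:
            raise ValueError("inconsistent attention shapes")
        if not (np.all(np.isfinite(self.V)) and np.all(np.isfinite(self.W))):
            raise ValueError("attention parameters must be finite")


@dataclass
class BagRepresentation:
    a: np.ndarray      # attention weights, aligned with the input patch order
    z_mean: np.ndarray
    z_var: np.ndarray
    z: np.ndarray      # concatenation (or z_mean alone when variance pooling is off)


def attention_weights(Z: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Softmax attention over patches, computed with max-score subtraction so
    scores spanning hundreds of units cannot overflow."""
    Z = np.asarray(Z, dtype=np.float64)
    if not np.all(np.isfinite(Z)):
        raise ValueError("non-finite embeddings")
    scores = np.tanh(Z @ params.V.T) @ params.W
    scores = scores - scores.max()
    e = np.exp(scores)
    return e / e.sum()


def weighted_mean(Z: np.ndarray, a: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    if a.shape[0] != Z.shape[0]:
        raise ValueError("weights/patches shape mismatch")
    return a @ Z


def weighted_variance(Z: np.ndarray, a: np.ndarray, z_mean: np.ndarray, k: int) -> np.ndarray:
    """Bias-corrected attention-weighted variance, k/(k-1) * sum a_j (z_j-zbar)^2.

    For k = 1 the correction factor is undefined; a single observation has no
    dispersion, so the zero vector is returned.
    """
    Z = np.asarray(Z, dtype=np.float64)
    if a.shape[0] != Z.shape[0] or z_mean.shape[0] != Z.shape[1]:
        raise ValueError("shape mismatch")
    if k == 1:
        return np.zeros(Z.shape[1])
    dev = Z - z_mean
    return (k / (k - 1.0)) * (np.asarray(a) @ (dev * dev))


def _canonical_order(Z: np.ndarray) -> np.ndarray:
    # lexicographic row order; makes pooling bitwise permutation-invariant
    return np.lexsort(Z.T[::-1])


def bag_representation(
    bag: PatchBag, params: AttentionParams, variance_pooling: bool = True
) -> BagRepresentation:
    """Pool a bag into its slide-level representation.

    Patches are reordered canonically before the sums so the result is exactly
    (bitwise) invariant to the order patches arrive in; the returned attention
    weights are mapped back to the input order.
    """
    order = _canonical_order(bag.Z)
    Zc = bag.Z[order]
    a_sorted = attention_weights(Zc, params)
    z_mean = weighted_mean(Zc, a_sorted)
    z_var = weighted_variance(Zc, a_sorted, z_mean, bag.k)
    a = np.empty_like(a_sorted)
    a[order] = a_sorted
    z = np.concatenate([z_mean, z_var]) if variance_pooling else z_mean.copy()
    return BagRepresentation(a=a, z_mean=z_mean, z_var=z_var, z=z)


# ---------------------------------------------------------------------------
# model


@dataclass
class TrainConfig:
    """Training contract for the attention + classification layers.

    The embeddings are frozen, mirroring two-step training in which the
    feature extractor is trained separately.  Validation loss drives both the
    learning-rate schedule (halved after 5 epochs without improvement) and
    early stopping (after 10 epochs without improvement).
    """

    learning_rate: float = 1e-5
    weight_decay: float = 1e-4
    lr_decay_patience: int = 5
    early_stop_patience: int = 10
    max_epochs: int = 150
    balanced_sampling: bool = True
    hidden: int = 128
    q: int = 128
    variance_pooling: bool = True
    # image-stage augmentations; recorded for the image pathway, no-ops on
    # precomputed embedding bags
    augmentations: tuple[str, ...] = (
        "hflip", "vflip", "color_jitter", "size_jitter", "rotation", "cutout",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "weight_decay"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("lr_decay_patience", "early_stop_patience", "max_epochs",
                     "hidden", "q"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


class VarMILModel:
    """Attention pooling plus an MLP head (2d -> hidden -> 2, ReLU).

    With ``variance_pooling=False`` the model degrades to attention-mean-only
    pooling (DeepMIL style) and the head input width is d.
    """

    def __init__(self, params: dict[str, np.ndarray], variance_pooling: bool = True):
        self.params = params
        self.variance_pooling = variance_pooling
        self.train_log: list[dict] = []

    # -- construction -------------------------------------------------------

    @classmethod
    def initialize(cls, d: int, config: TrainConfig, rng: np.random.Generator) -> "VarMILModel":
        q, h = config.q, config.hidden
        in_w = 2 * d if config.variance_pooling else d

        def glorot(shape):
            s = np.sqrt(2.0 / sum(shape))
            return rng.normal(0.0, s, size=shape)

        params = {
            "V": glorot((q, d)),
            "W": glorot((q,)) if q > 1 else glorot((1,)),
            "W1": glorot((h, in_w)),
            "b1": np.zeros(h),
            "W2": glorot((2, h)),
            "b2": np.zeros(2),
        }
        return cls(params, variance_pooling=config.variance_pooling)

    @property
    def attention(self) -> AttentionParams:
        return AttentionParams(self.params["V"], self.params["W"])

    # -- inference ----------------------------------------------------------

    def _head(self, z: np.ndarray) -> tuple[np.ndarray, dict]:
        p = self.params
        pre = p["W1"] @ z + p["b1"]
        hid = np.maximum(pre, 0.0)
        logits = p["W2"] @ hid + p["b2"]
        return logits, {"z": z, "pre": pre, "hid": hid}

    def predict_proba(self, bag: PatchBag) -> np.ndarray:
        if bag.d != self.params["V"].shape[1]:
            raise ValueError(
                f"model expects embedding width {self.params['V'].shape[1]}, "
                f"bag has width {bag.d}"
            )
        rep = bag_representation(bag, self.attention, self.variance_pooling)
        if rep.z.shape[0] != self.params["W1"].shape[1]:
            raise ValueError(
                f"head expects width {self.params['W1'].shape[1]}, got {rep.z.shape[0]}"
            )
        logits, _ = self._head(rep.z)
        logits = logits - logits.max()
        e = np.exp(logits)
        return e / e.sum()

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "variance_pooling": self.variance_pooling,
            "classes": list(CLASSES),
            "params": {k: v.tolist() for k, v in self.params.items()},
        })

    @classmethod
    def from_json(cls, text: str) -> "VarMILModel":
        obj = json.loads(text)
        params = {k: np.asarray(v, dtype=np.float64) for k, v in obj["params"].items()}
        return cls(params, variance_pooling=obj["variance_pooling"])


def predict(bag: PatchBag, model: VarMILModel) -> dict[str, float]:
    """Class probabilities for one bag, keyed by subtype name."""
    p = model.predict_proba(bag)
    return {CLASSES[0]: float(p[0]), CLASSES[1]: float(p[1])}


# ---------------------------------------------------------------------------
# training (manual gradients)


def _forward_backward(model: VarMILModel, bag: PatchBag, y: int) -> tuple[float, dict]:
    """Cross-entropy loss and gradients wrt V, W, W1, b1, W2, b2 for one bag.

    Exploits that sum_j a_j (z_j - zbar) = 0, so the variance's direct
    dependence on zbar contributes no gradient.
    """
    p = model.params
    order = _canonical_order(bag.Z)
    Z = bag.Z[order]
    k, d = Z.shape

    T = np.tanh(Z @ p["V"].T)          # (k, q)
    s = T @ p["W"]                     # (k,)
    s = s - s.max()
    e = np.exp(s)
    a = e / e.sum()
    z_mean = a @ Z
    dev = Z - z_mean
    if k > 1:
        c = k / (k - 1.0)
        z_var = c * (a @ (dev * dev))
    else:
        c = 0.0
        z_var = np.zeros(d)
    z = np.concatenate([z_mean, z_var]) if model.variance_pooling else z_mean

    logits, cache = model._head(z)
    m = logits.max()
    logp = logits - m - np.log(np.exp(logits - m).sum())
    loss = -logp[y]
    prob = np.exp(logp)

    dlogits = prob.copy()
    dlogits[y] -= 1.0
    grads = {
        "W2": np.outer(dlogits, cache["hid"]),
        "b2": dlogits,
    }
    dhid = p["W2"].T @ dlogits
    dpre = dhid * (cache["pre"] > 0)
    grads["W1"] = np.outer(dpre, z)
    grads["b1"] = dpre
    dz = p["W1"].T @ dpre
    dmean = dz[:d]
    dvar = dz[d:] if model.variance_pooling else np.zeros(d)

    # da_j = dmean . z_j + c * dvar . dev_j^2
    da = Z @ dmean
    if k > 1 and model.variance_pooling:
        da = da + c * ((dev * dev) @ dvar)
    ds = a * (da - a @ da)
    grads["W"] = T.T @ ds
    dT = np.outer(ds, p["W"])
    grads["V"] = (dT * (1.0 - T * T)).T @ Z
    return float(loss), grads


def _bag_loss(model: VarMILModel, bag: PatchBag, y: int) -> float:
    pr = model.predict_proba(bag)
    return float(-np.log(max(pr[y], 1e-300)))


def train(
    bags: Sequence[PatchBag],
    labels: Sequence[int],
    config: TrainConfig,
    val_bags: Sequence[PatchBag],
    val_labels: Sequence[int],
) -> VarMILModel:
    """Train attention + head by Adam on per-bag cross-entropy.

    Labels are 0 (NSMP) / 1 (p53abn).  Balanced sampling draws an equal
    number of bags per class each epoch.  The parameters achieving the best
    validation loss are returned; the per-epoch log is on ``model.train_log``.
    """
    labels = np.asarray(labels, dtype=int)
    val_labels = np.asarray(val_labels, dtype=int)
    if len(bags) != len(labels) or len(val_bags) != len(val_labels):
        raise ValueError("bags/labels length mismatch")
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    d = bags[0].d
    rng = np.random.default_rng(config.seed)
    model = VarMILModel.initialize(d, config, rng)

    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    t = 0
    lr = config.learning_rate

    idx_by_class = [np.flatnonzero(labels == c) for c in (0, 1)]
    best_loss = np.inf
    best_params = None
    since_improve = 0

    for epoch in range(config.max_epochs):
        if config.balanced_sampling:
            m = min(len(ix) for ix in idx_by_class)
            epoch_idx = np.concatenate(
                [rng.choice(ix, size=m, replace=False) for ix in idx_by_class]
            )
        else:
            epoch_idx = np.arange(len(bags))
        rng.shuffle(epoch_idx)

        train_loss = 0.0
        for i in epoch_idx:
            loss, grads = _forward_backward(model, bags[i], int(labels[i]))
            train_loss += loss
            t += 1
            for key, g in grads.items():
                adam_m[key] = b1 * adam_m[key] + (1 - b1) * g
                adam_v[key] = b2 * adam_v[key] + (1 - b2) * g * g
                mhat = adam_m[key] / (1 - b1 ** t)
                vhat = adam_v[key] / (1 - b2 ** t)
                par = model.params[key]
                par -= lr * (mhat / (np.sqrt(vhat) + eps) + config.weight_decay * par)
        train_loss /= max(len(epoch_idx), 1)

        val_loss = float(np.mean([
            _bag_loss(model, vb, int(vy)) for vb, vy in zip(val_bags, val_labels)
        ]))
        model.train_log.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss, "lr": lr}
        )
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_params = copy.deepcopy(model.params)
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.early_stop_patience:
                break
            if since_improve % config.lr_decay_patience == 0:
                lr *= 0.5

    if best_params is not None:
        model.params = best_params
    return model


# ---------------------------------------------------------------------------
# reference featurizer


class RandomProjectionFeaturizer:
    """Frozen map patch -> R^d: simple pixel statistics followed by a fixed
    random linear projection.  Stands in for a pretrained CNN feature
    extractor when working from images in tests and demos."""

    def __init__(self, d: int = 16, seed: int = 0):
        self.d = d
        self._rng_matrix = None
        self.seed = seed

    def _stats(self, patch: np.ndarray) -> np.ndarray:
        img = np.asarray(patch, dtype=np.float64)
        if img.ndim == 2:
            img = img[..., None]
        feats = []
        for ch in range(img.shape[2]):
            x = img[..., ch]
            gy, gx = np.gradient(x)
            feats += [x.mean(), x.std(), np.abs(gx).mean() + np.abs(gy).mean(),
                      np.percentile(x, 10), np.percentile(x, 90)]
        return np.asarray(feats)

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        stats = self._stats(patch)
        if self._rng_matrix is None or self._rng_matrix.shape[1] != stats.shape[0]:
            rng = np.random.default_rng(self.seed)
            self._rng_matrix = rng.normal(size=(self.d, stats.shape[0])) / np.sqrt(stats.shape[0])
        return self._rng_matrix @ stats
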