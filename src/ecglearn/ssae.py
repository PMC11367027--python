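"""Stacked sparse autoencoder classifier.

Each layer maps x -> z = sigma(w1 x + b1) and reconstructs x' = sigma(w2 z + b2);
the layer loss is mean half squared reconstruction error plus a Bernoulli
KL sparsity penalty on the mean unit activations rho_hat,

    L = 1/(2N) sum_i ||x'_i - x_i||^2 + beta * sum_j KL(rho || rho_hat_j),
    KL(rho || r) = rho ln(rho/r) + (1 - rho) ln((1 - rho)/(1 - r)).

Two layers are pretrained greedily (layer 2 on layer-1 codes); decoders are
kept but unused downstream.  A multi-label sigmoid head on the layer-2 codes
is then fit by binary cross-entropy, optionally fine-tuning the encoders.
All updates go through AdaMax on flat parameter vectors; gradients are
analytic (checked against finite differences in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adamax import adamax_init, adamax_step

_CLAMP = 1e-6  # rho_hat clamp delta


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class AELayer:
    """One autoencoder layer: logistic encoder and decoder."""

    w1: np.ndarray  # [S2, d_in]
    b1: np.ndarray  # [S2]
    w2: np.ndarray  # [d_in, S2]
    b2: np.ndarray  # [d_in]

    @property
    def code_dim(self) -> int:
        return self.w1.shape[0]

    @property
    def input_dim(self) -> int:
        return self.w1.shape[1]

    @classmethod
    def init(cls, d_in: int, s2: int, rng: np.random.Generator,
             scale: float = 0.1) -> "AELayer":
        return cls(w1=rng.uniform(-scale, scale, size=(s2, d_in)),
                   b1=np.zeros(s2),
                   w2=rng.uniform(-scale, scale, size=(d_in, s2)),
                   b2=np.zeros(d_in))


@dataclass
class SparsityStats:
    """Mean unit activations over a data pass, clamped away from {0, 1}."""

    rho_hat: np.ndarray


@dataclass
class SSAEClassifier:
    """Two pretrained sparse layers plus a multi-label sigmoid head."""

    layer1: AELayer
    layer2: AELayer
    head_W: np.ndarray  # [n_classes, S2_2]
    head_b: np.ndarray
    rho: float = 0.05
    beta: float = 3.0
    threshold: float = 0.5


def encode(layer: AELayer, x: np.ndarray) -> np.ndarray:
    """Code z = sigma(w1 x + b1); accepts vectors or row-batches."""
    x = np.asarray(x, dtype=np.float64)
    return _sigmoid(x @ layer.w1.T + layer.b1)


def decode(layer: AELayer, z: np.ndarray) -> np.ndarray:
    """Reconstruction x' = sigma(w2 z + b2)."""
    z = np.asarray(z, dtype=np.float64)
    return _sigmoid(z @ layer.w2.T + layer.b2)


def kl_bernoulli(rho: float, rho_hat: np.ndarray) -> np.ndarray:
    """Bernoulli KL divergence KL(rho || rho_hat), entrywise."""
    r = np.clip(rho_hat, _CLAMP, 1.0 - _CLAMP)
    return rho * np.log(rho / r) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - r))


def sae_loss(layer: AELayer, batch: np.ndarray, rho: float,
             beta: float) -> tuple[float, SparsityStats]:
    """Sparse-autoencoder loss of one layer on a batch (rows = samples)."""
    batch = np.atleast_2d(np.asarray(batch, dtype=np.float64))
    if not (0.0 < rho < 1.0):
        raise ValueError("rho must lie in (0, 1)")
    z = encode(layer, batch)
    x_rec = decode(layer, z)
    n = batch.shape[0]
    rec = 0.5 / n * float(np.sum((x_rec - batch) ** 2))
    rho_hat = np.clip(z.mean(axis=0), _CLAMP, 1.0 - _CLAMP)
    loss = rec + beta * float(np.sum(kl_bernoulli(rho, rho_hat)))
    return loss, SparsityStats(rho_hat=rho_hat)


# --- analytic gradients ----------------------------------------------------

def _layer_flat(layer: AELayer) -> np.ndarray:
    return np.concatenate([layer.w1.ravel(), layer.b1,
                           layer.w2.ravel(), layer.b2])


def _layer_unflat(layer: AELayer, flat: np.ndarray) -> AELayer:
    s2, d = layer.code_dim, layer.input_dim
    pos = 0
    w1 = flat[pos:pos + s2 * d].reshape(s2, d).copy(); pos += s2 * d
    b1 = flat[pos:pos + s2].copy(); pos += s2
    w2 = flat[pos:pos + d * s2].reshape(d, s2).copy(); pos += d * s2
    b2 = flat[pos:pos + d].copy()
    return AELayer(w1=w1, b1=b1, w2=w2, b2=b2)


def sae_loss_grad(layer: AELayer, batch: np.ndarray, rho: float,
                  beta: float) -> tuple[float, np.ndarray]:
    """Loss and flat gradient (w1, b1, w2, b2 order) on a batch."""
    batch = np.atleast_2d(np.asarray(batch, dtype=np.float64))
    n = batch.shape[0]
    z = encode(layer, batch)
    x_rec = decode(layer, z)
    rho_hat_raw = z.mean(axis=0)
    rho_hat = np.clip(rho_hat_raw, _CLAMP, 1.0 - _CLAMP)
    rec = 0.5 / n * float(np.sum((x_rec - batch) ** 2))
    loss = rec + beta * float(np.sum(kl_bernoulli(rho, rho_hat)))
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite autoencoder loss")

    dx_rec = (x_rec - batch) / n
    da2 = dx_rec * x_rec * (1.0 - x_rec)
    dw2 = da2.T @ z
    db2 = da2.sum(axis=0)
    dz = da2 @ layer.w2
    # KL term: dKL/drho_hat, zero where the clamp binds
    interior = (rho_hat_raw > _CLAMP) & (rho_hat_raw < 1.0 - _CLAMP)
    dkl = np.where(interior,
                   -rho / rho_hat + (1.0 - rho) / (1.0 - rho_hat), 0.0)
    dz = dz + beta * dkl[None, :] / n
    da1 = dz * z * (1.0 - z)
    dw1 = da1.T @ batch
    db1 = da1.sum(axis=0)
    grad = np.concatenate([dw1.ravel(), db1, dw2.ravel(), db2])
    return loss, grad


def pretrain_stack(features: np.ndarray, sizes: tuple[int, int] = (64, 32),
                   rho: float = 0.05, beta: float = 3.0, epochs: int = 20,
                   adamax_config: dict | None = None, seed: int = 0,
                   batch_size: int = 32) -> tuple[AELayer, AELayer, dict]:
    """Greedy layer-wise pretraining; layer 2 trains on layer-1 codes.

    Returns (layer1, layer2, history) where history maps ``layer1``/``layer2``
    to per-epoch mean batch losses.
    """
    features = np.asarray(features, dtype=np.float64)
    rng = np.random.default_rng(seed)
    s1, s2 = int(sizes[0]), int(sizes[1])
    if s1 <= 0 or s2 <= 0:
        raise ValueError("layer sizes must be positive")
    layer1 = AELayer.init(features.shape[1], s1, rng)
    layer2 = AELayer.init(s1, s2, rng)
    history: dict[str, list[float]] = {"layer1": [], "layer2": []}
    layer1, history["layer1"] = _train_layer(layer1, features, rho, beta, epochs,
                                             adamax_config, rng, batch_size)
    codes = encode(layer1, features)
    layer2, history["layer2"] = _train_layer(layer2, codes, rho, beta, epochs,
                                             adamax_config, rng, batch_size)
    return layer1, layer2, history


def _train_layer(layer: AELayer, data: np.ndarray, rho: float, beta: float,
                 epochs: int, adamax_config: dict | None,
                 rng: np.random.Generator, batch_size: int):
    if epochs == 0:
        return layer, []
    flat = _layer_flat(layer)
    state = adamax_init(flat.shape, **(adamax_config or {}))
    history = []
    n = data.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            current = _layer_unflat(layer, flat)
            loss, grad = sae_loss_grad(current, data[idx], rho, beta)
            state, flat = adamax_step(state, flat, grad)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return _layer_unflat(layer, flat), history


# --- classification head ---------------------------------------------------

def _clf_flat(clf: SSAEClassifier, finetune: bool) -> np.ndarray:
    parts = []
    if finetune:
        parts += [clf.layer1.w1.ravel(), clf.layer1.b1,
                  clf.layer2.w1.ravel(), clf.layer2.b1]
    parts += [clf.head_W.ravel(), clf.head_b]
    return np.concatenate(parts)


def _clf_unflat(clf: SSAEClassifier, flat: np.ndarray,
                finetune: bool) -> SSAEClassifier:
    import copy

    out = copy.deepcopy(clf)
    pos = 0
    if finetune:
        for layer in (out.layer1, out.layer2):
            n = layer.w1.size
            layer.w1 = flat[pos:pos + n].reshape(layer.w1.shape).copy(); pos += n
            n = layer.b1.size
            layer.b1 = flat[pos:pos + n].copy(); pos += n
    n = out.head_W.size
    out.head_W = flat[pos:pos + n].reshape(out.head_W.shape).copy(); pos += n
    out.head_b = flat[pos:pos + out.head_b.size].copy()
    return out


def _clf_loss_grad(clf: SSAEClassifier, X: np.ndarray, Y: np.ndarray,
                   finetune: bool) -> tuple[float, np.ndarray]:
    B, K = Y.shape
    z1 = encode(clf.layer1, X)
    z2 = encode(clf.layer2, z1)
    logits = z2 @ clf.head_W.T + clf.head_b
    loss = float(np.mean(np.logaddexp(0.0, logits) - Y * logits))
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite classifier loss")
    p = _sigmoid(logits)
    dlog = (p - Y) / (B * K)
    dhead_W = dlog.T @ z2
    dhead_b = dlog.sum(axis=0)
    if not finetune:
        return loss, np.concatenate([dhead_W.ravel(), dhead_b])
    dz2 = dlog @ clf.head_W
    da2 = dz2 * z2 * (1.0 - z2)
    dw1_2 = da2.T @ z1
    db1_2 = da2.sum(axis=0)
    dz1 = da2 @ clf.layer2.w1
    da1 = dz1 * z1 * (1.0 - z1)
    dw1_1 = da1.T @ X
    db1_1 = da1.sum(axis=0)
    return loss, np.concatenate([dw1_1.ravel(), db1_1, dw1_2.ravel(), db1_2,
                                 dhead_W.ravel(), dhead_b])


def fit_classifier(layers: tuple[AELayer, AELayer], features: np.ndarray,
                   labels: np.ndarray, epochs: int = 20,
                   adamax_config: dict | None = None, seed: int = 0,
                   finetune: bool = True, rho: float = 0.05, beta: float = 3.0,
                   threshold: float = 0.5,
                   batch_size: int = 32) -> SSAEClassifier:
    """Fit the multi-label head (and optionally fine-tune the encoders)."""
    features = np.asarray(features, dtype=np.float64)
    Y = np.asarray(labels, dtype=np.float64)
    if features.shape[0] != Y.shape[0]:
        raise ValueError("labels not aligned with features")
    layer1, layer2 = layers
    if layer2.input_dim != layer1.code_dim:
        raise ValueError("layer2 input dim must equal layer1 code dim")
    rng = np.random.default_rng(seed)
    import copy

    clf = SSAEClassifier(layer1=copy.deepcopy(layer1), layer2=copy.deepcopy(layer2),
                         head_W=rng.uniform(-0.1, 0.1,
                                            size=(Y.shape[1], layer2.code_dim)),
                         head_b=np.zeros(Y.shape[1]),
                         rho=rho, beta=beta, threshold=threshold)
    if epochs == 0:
        return clf
    flat = _clf_flat(clf, finetune)
    state = adamax_init(flat.shape, **(adamax_config or {}))
    n = features.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            current = _clf_unflat(clf, flat, finetune)
            _, grad = _clf_loss_grad(current, features[idx], Y[idx], finetune)
            state, flat = adamax_step(state, flat, grad)
    return _clf_unflat(clf, flat, finetune)


def predict(classifier: SSAEClassifier,
            features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class scores in (0, 1) and binary labels (score >= threshold)."""
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    z2 = encode(classifier.layer2, encode(classifier.layer1, features))
    scores = _sigmoid(z2 @ classifier.head_W.T + classifier.head_b)
    return scores, (scores >= classifier.threshold).astype(np.int64)


# --- serialization ---------------------------------------------------------

def save_classifier(clf: SSAEClassifier, path) -> None:
    import json
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for tag, layer in (("l1", clf.layer1), ("l2", clf.layer2)):
        for name in ("w1", "b1", "w2", "b2"):
            arrays[f"{tag}_{name}"] = getattr(layer, name)
    arrays["head_W"] = clf.head_W
    arrays["head_b"] = clf.head_b
    np.savez_compressed(path / "weights.npz", **arrays)
    (path / "manifest.json").write_text(json.dumps({
        "kind": "ssae_classifier", "rho": clf.rho, "beta": clf.beta,
        "threshold": clf.threshold,
    }, indent=1))


def load_classifier(path) -> SSAEClassifier:
    import json
    from pathlib import Path

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("kind") != "ssae_classifier":
        raise ValueError(f"{path}: not an SSAE classifier archive")
    with np.load(path / "weights.npz") as npz:
        def layer(tag):
            return AELayer(**{name: npz[f"{tag}_{name}"]
                              for name in ("w1", "b1", "w2", "b2")})
        return SSAEClassifier(layer1=layer("l1"), layer2=layer("l2"),
                              head_W=npz["head_W"], head_b=npz["head_b"],
                              rho=float(manifest["rho"]),
                              beta=float(manifest["beta"]),
                              threshold=float(manifest["threshold"]))
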