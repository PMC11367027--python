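"""Bidirectional LSTM feature extractor trained with AdaMax.

A single LSTM cell follows the standard gate equations: logistic input,
forget and output gates over the concatenation [h_{t-1}, x_t], a tanh
candidate cell state, and

    C_t = f_t * C_{t-1} + i_t * g_t,        h_t = o_t * tanh(C_t).

Two cells run over the (strided) lead-sample sequence in opposite directions
from zero states; the concatenation of the two final hidden states is the
fixed-length feature vector.  A throwaway multi-label sigmoid head provides
the supervised training signal (mean per-class binary cross-entropy);
gradients are computed by explicit backpropagation through time and applied
exclusively via :func:`ecglearn.adamax.adamax_step`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adamax import adamax_init, adamax_step
from .dataio import Dataset


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LSTMParams:
    """Gate weights/biases of one direction; weights act on [h_prev, x]."""

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_C: np.ndarray
    b_i: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_C: np.ndarray

    @property
    def H(self) -> int:
        return self.W_i.shape[0]

    @property
    def D(self) -> int:
        return self.W_i.shape[1] - self.W_i.shape[0]

    @classmethod
    def init(cls, H: int, D: int, rng: np.random.Generator,
             scale: float = 0.1, forget_bias: float = 1.0) -> "LSTMParams":
        def w():
            return rng.uniform(-scale, scale, size=(H, H + D))
        return cls(W_i=w(), W_f=w(), W_o=w(), W_C=w(),
                   b_i=np.zeros(H), b_f=np.full(H, forget_bias),
                   b_o=np.zeros(H), b_C=np.zeros(H))

    def zeros_like(self) -> "LSTMParams":
        return LSTMParams(*(np.zeros_like(a) for a in self._arrays()))

    def _arrays(self):
        return (self.W_i, self.W_f, self.W_o, self.W_C,
                self.b_i, self.b_f, self.b_o, self.b_C)


def lstm_cell_step(params: LSTMParams, h_prev: np.ndarray, C_prev: np.ndarray,
                   x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM step on vectors (or batches, rows = batch items)."""
    cat = np.concatenate([h_prev, x], axis=-1)
    i = _sigmoid(cat @ params.W_i.T + params.b_i)
    f = _sigmoid(cat @ params.W_f.T + params.b_f)
    o = _sigmoid(cat @ params.W_o.T + params.b_o)
    g = np.tanh(cat @ params.W_C.T + params.b_C)
    C = f * C_prev + i * g
    h = o * np.tanh(C)
    return h, C


@dataclass
class BiLSTMExtractor:
    """Paired forward/backward LSTM cells plus a training head."""

    forward: LSTMParams
    backward: LSTMParams
    head_W: np.ndarray  # [n_classes, 2H]
    head_b: np.ndarray
    stride: int = 10
    standardize: bool = True
    seed: int = 0

    @property
    def hidden_size(self) -> int:
        return self.forward.H

    @classmethod
    def create(cls, n_leads: int, hidden_size: int, n_classes: int,
               stride: int = 10, standardize: bool = True,
               seed: int = 0) -> "BiLSTMExtractor":
        rng = np.random.default_rng(seed)
        fwd = LSTMParams.init(hidden_size, n_leads, rng)
        bwd = LSTMParams.init(hidden_size, n_leads, rng)
        head_W = rng.uniform(-0.1, 0.1, size=(n_classes, 2 * hidden_size))
        return cls(forward=fwd, backward=bwd, head_W=head_W,
                   head_b=np.zeros(n_classes), stride=stride,
                   standardize=standardize, seed=seed)


def prepare_sequence(signal: np.ndarray, stride: int,
                     standardize: bool) -> np.ndarray:
    """Signal [n_leads, n_samples] -> timestep sequence [T, n_leads]."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sig = np.asarray(signal, dtype=np.float64)
    if standardize:
        mu = sig.mean(axis=1, keepdims=True)
        sd = sig.std(axis=1, keepdims=True)
        sig = (sig - mu) / (sd + 1e-8)
    seq = sig[:, ::stride].T
    if seq.shape[0] == 0:
        raise ValueError("empty timestep sequence after striding")
    return seq


def run_bilstm(extractor: BiLSTMExtractor, signal: np.ndarray) -> np.ndarray:
    """Feature vector [2H]: final forward state ++ final backward state."""
    seq = prepare_sequence(signal, extractor.stride, extractor.standardize)
    X = seq[None, :, :]  # batch of 1
    hf, _ = _run_direction(extractor.forward, X, reverse=False)
    hb, _ = _run_direction(extractor.backward, X, reverse=True)
    return np.concatenate([hf[0], hb[0]])


def _run_direction(params: LSTMParams, X: np.ndarray, reverse: bool,
                   keep_cache: bool = False):
    """Run one direction over X [B, T, D]; returns (final h [B,H], cache)."""
    B, T, _ = X.shape
    H = params.H
    h = np.zeros((B, H))
    C = np.zeros((B, H))
    order = range(T - 1, -1, -1) if reverse else range(T)
    cache = [] if keep_cache else None
    for t in order:
        x = X[:, t, :]
        cat = np.concatenate([h, x], axis=1)
        i = _sigmoid(cat @ params.W_i.T + params.b_i)
        f = _sigmoid(cat @ params.W_f.T + params.b_f)
        o = _sigmoid(cat @ params.W_o.T + params.b_o)
        g = np.tanh(cat @ params.W_C.T + params.b_C)
        C_new = f * C + i * g
        tc = np.tanh(C_new)
        h_new = o * tc
        if keep_cache:
            cache.append((cat, i, f, o, g, C, C_new, tc))
        h, C = h_new, C_new
    return h, cache


def _backprop_direction(params: LSTMParams, cache, dh_final: np.ndarray) -> LSTMParams:
    """BPTT through one direction given the gradient at the final hidden state."""
    grads = params.zeros_like()
    H = params.H
    dh = dh_final
    dC = np.zeros_like(dh_final)
    for (cat, i, f, o, g, C_prev, C, tc) in reversed(cache):
        do = dh * tc
        dC = dC + dh * o * (1.0 - tc * tc)
        df = dC * C_prev
        di = dC * g
        dg = dC * i
        dC_prev = dC * f
        da_i = di * i * (1.0 - i)
        da_f = df * f * (1.0 - f)
        da_o = do * o * (1.0 - o)
        da_g = dg * (1.0 - g * g)
        grads.W_i += da_i.T @ cat
        grads.W_f += da_f.T @ cat
        grads.W_o += da_o.T @ cat
        grads.W_C += da_g.T @ cat
        grads.b_i += da_i.sum(axis=0)
        grads.b_f += da_f.sum(axis=0)
        grads.b_o += da_o.sum(axis=0)
        grads.b_C += da_g.sum(axis=0)
        dcat = (da_i @ params.W_i + da_f @ params.W_f
                + da_o @ params.W_o + da_g @ params.W_C)
        dh = dcat[:, :H]
        dC = dC_prev
    return grads


# --- flat parameter vector <-> extractor ----------------------------------

def _flatten(extractor: BiLSTMExtractor) -> np.ndarray:
    parts = [a.ravel() for a in extractor.forward._arrays()]
    parts += [a.ravel() for a in extractor.backward._arrays()]
    parts += [extractor.head_W.ravel(), extractor.head_b.ravel()]
    return np.concatenate(parts)


def _unflatten(extractor: BiLSTMExtractor, flat: np.ndarray) -> BiLSTMExtractor:
    out = BiLSTMExtractor(
        forward=extractor.forward.zeros_like(),
        backward=extractor.backward.zeros_like(),
        head_W=np.zeros_like(extractor.head_W),
        head_b=np.zeros_like(extractor.head_b),
        stride=extractor.stride, standardize=extractor.standardize,
        seed=extractor.seed)
    pos = 0
    for tgt in (out.forward, out.backward):
        for name in ("W_i", "W_f", "W_o", "W_C", "b_i", "b_f", "b_o", "b_C"):
            ref = getattr(tgt, name)
            n = ref.size
            setattr(tgt, name, flat[pos:pos + n].reshape(ref.shape).copy())
            pos += n
    n = out.head_W.size
    out.head_W = flat[pos:pos + n].reshape(out.head_W.shape).copy()
    pos += n
    n = out.head_b.size
    out.head_b = flat[pos:pos + n].copy()
    return out


def loss_and_grad(extractor: BiLSTMExtractor, X: np.ndarray, Y: np.ndarray,
                  dropout_mask: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Mean per-class BCE of the head on a batch, and its flat gradient.

    X: [B, T, D] prepared sequences; Y: [B, K] binary labels.
    ``dropout_mask`` (values 0/1 scaled by 1/keep) multiplies the feature.
    """
    B, _, _ = X.shape
    K = Y.shape[1]
    hf, cache_f = _run_direction(extractor.forward, X, reverse=False, keep_cache=True)
    hb, cache_b = _run_direction(extractor.backward, X, reverse=True, keep_cache=True)
    F = np.concatenate([hf, hb], axis=1)
    if dropout_mask is not None:
        F = F * dropout_mask
    z = F @ extractor.head_W.T + extractor.head_b
    # BCE via softplus for stability: loss = mean(softplus(z) - y*z)
    loss = float(np.mean(np.logaddexp(0.0, z) - Y * z))
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite training loss")
    p = _sigmoid(z)
    dz = (p - Y) / (B * K)
    dhead_W = dz.T @ F
    dhead_b = dz.sum(axis=0)
    dF = dz @ extractor.head_W
    if dropout_mask is not None:
        dF = dF * dropout_mask
    H = extractor.hidden_size
    g_f = _backprop_direction(extractor.forward, cache_f, dF[:, :H])
    g_b = _backprop_direction(extractor.backward, cache_b, dF[:, H:])
    grad = np.concatenate([a.ravel() for a in g_f._arrays()]
                          + [a.ravel() for a in g_b._arrays()]
                          + [dhead_W.ravel(), dhead_b.ravel()])
    return loss, grad


def _dataset_tensor(extractor: BiLSTMExtractor, dataset: Dataset) -> np.ndarray:
    seqs = [prepare_sequence(r.signal, extractor.stride, extractor.standardize)
            for r in dataset.records]
    lengths = {s.shape for s in seqs}
    if len(lengths) != 1:
        raise ValueError("all records must share length and lead count for batching")
    return np.stack(seqs)


def train_bilstm(extractor: BiLSTMExtractor, dataset: Dataset, labels: np.ndarray,
                 epochs: int = 50, batch_size: int = 7, dropout: float = 0.5,
                 adamax_config: dict | None = None,
                 seed: int | None = None) -> tuple[BiLSTMExtractor, list[float]]:
    """Supervised training of the extractor; returns (extractor, loss history).

    One history entry per epoch (mean batch loss).  Dropout is applied to the
    concatenated feature during training only.  All parameter updates go
    through AdaMax on the flat parameter vector.
    """
    Y = np.asarray(labels, dtype=np.float64)
    if len(dataset) != Y.shape[0]:
        raise ValueError("labels not aligned with dataset")
    if epochs == 0:
        return extractor, []
    X = _dataset_tensor(extractor, dataset)
    rng = np.random.default_rng(extractor.seed + 1 if seed is None else seed)
    flat = _flatten(extractor)
    state = adamax_init(flat.shape, **(adamax_config or {}))
    keep = 1.0 - dropout
    history: list[float] = []
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            current = _unflatten(extractor, flat)
            mask = None
            if dropout > 0.0:
                mask = (rng.random((len(idx), 2 * extractor.hidden_size)) < keep) / keep
            loss, grad = loss_and_grad(current, X[idx], Y[idx], dropout_mask=mask)
            state, flat = adamax_step(state, flat, grad)
            batch_losses.append(loss)
        history.append(float(np.mean(batch_losses)))
    return _unflatten(extractor, flat), history


def extract_features(extractor: BiLSTMExtractor, dataset: Dataset) -> np.ndarray:
    """Deterministic feature matrix [n_records, 2H] (no dropout)."""
    X = _dataset_tensor(extractor, dataset)
    hf, _ = _run_direction(extractor.forward, X, reverse=False)
    hb, _ = _run_direction(extractor.backward, X, reverse=True)
    return np.concatenate([hf, hb], axis=1)


# --- serialization ---------------------------------------------------------

def save_extractor(extractor: BiLSTMExtractor, path) -> None:
    import json
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for tag, p in (("fwd", extractor.forward), ("bwd", extractor.backward)):
        for name in ("W_i", "W_f", "W_o", "W_C", "b_i", "b_f", "b_o", "b_C"):
            arrays[f"{tag}_{name}"] = getattr(p, name)
    arrays["head_W"] = extractor.head_W
    arrays["head_b"] = extractor.head_b
    np.savez_compressed(path / "weights.npz", **arrays)
    (path / "manifest.json").write_text(json.dumps({
        "kind": "bilstm_extractor",
        "hidden_size": extractor.hidden_size,
        "stride": extractor.stride,
        "standardize": extractor.standardize,
        "seed": extractor.seed,
    }, indent=1))


def load_extractor(path) -> BiLSTMExtractor:
    import json
    from pathlib import Path

    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("kind") != "bilstm_extractor":
        raise ValueError(f"{path}: not a BiLSTM extractor archive")
    with np.load(path / "weights.npz") as npz:
        def params(tag):
            return LSTMParams(**{name: npz[f"{tag}_{name}"]
                                 for name in ("W_i", "W_f", "W_o", "W_C",
                                              "b_i", "b_f", "b_o", "b_C")})
        return BiLSTMExtractor(forward=params("fwd"), backward=params("bwd"),
                               head_W=npz["head_W"], head_b=npz["head_b"],
                               stride=int(manifest["stride"]),
                               standardize=bool(manifest["standardize"]),
                               seed=int(manifest["seed"]))
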