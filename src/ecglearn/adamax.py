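"""From-scratch AdaMax optimizer.

AdaMax is the infinity-norm variant of Adam: the second-moment estimate is
replaced by an exponentially decaying maximum of past absolute gradients,

    m_t = beta1 * m_{t-1} + (1 - beta1) * g_t
    u_t = max(beta2 * u_{t-1}, |g_t|)          (entrywise)
    w_t = w_{t-1} - eta / (1 - beta1**t) * m_t / (u_t + eps)

with bias correction folded into the learning rate and a small eps guarding
the 0/0 case at t = 0 gradients.  The optimizer is stateless with respect to
the model: it updates flat parameter vectors; callers flatten/unflatten.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class AdamaxState:
    """Immutable optimizer state (first moment, infinity-norm accumulator)."""

    m: np.ndarray
    u: np.ndarray
    t: int
    eta: float
    beta1: float
    beta2: float
    epsilon: float


def adamax_init(shape, eta: float = 0.1, beta1: float = 0.9,
                beta2: float = 0.999, epsilon: float = 1e-8) -> AdamaxState:
    """Fresh state with zero moments; defaults match the reference settings."""
    if not (0.0 <= beta1 < 1.0):
        raise ValueError("beta1 must lie in [0, 1)")
    if not (0.0 <= beta2 < 1.0):
        raise ValueError("beta2 must lie in [0, 1)")
    if eta <= 0.0:
        raise ValueError("eta must be positive")
    if epsilon < 0.0:
        raise ValueError("epsilon must be nonnegative")
    return AdamaxState(m=np.zeros(shape), u=np.zeros(shape), t=0,
                       eta=float(eta), beta1=float(beta1),
                       beta2=float(beta2), epsilon=float(epsilon))


def adamax_step(state: AdamaxState, w: np.ndarray,
                G: np.ndarray) -> tuple[AdamaxState, np.ndarray]:
    """One update; returns (new state, new parameters), inputs untouched."""
    w = np.asarray(w, dtype=np.float64)
    G = np.asarray(G, dtype=np.float64)
    if w.shape != state.m.shape or G.shape != state.m.shape:
        raise ValueError(f"shape mismatch: state {state.m.shape}, w {w.shape}, G {G.shape}")
    if not np.all(np.isfinite(G)):
        raise ValueError("non-finite gradient entries")
    t = state.t + 1
    m = state.beta1 * state.m + (1.0 - state.beta1) * G
    u = np.maximum(state.beta2 * state.u, np.abs(G))
    scale = state.eta / (1.0 - state.beta1 ** t)
    w_new = w - scale * m / (u + state.epsilon)
    return replace(state, m=m, u=u, t=t), w_new
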