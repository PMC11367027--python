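"""Dragonfly-algorithm swarm optimizer and SSAE hyperparameter tuning.

Each dragonfly carries a position X and a step (speed) vector dX inside a
bounded search box.  Per member, five behaviors are computed over its
neighbors (members within the current neighborhood radius):

    separation  S_i = -sum_j (X - X_j)
    alignment   A_i = mean_j V_j
    cohesion    C_i = mean_j X_j - X
    food        F_i = X+ - X          (X+ = best position seen)
    enemy       E_i = X- + X          (X- = worst position seen)

and the update is dX <- s*S + a*A + c*C + f*F + e*E + w*dX, X <- X + dX.
A member with no neighbors takes a Levy-flight displacement instead.  The
neighborhood radius grows from 10% to 110% of each dimension's width over
the iteration budget (static swarms early, one dynamic swarm late); inertia
w anneals 0.9 -> 0.4; the behavior coefficients are redrawn each iteration
from the conventional ranges.  Fitness is minimized (for classifier tuning:
the validation error rate in percent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np



@dataclass
class Dragonfly:
    position: np.ndarray
    step: np.ndarray
    fitness: float = math.inf


@dataclass
class Swarm:
    """Swarm state: members, best/worst memory, schedules, seeded RNG."""

    members: list[Dragonfly]
    bounds: np.ndarray            # [d, 2] low/high
    T: int                        # iteration budget
    rng: np.random.Generator
    t: int = 0
    food: np.ndarray | None = None
    food_fitness: float = math.inf
    enemy: np.ndarray | None = None
    enemy_fitness: float = -math.inf
    coefficients: tuple = (0.1, 0.1, 0.7, 1.0, 0.1)  # s, a, c, f, e
    w: float = 0.9
    radius: np.ndarray | None = None

    def __post_init__(self) -> None:
        widths = self.bounds[:, 1] - self.bounds[:, 0]
        if self.radius is None:
            self.radius = 0.1 * widths


def init_swarm(bounds: np.ndarray, pop_size: int, iterations: int,
               seed: int) -> Swarm:
    bounds = np.asarray(bounds, dtype=np.float64)
    rng = np.random.default_rng(seed)
    low, high = bounds[:, 0], bounds[:, 1]
    members = [Dragonfly(position=rng.uniform(low, high),
                         step=np.zeros(bounds.shape[0]))
               for _ in range(pop_size)]
    return Swarm(members=members, bounds=bounds, T=iterations, rng=rng)


def _record_fitness(swarm: Swarm, member: Dragonfly, value: float) -> None:
    value = float(value) if np.isfinite(value) else math.inf
    member.fitness = value
    if value < swarm.food_fitness:
        swarm.food_fitness = value
        swarm.food = member.position.copy()
    if value > swarm.enemy_fitness and np.isfinite(value):
        swarm.enemy_fitness = value
        swarm.enemy = member.position.copy()


def _neighbors(swarm: Swarm, i: int) -> list[int]:
    xi = swarm.members[i].position
    out = []
    for j, m in enumerate(swarm.members):
        if j == i:
            continue
        if np.all(np.abs(m.position - xi) <= swarm.radius):
            out.append(j)
    return out


def compute_behaviors(swarm: Swarm, i: int):
    """Separation, alignment, cohesion, food and enemy vectors for member i.

    With no neighbors: S = 0, A = the member's own step, C = 0.
    """
    member = swarm.members[i]
    X = member.position
    idx = _neighbors(swarm, i)
    if idx:
        Xj = np.stack([swarm.members[j].position for j in idx])
        Vj = np.stack([swarm.members[j].step for j in idx])
        S = -np.sum(X[None, :] - Xj, axis=0)
        A = Vj.mean(axis=0)
        C = Xj.mean(axis=0) - X
    else:
        S = np.zeros_like(X)
        A = member.step.copy()
        C = np.zeros_like(X)
    F = swarm.food - X
    E = swarm.enemy + X
    return S, A, C, F, E


def _levy(d: int, rng: np.random.Generator, beta: float = 1.5) -> np.ndarray:
    num = math.gamma(1 + beta) * math.sin(math.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    sigma = (num / den) ** (1.0 / beta)
    u = rng.normal(0.0, sigma, size=d)
    v = rng.normal(0.0, 1.0, size=d)
    return 0.01 * u / np.abs(v) ** (1.0 / beta)


def _advance_schedules(swarm: Swarm) -> None:
    frac = swarm.t / max(swarm.T, 1)
    widths = swarm.bounds[:, 1] - swarm.bounds[:, 0]
    swarm.radius = widths * (0.1 + 1.0 * frac)
    swarm.w = 0.9 - frac * (0.9 - 0.4)
    r = swarm.rng
    swarm.coefficients = (2 * r.random() * 0.1, 2 * r.random() * 0.1,
                          2 * r.random() * 0.7, 2 * r.random(), 0.1)


def update_swarm(swarm: Swarm, fitness_of) -> Swarm:
    """One DFA iteration in place; returns the swarm for chaining."""
    _advance_schedules(swarm)
    s, a, c, f, e = swarm.coefficients
    low, high = swarm.bounds[:, 0], swarm.bounds[:, 1]
    d = swarm.bounds.shape[0]
    new_states = []
    for i, member in enumerate(swarm.members):
        idx = _neighbors(swarm, i)
        if idx:
            S, A, C, F, E = compute_behaviors(swarm, i)
            step = s * S + a * A + c * C + f * F + e * E + swarm.w * member.step
            pos = member.position + step
        else:
            pos = member.position + _levy(d, swarm.rng) * member.position
            step = np.zeros(d)
        clamp_lo = pos < low
        clamp_hi = pos > high
        pos = np.clip(pos, low, high)
        step = np.where(clamp_lo | clamp_hi, 0.0, step)
        new_states.append((pos, step))
    for member, (pos, step) in zip(swarm.members, new_states):
        member.position, member.step = pos, step
        try:
            value = fitness_of(pos)
        except Exception:
            value = math.inf
        _record_fitness(swarm, member, value)
    swarm.t += 1
    return swarm


def dfa_optimize(fitness, bounds: np.ndarray, pop_size: int = 20,
                 iterations: int = 100,
                 seed: int = 0) -> tuple[np.ndarray, float, list[dict]]:
    """Minimize ``fitness`` over a box; returns (best x, best f, history).

    History has one entry per iteration with the best-so-far (non-increasing)
    and mean population fitness.
    """
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    swarm = init_swarm(np.asarray(bounds, dtype=np.float64), pop_size,
                       iterations, seed)
    for member in swarm.members:
        try:
            value = fitness(member.position)
        except Exception:
            value = math.inf
        _record_fitness(swarm, member, value)
    history = []
    for _ in range(iterations):
        update_swarm(swarm, fitness)
        finite = [m.fitness for m in swarm.members if np.isfinite(m.fitness)]
        history.append({"iteration": swarm.t,
                        "best_fitness": swarm.food_fitness,
                        "mean_fitness": float(np.mean(finite)) if finite else math.inf})
    return swarm.food.copy(), swarm.food_fitness, history


def write_history_csv(history: list[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(history).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Hyperparameter search space and SSAE tuning
# ---------------------------------------------------------------------------

@dataclass
class HyperparamSpec:
    """Named box of hyperparameters with per-dimension scale/integrality.

    Log-scaled dimensions are searched in log10 space; integer dimensions are
    rounded only when a position is decoded for evaluation.
    """

    names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    scales: tuple[str, ...]       # "linear" | "log"
    integers: tuple[bool, ...]

    def __post_init__(self) -> None:
        for (lo, hi), scale in zip(self.bounds, self.scales):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite with low < high")
            if scale == "log" and lo <= 0:
                raise ValueError("log-scaled bounds must be positive")

    def internal_bounds(self) -> np.ndarray:
        out = []
        for (lo, hi), scale in zip(self.bounds, self.scales):
            if scale == "log":
                out.append((math.log10(lo), math.log10(hi)))
            else:
                out.append((lo, hi))
        return np.array(out)

    def decode(self, position: np.ndarray) -> dict:
        cfg = {}
        for name, v, scale, is_int in zip(self.names, position,
                                          self.scales, self.integers):
            x = 10.0 ** v if scale == "log" else float(v)
            cfg[name] = int(round(x)) if is_int else x
        return cfg


def default_ssae_spec() -> HyperparamSpec:
    """Default tuned dimensions: layer sizes, rho, beta, learning rate."""
    return HyperparamSpec(
        names=("size1", "size2", "rho", "beta", "eta"),
        bounds=((16, 128), (8, 64), (0.01, 0.2), (0.1, 10.0), (1e-3, 0.3)),
        scales=("log", "log", "log", "log", "log"),
        integers=(True, True, False, False, False),
    )


def classifier_error_rate(y_true: np.ndarray, y_pred: np.ndarray,
                          exact_match: bool = False) -> float:
    """Error rate in percent: 100 * misclassified / total.

    Under multi-label output the default reading is the mean over classes of
    the one-vs-rest misclassification rate (100 minus the macro-average
    accuracy); ``exact_match`` instead counts a sample as misclassified when
    any class decision is wrong.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("shape mismatch")
    if exact_match:
        wrong = np.any(y_true != y_pred, axis=1)
        return 100.0 * float(wrong.mean())
    return 100.0 * float(np.mean(y_true != y_pred))


def tune_ssae(train_features: np.ndarray, train_labels: np.ndarray,
              val_features: np.ndarray, val_labels: np.ndarray,
              spec: HyperparamSpec | None = None, pop_size: int = 6,
              iterations: int = 8, seed: int = 0, fitness_epochs: int = 5,
              exact_match: bool = False) -> tuple[dict, float, list[dict]]:
    """DFA search over SSAE hyperparameters with error-rate fitness.

    Each fitness evaluation trains a reduced-epoch SSAE at the decoded
    hyperparameters on the training split and scores the validation split;
    a failing evaluation scores +inf and the run continues.  Returns the best
    decoded config, its fitness (percent error), and the iteration history.
    """
    from . import ssae as _ssae

    spec = spec or default_ssae_spec()

    def fitness(position: np.ndarray) -> float:
        cfg = spec.decode(position)
        l1, l2, _ = _ssae.pretrain_stack(
            train_features, sizes=(cfg["size1"], cfg["size2"]),
            rho=cfg["rho"], beta=cfg["beta"], epochs=fitness_epochs,
            adamax_config={"eta": cfg["eta"]}, seed=seed + 1)
        clf = _ssae.fit_classifier((l1, l2), train_features, train_labels,
                                   epochs=fitness_epochs,
                                   adamax_config={"eta": cfg["eta"]},
                                   seed=seed + 2, rho=cfg["rho"], beta=cfg["beta"])
        _, pred = _ssae.predict(clf, val_features)
        return classifier_error_rate(val_labels, pred, exact_match=exact_match)

    best_pos, best_fit, history = dfa_optimize(
        fitness, spec.internal_bounds(), pop_size=pop_size,
        iterations=iterations, seed=seed)
    return spec.decode(best_pos), best_fit, history
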