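"""Continuous geometrical core-periphery scoring of single network layers.

A two-parameter family of transition vectors assigns a local core value to
each position of a node ordering: alpha in [0, 1] sets the sharpness of the
core/periphery boundary (alpha = 1 is a binary transition) and beta in
[0, 1] sets the size of the core (the first floor(beta * N) positions form
the low, peripheral segment). A permutation of nodes onto positions is
sought that maximizes the core quality

    R = sum_{i != j} A_ij * C_pos(i) * C_pos(j)

via simulated annealing over pairwise swaps; the per-node local values of
the best assignment, normalized to a maximum of 1, are the core scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataFormatError

__all__ = [
    "TransitionParams",
    "AnnealSchedule",
    "CoreAssignment",
    "CoreScoreProfile",
    "transition_vector",
    "core_quality",
    "anneal_assignment",
    "rscore_landscape",
    "core_scores",
    "core_score_summary",
]


@dataclass
class TransitionParams:
    """(alpha, beta) of the transition-vector family; both in [0, 1]."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ConfigError(f"alpha and beta must lie in [0, 1]; got {self}")


@dataclass
class AnnealSchedule:
    """Simulated-annealing schedule for the permutation search.

    The initial temperature is set from the standard deviation of R-changes
    over ``t0_probes`` random swaps; cooling is geometric. The search stops
    after ``patience`` consecutive temperatures without improving the best R.
    A deterministic greedy swap refinement always follows.
    """

    cooling: float = 0.995
    sweeps_per_temp: int = 100  # swaps per temperature = sweeps_per_temp * N
    patience: int = 20
    t0_probes: int = 100
    t0_scale: float = 1.0
    max_temps: int = 2000

    @classmethod
    def fast(cls) -> "AnnealSchedule":
        """Light-weight schedule for tests and small instances."""
        return cls(cooling=0.9, sweeps_per_temp=10, patience=5, max_temps=120)


@dataclass
class CoreAssignment:
    """A node ordering with its local core values and core quality R."""

    permutation: np.ndarray  # permutation[p] = node placed at position p
    local_values: np.ndarray  # per-node value C_pos(i), indexed by node
    R: float
    params: TransitionParams


@dataclass
class CoreScoreProfile:
    """Normalized per-node core scores for one layer."""

    scores: np.ndarray  # in [0, 1], max exactly 1
    alpha_used: float
    beta_used: float
    R_best: float
    n_restarts: int
    meta: dict = field(default_factory=dict)


def transition_vector(n_nodes: int, params: TransitionParams) -> np.ndarray:
    """Ordered local core values for positions 1..N.

    The first n1 = floor(beta * N) positions rise linearly to (1 - alpha)/2;
    the remaining positions rise linearly from just above (1 + alpha)/2 to
    exactly 1, leaving a boundary gap of (approximately) alpha:

        C_p = p / n1 * (1 - alpha) / 2                      for p <= n1
        C_p = (p - n1) / (N - n1) * (1 - alpha) / 2
              + (1 + alpha) / 2                             for p > n1

    alpha = 1 gives a binary 0/1 transition; alpha = 0 makes the boundary
    jump equal to the linear increment (the fuzziest boundary).
    """
    if n_nodes < 2:
        raise ConfigError("transition_vector needs at least 2 nodes")
    N = n_nodes
    n1 = int(np.floor(params.beta * N))
    p = np.arange(1, N + 1, dtype=float)
    C = np.empty(N)
    half_low = (1.0 - params.alpha) / 2.0
    if n1 > 0:
        C[:n1] = p[:n1] / n1 * half_low
    if n1 < N:
        C[n1:] = (p[n1:] - n1) / (N - n1) * half_low + (1.0 + params.alpha) / 2.0
    return C


def _check_layer(layer: np.ndarray) -> np.ndarray:
    A = np.asarray(layer, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DataFormatError("layer must be a square matrix")
    if not np.allclose(A, A.T, atol=1e-10):
        raise DataFormatError("layer is not symmetric")
    if np.any(A < 0):
        raise DataFormatError("layer has negative weights")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    return A


def _normalized_transition(n_nodes: int, params: TransitionParams) -> np.ndarray:
    """Transition vector scaled to unit Euclidean norm, so that R values are
    comparable across (alpha, beta)."""
    C = transition_vector(n_nodes, params)
    norm = np.linalg.norm(C)
    return C / norm if norm > 0 else C


def _quality_from_values(A: np.ndarray, v: np.ndarray) -> float:
    """R = sum over ordered pairs (i != j) of A_ij v_i v_j (diagonal is zero)."""
    return float(v @ A @ v)


def core_quality(
    layer: np.ndarray,
    order: np.ndarray,
    params: TransitionParams,
    normalize: bool = True,
) -> float:
    """Core quality R of a node ordering under (alpha, beta).

    ``order[p]`` is the node placed at position p (position N is the most
    core-like). The transition vector is unit-normalized by default.
    """
    A = _check_layer(layer)
    N = A.shape[0]
    order = np.asarray(order)
    if sorted(order.tolist()) != list(range(N)):
        raise DataFormatError("order must be a permutation of 0..N-1")
    C = _normalized_transition(N, params) if normalize else transition_vector(N, params)
    v = np.empty(N)
    v[order] = C  # node order[p] receives value C[p]
    return _quality_from_values(A, v)


def _greedy_refine(A: np.ndarray, C: np.ndarray, order: np.ndarray) -> tuple[np.ndarray, float]:
    """Deterministic best-swap hill climbing to a local maximum of R."""
    N = A.shape[0]
    v = np.empty(N)
    v[order] = C
    Av = A @ v
    R = float(v @ Av)
    pos_of = np.empty(N, dtype=int)
    pos_of[order] = np.arange(N)
    while True:
        D = v[None, :] - v[:, None]  # D[a, b] = v_b - v_a
        gains = 2.0 * D * (Av[:, None] - Av[None, :]) - 2.0 * D**2 * A
        a, b = np.unravel_index(np.argmax(gains), gains.shape)
        if gains[a, b] <= 1e-12:
            break
        da = v[b] - v[a]
        Av += A[:, a] * da - A[:, b] * da
        v[a], v[b] = v[b], v[a]
        R += float(gains[a, b])
        pos_of[a], pos_of[b] = pos_of[b], pos_of[a]
    order_out = np.empty(N, dtype=int)
    order_out[pos_of] = np.arange(N)
    return order_out, R


def _anneal_once(
    A: np.ndarray,
    C: np.ndarray,
    order0: np.ndarray,
    schedule: AnnealSchedule,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """One Metropolis run over pairwise position swaps, then greedy refinement."""
    N = A.shape[0]
    v = np.empty(N)
    v[order0] = C
    Av = A @ v
    R = float(v @ Av)
    pos_of = np.empty(N, dtype=int)
    pos_of[order0] = np.arange(N)

    # initial temperature from the spread of R-changes over random swaps
    probes = rng.integers(0, N, size=(schedule.t0_probes, 2))
    deltas = []
    for a, b in probes:
        if a == b:
            continue
        d = v[b] - v[a]
        deltas.append(2.0 * d * (Av[a] - Av[b]) - 2.0 * d * d * A[a, b])
    T = schedule.t0_scale * (np.std(deltas) if deltas else 1.0)
    T = max(T, 1e-12)

    best_R = R
    best_pos = pos_of.copy()
    stall = 0
    n_swaps = max(schedule.sweeps_per_temp * N, 1)
    for _ in range(schedule.max_temps):
        improved = False
        pairs = rng.integers(0, N, size=(n_swaps, 2))
        accept_u = rng.random(n_swaps)
        for (a, b), u in zip(pairs, accept_u):
            if a == b:
                continue
            d = v[b] - v[a]
            dR = 2.0 * d * (Av[a] - Av[b]) - 2.0 * d * d * A[a, b]
            if dR > 0 or u < np.exp(dR / T):
                Av += A[:, a] * d - A[:, b] * d
                v[a], v[b] = v[b], v[a]
                pos_of[a], pos_of[b] = pos_of[b], pos_of[a]
                R += dR
                if R > best_R + 1e-12:
                    best_R = R
                    best_pos = pos_of.copy()
                    improved = True
        stall = 0 if improved else stall + 1
        if stall >= schedule.patience:
            break
        T *= schedule.cooling
    order = np.empty(N, dtype=int)
    order[best_pos] = np.arange(N)
    return _greedy_refine(A, C, order)


def _initial_order(A: np.ndarray) -> np.ndarray:
    """Strength-ranked start: weakest nodes at peripheral (low) positions."""
    return np.argsort(A.sum(axis=0), kind="stable")


def anneal_assignment(
    layer: np.ndarray,
    params: TransitionParams,
    schedule: AnnealSchedule | None = None,
    n_restarts: int = 10,
    seed: int | np.random.SeedSequence | None = 0,
) -> CoreAssignment:
    """Best-of-``n_restarts`` annealed permutation maximizing core quality R.

    The first restart starts from the strength-ranked ordering, the rest
    from random orderings; the returned R is therefore never below the
    greedy-refined strength ranking.
    """
    if n_restarts < 1:
        raise ConfigError("n_restarts must be >= 1")
    A = _check_layer(layer)
    N = A.shape[0]
    C = _normalized_transition(N, params)
    schedule = schedule or AnnealSchedule()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    best: tuple[np.ndarray, float] | None = None
    for i, child in enumerate(ss.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        order0 = _initial_order(A) if i == 0 else rng.permutation(N)
        order, R = _anneal_once(A, C, order0, schedule, rng)
        if best is None or R > best[1]:
            best = (order, R)
    order, R = best
    local = np.empty(N)
    local[order] = C
    return CoreAssignment(permutation=order, local_values=local, R=R, params=params)


def rscore_landscape(
    layer: np.ndarray,
    alphas: np.ndarray | None = None,
    betas: np.ndarray | None = None,
    schedule: AnnealSchedule | None = None,
    n_restarts: int = 1,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[np.ndarray, TransitionParams]:
    """Maximized core quality over an (alpha, beta) lattice.

    Returns the R matrix (len(alphas) x len(betas)) and the lattice point
    attaining the global maximum. Default lattice: 21 x 21 over [0, 1]^2.
    """
    alphas = np.linspace(0.0, 1.0, 21) if alphas is None else np.asarray(alphas, float)
    betas = np.linspace(0.0, 1.0, 21) if betas is None else np.asarray(betas, float)
    if alphas.min() < 0 or alphas.max() > 1 or betas.min() < 0 or betas.max() > 1:
        raise ConfigError("landscape grid must lie within [0, 1]^2")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    R = np.empty((len(alphas), len(betas)))
    children = iter(ss.spawn(len(alphas) * len(betas)))
    for i, a in enumerate(alphas):
        for j, b in enumerate(betas):
            assignment = anneal_assignment(
                layer, TransitionParams(a, b), schedule, n_restarts, next(children)
            )
            R[i, j] = assignment.R
    i, j = np.unravel_index(np.argmax(R), R.shape)
    return R, TransitionParams(float(alphas[i]), float(betas[j]))


def core_scores(
    layer: np.ndarray,
    alpha_used: float,
    beta_used: float,
    schedule: AnnealSchedule | None = None,
    n_restarts: int = 10,
    seed: int | np.random.SeedSequence | None = 0,
    mode: str = "point",
    alphas: np.ndarray | None = None,
    betas: np.ndarray | None = None,
) -> CoreScoreProfile:
    """Per-node core scores, normalized to a maximum of 1.

    mode="point": the local values of the best assignment at
    (alpha_used, beta_used). mode="aggregate": sum over an (alpha, beta)
    lattice of each node's local value weighted by the corresponding best R
    (the weighted-aggregation variant).
    """
    params = TransitionParams(alpha_used, beta_used)
    if mode == "point":
        assignment = anneal_assignment(layer, params, schedule, n_restarts, seed)
        raw = assignment.local_values
        R_best = assignment.R
    elif mode == "aggregate":
        alphas = np.linspace(0.0, 1.0, 11) if alphas is None else np.asarray(alphas, float)
        betas = np.linspace(0.05, 0.95, 10) if betas is None else np.asarray(betas, float)
        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        children = iter(ss.spawn(len(alphas) * len(betas)))
        N = np.asarray(layer).shape[0]
        raw = np.zeros(N)
        R_best = -np.inf
        for a in alphas:
            for b in betas:
                assignment = anneal_assignment(
                    layer, TransitionParams(a, b), schedule, n_restarts, next(children)
                )
                raw = raw + assignment.local_values * assignment.R
                R_best = max(R_best, assignment.R)
    else:
        raise ConfigError(f"unknown core-score mode {mode!r}")
    top = raw.max()
    scores = raw / top if top > 0 else np.ones_like(raw)
    return CoreScoreProfile(
        scores=scores,
        alpha_used=alpha_used,
        beta_used=beta_used,
        R_best=float(R_best),
        n_restarts=n_restarts,
        meta={"mode": mode},
    )


def core_score_summary(profiles: list[CoreScoreProfile]) -> tuple[np.ndarray, float]:
    """Per-node mean score over layers and the variance of those means over
    nodes (population variance)."""
    if not profiles:
        raise ConfigError("core_score_summary needs at least one profile")
    mat = np.stack([p.scores for p in profiles])
    mean_per_node = mat.mean(axis=0)
    return mean_per_node, float(mean_per_node.var())
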