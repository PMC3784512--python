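"""Multilayer modularity, Louvain-like optimization, and dynamic diagnostics.

The quality function couples a Newman-Girvan intra-layer term (resolution
gamma per layer) with ordinal inter-layer identity coupling (strength omega
between a node and itself in adjacent layers):

    Q = (1/2mu) * sum_{ijlr} [ (A_ijl - gamma_l * k_il * k_jl / (2 m_l)) d_lr
                               + d_ij * C_jlr ] * delta(g_il, g_jr)

where 2mu is the sum of all intra-layer strengths plus all inter-layer
coupling strengths, and C_jlr = omega for |l - r| = 1 (zero otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataFormatError
from .netbuild import AdjacencyTensor

__all__ = [
    "ModularityParams",
    "MultilayerPartition",
    "CommunityDiagnostics",
    "build_supra_matrix",
    "multilayer_modularity",
    "louvain_multilayer",
    "run_ensemble",
    "flexibility",
    "count_communities",
]

_MOVE_TOL = 1e-12


@dataclass
class ModularityParams:
    """Resolution and coupling parameters of the multilayer quality function.

    gamma may be a scalar (same structural resolution in every layer) or a
    per-layer sequence. omega is the inter-layer coupling between a node and
    itself in adjacent layers only (ordinal/temporal coupling).
    """

    gamma: float | np.ndarray = 1.0
    omega: float = 1.0

    def gamma_per_layer(self, n_layers: int) -> np.ndarray:
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if g.size == 1:
            g = np.full(n_layers, g[0])
        if g.size != n_layers:
            raise ConfigError(f"gamma has {g.size} entries for {n_layers} layers")
        if np.any(g <= 0):
            raise ConfigError("gamma must be positive")
        return g

    def validate(self) -> None:
        if self.omega < 0:
            raise ConfigError("omega must be nonnegative")


@dataclass
class MultilayerPartition:
    """Community labels per (node, layer); label ids are global across layers."""

    labels: np.ndarray  # (n_nodes, n_layers), positive integers

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise DataFormatError("partition labels must be (n_nodes, n_layers)")
        if np.any(self.labels < 1):
            raise DataFormatError("community ids must be positive integers")

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def n_layers(self) -> int:
        return self.labels.shape[1]


@dataclass
class CommunityDiagnostics:
    """Summary diagnostics of one or more multilayer partitions."""

    Q: float
    n_communities: float
    flexibility: np.ndarray
    mean_flexibility: float
    Q_se: float | None = None
    n_communities_se: float | None = None
    mean_flexibility_se: float | None = None
    extras: dict = field(default_factory=dict)


def _validate_tensor(W: np.ndarray) -> None:
    if W.ndim != 3 or W.shape[0] != W.shape[1]:
        raise DataFormatError("tensor must have shape (N, N, L)")
    if np.any(W < 0):
        raise DataFormatError("negative weights are not allowed")
    for l in range(W.shape[2]):
        if not np.allclose(W[:, :, l], W[:, :, l].T, atol=1e-10):
            raise DataFormatError(f"layer {l} is not symmetric")


def _weights(tensor: AdjacencyTensor | np.ndarray) -> np.ndarray:
    W = tensor.weights if isinstance(tensor, AdjacencyTensor) else np.asarray(tensor, float)
    _validate_tensor(W)
    return W


def build_supra_matrix(
    tensor: AdjacencyTensor | np.ndarray,
    params: ModularityParams,
    interlayer_perms: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, float]:
    """Dense supra-modularity matrix B and the normalization 2mu.

    Slot u = l * N + i holds node i of layer l. Diagonal blocks are
    A_l - gamma_l * k k^T / (2 m_l); off-diagonal blocks couple each node to
    itself (or to its image under ``interlayer_perms[l]``, for null models)
    in adjacent layers with weight omega. Q of a partition is
    sum_{u,v same community} B[u, v] / 2mu.
    """
    params.validate()
    W = _weights(tensor)
    N, _, L = W.shape
    gammas = params.gamma_per_layer(L)
    if interlayer_perms is not None and len(interlayer_perms) != L - 1:
        raise ConfigError(f"need {L - 1} inter-layer permutations, got {len(interlayer_perms)}")
    B = np.zeros((N * L, N * L))
    total_intra = 0.0
    for l in range(L):
        A = W[:, :, l]
        k = A.sum(axis=0)
        two_m = k.sum()
        total_intra += two_m
        block = A.copy()
        if two_m > 0:
            block -= gammas[l] * np.outer(k, k) / two_m
        B[l * N : (l + 1) * N, l * N : (l + 1) * N] = block
    for l in range(L - 1):
        perm = np.arange(N) if interlayer_perms is None else np.asarray(interlayer_perms[l])
        rows = l * N + np.arange(N)
        cols = (l + 1) * N + perm
        B[rows, cols] = params.omega
        B[cols, rows] = params.omega
    two_mu = total_intra + 2.0 * params.omega * N * (L - 1)
    return B, two_mu


def multilayer_modularity(
    tensor: AdjacencyTensor | np.ndarray,
    partition: MultilayerPartition,
    params: ModularityParams,
    interlayer_perms: list[np.ndarray] | None = None,
) -> float:
    """Exact evaluation of the multilayer quality function for a partition."""
    W = _weights(tensor)
    N, _, L = W.shape
    if partition.labels.shape != (N, L):
        raise DataFormatError(
            f"partition shape {partition.labels.shape} does not match tensor ({N}, {L})"
        )
    B, two_mu = build_supra_matrix(W, params, interlayer_perms)
    flat = partition.labels.T.reshape(-1)  # slot u = l*N + i
    same = flat[:, None] == flat[None, :]
    return float(np.sum(B[same]) / two_mu)


def _louvain_one_level(B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Greedy single-node moves on a generic symmetric modularity matrix.

    Returns community labels (0-based, not necessarily consecutive). Each
    accepted move strictly increases sum_{same community} B.
    """
    n = B.shape[0]
    labels = np.arange(n)
    moved = True
    while moved:
        moved = False
        for v in rng.permutation(n):
            lv = labels[v]
            gains = np.bincount(labels, weights=B[v], minlength=n)
            # B[v, v] travels with v wherever it goes; exclude it so the
            # stay-gain and move-gains are comparable
            gains[lv] -= B[v, v]
            best = int(np.argmax(gains))
            if best != lv and gains[best] > gains[lv] + _MOVE_TOL:
                labels[v] = best
                moved = True
    return labels


def _aggregate(B: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse communities into super-nodes: B' = S^T B S."""
    uniq, inv = np.unique(labels, return_inverse=True)
    k = len(uniq)
    S = np.zeros((B.shape[0], k))
    S[np.arange(B.shape[0]), inv] = 1.0
    return S.T @ B @ S, inv


def _louvain_generic(
    B: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Full Louvain (local moves + aggregation) on a supra-modularity matrix."""
    n = B.shape[0]
    membership = np.arange(n)
    current = B
    while True:
        labels = _louvain_one_level(current, rng)
        if len(np.unique(labels)) == current.shape[0]:
            break
        current, inv = _aggregate(current, labels)
        membership = inv[membership]
        if current.shape[0] == 1:
            break
    return membership


def louvain_multilayer(
    tensor: AdjacencyTensor | np.ndarray,
    params: ModularityParams,
    seed: int | np.random.SeedSequence | None = 0,
    interlayer_perms: list[np.ndarray] | None = None,
) -> tuple[MultilayerPartition, float]:
    """Locally greedy (Louvain-like) maximization of multilayer modularity.

    Node-visit order is randomized by ``seed``; identical seed and input give
    an identical partition. The returned Q equals
    ``multilayer_modularity`` of the returned partition.
    """
    W = _weights(tensor)
    N, _, L = W.shape
    B, two_mu = build_supra_matrix(W, params, interlayer_perms)
    rng = np.random.default_rng(seed)
    membership = _louvain_generic(B, rng)
    labels = membership.reshape(L, N).T  # slot u = l*N + i
    _, labels = np.unique(labels, return_inverse=True)
    labels = labels.reshape(N, L) + 1
    partition = MultilayerPartition(labels=labels)
    flat = partition.labels.T.reshape(-1)
    same = flat[:, None] == flat[None, :]
    Q = float(np.sum(B[same]) / two_mu)
    return partition, Q


def flexibility(partition: MultilayerPartition) -> tuple[np.ndarray, float]:
    """Per-node flexibility: fraction of adjacent-layer transitions at which
    the node changes community, f_i in [0, 1]; plus the network mean."""
    if partition.n_layers < 2:
        raise ConfigError("flexibility is undefined for a single-layer partition")
    changes = partition.labels[:, 1:] != partition.labels[:, :-1]
    f = changes.sum(axis=1) / (partition.n_layers - 1)
    return f.astype(float), float(f.mean())


def count_communities(partition: MultilayerPartition) -> int:
    """Number of distinct non-empty community ids across the whole partition."""
    return int(len(np.unique(partition.labels)))


def run_ensemble(
    tensor: AdjacencyTensor | np.ndarray,
    params: ModularityParams,
    n_runs: int = 100,
    seed: int | np.random.SeedSequence | None = 0,
    interlayer_perms: list[np.ndarray] | None = None,
) -> tuple[list[tuple[MultilayerPartition, float]], CommunityDiagnostics]:
    """Repeat the modularity optimization ``n_runs`` times with independent
    derived seeds and average the three dynamic diagnostics over runs."""
    if n_runs < 1:
        raise ConfigError("n_runs must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_runs)
    runs: list[tuple[MultilayerPartition, float]] = []
    qs, ncs, flexes = [], [], []
    for child in children:
        part, q = louvain_multilayer(tensor, params, child, interlayer_perms)
        runs.append((part, q))
        qs.append(q)
        ncs.append(count_communities(part))
        f, _ = flexibility(part)
        flexes.append(f)
    qs_arr = np.array(qs)
    ncs_arr = np.array(ncs, dtype=float)
    fmat = np.stack(flexes)  # (runs, nodes)
    mean_flex_per_run = fmat.mean(axis=1)

    def _se(a: np.ndarray) -> float:
        return float(a.std(ddof=1) / np.sqrt(len(a))) if len(a) > 1 else 0.0

    diags = CommunityDiagnostics(
        Q=float(qs_arr.mean()),
        n_communities=float(ncs_arr.mean()),
        flexibility=fmat.mean(axis=0),
        mean_flexibility=float(mean_flex_per_run.mean()),
        Q_se=_se(qs_arr),
        n_communities_se=_se(ncs_arr),
        mean_flexibility_se=_se(mean_flex_per_run),
        extras={"per_run_Q": qs, "per_run_n_communities": ncs},
    )
    return runs, diags
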