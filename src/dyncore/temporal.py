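"""Nodal null model and temporal core / bulk / periphery classification.

The null model rewires the ends of the multilayer network's inter-layer
identity edges uniformly at random (one independent permutation per layer
interface), leaving every intra-layer adjacency matrix untouched. Node
flexibilities from modularity optimizations of the rewired networks form a
null distribution; regions are classified against its 2.5% / 97.5%
confidence bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import (
    ModularityParams,
    flexibility,
    louvain_multilayer,
)
from .errors import ConfigError, DataFormatError
from .netbuild import AdjacencyTensor

__all__ = [
    "RewiredCoupling",
    "NullEnsemble",
    "CoreClassification",
    "rewire_interlayer",
    "null_flexibility_ensemble",
    "classify",
]

CLASS_CORE = "core"
CLASS_BULK = "bulk"
CLASS_PERIPHERY = "periphery"


@dataclass
class RewiredCoupling:
    """A nodal null model: the original tensor plus one random permutation of
    inter-layer edge ends per adjacent-layer interface."""

    tensor: AdjacencyTensor | np.ndarray
    permutations: list[np.ndarray]

    @property
    def n_interfaces(self) -> int:
        return len(self.permutations)


@dataclass
class NullEnsemble:
    """Pooled null flexibility distribution and its confidence band."""

    n_rewirings: int
    null_flexibilities: np.ndarray  # (n_rewirings, n_nodes), averaged over opts
    band_low: float
    band_high: float
    pooling: str = "all"
    meta: dict = field(default_factory=dict)


@dataclass
class CoreClassification:
    labels: list[str]  # one of core/bulk/periphery per region
    region_labels: list[str] | None = None

    def counts(self) -> dict[str, int]:
        return {
            c: sum(1 for x in self.labels if x == c)
            for c in (CLASS_CORE, CLASS_BULK, CLASS_PERIPHERY)
        }


def _n_layers(tensor: AdjacencyTensor | np.ndarray) -> tuple[int, int]:
    W = tensor.weights if isinstance(tensor, AdjacencyTensor) else np.asarray(tensor)
    return W.shape[0], W.shape[2]


def rewire_interlayer(
    tensor: AdjacencyTensor | np.ndarray,
    params: ModularityParams | None = None,
    seed: int | np.random.SeedSequence | None = 0,
) -> RewiredCoupling:
    """Draw a nodal null model by permuting inter-layer edge ends.

    Intra-layer adjacency is shared with the input (unchanged bit-for-bit);
    the identity coupling at each interface l -> l+1 is replaced by an
    independent uniformly random permutation. Coupling weights (omega) are
    preserved because only the edge ends move.
    """
    n_nodes, n_layers = _n_layers(tensor)
    if n_layers < 2:
        raise ConfigError("rewiring needs at least 2 layers")
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n_nodes) for _ in range(n_layers - 1)]
    return RewiredCoupling(tensor=tensor, permutations=perms)


def null_flexibility_ensemble(
    tensor: AdjacencyTensor | np.ndarray,
    params: ModularityParams,
    n_rewirings: int = 100,
    n_opts: int = 1,
    seed: int | np.random.SeedSequence | None = 0,
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> NullEnsemble:
    """Null distribution of nodal flexibility over rewired couplings.

    For each of ``n_rewirings`` independently rewired null networks,
    multilayer modularity is optimized ``n_opts`` times and nodal
    flexibility averaged over optimizations. The confidence band is taken
    at ``percentiles`` (linear interpolation) of the pooled
    (rewiring, node) values.
    """
    if n_rewirings < 1:
        raise ConfigError("n_rewirings must be >= 1")
    if n_opts < 1:
        raise ConfigError("n_opts must be >= 1")
    n_nodes, _ = _n_layers(tensor)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_rewirings)
    values = np.empty((n_rewirings, n_nodes))
    for r, child in enumerate(children):
        perm_seed, *opt_seeds = child.spawn(1 + n_opts)
        null_model = rewire_interlayer(tensor, params, perm_seed)
        per_opt = np.empty((n_opts, n_nodes))
        for o, opt_seed in enumerate(opt_seeds):
            try:
                part, _ = louvain_multilayer(
                    tensor, params, opt_seed, interlayer_perms=null_model.permutations
                )
            except Exception as exc:  # pragma: no cover - defensive
                raise type(exc)(f"rewiring {r}: {exc}") from exc
            per_opt[o], _ = flexibility(part)
        values[r] = per_opt.mean(axis=0)
    lo, hi = np.percentile(values.ravel(), percentiles, method="linear")
    return NullEnsemble(
        n_rewirings=n_rewirings,
        null_flexibilities=values,
        band_low=float(lo),
        band_high=float(hi),
        pooling="all",
        meta={"percentiles": list(percentiles), "n_opts": n_opts},
    )


def classify(
    empirical_flexibility: np.ndarray,
    ensemble: NullEnsemble,
    region_labels: list[str] | None = None,
) -> CoreClassification:
    """Three-way temporal classification of regions.

    core: mean nodal flexibility strictly below the 2.5% bound of the null
    distribution; periphery: strictly above the 97.5% bound; bulk:
    everything in between (boundary equality is assigned to bulk).
    """
    f = np.asarray(empirical_flexibility, dtype=float)
    if ensemble.null_flexibilities.size == 0:
        raise DataFormatError("empty null ensemble")
    if region_labels is not None and len(region_labels) != len(f):
        raise DataFormatError("region_labels length does not match flexibility vector")
    labels = []
    for v in f:
        if v < ensemble.band_low:
            labels.append(CLASS_CORE)
        elif v > ensemble.band_high:
            labels.append(CLASS_PERIPHERY)
        else:
            labels.append(CLASS_BULK)
    return CoreClassification(labels=labels, region_labels=region_labels)
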