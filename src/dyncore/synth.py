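"""Synthetic multilayer data with planted ground truth.

Generators for (i) windowed multichannel time series whose community
structure evolves across windows, (ii) multilayer adjacency tensors drawn
directly from planted block structure (a fast fixture that bypasses
spectral estimation), and (iii) behavioral cohorts whose learning parameter
is tied to the planted flexibility structure. All generators are
deterministic given their seed; one global seed expands into per-component
substreams via ``numpy.random.SeedSequence`` spawning.

These are fixtures: the generative choices (band-limited latent signals,
beta-distributed weights, Laplace movement-time noise) are modeling
conveniences, not estimates of any empirical process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .netbuild import AdjacencyTensor, TimeSeriesSet, scale_band

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_timeseries",
    "generate_adjacency_tensor",
    "generate_community_tensor",
    "generate_learning_cohort",
]

#: floor switching probability used in the bulk-stratum default (see below)
_CORE_SURROGATE_FLOOR = 0.02


@dataclass
class SyntheticConfig:
    """Parameters of the planted multilayer generator.

    core nodes keep one community label across layers; periphery nodes
    resample their label at each layer transition with
    ``periphery_switch_prob``; the remaining bulk nodes switch with
    ``bulk_switch_prob`` (default: geometric mean of a 0.02 floor and the
    periphery probability, giving three distinguishable strata).
    """

    n_regions: int = 40
    n_layers: int = 8
    window_len: int = 60
    sampling_interval: float = 2.0
    n_communities: int = 4
    core_fraction: float = 0.25
    periphery_fraction: float = 0.25
    periphery_switch_prob: float = 0.9
    bulk_switch_prob: float | None = None
    switch_prob_jitter: float = 0.0
    coupling_strength: float = 0.8
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ConfigError("n_layers must be >= 2")
        if self.n_communities > self.n_regions:
            raise ConfigError(
                f"n_communities ({self.n_communities}) exceeds n_regions ({self.n_regions})"
            )
        for name in ("core_fraction", "periphery_fraction", "periphery_switch_prob",
                     "coupling_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]; got {v}")
        if self.core_fraction + self.periphery_fraction > 1.0:
            raise ConfigError("core_fraction + periphery_fraction must be <= 1")
        if self.bulk_switch_prob is not None and not 0.0 <= self.bulk_switch_prob <= 1.0:
            raise ConfigError("bulk_switch_prob must be in [0, 1]")
        if not 0.0 <= self.switch_prob_jitter <= 1.0:
            raise ConfigError("switch_prob_jitter must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")

    @property
    def effective_bulk_switch_prob(self) -> float:
        if self.bulk_switch_prob is not None:
            return self.bulk_switch_prob
        return float(np.sqrt(_CORE_SURROGATE_FLOOR * self.periphery_switch_prob))

    def region_labels(self) -> list[str]:
        return [f"R{i:03d}" for i in range(self.n_regions)]


@dataclass
class GroundTruth:
    """Planted structure recorded alongside every generated artifact."""

    planted_partition: np.ndarray  # (n_regions, n_layers) community labels
    planted_core_nodes: np.ndarray
    planted_periphery_nodes: np.ndarray
    planted_bulk_nodes: np.ndarray
    subject_kappa: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        core = set(self.planted_core_nodes.tolist())
        per = set(self.planted_periphery_nodes.tolist())
        if core & per:
            raise ConfigError("planted core and periphery node sets overlap")


def _component_rng(seed: int, component: int) -> np.random.Generator:
    """Independent substream for a pipeline component of one global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(component,)))


def _planted_roles(config: SyntheticConfig, rng: np.random.Generator):
    n = config.n_regions
    n_core = int(round(config.core_fraction * n))
    n_per = int(round(config.periphery_fraction * n))
    order = rng.permutation(n)
    core = np.sort(order[:n_core])
    periphery = np.sort(order[n_core : n_core + n_per])
    bulk = np.sort(order[n_core + n_per :])
    return core, bulk, periphery


def _planted_labels(config: SyntheticConfig, rng: np.random.Generator):
    """Per-(node, layer) community labels implementing the three strata."""
    n, L, k = config.n_regions, config.n_layers, config.n_communities
    core, bulk, periphery = _planted_roles(config, rng)
    labels = np.empty((n, L), dtype=int)
    labels[:, 0] = rng.integers(1, k + 1, size=n)
    switch_prob = np.zeros(n)
    switch_prob[periphery] = config.periphery_switch_prob
    switch_prob[bulk] = config.effective_bulk_switch_prob
    if config.switch_prob_jitter > 0:
        # per-node heterogeneity within the switching strata (core stays 0)
        movers = np.concatenate([bulk, periphery])
        jitter = rng.uniform(-config.switch_prob_jitter, config.switch_prob_jitter,
                             size=len(movers))
        switch_prob[movers] = np.clip(switch_prob[movers] + jitter, 0.0, 1.0)
    # Each node switches at exactly round(p * (L - 1)) randomly chosen layer
    # interfaces, and a switch always lands in a *different* community, so a
    # node's planted flexibility equals its switch probability (up to
    # rounding) rather than a binomial draw around it.
    switch_at = np.zeros((n, L - 1), dtype=bool)
    for i in range(n):
        n_switches = int(round(switch_prob[i] * (L - 1)))
        if n_switches > 0:
            switch_at[i, rng.permutation(L - 1)[:n_switches]] = True
    for l in range(1, L):
        if k > 1:
            offsets = rng.integers(1, k, size=n)
            new_labels = (labels[:, l - 1] - 1 + offsets) % k + 1
        else:
            new_labels = labels[:, l - 1]
        labels[:, l] = np.where(switch_at[:, l - 1], new_labels, labels[:, l - 1])
    return labels, core, bulk, periphery


def _bandlimited_noise(
    n_samples: int, sampling_interval: float, band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance white noise restricted to ``band`` by FFT masking."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=sampling_interval)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    out = np.fft.irfft(spec, n=n_samples)
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_timeseries(config: SyntheticConfig) -> tuple[TimeSeriesSet, GroundTruth]:
    """Windowed time series with planted evolving community structure.

    Within each window, every node's signal is
    sqrt(coupling_strength) * latent(community, window)
    + sqrt(1 - coupling_strength) * independent noise, scaled by
    ``noise_sd``; latent community signals are white noise band-limited to
    the scale-2 dyadic band of the configured sampling interval.
    """
    rng = _component_rng(config.seed, 0)
    labels, core, bulk, periphery = _planted_labels(config, rng)
    band = scale_band(2, config.sampling_interval)
    n, L, w = config.n_regions, config.n_layers, config.window_len
    values = np.empty((n, L * w))
    c = config.coupling_strength
    for l in range(L):
        latents = {
            comm: _bandlimited_noise(w, config.sampling_interval, band, rng)
            for comm in range(1, config.n_communities + 1)
        }
        noise = rng.standard_normal((n, w))
        for i in range(n):
            shared = latents[labels[i, l]]
            values[i, l * w : (l + 1) * w] = config.noise_sd * (
                np.sqrt(c) * shared + np.sqrt(1.0 - c) * noise[i]
            )
    blocks = [(l * w, (l + 1) * w) for l in range(L)]
    ts = TimeSeriesSet(
        values=values,
        region_labels=config.region_labels(),
        sampling_interval=config.sampling_interval,
        blocks=blocks,
    )
    truth = GroundTruth(
        planted_partition=labels,
        planted_core_nodes=core,
        planted_periphery_nodes=periphery,
        planted_bulk_nodes=bulk,
    )
    return ts, truth


def _beta_draws(mean: float, size: tuple[int, ...], concentration: float,
                rng: np.random.Generator) -> np.ndarray:
    """[0, 1]-valued draws with the requested mean (degenerate at 0/1)."""
    if mean <= 0.0:
        return np.zeros(size)
    if mean >= 1.0:
        return np.ones(size)
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return rng.beta(a, b, size=size)


def _symmetrize(layer: np.ndarray) -> np.ndarray:
    out = np.triu(layer, k=1)
    return out + out.T


def generate_adjacency_tensor(
    config: SyntheticConfig,
    block_params: tuple[float, float, float] = (0.9, 0.5, 0.1),
    concentration: float = 10.0,
) -> tuple[AdjacencyTensor, GroundTruth]:
    """Multilayer tensor with planted geometrical core-periphery structure.

    ``block_params`` are the weight means for core-core, core-other and
    other-other pairs ("other" = bulk or periphery); they must be ordered
    cc >= co >= oo and lie in [0, 1]. Weights are beta-distributed with the
    stated means; layers are symmetric with zero diagonal. The planted
    temporal partition (strata label dynamics) is recorded as well.
    """
    cc, co, oo = block_params
    for v in block_params:
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"block weight means must be in [0, 1]; got {block_params}")
    if not cc >= co >= oo:
        raise ConfigError(f"block means must be ordered cc >= co >= oo; got {block_params}")
    rng = _component_rng(config.seed, 1)
    labels, core, bulk, periphery = _planted_labels(config, rng)
    n, L = config.n_regions, config.n_layers
    is_core = np.zeros(n, dtype=bool)
    is_core[core] = True
    mean_matrix = np.where(
        is_core[:, None] & is_core[None, :], cc,
        np.where(is_core[:, None] | is_core[None, :], co, oo),
    )
    layers = []
    for _ in range(L):
        raw = rng.beta(np.maximum(mean_matrix * concentration, 1e-12),
                       np.maximum((1.0 - mean_matrix) * concentration, 1e-12))
        raw = np.where(mean_matrix <= 0.0, 0.0, np.where(mean_matrix >= 1.0, 1.0, raw))
        layers.append(_symmetrize(raw))
    tensor = AdjacencyTensor(
        weights=np.stack(layers, axis=2),
        region_labels=config.region_labels(),
    )
    truth = GroundTruth(
        planted_partition=labels,
        planted_core_nodes=core,
        planted_periphery_nodes=periphery,
        planted_bulk_nodes=bulk,
        extras={"block_params": list(block_params)},
    )
    return tensor, truth


def generate_community_tensor(
    config: SyntheticConfig,
    within_mean: float = 0.7,
    between_mean: float = 0.1,
    concentration: float = 10.0,
) -> tuple[AdjacencyTensor, GroundTruth]:
    """Multilayer tensor whose layer weights follow the evolving planted
    partition: pairs sharing a community label in a layer receive
    beta-distributed weights of mean ``within_mean``, all other pairs
    ``between_mean``."""
    if not 0.0 <= between_mean <= within_mean <= 1.0:
        raise ConfigError("need 0 <= between_mean <= within_mean <= 1")
    rng = _component_rng(config.seed, 2)
    labels, core, bulk, periphery = _planted_labels(config, rng)
    n, L = config.n_regions, config.n_layers
    layers = []
    for l in range(L):
        same = labels[:, l][:, None] == labels[:, l][None, :]
        w_in = _beta_draws(within_mean, (n, n), concentration, rng)
        w_out = _beta_draws(between_mean, (n, n), concentration, rng)
        layers.append(_symmetrize(np.where(same, w_in, w_out)))
    tensor = AdjacencyTensor(
        weights=np.stack(layers, axis=2),
        region_labels=config.region_labels(),
    )
    truth = GroundTruth(
        planted_partition=labels,
        planted_core_nodes=core,
        planted_periphery_nodes=periphery,
        planted_bulk_nodes=bulk,
        extras={"within_mean": within_mean, "between_mean": between_mean},
    )
    return tensor, truth


def generate_learning_cohort(
    n_subjects: int = 20,
    effect_size: float = 1.0,
    noise_scale: float = 0.1,
    outlier_rate: float = 0.05,
    n_trials: int = 120,
    A: float = 2.5,
    B: float = 1.0,
    kappa_base: float = -0.02,
    kappa_span: float = 0.06,
    base_config: SyntheticConfig | None = None,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], list[SyntheticConfig], GroundTruth]:
    """Cohort of synthetic subjects linking planted flexibility to learning.

    Each subject s carries a latent trait u_s in [0, 1] that controls both
    (i) the switching probability of the planted periphery in that
    subject's multilayer network config (larger u -> more right-skewed
    flexibility distribution) and (ii) the planted learning parameter
    kappa_s = kappa_base - effect_size * kappa_span * u_s + jitter, so the
    planted Spearman correlation between flexibility skewness and kappa is
    negative for effect_size > 0 and absent for effect_size = 0.

    Movement-time tables follow A * exp(kappa_s * t) + B plus Laplace noise;
    with probability ``outlier_rate`` a trial's MT is multiplied by a factor
    drawn uniformly from [2, 4] (exercising the robust fit).
    """
    if n_subjects < 3:
        raise ConfigError("n_subjects must be >= 3")
    if A <= 0 or B <= 0:
        raise ConfigError("A and B must be positive")
    if not 0.0 <= outlier_rate <= 1.0:
        raise ConfigError("outlier_rate must be in [0, 1]")
    rng = _component_rng(seed, 3)
    base = base_config or SyntheticConfig(seed=seed)
    # evenly spread traits, shuffled, so every cohort spans the trait range
    u = rng.permutation(np.linspace(0.0, 1.0, n_subjects))
    kappas = kappa_base - effect_size * kappa_span * u + rng.normal(0.0, 0.002, n_subjects)
    tables: list[pd.DataFrame] = []
    configs: list[SyntheticConfig] = []
    for s in range(n_subjects):
        switch = 0.25 + 0.7 * u[s]
        configs.append(
            replace(
                base,
                periphery_switch_prob=float(switch),
                switch_prob_jitter=max(base.switch_prob_jitter, 0.15),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        t = np.arange(1, n_trials + 1, dtype=float)
        mt = A * np.exp(kappas[s] * t) + B
        mt = mt + rng.laplace(0.0, noise_scale, n_trials) if noise_scale > 0 else mt
        if outlier_rate > 0:
            hit = rng.random(n_trials) < outlier_rate
            mt = np.where(hit, mt * rng.uniform(2.0, 4.0, n_trials), mt)
        mt = np.maximum(mt, 0.05 * B)
        tables.append(
            pd.DataFrame(
                {
                    "subject": f"S{s:03d}",
                    "sequence": "EXT_1",
                    "type": "EXT",
                    "trial": t.astype(int),
                    "MT_s": mt,
                }
            )
        )
    truth = GroundTruth(
        planted_partition=np.zeros((0, 2), dtype=int),
        planted_core_nodes=np.array([], dtype=int),
        planted_periphery_nodes=np.array([], dtype=int),
        planted_bulk_nodes=np.array([], dtype=int),
        subject_kappa=kappas,
        extras={"trait": u.tolist(), "effect_size": effect_size,
                "A": A, "B": B, "noise_scale": noise_scale,
                "outlier_rate": outlier_rate},
    )
    return tables, configs, truth
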