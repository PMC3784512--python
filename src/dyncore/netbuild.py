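"""Multilayer functional network construction from windowed time series.

The pipeline is: (1) decompose each regional time series with the maximal
overlap discrete wavelet transform (MODWT), (2) estimate band-averaged
magnitude-squared coherence between every pair of regional coefficient
series within each time window, and (3) stack the per-window coherence
matrices into a rank-3 adjacency tensor (regions x regions x windows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .errors import ConfigError, DataFormatError, NumericalError

__all__ = [
    "TimeSeriesSet",
    "AdjacencyTensor",
    "EstimatorParams",
    "scale_band",
    "modwt_scale",
    "band_coherence",
    "build_tensor",
]

# Orthonormal Daubechies scaling (low-pass) filters, indexed by number of taps.
# "db2" (4 taps) is the default family used throughout.
_SCALING_FILTERS: dict[str, np.ndarray] = {
    "haar": np.array([1.0, 1.0]) / np.sqrt(2.0),
    "db2": np.array(
        [
            (1.0 + np.sqrt(3.0)),
            (3.0 + np.sqrt(3.0)),
            (3.0 - np.sqrt(3.0)),
            (1.0 - np.sqrt(3.0)),
        ]
    )
    / (4.0 * np.sqrt(2.0)),
    "db4": np.array(
        [
            0.23037781330885523,
            0.7148465705525415,
            0.6308807679295904,
            -0.02798376941698385,
            -0.18703481171888114,
            0.030841381835986965,
            0.032883011666982945,
            -0.010597401784997278,
        ]
    ),
}


def wavelet_filters(family: str) -> tuple[np.ndarray, np.ndarray]:
    """Return the MODWT (rescaled) scaling and wavelet filters for *family*.

    MODWT filters are the orthonormal DWT filters divided by sqrt(2); the
    wavelet filter is the quadrature mirror of the scaling filter.
    """
    try:
        g = _SCALING_FILTERS[family]
    except KeyError:
        raise ConfigError(
            f"unknown wavelet family {family!r}; available: {sorted(_SCALING_FILTERS)}"
        ) from None
    g_modwt = g / np.sqrt(2.0)
    L = len(g)
    h_modwt = np.array([(-1.0) ** t * g_modwt[L - 1 - t] for t in range(L)])
    return g_modwt, h_modwt


@dataclass
class TimeSeriesSet:
    """Windowed multichannel time series.

    Attributes
    ----------
    values : ndarray, shape (n_regions, n_samples)
    region_labels : list of str
    sampling_interval : float
        Seconds between consecutive samples.
    blocks : list of (start, end)
        0-based half-open sample windows, non-overlapping, in order.
    block_types : optional list of str
        One label per block (e.g. condition names).
    """

    values: np.ndarray
    region_labels: list[str]
    sampling_interval: float
    blocks: list[tuple[int, int]]
    block_types: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataFormatError("values must be a 2-D (n_regions, n_samples) array")
        if len(self.region_labels) != self.values.shape[0]:
            raise DataFormatError(
                f"{len(self.region_labels)} region labels for "
                f"{self.values.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataFormatError("time series contain non-finite values")
        if self.sampling_interval <= 0:
            raise ConfigError("sampling_interval must be positive")
        n = self.values.shape[1]
        prev_end = 0
        for start, end in self.blocks:
            if not (0 <= start < end <= n):
                raise DataFormatError(f"block ({start}, {end}) outside sample range [0, {n})")
            if start < prev_end:
                raise DataFormatError(f"block ({start}, {end}) overlaps previous block")
            prev_end = end
        if self.block_types is not None and len(self.block_types) != len(self.blocks):
            raise DataFormatError("block_types length must match blocks")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class AdjacencyTensor:
    """Weighted multilayer functional network (one layer per time window)."""

    weights: np.ndarray  # (n_regions, n_regions, n_layers)
    region_labels: list[str]
    layer_meta: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3 or self.weights.shape[0] != self.weights.shape[1]:
            raise DataFormatError("weights must have shape (N, N, L)")
        if len(self.region_labels) != self.weights.shape[0]:
            raise DataFormatError("region_labels length must match weights")
        if not self.layer_meta:
            self.layer_meta = [f"layer_{l + 1:03d}" for l in range(self.weights.shape[2])]

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def n_layers(self) -> int:
        return self.weights.shape[2]

    def validate(self, atol: float = 1e-10) -> None:
        """Check symmetry, zero diagonal and the [0, 1] weight range."""
        W = self.weights
        for l in range(self.n_layers):
            if not np.allclose(W[:, :, l], W[:, :, l].T, atol=atol):
                raise DataFormatError(f"layer {l} is not symmetric")
            if np.any(np.abs(np.diagonal(W[:, :, l])) > atol):
                raise DataFormatError(f"layer {l} has a nonzero diagonal")
        if W.min() < -atol or W.max() > 1 + atol:
            raise DataFormatError("weights outside [0, 1]")


@dataclass
class EstimatorParams:
    """Welch coherence estimator settings (recorded in output metadata)."""

    nperseg: int = 32
    overlap: float = 0.5
    window: str = "hann"

    @property
    def noverlap(self) -> int:
        return int(round(self.nperseg * self.overlap))

    @property
    def step(self) -> int:
        return self.nperseg - self.noverlap


def scale_band(scale: int, sampling_interval: float) -> tuple[float, float]:
    """Dyadic frequency band of a MODWT scale.

    band(j) = [Nyquist / 2**j, Nyquist / 2**(j-1)] with
    Nyquist = 1 / (2 * sampling_interval).
    """
    if scale < 1:
        raise ConfigError("scale must be >= 1")
    nyquist = 1.0 / (2.0 * sampling_interval)
    return nyquist / 2**scale, nyquist / 2 ** (scale - 1)


def min_series_length(scale: int, family: str = "db2") -> int:
    """Filter support of the equivalent MODWT filter at *scale*."""
    L = len(_SCALING_FILTERS[family])
    return (2**scale - 1) * (L - 1) + 1


def _circular_filter(v: np.ndarray, filt: np.ndarray, stride: int) -> np.ndarray:
    """Circularly convolve *v* with *filt* upsampled by *stride* (MODWT step)."""
    out = np.zeros_like(v)
    for tap, coeff in enumerate(filt):
        out += coeff * np.roll(v, tap * stride)
    return out


def modwt_scale(
    series: np.ndarray,
    scale: int,
    family: str = "db2",
    boundary: str = "reflection",
) -> np.ndarray:
    """Undecimated wavelet coefficients of *series* at a single scale.

    Runs the MODWT pyramid algorithm down to level ``scale`` and returns the
    wavelet coefficients of that level only; the output has the same length
    as the input.

    Parameters
    ----------
    series : 1-D array of finite values.
    scale : wavelet level j >= 1 (dyadic band ``scale_band(j, dt)``).
    family : wavelet family name ("haar", "db2", "db4"); "db2" is the
        4-tap Daubechies filter.
    boundary : "reflection" (default) extends the series with its mirror
        image before the circular transform; "periodic" uses the series
        as-is.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise DataFormatError("modwt_scale expects a 1-D series")
    if not np.all(np.isfinite(x)):
        raise DataFormatError("series contains non-finite values")
    if scale < 1:
        raise ConfigError("scale must be >= 1")
    wavelet_filters(family)  # validate family before the length check
    need = min_series_length(scale, family)
    if len(x) < need:
        raise DataFormatError(
            f"series of length {len(x)} too short for MODWT scale {scale} "
            f"({family}); minimum length is {need}"
        )
    if boundary == "reflection":
        v = np.concatenate([x, x[::-1]])
    elif boundary == "periodic":
        v = x.copy()
    else:
        raise ConfigError(f"unknown boundary rule {boundary!r}")

    g, h = wavelet_filters(family)
    w = v
    for j in range(1, scale + 1):
        stride = 2 ** (j - 1)
        w = _circular_filter(v, h, stride)
        v = _circular_filter(v, g, stride)
    return w[: len(x)]


def equivalent_modwt_filter(scale: int, family: str = "db2") -> np.ndarray:
    """Single equivalent filter whose circular convolution yields scale-j
    MODWT coefficients (used as an independent cross-check of the pyramid)."""
    g, h = wavelet_filters(family)
    filt = np.array([1.0])
    for j in range(1, scale):
        up = np.zeros(2 ** (j - 1) * (len(g) - 1) + 1)
        up[:: 2 ** (j - 1)] = g
        filt = np.convolve(filt, up)
    up = np.zeros(2 ** (scale - 1) * (len(h) - 1) + 1)
    up[:: 2 ** (scale - 1)] = h
    return np.convolve(filt, up)


def _check_segments(n: int, params: EstimatorParams) -> int:
    if n < params.nperseg + params.step:
        raise DataFormatError(
            f"series of length {n} yields fewer than 2 Welch segments "
            f"(nperseg={params.nperseg}, overlap={params.overlap}); "
            f"need at least {params.nperseg + params.step} samples"
        )
    return 1 + (n - params.nperseg) // params.step


def band_coherence(
    x: np.ndarray,
    y: np.ndarray,
    sampling_interval: float,
    band: tuple[float, float],
    params: EstimatorParams | None = None,
) -> float:
    """Band-averaged magnitude-squared coherence between two series.

    Welch cross-spectral estimation (Hann window, 50% overlap by default)
    followed by averaging the magnitude-squared coherence over all discrete
    frequencies inside ``band`` (inclusive endpoints). Returns a value in
    [0, 1].
    """
    params = params or EstimatorParams()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataFormatError(f"shape mismatch: {x.shape} vs {y.shape}")
    _check_segments(len(x), params)
    fs = 1.0 / sampling_interval
    f, cxy = signal.coherence(
        x, y, fs=fs, window=params.window, nperseg=params.nperseg, noverlap=params.noverlap
    )
    lo, hi = band
    mask = (f >= lo - 1e-12) & (f <= hi + 1e-12)
    if not mask.any():
        raise ConfigError(f"no estimator frequencies inside band {band}")
    value = float(np.mean(cxy[mask]))
    if not np.isfinite(value):
        raise NumericalError("coherence estimate is non-finite")
    return min(max(value, 0.0), 1.0)


def _welch_coherence_matrix(
    block: np.ndarray, sampling_interval: float, params: EstimatorParams
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Welch magnitude-squared coherence for a (regions, samples)
    block. Matches ``scipy.signal.coherence`` with constant detrending."""
    n_regions, n = block.shape
    k = _check_segments(n, params)
    win = signal.get_window(params.window, params.nperseg)
    starts = np.arange(k) * params.step
    # (regions, segments, nperseg)
    segs = np.stack([block[:, s : s + params.nperseg] for s in starts], axis=1)
    segs = segs - segs.mean(axis=2, keepdims=True)
    spec = np.fft.rfft(segs * win, axis=2)  # (regions, segments, freqs)
    freqs = np.fft.rfftfreq(params.nperseg, d=sampling_interval)
    # cross-spectra averaged over segments; scaling constants cancel
    pxy = np.einsum("isf,jsf->ijf", spec, np.conj(spec)) / k
    pxx = np.real(np.einsum("iif->if", pxy))
    denom = pxx[:, None, :] * pxx[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(pxy) ** 2 / denom
    return freqs, np.real(coh)


def build_tensor(
    ts: TimeSeriesSet,
    scale: int = 2,
    family: str = "db2",
    params: EstimatorParams | None = None,
    boundary: str = "reflection",
) -> AdjacencyTensor:
    """Assemble the multilayer functional network of a time-series set.

    For every block, each region's series is MODWT-decomposed at ``scale``
    and the pairwise band-averaged magnitude-squared coherence of the
    coefficient series forms that layer's weighted adjacency matrix
    (symmetric, zero diagonal, weights in [0, 1]).
    """
    params = params or EstimatorParams()
    if len(ts.blocks) < 2:
        raise ConfigError("build_tensor requires at least 2 blocks")
    band = scale_band(scale, ts.sampling_interval)
    N = ts.n_regions
    layers = []
    for bi, (start, end) in enumerate(ts.blocks):
        block = ts.values[:, start:end]
        coeffs = np.stack(
            [modwt_scale(block[i], scale, family, boundary) for i in range(N)]
        )
        freqs, coh = _welch_coherence_matrix(coeffs, ts.sampling_interval, params)
        mask = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12)
        layer = coh[:, :, mask].mean(axis=2)
        if not np.all(np.isfinite(layer)):
            bad = np.argwhere(~np.isfinite(layer))
            i, j = bad[0]
            raise NumericalError(
                f"non-finite coherence for region pair "
                f"({ts.region_labels[i]}, {ts.region_labels[j]}) in block {bi}"
            )
        np.fill_diagonal(layer, 0.0)
        layer = np.clip(0.5 * (layer + layer.T), 0.0, 1.0)
        layers.append(layer)
    block_types: Sequence[str]
    if ts.block_types is not None:
        block_types = ts.block_types
    else:
        block_types = [f"block_{i + 1:03d}" for i in range(len(ts.blocks))]
    meta = {
        "wavelet_family": family,
        "scale": scale,
        "band_hz": list(band),
        "boundary": boundary,
        "estimator": {
            "kind": "welch_msc",
            "nperseg": params.nperseg,
            "overlap": params.overlap,
            "window": params.window,
        },
        "sampling_interval_s": ts.sampling_interval,
    }
    return AdjacencyTensor(
        weights=np.stack(layers, axis=2),
        region_labels=list(ts.region_labels),
        layer_meta=list(block_types),
        meta=meta,
    )
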