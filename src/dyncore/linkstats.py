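"""Distribution moments and correlation machinery for the linking analyses.

Kurtosis is reported non-excess (a Gaussian gives 3) and moments use
population (1/n) estimators by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
from scipy import stats

from .errors import ConfigError, DataFormatError, DegenerateDataError

__all__ = [
    "MomentSummary",
    "CorrelationResult",
    "moments",
    "spearman",
    "pearson",
    "link_flexibility_learning",
    "link_flexibility_corescore",
]


@dataclass
class MomentSummary:
    """Standardized third (skewness) and fourth (non-excess kurtosis) moments."""

    skewness: float
    kurtosis: float


@dataclass
class CorrelationResult:
    method: str
    coefficient: float
    p_value: float
    n: int


def moments(values: np.ndarray, bias: bool = True) -> MomentSummary:
    """Skewness and non-excess kurtosis of a sample.

    bias=True (default) uses population 1/n central moments; bias=False
    applies the standard small-sample corrections.
    """
    x = np.asarray(values, dtype=float)
    if len(np.unique(x)) < 3:
        raise DegenerateDataError("moments need at least 3 distinct values")
    if x.var() == 0:
        raise DegenerateDataError("zero-variance sample has undefined moments")
    skew = float(stats.skew(x, bias=bias))
    kurt = float(stats.kurtosis(x, fisher=False, bias=bias))
    return MomentSummary(skewness=skew, kurtosis=kurt)


def _check_pair(x: np.ndarray, y: np.ndarray, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataFormatError(f"paired vectors must match; got {x.shape} and {y.shape}")
    if len(x) < min_n:
        raise DataFormatError(f"need at least {min_n} pairs; got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for a constant vector")
    return x, y


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    return float(np.sum(rxc * ryc) / np.sqrt(np.sum(rxc**2) * np.sum(ryc**2)))


def spearman(
    x: np.ndarray,
    y: np.ndarray,
    p_method: str = "asymptotic",
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    p_method: "asymptotic" (scipy t-approximation), "exact" (enumeration of
    all orderings; n <= 9 only) or "permutation" (Monte Carlo with
    ``n_permutations`` draws). Two-sided throughout.
    """
    x, y = _check_pair(x, y, 4)
    rho, p_asym = stats.spearmanr(x, y)
    rho = float(rho)
    n = len(x)
    if p_method == "asymptotic":
        p = float(p_asym)
    elif p_method == "exact":
        if n > 9:
            raise ConfigError("exact enumeration limited to n <= 9")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        count = 0
        total = 0
        for perm in _iter_permutations(range(n)):
            r = _rank_corr(rx, ry[list(perm)])
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = count / total
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        hits = 0
        for _ in range(n_permutations):
            r = _rank_corr(rx, rng.permutation(ry))
            hits += abs(r) >= abs(rho) - 1e-12
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise ConfigError(f"unknown p_method {p_method!r}")
    return CorrelationResult(method="spearman", coefficient=rho, p_value=p, n=n)


def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Product-moment correlation with a two-sided p-value."""
    x, y = _check_pair(x, y, 3)
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        method="pearson",
        coefficient=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(x),
    )


def link_flexibility_learning(
    flexibility_per_subject: list[np.ndarray] | np.ndarray,
    kappas: np.ndarray,
    p_method: str = "asymptotic",
) -> dict[str, CorrelationResult]:
    """Spearman correlations of flexibility-distribution moments with kappa.

    For each subject, skewness and kurtosis of the regional flexibility
    distribution are computed and rank-correlated with the subject's learning
    parameter. Flexibility should be estimated from data that precedes the
    behavioral window so the correlations retain their predictive framing.
    """
    kappas = np.asarray(kappas, dtype=float)
    if len(flexibility_per_subject) != len(kappas):
        raise DataFormatError("one flexibility vector per subject is required")
    if len(kappas) < 4:
        raise DataFormatError("need at least 4 subjects")
    skews, kurts = [], []
    for s, flex in enumerate(flexibility_per_subject):
        try:
            m = moments(np.asarray(flex, dtype=float))
        except DegenerateDataError as exc:
            raise DegenerateDataError(f"subject {s}: {exc}") from exc
        skews.append(m.skewness)
        kurts.append(m.kurtosis)
    return {
        "skewness_vs_kappa": spearman(np.array(skews), kappas, p_method=p_method),
        "kurtosis_vs_kappa": spearman(np.array(kurts), kappas, p_method=p_method),
    }


def link_flexibility_corescore(
    flexibility_per_region: np.ndarray,
    core_score_per_region: np.ndarray,
) -> CorrelationResult:
    """Pearson correlation across regions between flexibility and mean
    geometrical core score."""
    return pearson(flexibility_per_region, core_score_per_region)
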