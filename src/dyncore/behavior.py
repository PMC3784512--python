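"""Movement-time extraction and robust exponential learning-curve fitting.

Movement time (MT) for a trial is the interval between the first and last
key presses. Learning is summarized per sequence by fitting

    MT(t) = A * exp(kappa * t) + B,    A > 0, B > 0,

to the per-trial MT series by least absolute residuals (LAR). kappa is the
learning parameter: negative values indicate decreasing MT, i.e. learning.
A + B estimates starting speed and B the fastest attainable speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConfigError, DataFormatError

__all__ = [
    "LearningFit",
    "movement_time",
    "fit_learning_curve",
    "fit_subject",
    "cumulative_practice_trials",
    "practice_schedule_table",
]

#: trials of every sequence during each scanning session
TRIALS_PER_SCAN = 50
#: per-sequence trials per home training session, by training intensity
HOME_TRIALS = {"EXT": 64, "MOD": 10, "MIN": 1}
#: home training sessions between consecutive scanning sessions
HOME_SESSIONS_PER_INTERVAL = 10


@dataclass
class LearningFit:
    """Parameters of the exponential-plus-constant learning curve."""

    kappa: float
    A: float
    B: float
    loss: float
    converged: bool
    degenerate: bool = False
    meta: dict = field(default_factory=dict)


def movement_time(first_press: float, last_press: float) -> float:
    """MT = last_press - first_press (seconds); raises on reversed order."""
    if last_press < first_press:
        raise DataFormatError(
            f"last press ({last_press}) precedes first press ({first_press})"
        )
    return float(last_press - first_press)


def _initial_kappa(t: np.ndarray, mt: np.ndarray) -> float:
    """Log-linear seed: slope of log(MT - ~asymptote) against trial index."""
    b0 = 0.9 * mt.min()
    y = np.log(np.maximum(mt - b0, 1e-9))
    slope = np.polyfit(t, y, 1)[0]
    if not np.isfinite(slope) or slope == 0:
        return -0.01
    return float(slope)


def _loss(params: np.ndarray, t: np.ndarray, mt: np.ndarray, kind: str) -> float:
    kappa, log_a, log_b = params
    pred = np.exp(log_a) * np.exp(np.clip(kappa * t, -500, 50)) + np.exp(log_b)
    resid = mt - pred
    if kind == "l1":
        return float(np.sum(np.abs(resid)))
    return float(np.sum(resid**2))


def fit_learning_curve(
    trials: pd.DataFrame | np.ndarray,
    loss: str = "l1",
    t_column: str = "trial",
    mt_column: str = "MT_s",
    n_starts: int = 8,
) -> LearningFit:
    """Fit MT(t) = A exp(kappa t) + B by least absolute residuals.

    Parameters
    ----------
    trials : DataFrame with trial-index and MT columns, or an (n, 2) array
        of (t, MT) rows. At least 4 trials with positive MT are required.
    loss : "l1" (LAR, default) or "l2" (least squares, for comparison).
    n_starts : deterministic multi-start count; kappa starting points form a
        grid around a log-linear initial estimate.

    Degenerate inputs (constant MT) are fitted but flagged.
    """
    if loss not in ("l1", "l2"):
        raise ConfigError(f"unknown loss {loss!r}")
    if isinstance(trials, pd.DataFrame):
        t = trials[t_column].to_numpy(dtype=float)
        mt = trials[mt_column].to_numpy(dtype=float)
    else:
        arr = np.asarray(trials, dtype=float)
        t, mt = arr[:, 0], arr[:, 1]
    if len(t) < 4:
        raise DataFormatError(f"need at least 4 trials to fit 3 parameters; got {len(t)}")
    if np.any(mt <= 0):
        raise DataFormatError("movement times must be positive")
    if np.any(np.diff(t) <= 0):
        raise DataFormatError("trial indices must be strictly increasing")

    degenerate = np.ptp(mt) < 1e-12
    k0 = _initial_kappa(t, mt)
    spread = mt.max() - mt.min()
    a0 = max(spread, 1e-3)
    b0 = max(0.9 * mt.min(), 1e-6)
    kappa_grid = np.array([k0 * f for f in (0.25, 0.5, 1.0, 2.0)] + [-0.2, -0.05, -0.01, 0.01])
    starts = [np.array([k, np.log(a0), np.log(b0)]) for k in kappa_grid[:n_starts]]

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            _loss,
            x0,
            args=(t, mt, loss),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    kappa, log_a, log_b = best.x
    return LearningFit(
        kappa=float(kappa),
        A=float(np.exp(log_a)),
        B=float(np.exp(log_b)),
        loss=float(best.fun),
        converged=any_converged,
        degenerate=bool(degenerate),
        meta={"loss_kind": loss, "n_starts": len(starts), "n_trials": len(t)},
    )


def fit_subject(
    table: pd.DataFrame,
    loss: str = "l1",
    sequence_column: str = "sequence",
) -> tuple[float, dict[str, LearningFit]]:
    """Fit each sequence separately and average kappa over sequences."""
    fits: dict[str, LearningFit] = {}
    for seq, group in table.groupby(sequence_column, sort=True):
        fits[str(seq)] = fit_learning_curve(group, loss=loss)
    if not fits:
        raise DataFormatError("empty trial table")
    kappa = float(np.mean([f.kappa for f in fits.values()]))
    return kappa, fits


def cumulative_practice_trials(sequence_type: str, session: int) -> int:
    """Cumulative practiced trials per sequence of a type after a scanning
    session, from the experimental design: 50 trials per sequence per scan,
    plus 10 home sessions (64/10/1 trials per EXT/MOD/MIN sequence each)
    between consecutive scans."""
    if sequence_type not in HOME_TRIALS:
        raise ConfigError(f"unknown sequence type {sequence_type!r}")
    if not 1 <= session <= 4:
        raise ConfigError("session must be in 1..4")
    home = HOME_TRIALS[sequence_type] * HOME_SESSIONS_PER_INTERVAL * (session - 1)
    return TRIALS_PER_SCAN * session + home


def practice_schedule_table() -> pd.DataFrame:
    """Cumulative trials per sequence type and scanning session (4 columns)."""
    rows = {
        st: [cumulative_practice_trials(st, s) for s in range(1, 5)]
        for st in ("MIN", "MOD", "EXT")
    }
    return pd.DataFrame(rows, index=[f"Session {s}" for s in range(1, 5)]).T
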