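"""Output analysis: burn-in detection, cross-run summaries, and PRCC.

Homeostasis (the end of the initialization transient) is declared on the
series ``s(t) = median(t) + IQR(t)`` built across replicate runs: the
stabilization day is the first day after which every sliding window of
``window`` days stays within a relative tolerance of its own mean.  A series
that never offers a stable suffix yields ``None``.

PRCC (partial rank correlation coefficient) measures the monotone influence
of a parameter X on an output Y after removing the rank-linear influence of
controlling parameters: all variables are rank-transformed, X and Y are each
regressed on the controls, and the Pearson correlation of the two residual
vectors is returned.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "detect_homeostasis",
    "rolling_mean",
    "median_iqr",
    "prcc",
]


def median_iqr(values: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Across-run median and interquartile range."""
    med = np.median(values, axis=axis)
    q1, q3 = np.percentile(values, [25, 75], axis=axis)
    return med, q3 - q1


def rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean with shrinking edge windows (length preserved)."""
    import pandas as pd

    return pd.Series(np.asarray(x, dtype=float)).rolling(
        window, center=True, min_periods=1
    ).mean().to_numpy()


def detect_homeostasis(
    median: np.ndarray,
    iqr: np.ndarray | None = None,
    window: int = 180,
    tol: float = 0.05,
    eps: float = 1e-9,
) -> int | None:
    """First day from which ``median + IQR`` stays stable to the end.

    A window ``[t, t + window)`` is stable when ``max |s - mean(s)| <
    tol * max(mean(s), eps)``.  The stabilization day is the first day such
    that every subsequent full window is stable; ``None`` when no such day
    leaves at least one full window.  A constant (or all-zero) series
    stabilizes on day 0.
    """
    s = np.asarray(median, dtype=float)
    if iqr is not None:
        s = s + np.asarray(iqr, dtype=float)
    T = len(s)
    if T < window:
        raise ValueError(f"need at least window={window} days of data, got {T}")
    win = np.lib.stride_tricks.sliding_window_view(s, window)
    means = win.mean(axis=1)
    dev = np.abs(win - means[:, None]).max(axis=1)
    stable = dev < tol * np.maximum(means, eps)
    if stable.all():
        return 0
    last_unstable = int(np.flatnonzero(~stable).max())
    first = last_unstable + 1
    return first if first < len(stable) else None


def prcc(
    x: np.ndarray, y: np.ndarray, controls: np.ndarray
) -> float:
    """Partial rank correlation of ``x`` and ``y`` given ``controls``.

    ``controls`` has one column per controlling variable.  Requires at least
    10 joint samples; a constant ``x`` or ``y`` has no defined ranks and is
    signalled as an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.atleast_2d(np.asarray(controls, dtype=float))
    if C.shape[0] != len(x):
        C = C.T
    n = len(x)
    if n < 10:
        raise ValueError(f"PRCC needs at least 10 samples, got {n}")
    if len(y) != n or C.shape[0] != n:
        raise ValueError("x, y and controls must have matching sample counts")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("PRCC is undefined for a constant variable")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = np.column_stack([stats.rankdata(C[:, j]) for j in range(C.shape[1])])
    design = np.column_stack([np.ones(n), rc])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    denom = np.sqrt((res_x**2).sum() * (res_y**2).sum())
    if denom == 0:
        raise ValueError("PRCC is undefined: residuals are constant")
    return float((res_x * res_y).sum() / denom)
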