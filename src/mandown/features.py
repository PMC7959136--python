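"""Windowed statistics and extreme-value signals.

The detection variables are sliding-window extrema of windowed statistics of
the feature signals: for fall detection the minimum/maximum of the windowed
mean, for immobility the minimum of the windowed log10-variance, and for the
down state the maximum of the windowed mean tilt.

Both passes are causal-forward with stride one sample: the statistic at t is
taken over samples ``[t, t+tau)`` and the extremum at t is taken over the
statistic values starting in ``[t, t+tau)``.  Each pass shortens the series
by ``window - 1`` samples, so only full windows contribute; millisecond
windows convert to samples with round-half-up.

Variance is the unbiased sample variance and is floored at ``1e-12`` before
the log10 so that perfectly still synthetic segments stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import EmptyInputError, WindowTooLongError

#: Floor applied to variances before log10 (units: g^2 or rad^2/s^2).
VARIANCE_FLOOR = 1e-12

MEAN = "mean"
VARIANCE = "variance"
LOG_VARIANCE = "log_variance"

_STATISTICS = (MEAN, VARIANCE, LOG_VARIANCE)
_EXTREMA = ("min", "max")


def window_samples(tau_ms: float, fs: float, minimum: int = 1) -> int:
    """Convert a window size in ms to samples (round half up)."""
    if tau_ms <= 0:
        raise ValueError("window size must be positive")
    n = int(np.floor(tau_ms * fs / 1000.0 + 0.5))
    if n < minimum:
        raise ValueError(
            f"window of {tau_ms} ms at {fs} Hz spans {n} sample(s); "
            f"need at least {minimum}"
        )
    return n


def windowed_statistic(s: np.ndarray, tau_ms: float, statistic: str,
                       fs: float) -> np.ndarray:
    """Sliding-window mean or (log10-)variance over ``[t, t+tau)``.

    Output length is ``len(s) - window + 1``; variance windows must span at
    least two samples.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if s.size == 0:
        raise EmptyInputError("empty series")
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    n = window_samples(tau_ms, fs, minimum=1 if statistic == MEAN else 2)
    if s.size < n:
        raise WindowTooLongError(
            f"series of {s.size} samples is shorter than the "
            f"{tau_ms} ms window ({n} samples)"
        )
    windows = sliding_window_view(s, n)
    if statistic == MEAN:
        return windows.mean(axis=-1)
    var = windows.var(axis=-1, ddof=1)
    if statistic == VARIANCE:
        return var
    return np.log10(np.maximum(var, VARIANCE_FLOOR))


@dataclass
class ExtremeValueSignal:
    """Sliding extremum of a windowed statistic of a feature signal.

    ``values[t]`` summarises raw samples ``[t, t + span)`` where
    ``span = 2 * window - 1`` samples: the statistic window and the
    extremum window share the same size tau.
    """

    source: str
    statistic: str
    extremum: str
    tau_ms: float
    fs: float
    values: np.ndarray
    span: int

    def __post_init__(self):
        if self.extremum not in _EXTREMA:
            raise ValueError(f"extremum must be one of {_EXTREMA}")

    def __len__(self) -> int:
        return len(self.values)

    def peak(self) -> float:
        """The series-level extreme value (min for min-signals, max for
        max-signals) used when characterising scenario occurrences."""
        return float(self.values.min() if self.extremum == "min"
                     else self.values.max())


def extreme_value_signal(s: np.ndarray, tau_ms: float, statistic: str,
                         extremum: str, fs: float,
                         source: str = "") -> ExtremeValueSignal:
    """Build the extreme-value signal of a feature series.

    The statistic (mean, or log10 of the unbiased variance) is evaluated on
    windows ``[t, t+tau)`` and the requested extremum is then taken over a
    window of the same length on the statistic series.
    """
    if extremum not in _EXTREMA:
        raise ValueError(f"extremum must be one of {_EXTREMA}")
    stat = windowed_statistic(s, tau_ms, statistic, fs)
    n = window_samples(tau_ms, fs)
    if stat.size < n:
        raise WindowTooLongError(
            f"statistic series of {stat.size} samples is shorter than the "
            f"{tau_ms} ms extremum window ({n} samples)"
        )
    windows = sliding_window_view(stat, n)
    values = windows.min(axis=-1) if extremum == "min" else windows.max(axis=-1)
    stat_n = window_samples(tau_ms, fs, minimum=1 if statistic == MEAN else 2)
    return ExtremeValueSignal(
        source=source,
        statistic=statistic,
        extremum=extremum,
        tau_ms=tau_ms,
        fs=fs,
        values=values,
        span=stat_n + n - 1,
    )
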