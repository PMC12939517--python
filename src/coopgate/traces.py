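"""Idealized current traces, dwell-time series and classical cluster metrics.

A *current trace* is the integer number of simultaneously open channels per
RC time step.  Its run-length encoding is the *dwell-time series*: pairs of
(conduction level, duration) for each maximal constant-level run.  The
classical metrics are I/Imax (time-averaged current over the maximum
possible, equal to the mean per-channel open probability) and NPo (mean
number of open channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidParameterError
from .gating import ModelParams, simulate
from .seeding import derive_seed

__all__ = [
    "CurrentTrace",
    "DwellTimeSeries",
    "extract_dwells",
    "relative_current",
    "npo",
    "activation_curve",
    "half_activation_drift",
]


@dataclass
class CurrentTrace:
    """Integer open-channel counts per RC time step."""

    values: np.ndarray
    n_channels: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1 or self.values.size < 1:
            raise InvalidParameterError("trace must be a non-empty 1-D sequence")
        if self.n_channels < 1:
            raise InvalidParameterError("n_channels must be >= 1")
        vmin, vmax = int(self.values.min()), int(self.values.max())
        if vmin < 0 or vmax > self.n_channels:
            raise InvalidParameterError(
                f"trace values must lie in [0, {self.n_channels}]; "
                f"found range [{vmin}, {vmax}]"
            )

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class DwellTimeSeries:
    """Run-length records: conduction level and duration of each dwell.

    Durations are in RC time units (integer step counts); consecutive
    levels always differ because runs are maximal.
    """

    levels: np.ndarray
    durations: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)
        self.durations = np.asarray(self.durations, dtype=np.int64)
        if self.levels.shape != self.durations.shape or self.levels.ndim != 1:
            raise InvalidParameterError("levels and durations must be equal-length 1-D")
        if self.levels.size and self.durations.min() < 1:
            raise InvalidParameterError("durations must be positive integers")
        if self.levels.size > 1 and np.any(np.diff(self.levels) == 0):
            raise InvalidParameterError("consecutive dwell levels must differ")

    def __len__(self) -> int:
        return int(self.levels.size)

    def decode(self) -> np.ndarray:
        """Reconstruct the level-per-step sequence (inverse of extraction)."""
        return np.repeat(self.levels, self.durations)


def extract_dwells(trace: CurrentTrace | np.ndarray) -> DwellTimeSeries:
    """Run-length encode a current trace into its dwell-time series."""
    if isinstance(trace, CurrentTrace):
        values, meta = trace.values, dict(trace.meta)
    else:
        values, meta = np.asarray(trace), {}
    if values.size == 0:
        raise InvalidParameterError("cannot extract dwells from an empty trace")
    v = values.astype(np.int64)
    changes = np.flatnonzero(np.diff(v))
    starts = np.concatenate(([0], changes + 1))
    ends = np.concatenate((changes + 1, [v.size]))
    return DwellTimeSeries(levels=v[starts], durations=ends - starts, meta=meta)


def relative_current(trace: CurrentTrace) -> float:
    """I/Imax: total current over the maximal possible current.

    Equals the mean per-channel open probability.
    """
    return float(trace.values.sum()) / (trace.n_channels * len(trace))


def npo(trace: CurrentTrace) -> float:
    """Mean number of simultaneously open channels."""
    return float(np.mean(trace.values))


def activation_curve(params_template: ModelParams,
                     drift_grid: Sequence[float],
                     replicates: int = 1,
                     master_seed: int | None = None) -> pd.DataFrame:
    """Mean I/Imax (with standard error) over a grid of drift values.

    Each (drift, replicate) pair runs one independent simulation with a
    seed derived deterministically from ``master_seed`` (defaulting to the
    template's seed).  With a single replicate the ``se`` column is NaN.
    """
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    master = params_template.seed if master_seed is None else master_seed
    grid = [float(d) for d in drift_grid]
    # validate the whole grid before running anything
    for d in grid:
        params_template.with_(drift=d)
    rows = []
    for d in grid:
        vals = []
        for rep in range(replicates):
            seed = derive_seed(master, "activation", round(d, 6), rep)
            p = params_template.with_(drift=d, seed=seed)
            trace, _ = simulate(p)
            vals.append(relative_current(trace))
        vals = np.asarray(vals)
        se = (vals.std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else np.nan
        rows.append({"drift": d, "mean": vals.mean(), "se": se, "n": replicates})
    return pd.DataFrame(rows)


def half_activation_drift(drifts: Sequence[float], means: Sequence[float],
                          level: float = 0.5) -> float:
    """Drift at which the activation curve crosses ``level``.

    Linear interpolation between the first pair of neighbouring grid points
    that bracket the level; the curve is assumed nondecreasing up to noise.
    """
    x = np.asarray(drifts, dtype=float)
    y = np.asarray(means, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    for i in range(x.size - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            return float(x[i] + (level - y0) * (x[i + 1] - x[i]) / (y1 - y0))
    raise InsufficientDataError(
        f"activation curve does not cross {level} on the supplied grid"
    )
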