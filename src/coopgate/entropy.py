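"""Shannon entropy and Sample Entropy of idealized multi-channel records.

Shannon entropy is computed in bits from one of two histograms used
throughout the study: the 7-bin current-level histogram (levels 0..6, for
clusters of up to six channels) or a 100-bin logarithmically spaced
histogram of dwell durations whose range must span the *whole comparison
set* of series, so that entropies of different series are comparable.

Sample Entropy (nats) quantifies temporal irregularity of the dwell-time
sequence: the negative log of the conditional probability that templates
similar for m points (Chebyshev distance < r) remain similar for m+1
points.  The similarity radius is conventionally 20% of the series'
standard deviation.  Long series are analysed in consecutive 5000-point
windows, with r taken per window by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist

from . import _kernels
from .errors import (InsufficientDataError, InvalidParameterError,
                     InvalidRadiusError, UnsupportedCapacityError)
from .traces import CurrentTrace, DwellTimeSeries

__all__ = [
    "EntropyResult",
    "shannon_entropy",
    "current_histogram",
    "log_dwell_bins",
    "log_dwell_histogram",
    "dwell_shannon_entropy",
    "sample_entropy",
    "sample_entropy_bruteforce",
    "windowed_sampen",
]

N_CURRENT_BINS = 7        # levels 0..6, clusters of up to six channels
N_DWELL_BINS = 100


@dataclass
class EntropyResult:
    """An entropy estimate with uncertainty and provenance.

    ``value`` is in bits for Shannon entropy, nats for Sample Entropy.
    ``se`` and ``n_windows`` are present for windowed estimates.
    """

    value: float
    se: float | None = None
    n_windows: int | None = None
    n_undefined: int = 0
    spec: dict = field(default_factory=dict)


def shannon_entropy(probabilities) -> float:
    """Shannon entropy -sum p log2 p of a normalized probability vector."""
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < -1e-12):
        raise InvalidParameterError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise InvalidParameterError(
            f"probabilities must sum to 1 (got {p.sum():.12g})"
        )
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _trace_values(trace) -> np.ndarray:
    if isinstance(trace, CurrentTrace):
        return trace.values
    return np.asarray(trace)


def current_histogram(trace) -> np.ndarray:
    """Relative frequency of each current level 0..6 (length-7 vector)."""
    v = _trace_values(trace).astype(np.int64)
    if v.size == 0:
        raise InvalidParameterError("empty trace")
    if v.min() < 0 or v.max() >= N_CURRENT_BINS:
        raise UnsupportedCapacityError(
            f"current levels must lie in [0, {N_CURRENT_BINS - 1}]; "
            f"found {int(v.min())}..{int(v.max())}"
        )
    counts = np.bincount(v, minlength=N_CURRENT_BINS)
    return counts / v.size


def _durations(series) -> np.ndarray:
    if isinstance(series, DwellTimeSeries):
        return series.durations
    return np.asarray(series)


def log_dwell_bins(dmin: float, dmax: float, n_bins: int = N_DWELL_BINS) -> np.ndarray:
    """Geometrically spaced bin edges over [dmin, dmax] (n_bins + 1 edges)."""
    if n_bins < 2:
        raise InvalidParameterError("n_bins must be >= 2")
    if dmin < 1 or dmin >= dmax:
        raise InvalidParameterError("need 1 <= dmin < dmax for log-spaced bins")
    return np.geomspace(dmin, dmax, n_bins + 1)


def log_dwell_histogram(series, n_bins: int = N_DWELL_BINS,
                        drange: tuple[float, float] | None = None) -> np.ndarray:
    """Normalized histogram of dwell durations on log-spaced bins.

    ``drange`` must span the global minimum..maximum over *all* series being
    compared; it defaults to this series' own range.  Bins are half-open
    [low, high) with the final bin closed (numpy convention).  A degenerate
    range collapses to a single bin with a warning.
    """
    d = _durations(series).astype(float)
    if d.size == 0:
        raise InvalidParameterError("empty dwell series")
    if d.min() < 1:
        raise InvalidParameterError("durations must be >= 1 RC time unit")
    lo, hi = (float(d.min()), float(d.max())) if drange is None else map(float, drange)
    if lo == hi:
        warnings.warn("degenerate dwell range (min == max): single-bin histogram",
                      stacklevel=2)
        return np.array([1.0])
    counts, _ = np.histogram(d, bins=log_dwell_bins(lo, hi, n_bins))
    n_in = counts.sum()
    if n_in < d.size:
        raise InvalidParameterError(
            "durations fall outside the supplied range; the range must cover "
            "the global minimum and maximum of the comparison set"
        )
    return counts / n_in


def dwell_shannon_entropy(series, n_bins: int = N_DWELL_BINS,
                          drange: tuple[float, float] | None = None) -> float:
    """Shannon entropy (bits) of the log-binned dwell-duration histogram."""
    return shannon_entropy(log_dwell_histogram(series, n_bins, drange))


def _check_sampen_args(x: np.ndarray, m: int, r: float) -> None:
    if m < 1:
        raise InvalidParameterError("template length m must be >= 1")
    if r <= 0:
        raise InvalidRadiusError(
            f"similarity radius must be positive (got r={r:g}); a constant "
            "series has zero standard deviation and no valid radius"
        )
    if x.size <= m + 1:
        raise InsufficientDataError(
            f"series length {x.size} too short for m={m} (need > m+1 points)"
        )


def sample_entropy(series, m: int = 2, r: float | None = None,
                   r_fraction: float = 0.2) -> float:
    """Sample Entropy SampEn(m, r) of a numeric sequence, in nats.

    Template pairs (i < j) are drawn from the common index range
    0..N-m-1 for both template lengths; self-matches are excluded; the
    Chebyshev distance must be strictly below r.  If ``r`` is omitted it is
    ``r_fraction`` times the series' standard deviation.  Returns NaN when
    no template pair matches at length m+1 (entropy undefined).
    """
    x = _durations(series).astype(np.float64)
    if r is None:
        r = r_fraction * float(x.std())
    _check_sampen_args(x, m, float(r))
    a, b = _kernels.sampen_match_counts(x, m, float(r))
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def sample_entropy_bruteforce(series, m: int = 2, r: float | None = None,
                              r_fraction: float = 0.2) -> float:
    """Reference SampEn via explicit pairwise Chebyshev distances.

    Independent of the compiled kernel: builds the template embeddings and
    evaluates all pairwise distances with scipy.  Identical conventions
    (common index range, strict inequality, self-match exclusion).
    """
    x = _durations(series).astype(np.float64)
    if r is None:
        r = r_fraction * float(x.std())
    _check_sampen_args(x, m, float(r))
    emb_m1 = sliding_window_view(x, m + 1)          # indices 0..N-m-1
    emb_m = sliding_window_view(x, m)[: emb_m1.shape[0]]
    b = int(np.count_nonzero(pdist(emb_m, metric="chebyshev") < r))
    a = int(np.count_nonzero(pdist(emb_m1, metric="chebyshev") < r))
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def windowed_sampen(series, window: int = 5000, m: int = 2,
                    r_fraction: float = 0.2, r: float | None = None,
                    error: str = "sem") -> EntropyResult:
    """Mean Sample Entropy over consecutive non-overlapping windows.

    Each complete window of ``window`` points is analysed with
    ``r = r_fraction * (that window's SD)`` unless a global ``r`` is
    supplied.  Windows with undefined entropy are dropped and counted.
    ``error`` selects the across-window uncertainty: "sem" (default) or
    "sd".  With a single window the uncertainty is None.
    """
    if error not in ("sem", "sd"):
        raise InvalidParameterError("error must be 'sem' or 'sd'")
    x = _durations(series).astype(np.float64)
    if window < m + 2:
        raise InvalidParameterError("window too short for the template length")
    n_win = x.size // window
    if n_win < 1:
        raise InsufficientDataError(
            f"series of length {x.size} holds no complete {window}-point window"
        )
    values = []
    n_undefined = 0
    for w in range(n_win):
        seg = x[w * window:(w + 1) * window]
        rw = r if r is not None else r_fraction * float(seg.std())
        v = sample_entropy(seg, m=m, r=rw)
        if np.isfinite(v):
            values.append(v)
        else:
            n_undefined += 1
    if not values:
        raise InsufficientDataError("Sample Entropy undefined in every window")
    vals = np.asarray(values)
    if vals.size > 1:
        sd = float(vals.std(ddof=1))
        se = sd / np.sqrt(vals.size) if error == "sem" else sd
    else:
        se = None
    return EntropyResult(
        value=float(vals.mean()), se=se, n_windows=int(vals.size),
        n_undefined=n_undefined,
        spec={"metric": "sampen", "m": m, "r_fraction": r_fraction,
              "r": r, "window": window, "error": error},
    )
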