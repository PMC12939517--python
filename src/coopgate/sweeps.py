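"""Parameter sweeps over cluster size, drift and cooperation mode.

Drives the simulation experiments of the study: for each grid point and
cooperation mode a number of replicate simulations is run with
deterministically derived seeds, the selected metric (I/Imax, NPo, Shannon
entropy of currents or dwell times, Sample Entropy of dwell times) is
aggregated with its uncertainty, and the resulting trend can be fitted
with a low-degree polynomial.  Includes the entropy-based diagnostic that
labels a Shannon-current-vs-Nch sweep as cooperative or not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .entropy import (current_histogram, dwell_shannon_entropy,
                      sample_entropy, shannon_entropy)
from .errors import InsufficientDataError, InvalidParameterError
from .gating import ModelParams, simulate
from .seeding import derive_seed
from .traces import extract_dwells, npo, relative_current

__all__ = [
    "CooperationMode",
    "COOPERATION_MODES",
    "get_mode",
    "SweepResult",
    "PolynomialFit",
    "nch_sweep",
    "drift_sweep",
    "fit_polynomial",
    "fitted_maximum",
    "cooperation_signature",
    "SignatureResult",
    "METRICS",
]


@dataclass(frozen=True)
class CooperationMode:
    """A named cooperation setting: label and per-open-neighbor drift."""

    label: str
    coop_drift: float


#: The four canonical modes.  Negative coop_drift favours opening
#: (positive cooperation); positive favours closure (negative cooperation).
COOPERATION_MODES = {
    "none": CooperationMode("none", 0.0),
    "negative": CooperationMode("negative", +0.1),
    "weak-positive": CooperationMode("weak-positive", -0.05),
    "strong-positive": CooperationMode("strong-positive", -0.1),
}

METRICS = ("i_imax", "npo", "shannon_current", "shannon_dwell", "sampen")


def get_mode(mode) -> CooperationMode:
    if isinstance(mode, CooperationMode):
        return mode
    try:
        return COOPERATION_MODES[mode]
    except KeyError:
        raise InvalidParameterError(
            f"unknown cooperation mode {mode!r}; "
            f"choose from {sorted(COOPERATION_MODES)}"
        ) from None


@dataclass
class PolynomialFit:
    """Least-squares polynomial fit: coefficients highest-degree first."""

    coefficients: np.ndarray
    degree: int
    residual: float
    stationary_points: list[float]


@dataclass
class SweepResult:
    """Aggregated sweep table plus optional per-mode fits.

    ``table`` is long-format with columns
    (axis value, mode, metric, mean, se, n).
    """

    axis: str
    metric: str
    table: pd.DataFrame
    fits: dict = field(default_factory=dict)
    max_locations: dict = field(default_factory=dict)


def _run_grid(axis: str, grid, modes, params_template: ModelParams,
              replicates: int, master_seed: int, fixed: dict):
    """Simulate every (axis value, mode, replicate) and collect raw results.

    Returns a dict keyed by (axis value, mode label, replicate) holding the
    per-run scalars and the dwell-duration array.  Each replicate's seed is
    a pure function of (master seed, axis value, mode label, replicate).
    """
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    mode_objs = [get_mode(mo) for mo in modes]
    # validate the complete grid before any simulation
    points = []
    for g in grid:
        for mode in mode_objs:
            kwargs = dict(fixed)
            kwargs[axis] = g
            kwargs["coop_drift"] = mode.coop_drift
            params_template.with_(**kwargs)      # raises if invalid
            points.append((g, mode))
    runs = {}
    for g, mode in points:
        for rep in range(replicates):
            seed = derive_seed(master_seed, "sweep", axis, round(float(g), 6),
                               mode.label, rep)
            kwargs = dict(fixed)
            kwargs[axis] = g
            kwargs.update(coop_drift=mode.coop_drift, seed=seed)
            p = params_template.with_(**kwargs)
            trace, _ = simulate(p)
            dwells = extract_dwells(trace)
            runs[(g, mode.label, rep)] = {
                "i_imax": relative_current(trace),
                "npo": npo(trace),
                "current_hist": current_histogram(trace),
                "durations": dwells.durations,
            }
    return runs, [m.label for m in mode_objs]


def _aggregate(runs, axis, grid, mode_labels, replicates, metric,
               m: int, window: int, r_fraction: float, n_bins: int):
    """Reduce raw runs to (mean, se, n) rows for the selected metric."""
    if metric not in METRICS:
        raise InvalidParameterError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "shannon_dwell":
        alldur = np.concatenate([r["durations"] for r in runs.values()])
        drange = (float(alldur.min()), float(alldur.max()))
    rows = []
    for g in grid:
        for label in mode_labels:
            reps = [runs[(g, label, rep)] for rep in range(replicates)]
            if metric == "sampen":
                # pool complete windows across replicates
                vals = []
                for r in reps:
                    x = r["durations"].astype(float)
                    for w in range(x.size // window):
                        seg = x[w * window:(w + 1) * window]
                        v = sample_entropy(seg, m=m, r=r_fraction * seg.std())
                        if np.isfinite(v):
                            vals.append(v)
                if not vals:
                    raise InsufficientDataError(
                        f"no complete {window}-point window at {axis}={g}, "
                        f"mode={label}"
                    )
            else:
                per_rep = {
                    "i_imax": lambda r: r["i_imax"],
                    "npo": lambda r: r["npo"],
                    "shannon_current": lambda r: shannon_entropy(r["current_hist"]),
                    "shannon_dwell": lambda r: dwell_shannon_entropy(
                        r["durations"], n_bins=n_bins, drange=drange),
                }[metric]
                vals = [per_rep(r) for r in reps]
            vals = np.asarray(vals, dtype=float)
            se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
            rows.append({axis: g, "mode": label, "metric": metric,
                         "mean": vals.mean(), "se": se, "n": vals.size})
    return pd.DataFrame(rows)


def nch_sweep(modes: Iterable, n_channels_grid: Sequence[int] = range(1, 7),
              metric: str = "shannon_current",
              params_template: ModelParams | None = None,
              replicates: int = 3, master_seed: int = 0,
              m: int = 2, window: int = 5000, r_fraction: float = 0.2,
              n_bins: int = 100, fit_degree: int | None = None) -> SweepResult:
    """Sweep the cluster size at fixed drift (default: half-activation).

    One simulation per (Nch, mode, replicate); Sample Entropy pools 5000
    point windows across replicates, the dwell-time Shannon entropy uses a
    log-bin range global to the whole sweep (the comparison set).
    """
    template = params_template or ModelParams()
    grid = [int(n) for n in n_channels_grid]
    runs, labels = _run_grid("n_channels", grid, modes, template,
                             replicates, master_seed, fixed={})
    table = _aggregate(runs, "n_channels", grid, labels, replicates,
                       metric, m, window, r_fraction, n_bins)
    result = SweepResult(axis="n_channels", metric=metric, table=table)
    if fit_degree is not None:
        for label in labels:
            sub = table[table["mode"] == label]
            result.fits[label] = fit_polynomial(sub["n_channels"], sub["mean"],
                                                fit_degree)
    return result


def drift_sweep(modes: Iterable, drift_grid: Sequence[float],
                n_channels: int = 4, metric: str = "shannon_current",
                params_template: ModelParams | None = None,
                replicates: int = 3, master_seed: int = 0,
                m: int = 2, window: int = 5000, r_fraction: float = 0.2,
                n_bins: int = 100, fit_degree: int = 3) -> SweepResult:
    """Sweep the global drift at fixed cluster size.

    For entropy metrics the drift location of the fitted-curve maximum is
    reported per mode in ``max_locations``.
    """
    template = params_template or ModelParams()
    grid = [float(d) for d in drift_grid]
    runs, labels = _run_grid("drift", grid, modes, template, replicates,
                             master_seed, fixed={"n_channels": int(n_channels)})
    table = _aggregate(runs, "drift", grid, labels, replicates,
                       metric, m, window, r_fraction, n_bins)
    result = SweepResult(axis="drift", metric=metric, table=table)
    if metric in ("shannon_current", "shannon_dwell", "sampen"):
        for label in labels:
            sub = table[table["mode"] == label]
            fit = fit_polynomial(sub["drift"], sub["mean"], fit_degree)
            result.fits[label] = fit
            result.max_locations[label] = fitted_maximum(
                fit, (min(grid), max(grid)))
    return result


def fit_polynomial(x, y, degree: int) -> PolynomialFit:
    """Ordinary least-squares polynomial fit of degree 2 or 3 (or any >= 1).

    Returns coefficients highest-degree first, the residual sum of squares
    and the real stationary points of the fitted curve inside the data
    range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidParameterError("x and y must have equal length")
    if x.size <= degree:
        raise InsufficientDataError(
            f"need more than {degree} points to fit degree {degree} "
            f"(got {x.size})"
        )
    coeffs = np.polyfit(x, y, degree)
    resid = float(np.sum((np.polyval(coeffs, x) - y) ** 2))
    deriv = np.polyder(coeffs)
    stationary = []
    if deriv.size > 1:
        roots = np.roots(deriv)
        for root in roots:
            if abs(root.imag) < 1e-9 and x.min() <= root.real <= x.max():
                stationary.append(float(root.real))
    return PolynomialFit(coefficients=coeffs, degree=degree, residual=resid,
                         stationary_points=sorted(stationary))


def fitted_maximum(fit: PolynomialFit, xrange: tuple[float, float]) -> float:
    """Location of the maximum of the fitted curve on [xrange]."""
    candidates = [xrange[0], xrange[1]] + [
        s for s in fit.stationary_points if xrange[0] <= s <= xrange[1]
    ]
    values = np.polyval(fit.coefficients, candidates)
    return float(candidates[int(np.argmax(values))])


@dataclass
class SignatureResult:
    """Diagnostic outcome of a Shannon-current-vs-Nch sweep."""

    label: str                       # "no-cooperation" | "cooperative" | "inconclusive"
    stabilization_nch: int | None    # first Nch whose increment fell below 1 SE
    increments: pd.DataFrame         # per-step increments and combined SEs


def cooperation_signature(sweep, mode: str | None = None) -> SignatureResult:
    """Classify inter-channel cooperation from Shannon entropy vs Nch.

    A monotonic rise with every successive increment exceeding twice its
    combined standard error indicates independent gating; an initial rise
    followed by stabilization (an increment below one combined SE)
    indicates cooperation, the earlier the stronger.  If no increment is
    statistically resolved at all, the verdict is "inconclusive".
    """
    table = sweep.table if isinstance(sweep, SweepResult) else sweep
    if mode is not None:
        table = table[table["mode"] == mode]
    elif "mode" in table and table["mode"].nunique() > 1:
        raise InvalidParameterError(
            "sweep table holds several modes; pass mode=<label>"
        )
    table = table.sort_values("n_channels")
    nch = table["n_channels"].to_numpy()
    if list(nch) != list(range(1, 7)):
        raise InsufficientDataError("signature requires an Nch = 1..6 sweep")
    if (table["n"] < 3).any():
        raise InsufficientDataError("signature requires >= 3 replicates per point")
    mean = table["mean"].to_numpy()
    se = table["se"].to_numpy(dtype=float)
    inc = np.diff(mean)
    comb = np.sqrt(se[:-1] ** 2 + se[1:] ** 2)
    details = pd.DataFrame({"n_channels": nch[1:], "increment": inc,
                            "combined_se": comb})
    if np.all(inc > 2 * comb):
        return SignatureResult("no-cooperation", None, details)
    if np.any(inc > 2 * comb):
        below = np.flatnonzero(inc < comb)
        stab = int(nch[1:][below[0]]) if below.size else None
        return SignatureResult("cooperative", stab, details)
    return SignatureResult("inconclusive", None, details)
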