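"""Plain-text I/O for traces, event tables, sweep tables and run configs.

All formats are line-oriented delimited text with ``#``-prefixed metadata
headers, deterministic for fixed input (stable column order, 6 significant
digits for floats).  Event tables (``level,duration`` rows) are both
written by the simulator and accepted from external idealization software.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .errors import EventTableParseError, InvalidParameterError
from .gating import ModelParams
from .sweeps import SweepResult
from .traces import CurrentTrace, DwellTimeSeries

__all__ = [
    "read_event_table", "write_event_table",
    "read_trace", "write_trace",
    "write_sweep", "RunConfig",
]

_FLOAT_FMT = "%.6g"


def _header_lines(kind: str, meta: dict) -> list[str]:
    lines = [f"# coopgate {kind} v{__version__}"]
    for key in sorted(meta):
        lines.append(f"# {key} = {meta[key]!r}")
    return lines


def _parse_meta(lines) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if " = " in body:
            key, _, value = body.partition(" = ")
            try:
                meta[key.strip()] = eval(value, {"__builtins__": {}})  # literals only
            except Exception:
                meta[key.strip()] = value.strip()
    return meta


def write_trace(trace: CurrentTrace, path) -> None:
    """One current level per line, preceded by a metadata header."""
    lines = _header_lines("trace", {**trace.meta, "n_channels": trace.n_channels})
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
            np.savetxt(fh, trace.values, fmt="%d")
    except OSError as exc:
        raise OSError(f"cannot write trace to {path!r}: {exc}") from exc


def read_trace(path, n_channels: int | None = None) -> CurrentTrace:
    """Read a single-column idealized current trace with ``#`` headers."""
    meta, values = {}, []
    try:
        with open(path) as fh:
            header = []
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    header.append(line)
                    continue
                try:
                    values.append(int(line.split()[0]))
                except ValueError:
                    raise EventTableParseError(
                        f"{path}:{lineno}: not an integer current level: {line!r}"
                    ) from None
    except OSError as exc:
        raise OSError(f"cannot read trace from {path!r}: {exc}") from exc
    meta = _parse_meta(header)
    if not values:
        raise EventTableParseError(f"{path}: no trace samples found")
    nch = n_channels or meta.get("n_channels") or max(max(values), 1)
    return CurrentTrace(np.asarray(values, dtype=np.int16), int(nch), meta)


def write_event_table(dwells: DwellTimeSeries, path) -> None:
    """Two-column ``level,duration`` event table with metadata header."""
    lines = _header_lines("event-table", dwells.meta)
    lines.append("# columns: level,duration")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
            for lvl, dur in zip(dwells.levels, dwells.durations):
                fh.write(f"{int(lvl)},{int(dur)}\n")
    except OSError as exc:
        raise OSError(f"cannot write event table to {path!r}: {exc}") from exc


def read_event_table(path, merge_equal: bool = True) -> DwellTimeSeries:
    """Parse an idealized event table (``level,duration`` per line).

    ``#`` comment lines are ignored.  Consecutive rows with equal levels —
    emitted by some idealization software — are merged into one dwell with
    a warning.  Malformed rows raise with the offending line number.
    """
    levels, durations, header = [], [], []
    try:
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    header.append(line)
                    continue
                parts = [p for p in line.replace("\t", ",").replace(";", ",")
                         .split(",") if p.strip()]
                if len(parts) != 2:
                    raise EventTableParseError(
                        f"{path}:{lineno}: expected two columns "
                        f"'level,duration', got {line!r}"
                    )
                try:
                    lvl = int(parts[0])
                    dur = int(float(parts[1]))
                except ValueError:
                    raise EventTableParseError(
                        f"{path}:{lineno}: non-numeric entry in {line!r}"
                    ) from None
                if dur < 1:
                    raise EventTableParseError(
                        f"{path}:{lineno}: duration must be >= 1, got {dur}"
                    )
                if lvl < 0:
                    raise EventTableParseError(
                        f"{path}:{lineno}: level must be >= 0, got {lvl}"
                    )
                levels.append(lvl)
                durations.append(dur)
    except OSError as exc:
        raise OSError(f"cannot read event table from {path!r}: {exc}") from exc
    if not levels:
        raise EventTableParseError(f"{path}: no dwell rows found")
    lv = np.asarray(levels, dtype=np.int64)
    du = np.asarray(durations, dtype=np.int64)
    repeats = np.flatnonzero(np.diff(lv) == 0)
    if repeats.size:
        if not merge_equal:
            raise EventTableParseError(
                f"{path}: consecutive dwells with equal level at row "
                f"{int(repeats[0]) + 2}"
            )
        warnings.warn(
            f"{path}: merged {repeats.size} consecutive dwell(s) with "
            "identical level", stacklevel=2)
        keep = np.concatenate(([0], np.flatnonzero(np.diff(lv)) + 1))
        sums = np.add.reduceat(du, keep)
        lv, du = lv[keep], sums
    return DwellTimeSeries(lv, du, _parse_meta(header))


def write_sweep(result: SweepResult, path, fits_path=None) -> None:
    """Write a sweep table as deterministic TSV (+ optional JSON fit sidecar)."""
    table = result.table
    cols = list(table.columns)
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(_header_lines(
                "sweep", {"axis": result.axis, "metric": result.metric})) + "\n")
            fh.write("\t".join(cols) + "\n")
            for _, row in table.iterrows():
                cells = []
                for c in cols:
                    v = row[c]
                    if isinstance(v, (float, np.floating)):
                        cells.append(_FLOAT_FMT % v)
                    else:
                        cells.append(str(v))
                fh.write("\t".join(cells) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write sweep to {path!r}: {exc}") from exc
    if fits_path is not None:
        payload = {
            mode: {
                "degree": fit.degree,
                "coefficients": [float(c) for c in fit.coefficients],
                "residual": fit.residual,
                "stationary_points": fit.stationary_points,
            }
            for mode, fit in result.fits.items()
        }
        if result.max_locations:
            payload["_max_locations"] = {k: float(v) for k, v
                                         in result.max_locations.items()}
        with open(fits_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class RunConfig:
    """Serializable bundle of model, metric and sweep settings.

    Defaults reproduce the reference study conditions: barrier 2.0 kT,
    boundary scale 14 rcu, time-scale ratio 600, 25,000 dwells, similarity
    radius 20% of the window SD, 5000-point windows, 100 log-spaced dwell
    bins / 7 current bins.
    """

    model: ModelParams = field(default_factory=ModelParams)
    m: int = 2
    r_fraction: float = 0.2
    window: int = 5000
    dwell_bins: int = 100
    current_bins: int = 7
    axis: str = "nch"
    modes: tuple = ("none", "negative", "weak-positive", "strong-positive")
    replicates: int = 3
    master_seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.model.to_dict()
        d["modes"] = list(self.modes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "model" in d:
            d["model"] = ModelParams.from_dict(d["model"])
        if "modes" in d:
            d["modes"] = tuple(d["modes"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise InvalidParameterError(f"{path}: not a mapping")
        return cls.from_dict(data)
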