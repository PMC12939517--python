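"""Lattice random-walk model of a cooperatively gating ion-channel cluster.

Each of the ``n_channels`` channels is described by a reaction coordinate
(RC) hopping on a one-dimensional integer lattice.  A threshold point (TP,
at 0 in internal coordinates) separates the closed (RC < TP) from the open
(RC > TP) half-space and carries a triangular energy barrier of height
``u_tp`` (kT) with half-width 1.5 rcu.  Outside the barrier the potential is
a ramp whose slope encodes channel activation (``drift``, positive values
favour opening) plus an additive cooperative term ``coop_drift`` per open
neighbor (negative values favour opening -> positive cooperation).  Two
boundaries placed mirror-symmetrically about TP fluctuate on a slower time
scale (one boundary step per ``timescale_ratio`` RC steps), emulating
membrane fluctuations that widen or shrink the conformational space.

The recorded observable is the idealized cluster current: the number of
open channels after every RC time step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .errors import InvalidParameterError

__all__ = [
    "ModelParams",
    "ClusterState",
    "PotentialSpec",
    "jump_probabilities",
    "potential_energy",
    "local_gradient",
    "step_channels",
    "step_boundaries",
    "initial_state",
    "simulate",
]

#: Maximum potential difference per lattice step for which Eqs. of motion
#: yield probabilities inside [0, 1]:  q = 1/2 + dU/(4 kT).
_MAX_STEP_ENERGY_FACTOR = 2.0


@dataclass(frozen=True)
class ModelParams:
    """Complete parameter set of one cluster simulation.

    Attributes
    ----------
    n_channels:
        Number of channels in the cluster (1-6 in the reference study).
    u_tp:
        Barrier peak height in kT above the adjacent ramp endpoints.
    b_max:
        Boundary scale in reaction-coordinate units; boundaries start at
        +-b_max and are reflected at +-2*b_max and at TP-+1.
    timescale_ratio:
        RC steps per boundary step (ratio of diffusion time scales).
    drift:
        Global activation force in kT/rcu.  Positive drift favours the
        open side; 0 is half-activation.
    coop_drift:
        Additive potential-gradient increment per open neighbor, kT/rcu.
        Negative -> positive cooperation, positive -> negative cooperation.
    kT:
        Thermal energy scale; energies are quoted in kT, so 1 by default.
    n_dwells:
        Target number of dwells (constant-current runs) in the output.
    seed:
        Seed of the single random stream driving the whole simulation.
    burn_in_cycles:
        Boundary cycles simulated and discarded before recording starts.
    """

    n_channels: int = 1
    u_tp: float = 2.0
    b_max: int = 14
    timescale_ratio: int = 600
    drift: float = 0.0
    coop_drift: float = 0.0
    kT: float = 1.0
    n_dwells: int = 25_000
    seed: int = 0
    burn_in_cycles: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def barrier_slope(self) -> float:
        """Barrier slope B = u_tp / 1.5 in kT/rcu."""
        return self.u_tp / 1.5

    def validate(self) -> None:
        if self.n_channels < 1:
            raise InvalidParameterError("n_channels must be >= 1")
        if self.b_max < 2:
            raise InvalidParameterError("b_max must be >= 2")
        if self.timescale_ratio < 1:
            raise InvalidParameterError("timescale_ratio must be >= 1")
        if self.n_dwells < 1:
            raise InvalidParameterError("n_dwells must be >= 1")
        if self.burn_in_cycles < 0:
            raise InvalidParameterError("burn_in_cycles must be >= 0")
        if self.kT <= 0:
            raise InvalidParameterError("kT must be positive")
        limit = _MAX_STEP_ENERGY_FACTOR * self.kT
        worst_ramp = abs(self.drift) + (self.n_channels - 1) * abs(self.coop_drift)
        if max(worst_ramp, self.barrier_slope) > limit + 1e-12:
            raise InvalidParameterError(
                "jump probabilities would leave [0, 1]: "
                f"max(|drift| + (Nch-1)|coop_drift|, u_tp/1.5) = "
                f"{max(worst_ramp, self.barrier_slope):g} kT/rcu exceeds 2 kT/rcu"
            )

    def to_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "u_tp": self.u_tp,
            "b_max": self.b_max,
            "timescale_ratio": self.timescale_ratio,
            "drift": self.drift,
            "coop_drift": self.coop_drift,
            "kT": self.kT,
            "n_dwells": self.n_dwells,
            "seed": self.seed,
            "burn_in_cycles": self.burn_in_cycles,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def with_(self, **kwargs) -> "ModelParams":
        """A copy with some fields replaced (validated)."""
        return replace(self, **kwargs)


@dataclass
class ClusterState:
    """Instantaneous configuration: RC positions and boundary positions.

    Internal coordinates place the threshold point at 0; RC positions are
    integer offsets from it and never 0.
    """

    rc_positions: np.ndarray
    b1: int
    b2: int
    tp: int = 0

    def __post_init__(self) -> None:
        self.rc_positions = np.asarray(self.rc_positions, dtype=np.int64)

    @property
    def n_open(self) -> int:
        return int(np.count_nonzero(self.rc_positions > self.tp))

    def copy(self) -> "ClusterState":
        return ClusterState(self.rc_positions.copy(), self.b1, self.b2, self.tp)

    def validate(self, params: ModelParams) -> None:
        tp = self.tp
        if self.b2 - tp != tp - self.b1:
            raise InvalidParameterError("boundaries must mirror each other about TP")
        if not (tp + 2 <= self.b2 < 2 * params.b_max):
            raise InvalidParameterError("b2 out of range [TP+2, 2*b_max)")
        rc = self.rc_positions
        if rc.shape != (params.n_channels,):
            raise InvalidParameterError("rc_positions length must equal n_channels")
        if np.any(rc == tp) or np.any(rc <= self.b1) or np.any(rc >= self.b2):
            raise InvalidParameterError("RC positions must lie strictly inside "
                                        "(b1, b2) and off the threshold point")


@dataclass(frozen=True)
class PotentialSpec:
    """Slopes of the piecewise-linear RC potential for a parameter set."""

    barrier_slope: float
    drift: float
    coop_drift: float

    @classmethod
    def from_params(cls, params: ModelParams) -> "PotentialSpec":
        return cls(params.barrier_slope, params.drift, params.coop_drift)

    def ramp_slope(self, n_open_neighbors: int) -> float:
        """Potential slope (kT/rcu) on the outer ramp segments.

        Positive drift is an opening force, hence a *negative* potential
        slope; open neighbors add ``coop_drift`` to the gradient.
        """
        return -self.drift + n_open_neighbors * self.coop_drift


def jump_probabilities(delta_u: float, kT: float = 1.0) -> tuple[float, float]:
    """Left/right hop probabilities for a potential difference ``delta_u``.

    ``q_left = 1/2 + delta_u/(4 kT)`` and ``p_right = 1 - q_left``: the RC
    preferentially moves downhill.  Valid only for ``|delta_u| <= 2 kT``.
    """
    if abs(delta_u) > _MAX_STEP_ENERGY_FACTOR * kT + 1e-12:
        raise InvalidParameterError(
            f"|delta_u| = {abs(delta_u):g} exceeds 2 kT = {2 * kT:g}; "
            "jump probability would leave [0, 1]"
        )
    q_left = 0.5 + delta_u / (4.0 * kT)
    return q_left, 1.0 - q_left


def potential_energy(x: float, state: ClusterState, n_open_neighbors: int,
                     params: ModelParams) -> float:
    """Piecewise-linear RC potential U(x) in kT, relative to U(b1) = 0.

    Ramp segments [b1, TP-1.5) and (TP+1.5, b2] carry the activation +
    cooperation slope; the barrier rises with slope ``u_tp/1.5`` from
    TP-1.5 to a peak of height ``u_tp`` above the ramp endpoint at TP and
    descends symmetrically to TP+1.5.
    """
    spec = PotentialSpec.from_params(params)
    s = spec.ramp_slope(n_open_neighbors)
    bslope = spec.barrier_slope
    tp = state.tp
    u_ramp_end = (tp - 1.5 - state.b1) * s      # U at TP-1.5
    xr = x - tp
    if xr < -1.5:
        return (x - state.b1) * s
    if xr < 0.0:
        return u_ramp_end + (xr + 1.5) * bslope
    if xr <= 1.5:
        return u_ramp_end + params.u_tp - xr * bslope
    return u_ramp_end + (xr - 1.5) * s


def local_gradient(x: int, state: ClusterState, n_open_neighbors: int,
                   params: ModelParams) -> float:
    """Centred potential difference U(x+1/2) - U(x-1/2) at lattice site x."""
    if not (state.b1 < x < state.b2) or x == state.tp:
        raise InvalidParameterError(
            f"x={x} outside the admissible interval ({state.b1}, {state.b2}) "
            "or on the threshold point"
        )
    return (potential_energy(x + 0.5, state, n_open_neighbors, params)
            - potential_energy(x - 0.5, state, n_open_neighbors, params))


def step_channels(state: ClusterState, params: ModelParams,
                  rng: np.random.Generator) -> ClusterState:
    """One synchronous RC time step for every channel (reference path).

    Move probabilities are computed from the open/closed pattern at step
    entry; a move onto a boundary is rejected and a move onto TP becomes a
    two-site jump across it.  Channels draw in index order, one uniform
    variate each, exactly like the compiled kernel.
    """
    new = state.copy()
    rc = new.rc_positions
    n_open = state.n_open
    for i in range(params.n_channels):
        x = int(rc[i])
        nbr = n_open - (1 if x > state.tp else 0)
        du = local_gradient(x, state, nbr, params)
        q_left, _ = jump_probabilities(du, params.kT)
        step = -1 if rng.random() < q_left else 1
        nx = x + step
        if nx == new.b1 or nx == new.b2:
            nx = x
        elif nx == state.tp:
            nx = 2 * state.tp - x
        rc[i] = nx
    return new


def step_boundaries(state: ClusterState, params: ModelParams,
                    rng: np.random.Generator) -> ClusterState:
    """One synchronous boundary step (reference path).

    Both boundaries move one rcu toward or away from TP with equal
    probability; moves reaching +-2*b_max or TP-+1 are rejected.  An inward
    move overtaking an RC pushes that RC to the nearest admissible interior
    site on its own side of TP, preserving its open/closed state.
    """
    new = state.copy()
    half = state.b2 - state.tp
    if rng.random() < 0.5:
        nb = half - 1
        if nb >= 2:
            new.b1, new.b2 = state.tp - nb, state.tp + nb
            rc = new.rc_positions
            rc[rc - state.tp >= nb] = state.tp + nb - 1
            rc[rc - state.tp <= -nb] = state.tp - nb + 1
    else:
        nb = half + 1
        if nb < 2 * params.b_max:
            new.b1, new.b2 = state.tp - nb, state.tp + nb
    return new


def initial_state(params: ModelParams, rng: np.random.Generator) -> ClusterState:
    """Boundaries at +-b_max; RCs uniform on admissible sites excluding TP."""
    b = params.b_max
    sites = np.array([x for x in range(-b + 1, b) if x != 0], dtype=np.int64)
    rc = sites[rng.integers(0, sites.size, size=params.n_channels)]
    return ClusterState(rc, -b, b)


def _truncate_to_dwells(values: np.ndarray, n_dwells: int) -> np.ndarray:
    """Cut the trace at the end of its ``n_dwells``-th constant-level run."""
    changes = np.flatnonzero(np.diff(values.astype(np.int16)))
    if changes.size + 1 > n_dwells:
        values = values[: changes[n_dwells - 1] + 1]
    return values


def simulate(params: ModelParams, max_steps: int | None = None):
    """Run the full cluster simulation until ``n_dwells`` dwells are recorded.

    Returns ``(trace, final_state)`` where ``trace`` is a
    :class:`coopgate.traces.CurrentTrace` whose run-length encoding has
    exactly ``params.n_dwells`` dwells (the final dwell may be censored by
    the recording end).  Identical parameters (including seed) give
    bit-identical output.  Termination is checked once per boundary cycle.

    ``max_steps`` optionally bounds the number of recorded RC steps as a
    safety valve; exceeding it raises :class:`InsufficientDataError`.
    """
    from .errors import InsufficientDataError
    from .traces import CurrentTrace

    params.validate()
    rng = np.random.default_rng(params.seed)
    state = initial_state(params, rng)
    rc = state.rc_positions          # modified in place by the kernel
    b = params.b_max
    ratio = params.timescale_ratio
    inv4kT = 0.25 / params.kT
    ramp0 = -params.drift

    if params.burn_in_cycles:
        scratch = np.empty(params.burn_in_cycles * ratio, dtype=np.int8)
        b, _, _, _ = _kernels.run_cycles(
            rc, b, params.b_max, ratio, params.barrier_slope, ramp0,
            params.coop_drift, inv4kT, scratch, -1, 0,
            np.iinfo(np.int64).max, rng)

    chunks: list[np.ndarray] = []
    prev_level = -1                  # first recorded sample opens dwell #1
    dwell_count = 0
    total = 0
    n_cycles = 500
    while dwell_count < params.n_dwells:
        out = np.empty(n_cycles * ratio, dtype=np.int8)
        b, prev_level, dwell_count, idx = _kernels.run_cycles(
            rc, b, params.b_max, ratio, params.barrier_slope, ramp0,
            params.coop_drift, inv4kT, out, prev_level, dwell_count,
            params.n_dwells, rng)
        chunks.append(out[:idx])
        total += idx
        if max_steps is not None and total >= max_steps and dwell_count < params.n_dwells:
            raise InsufficientDataError(
                f"only {dwell_count} of {params.n_dwells} dwells after "
                f"{total} recorded steps (max_steps={max_steps})"
            )
        n_cycles = min(n_cycles * 4, 50_000)

    values = _truncate_to_dwells(np.concatenate(chunks), params.n_dwells)
    final = ClusterState(rc, -b, b)
    meta = params.to_dict()
    trace = CurrentTrace(values=values, n_channels=params.n_channels, meta=meta)
    return trace, final


def simulate_reference(params: ModelParams):
    """Pure-Python simulation, draw-for-draw identical to :func:`simulate`.

    Orders of magnitude slower; intended for validating the compiled kernel
    on short runs.
    """
    from .traces import CurrentTrace

    params.validate()
    rng = np.random.default_rng(params.seed)
    state = initial_state(params, rng)
    for _ in range(params.burn_in_cycles):
        for _ in range(params.timescale_ratio):
            state = step_channels(state, params, rng)
        state = step_boundaries(state, params, rng)
    values: list[int] = []
    prev_level = -1
    dwell_count = 0
    while dwell_count < params.n_dwells:
        for _ in range(params.timescale_ratio):
            state = step_channels(state, params, rng)
            level = state.n_open
            values.append(level)
            if level != prev_level:
                dwell_count += 1
                prev_level = level
        state = step_boundaries(state, params, rng)
    arr = _truncate_to_dwells(np.asarray(values, dtype=np.int8), params.n_dwells)
    trace = CurrentTrace(values=arr, n_channels=params.n_channels,
                         meta=params.to_dict())
    return trace, state
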