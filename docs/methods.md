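# Methods

## Model

A cluster of `Nch` identical channels is simulated as `Nch` coupled
discrete random walks. Channel *i*'s reaction coordinate (RC) moves on the
integer lattice between two shared boundaries `B1 < TP < B2`; the
threshold point TP (internal coordinate 0) is excluded and separates
closed (left) from open (right) conformations. The potential `U(x)` is
continuous and piecewise linear:

* ramps on `[B1, TP−1.5)` and `(TP+1.5, B2]` with slope
  `s = −A + N_OpenNeighbors·Δdrift` (kT/rcu), where `A` is the activation
  drift and `N_OpenNeighbors` counts the *other* channels currently open;
* a barrier rising with slope `B = U_TP/1.5` from `TP−1.5` to a peak
  `U_TP` above the ramp endpoint at TP and descending symmetrically to
  `TP+1.5`.

Hop probabilities are `q_left = 1/2 + ΔU/(4kT)`, `p_right = 1 − q_left`,
with `ΔU = U(x+1/2) − U(x−1/2)`. This bounds admissible slopes:
`max(|A| + (Nch−1)|Δdrift|, U_TP/1.5) ≤ 2 kT/rcu`, enforced at parameter
construction.

Sign conventions. `q_left` grows with `ΔU`, i.e. the walker moves
downhill. The user-facing `drift` is the activation *force*: positive
values favour the open side, so it enters the potential slope as `−drift`.
Consequently `Δdrift < 0` (per open neighbor) is positive cooperation and
`Δdrift > 0` negative cooperation; the four canonical modes are
none (0), negative (+0.1), weak-positive (−0.05), strong-positive
(−0.1 kT/rcu).

One simulation step updates all channels synchronously: moves are drawn in
channel index order using the open/closed pattern at step entry (this
avoids any dependence on an arbitrary update order). Rules:

* a move landing on `B1`/`B2` is rejected (the RC keeps its position);
* a move landing on TP becomes a two-site jump across it (±1 → ∓1),
  decided by the local barrier gradient alone — the skip is kinematic,
  with no additional acceptance factor;
* after every `D_RC/D_B` channel steps both boundaries move one rcu,
  synchronously and mirror-symmetrically, inward or outward with equal
  probability; moves reaching `±2·Bmax` or `TP∓1` are rejected. When an
  inward move overtakes an RC, the RC is pushed to the nearest admissible
  interior site on its own side of TP, preserving its conduction state
  (the record of open/closed states must not be altered by a boundary
  event).

The idealized current `I(t)` (number of RCs right of TP) is recorded after
every channel step. Initial conditions: boundaries at `±Bmax`, RC
positions uniform on the admissible sites; recording starts immediately
(a burn-in in boundary cycles is available, default 0). The run ends at
the first boundary-cycle check at which the run-length encoding of the
trace holds at least `n_dwells` dwells; the trace is then truncated at the
end of the `n_dwells`-th dwell, so the final dwell may be censored (first
and last dwells are retained). All randomness flows from one
`numpy.random.Generator` seeded by `ModelParams.seed`; draw order is fixed
(channels in index order, then the boundary), and the compiled numba
kernel consumes the stream identically to the pure-Python reference
implementation, which the tests check draw-for-draw.

### Default parameters

| parameter | default | meaning |
|---|---|---|
| `u_tp` | 2.0 kT | barrier peak above the ramp endpoints |
| `b_max` | 14 rcu | boundary start `±b_max`, reflection at `±2·b_max` |
| `timescale_ratio` | 600 | RC steps per boundary step (`D_RC/D_B`) |
| `drift` | 0 kT/rcu | half-activation; study range −0.7…0.7 in 0.1 steps |
| `coop_drift` | 0 kT/rcu | per-open-neighbor gradient increment |
| `n_dwells` | 25 000 | recorded dwell count per run |
| `kT` | 1 | energies are quoted in kT |

The barrier height is anchored to the adjacent ramp endpoints
(`U_TP − U_{TP−1.5} = 2 kT`), making the barrier slope constant and
independent of drift and boundary excursions; an absolute anchoring would
push hop probabilities out of [0, 1] for wide boundary excursions.

## Entropy metrics

**Shannon entropy** `H = −Σ p log2 p` (bits) is applied to two
histograms: the current-level histogram with 7 bins at levels 0…6
(clusters of up to six channels), and the dwell-duration histogram with
100 geometrically spaced bins spanning the global minimum–maximum of the
*whole comparison set* — the caller must pass that shared range when
comparing series, since per-series ranges make entropies incomparable.
Bins are half-open `[lo, hi)` with the final bin closed; a degenerate
range collapses to a single bin with a warning.

**Sample Entropy** uses the standard estimator: template pairs `i < j`
drawn from the common index range `0 … N−m−1` for both template lengths,
Chebyshev distance strictly below `r`, self-matches excluded,
`SampEn = −ln(A/B)`. Zero matches at length `m+1` yield NaN ("undefined"),
never an exception; a constant series (zero SD, hence zero radius) raises
an invalid-radius error. Long dwell series are analysed in consecutive
non-overlapping 5000-point windows with `r = 0.2 ×` that window's SD;
windows are treated as independent samples (mean ± SEM across windows,
SD available by flag, a global-`r` override available). The per-window
radius makes windowed SampEn sensitive to the window length through the
window SD: shorter windows miss rare long dwells, shrink `r` and raise
SampEn. This is a known property of the estimator on heavy-tailed dwell
distributions, and the reason a single window length (5000) is fixed for
all comparisons. SampEn is applied to the duration sequence only; levels
are not interleaved.

## Sweeps, fits and the cooperation diagnostic

Sweep drivers run one simulation per (grid point, mode, replicate) with
seeds that are a pure function of (master seed, axis value, mode label,
replicate index), so any point can be reproduced in isolation. Defaults
use 3 replicate seeds per point; scalar metrics aggregate across
replicates, windowed SampEn pools windows across replicates. Trends are
summarized by ordinary least-squares polynomials (degree 2 for
entropy-vs-size, degree 3 for entropy-vs-drift, configurable); the
location of the fitted maximum on the data range is reported for
entropy-vs-drift sweeps.

The cooperation diagnostic classifies a Shannon-current-vs-Nch sweep
(Nch = 1…6, ≥ 3 replicates): all successive increments above twice their
combined SE → independent gating; a significant initial rise followed by
an increment below one combined SE → cooperative, with strength ranked by
how early stabilization occurs; no resolved increment at all →
inconclusive. The 2-SE/1-SE thresholds are package choices; the
underlying criterion is qualitative.

## What the generator does and does not emulate

The simulator produces idealized records: unit conductance per channel,
no amplitude noise, no filtering, no missed events — by design, so that
entropy differences reflect cooperation alone. Dwell durations are in RC
time units; no mapping to physical time is attempted. Consequences for
interpreting test results on real data: passing tests demonstrate the
metrics' sensitivity to cooperation under ideal idealization; they say
nothing about robustness to idealization errors, baseline drift, or
channel-specific kinetic schemes (the model has a single barrier, not a
multi-state kinetic scheme, and reproduces no exponential mixture
structure beyond what the random walk induces). The fluctuating
boundaries induce long-range correlations; a practical consequence is
that time averages converge slowly (the boundary random walk mixes over
hundreds of cycles), so single-run metrics carry substantial run-to-run
variability, which is why sweeps default to replicate seeds and
windowed/replicated error bars.

## Numerical and test-size choices

* The inner loops (simulation and SampEn counting) are numba-compiled;
  both have pure-Python/scipy reference implementations and the test
  suite asserts exact agreement (bit-identical traces; identical SampEn
  on random series).
* `ΔU` is evaluated exactly from the continuous piecewise-linear
  potential; for integer sites no lattice step straddles the breakpoints
  at `TP±1.5`, so no slope averaging is ever needed.
* Probability-vector inputs to the Shannon entropy must sum to 1 within
  1e−9; polynomial fits require more points than the degree.
* Statistical tests choose problem sizes for resolution, not speed:
  e.g. the dwell-rate-vs-Nch comparison uses runs truncated to a common
  4,000,000 steps with 24–72 replicate seeds per cluster size, and the
  SampEn-vs-Nch trend uses 72 replicate 25,000-dwell runs for the
  no-cooperation mode, because its later increments are a few hundredths
  of a nat. Smaller problem sizes leave these real trends inside the noise.

## Known limitations

* Cooperation acts only through the additive ramp-gradient term; boundary
  modulation as an interaction mechanism is not implemented.
* Windowed SampEn means depend on the window length (see above); only
  equal-window comparisons are meaningful.
* Dwell-count-terminated runs weight tight-boundary episodes more than
  time-terminated runs of equal length would; metrics that are ratios
  over steps (I/Imax, NPo) are slightly pulled toward their
  tight-boundary values at small `n_dwells`.
* Entropy error bars treat windows/replicates as independent; residual
  correlation through the boundary process makes them mildly optimistic.
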