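# coopgate

Stochastic simulation of **cooperatively gating ion-channel clusters** and
**information-entropy analysis** of the resulting (or externally supplied)
idealized multi-channel records.

Ion channels of one type often assemble into membrane clusters in which the
opening of one channel changes the opening probability of its neighbors.
Experimentally only the superimposed cluster current is accessible, which
defeats most single-channel analysis methods. `coopgate` is aimed at
biophysicists who want to (i) generate controlled multi-channel data with a
known cooperation mode and strength, and (ii) quantify cooperativity in
idealized patch-clamp records through entropy metrics rather than open
probability alone.

## The model

Each of the `Nch` channels is a reaction coordinate (RC) performing a
biased random walk on a 1-D lattice. A threshold point TP separates closed
(RC < TP) from open (RC > TP) conformations and carries a triangular
energy barrier of height `U_TP` (default 2 kT) with half-width 1.5 rcu.
Outside the barrier the potential is a linear ramp whose slope combines

* a global **drift** `A` (kT/rcu) — the activation force exerted by
  voltage/ligand sensors; positive drift favours opening, `A = 0` is
  half-activation;
* a cooperative term `N_OpenNeighbors · Δdrift` — each open neighbor adds
  `Δdrift` to the potential gradient. `Δdrift < 0` is positive cooperation
  (opening begets opening), `Δdrift > 0` negative cooperation, `0` none.

Hops follow `q_left = 1/2 + ΔU/(4kT)`, `p_right = 1 − q_left`, where `ΔU`
is the potential difference across the lattice step centred on the RC.
Two boundaries `B1, B2`, mirror-symmetric about TP, fluctuate on a slower
time scale (`D_RC/D_B = 600` RC steps per boundary step, amplitude
`2·Bmax` with `Bmax = 14`), emulating membrane fluctuations. The recorded
observable is the idealized current `I(t)`: the number of open channels
per RC time step. Its run-length encoding is the dwell-time series of
cluster conduction levels.

Analysis metrics:

* `I/Imax = Σ I(t) / (Nch · steps)` — mean per-channel open probability;
  `NPo` — mean number of open channels.
* **Shannon entropy** `H = −Σ p_i log2 p_i` (bits) of either the 7-bin
  current-level histogram (levels 0…6) or a 100-bin logarithmically
  spaced dwell-duration histogram whose range must span the whole
  comparison set.
* **Sample Entropy** `SampEn(m, r) = −ln(A/B)` (nats) of the dwell-time
  sequence: `B`/`A` count template pairs of length `m`/`m+1` closer than
  `r` in Chebyshev distance (self-matches excluded, `r` = 20 % of the
  window SD, 5000-point windows by default).

## Worked example

```python
import coopgate as cg

params = cg.ModelParams(n_channels=4, drift=0.0, coop_drift=0.0,
                        n_dwells=25_000, seed=42)
trace, _ = cg.simulate(params)
dwells = cg.extract_dwells(trace)
print(cg.relative_current(trace), cg.npo(trace))
```

prints `0.4960 1.9841`: four independent channels at half-activation are
each open about half the time, so on average ~2 of 4 are open. Comparing
an independent with a strongly positively cooperating 4-channel cluster
(`coop_drift = −0.1`, see `examples/entropy_metrics.py`):

```
mode=none
  Shannon (current levels): 2.021 bits
  Shannon (dwell times)   : 4.054 bits
  SampEn m=2 (dwell times): 0.582 +- 0.120 nats over 5 windows
mode=strong-positive
  Shannon (current levels): 1.391 bits
  Shannon (dwell times)   : 3.883 bits
  SampEn m=2 (dwell times): 0.131 +- 0.038 nats over 5 windows
```

Cooperation orders the cluster: fewer current levels are visited (current
entropy drops from the near-binomial 2.02 bits toward the synchronized
limit) and the dwell-time sequence becomes more regular (SampEn drops by a
factor ~4). The `examples/` directory holds one short script per
capability (simulation, entropy metrics, cooperation diagnosis from
entropy-vs-size sweeps, activation-curve shifts).

External records are accepted as plain-text event tables
(`level,duration` rows) or single-column idealized traces; see
`coopgate.read_event_table`.

## Command line

A thin CLI mirrors the library:

```sh
coopgate simulate --n-channels 4 --coop-drift -0.1 --seed 1 --format both --out run
coopgate analyze  --events run.dwells.csv
coopgate entropy  --events run.dwells.csv --metric sampen --m 2 --window 5000
coopgate sweep    --axis nch --metric shannon_current --replicates 3 --out sweep.tsv
```

Exit codes: 0 success, 2 invalid parameters, 3 insufficient data, 4 I/O.

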