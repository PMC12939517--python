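"""Simulate one channel cluster and report its classical gating metrics.

Runs a 4-channel cluster at half-activation (drift 0) without cooperation,
extracts the dwell-time series and prints I/Imax (the mean per-channel
open probability), NPo (the mean number of open channels) and dwell
statistics.  With independent channels at drift 0 expect I/Imax near 0.5
and NPo near half the cluster size.
"""

import coopgate as cg

params = cg.ModelParams(n_channels=4, drift=0.0, coop_drift=0.0,
                        n_dwells=25_000, seed=42)
trace, _ = cg.simulate(params)
dwells = cg.extract_dwells(trace)

print(f"simulated steps   : {len(trace)}")
print(f"dwells recorded   : {len(dwells)}")
print(f"I/Imax            : {cg.relative_current(trace):.4f}")
print(f"NPo               : {cg.npo(trace):.4f}")
print(f"mean dwell (steps): {dwells.durations.mean():.2f}")
print(f"longest dwell     : {dwells.durations.max()}")
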