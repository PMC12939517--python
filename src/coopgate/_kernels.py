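"""Numba inner loops for the lattice simulator and Sample Entropy.

These kernels are exact transcriptions of the pure-Python reference code in
:mod:`coopgate.gating` and :mod:`coopgate.entropy`; they consume the numpy
``Generator`` stream in the identical order, so fast and reference paths are
bit-for-bit interchangeable (asserted in the test suite).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_cycles(rc, b, b_max, ratio, barrier, ramp0, coop_drift, inv4kT,
               out, prev_level, dwell_count, dwell_target, rng):
    """Advance the cluster through boundary cycles, recording the current.

    Each cycle is ``ratio`` synchronous channel steps followed by one
    boundary step.  The idealized current (number of RCs right of the
    threshold) is recorded after every channel step.  The kernel stops at a
    cycle boundary once ``dwell_count`` (runs seen so far in the recorded
    level sequence) reaches ``dwell_target``, or when ``out`` is full.

    ``rc`` is modified in place.  ``ramp0`` is the potential slope on the
    ramp segments at zero open neighbors (= -drift).  Returns the updated
    ``(b, prev_level, dwell_count, n_recorded)``.
    """
    nch = rc.shape[0]
    idx = 0
    max_cycles = out.shape[0] // ratio
    for _c in range(max_cycles):
        for _t in range(ratio):
            n_open = 0
            for i in range(nch):
                if rc[i] > 0:
                    n_open += 1
            for i in range(nch):
                x = rc[i]
                # centred potential difference over [x-0.5, x+0.5]
                if x == -1:
                    du = barrier
                elif x == 1:
                    du = -barrier
                else:
                    nbr = n_open - (1 if x > 0 else 0)
                    du = ramp0 + nbr * coop_drift
                q_left = 0.5 + du * inv4kT
                step = -1 if rng.random() < q_left else 1
                nx = x + step
                if nx == -b or nx == b:
                    nx = x          # reflecting walls: move rejected
                elif nx == 0:
                    nx = -x         # threshold is skipped: +-1 -> -+1
                rc[i] = nx
            level = 0
            for i in range(nch):
                if rc[i] > 0:
                    level += 1
            out[idx] = level
            idx += 1
            if level != prev_level:
                dwell_count += 1
                prev_level = level
        u = rng.random()
        if u < 0.5:
            nb = b - 1              # synchronous inward move
            if nb >= 2:
                b = nb
                for i in range(nch):
                    if rc[i] >= b:
                        rc[i] = b - 1
                    elif rc[i] <= -b:
                        rc[i] = -(b - 1)
        else:
            nb = b + 1              # synchronous outward move
            if nb < 2 * b_max:
                b = nb
        if dwell_count >= dwell_target:
            break
    return b, prev_level, dwell_count, idx


@njit(cache=True)
def sampen_match_counts(x, m, r):
    """Template match counts for Sample Entropy via Chebyshev distance.

    Counts pairs i < j drawn from the common index range 0..N-m-1 whose
    length-m templates (B) and length-(m+1) templates (A) are closer than
    r in the maximum metric.  Self-matches are excluded by construction.
    """
    n = x.shape[0]
    n_templates = n - m           # number of (m+1)-length templates
    a = 0
    bcount = 0
    for i in range(n_templates - 1):
        for j in range(i + 1, n_templates):
            d = 0.0
            for k in range(m):
                diff = abs(x[i + k] - x[j + k])
                if diff > d:
                    d = diff
            if d < r:
                bcount += 1
                if abs(x[i + m] - x[j + m]) < r:
                    a += 1
    return a, bcount
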