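"""Independent brute-force oracles used to anchor the fast implementations.

Deliberately written in plain Python with exhaustive enumeration (O(n^2)
coincidence checks, explicit interval-list union) so they share no code
path with the vectorized sweep they validate.
"""

from __future__ import annotations

import math


def oracle_tiled_fraction(times, dt, duration):
    """Union of the tiles [t-dt, t+dt] clipped to [0, duration], as a fraction."""
    intervals = sorted((max(t - dt, 0.0), min(t + dt, duration)) for t in times)
    total = 0.0
    cur_lo = cur_hi = None
    for lo, hi in intervals:
        if cur_hi is None:
            cur_lo, cur_hi = lo, hi
        elif lo <= cur_hi:
            cur_hi = max(cur_hi, hi)
        else:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
    if cur_hi is not None:
        total += cur_hi - cur_lo
    return total / duration


def oracle_coincident_fraction(times_a, times_b, dt):
    """Proportion of A spikes with at least one B spike within dt (closed window)."""
    if len(times_a) == 0:
        return math.nan
    hits = sum(1 for a in times_a if any(abs(a - b) <= dt for b in times_b))
    return hits / len(times_a)


def oracle_sttc(times_a, times_b, dt, duration):
    """Brute-force STTC; NaN for empty trains or a zero denominator."""
    if len(times_a) == 0 or len(times_b) == 0:
        return math.nan
    ta = oracle_tiled_fraction(times_a, dt, duration)
    tb = oracle_tiled_fraction(times_b, dt, duration)
    pa = oracle_coincident_fraction(times_a, times_b, dt)
    pb = oracle_coincident_fraction(times_b, times_a, dt)
    da, db = 1.0 - pa * tb, 1.0 - pb * ta
    if da == 0.0 or db == 0.0:
        return math.nan
    return 0.5 * ((pa - tb) / da + (pb - ta) / db)
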