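"""Counter-based random substreams for reproducible, partition-independent draws.

The external Poisson drive of every neuron is generated from a keyed,
counter-based stream (a splitmix64-style 64-bit mixer) so that the sequence
seen by neuron ``n`` in communication step ``t`` depends only on
``(seed, n, t, purpose)`` — never on how the grid is partitioned or in which
order partitions are processed.  All routines are numba-compiled and usable
both from Python and from inside the simulation kernel.
"""

from __future__ import annotations

import math

import numba
import numpy as np

U64_GOLDEN = np.uint64(0x9E3779B97F4A7C15)

PURPOSE_EXTERNAL = 0xE0


@numba.njit(numba.uint64(numba.uint64), cache=True, inline="always")
def _mix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@numba.njit(numba.uint64(numba.uint64, numba.uint64, numba.uint64, numba.uint64),
            cache=True, inline="always")
def stream_key(seed, neuron, step, purpose):
    """64-bit stream key from (seed, neuron_id, step_index, purpose)."""
    h = _mix64(seed)
    h = _mix64(h ^ (neuron * np.uint64(0xA24BAED4963EE407)))
    h = _mix64(h ^ (step * np.uint64(0x9FB21C651E98DF25)))
    h = _mix64(h ^ purpose)
    return h


@numba.njit(numba.float64(numba.uint64, numba.uint64), cache=True, inline="always")
def uniform01(key, counter):
    """counter-th uniform in [0, 1) of the keyed stream (53-bit mantissa)."""
    x = _mix64(key + counter * U64_GOLDEN)
    return (x >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@numba.njit(cache=True, inline="always")
def normal_draw(key, counter):
    """Standard-normal draw (Box-Muller); consumes two counter slots.

    Returns (z, next_counter).
    """
    u1 = uniform01(key, counter)
    u2 = uniform01(key, counter + np.uint64(1))
    # avoid log(0)
    u1 = max(u1, 1e-300)
    z = math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)
    return z, counter + np.uint64(2)


@numba.njit(cache=True, inline="always")
def poisson_draw(lam, key, counter):
    """Poisson(lam) draw by Knuth inversion (suitable for small lam).

    Returns (k, next_counter).
    """
    if lam <= 0.0:
        return 0, counter
    L = math.exp(-lam)
    k = 0
    p = 1.0
    while True:
        p *= uniform01(key, counter)
        counter += np.uint64(1)
        if p <= L:
            return k, counter
        k += 1
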