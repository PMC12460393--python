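"""Counter-based per-index randomness.

Symbol sequences in this package are conceptually infinite: a realization of
an i.i.d. symbol process indexed by the integers.  We materialize only the
finitely many symbols a cocycle actually reads, so the value at index ``i``
must depend on (seed, i) alone and never on the order in which indices are
visited.  Sequential generators cannot provide that, so we derive one uniform
variate per index with a splitmix64-style integer hash, vectorized over
numpy uint64 arrays (wrap-around on uint64 is the intended modular
arithmetic).
"""

from __future__ import annotations

import numpy as np

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


def _splitmix64(z: np.ndarray) -> np.ndarray:
    # 1-d view so the modular uint64 arithmetic wraps silently
    z0 = np.asarray(z, dtype=np.uint64)
    z = np.atleast_1d(z0).copy()
    z += _GOLDEN
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    z ^= z >> np.uint64(31)
    return z.reshape(z0.shape)


def mix_key(*parts: int) -> int:
    """Fold integers into a single 64-bit key, order-sensitively."""
    key = np.zeros((), dtype=np.uint64)
    for p in parts:
        key = _splitmix64(key ^ np.asarray(p).astype(np.uint64) * _GOLDEN)
    return int(key)


def index_uniforms(key: int, indices) -> np.ndarray:
    """Uniform(0,1) variates addressed by integer index under a fixed key.

    ``indices`` may be any integer array (negative indices are valid; the
    uint64 cast is a bijection on 64-bit integers).  53 mantissa bits are
    used so values lie in [0, 1).
    """
    idx = np.asarray(indices).astype(np.int64).astype(np.uint64)
    z = _splitmix64(idx * _GOLDEN ^ np.uint64(key))
    return (z >> np.uint64(11)).astype(np.float64) * (1.0 / (1 << 53))
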