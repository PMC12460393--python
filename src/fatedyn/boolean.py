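"""Kauffman-style random Boolean networks (the NK model).

A network has N binary genes; gene i reads K fixed input genes and updates
through its own Boolean truth table of length 2^K.  All genes update
synchronously, so the dynamics on {0, 1}^N are a deterministic function and
every orbit eventually enters a cycle — a periodic orbit that, once
entered, is never left.  There are 2^(2^K) Boolean maps of K inputs, so a
random network draws each gene's table uniformly from that exponentially
large family (and its K distinct inputs uniformly without replacement).

States are encoded both as bit vectors and as integers (bit 0 = gene 0) so
the full transition graph on 2^N states can be built as a single successor
array; cycles and basins then follow from standard functional-graph
analysis, and perturbation-return probabilities from single-bit flips of
cycle states.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BooleanNetwork",
    "CycleSet",
    "count_boolean_maps",
    "generate_random_network",
    "step",
    "enumerate_cycles",
    "perturbation_analysis",
    "EXHAUSTIVE_LIMIT",
]

EXHAUSTIVE_LIMIT = 20  # ~10^6 states; beyond this enumeration refuses


def count_boolean_maps(K: int) -> int:
    """Number of Boolean functions of K inputs: 2^(2^K) (exact integer)."""
    if K < 0:
        raise ValueError("K must be nonnegative")
    return 2 ** (2 ** K)


@dataclass
class BooleanNetwork:
    """N genes, each reading K inputs through a truth table of length 2^K.

    ``inputs[i]`` lists the K (0-based) input gene indices of gene i;
    ``tables[i][idx]`` is the output bit, where ``idx`` is the big-endian
    encoding of the input bits (first listed input is the most significant
    bit).
    """

    N: int
    K: int
    inputs: np.ndarray
    tables: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=np.int64)
        self.tables = np.asarray(self.tables, dtype=np.int64)
        if not (1 <= self.K <= self.N):
            raise ValueError(f"need 1 <= K <= N, got K={self.K}, N={self.N}")
        if self.inputs.shape != (self.N, self.K):
            raise ValueError(f"inputs must have shape ({self.N}, {self.K})")
        if self.tables.shape != (self.N, 2 ** self.K):
            raise ValueError(f"tables must have shape ({self.N}, {2 ** self.K})")
        if np.any((self.inputs < 0) | (self.inputs >= self.N)):
            raise ValueError("input indices out of range")
        if np.any((self.tables != 0) & (self.tables != 1)):
            raise ValueError("table entries must be 0 or 1")

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.inputs.tobytes())
        h.update(self.tables.tobytes())
        return h.hexdigest()

    # -- state codecs ------------------------------------------------------

    def encode(self, s: Sequence[int]) -> int:
        s = np.asarray(s, dtype=np.int64)
        if s.shape != (self.N,):
            raise ValueError(f"state must have length {self.N}")
        return int(np.sum(s << np.arange(self.N)))

    def decode(self, code: int) -> np.ndarray:
        return (code >> np.arange(self.N)) & 1

    def successor_table(self) -> np.ndarray:
        """Successor code for every one of the 2^N states (vectorized)."""
        codes = np.arange(2 ** self.N, dtype=np.int64)
        bits = (codes[:, None] >> np.arange(self.N)) & 1  # (2^N, N)
        nxt = np.zeros_like(codes)
        weights = 1 << np.arange(self.K - 1, -1, -1, dtype=np.int64)
        for i in range(self.N):
            idx = bits[:, self.inputs[i]] @ weights
            nxt |= self.tables[i, idx] << i
        return nxt

    def to_json_dict(self) -> dict:
        return {"N": self.N, "K": self.K, "inputs": self.inputs.tolist(),
                "tables": self.tables.tolist(), "seed": self.seed}

    @classmethod
    def from_json_dict(cls, d: dict) -> "BooleanNetwork":
        return cls(N=d["N"], K=d["K"], inputs=np.asarray(d["inputs"]),
                   tables=np.asarray(d["tables"]), seed=d.get("seed"))


def generate_random_network(N: int, K: int, seed: int) -> BooleanNetwork:
    """Draw a random NK network: uniform distinct inputs, uniform tables."""
    if not (1 <= K <= N):
        raise ValueError(f"need 1 <= K <= N, got K={K}, N={N}")
    rng = np.random.default_rng(seed)
    inputs = np.stack([rng.choice(N, size=K, replace=False) for _ in range(N)])
    tables = rng.integers(0, 2, size=(N, 2 ** K))
    return BooleanNetwork(N=N, K=K, inputs=inputs, tables=tables, seed=seed)


def step(net: BooleanNetwork, s: Sequence[int]) -> np.ndarray:
    """One synchronous update: every gene reads its inputs from s at once."""
    s = np.asarray(s, dtype=np.int64)
    if s.shape != (net.N,):
        raise ValueError(f"state must have length {net.N}")
    weights = 1 << np.arange(net.K - 1, -1, -1, dtype=np.int64)
    idx = s[net.inputs] @ weights
    return net.tables[np.arange(net.N), idx]


@dataclass
class CycleSet:
    """All cycles of a network plus the basin partition of {0, 1}^N.

    ``cycles[c]`` lists state codes in orbit order, rotated so the
    lexicographically smallest code comes first (canonical form, so cycle
    identity is testable).  ``basin_map[code]`` is the index of the cycle
    every orbit from ``code`` terminates in; basin sizes partition 2^N.
    """

    cycles: list
    basin_map: np.ndarray
    network_hash: str

    @property
    def basin_sizes(self) -> np.ndarray:
        return np.bincount(self.basin_map, minlength=len(self.cycles))

    def cycle_states(self, net: BooleanNetwork, c: int) -> np.ndarray:
        return np.stack([net.decode(code) for code in self.cycles[c]])

    def to_json_dict(self) -> dict:
        return {"cycles": [list(map(int, c)) for c in self.cycles],
                "basin_sizes": self.basin_sizes.tolist()}


def _canonical_rotation(cycle: list[int]) -> list[int]:
    k = int(np.argmin(cycle))
    return cycle[k:] + cycle[:k]


def enumerate_cycles(net: BooleanNetwork, limit: int = EXHAUSTIVE_LIMIT) -> CycleSet:
    """Exhaustively find all cycles and basins of the synchronous dynamics.

    Builds the full successor array on 2^N states, peels off transient
    states by repeatedly removing in-degree-zero states (what remains lies
    on cycles), extracts the cycles, and propagates cycle membership back
    through the transients.  Refuses for N above ``limit``.
    """
    if net.N > limit:
        raise ValueError(
            f"N={net.N} exceeds the exhaustive limit {limit} (2^N states); "
            "use trajectory sampling instead")
    succ = net.successor_table()
    n_states = succ.size

    # peel transients: states never reached again cannot lie on a cycle
    indeg = np.bincount(succ, minlength=n_states)
    frontier = np.flatnonzero(indeg == 0)
    on_cycle = np.ones(n_states, dtype=bool)
    while frontier.size:
        on_cycle[frontier] = False
        targets = succ[frontier]
        np.subtract.at(indeg, targets, 1)
        frontier = targets[(indeg[targets] == 0) & on_cycle[targets]]
        frontier = np.unique(frontier)

    # group the remaining states into cycles by walking each once
    basin_map = np.full(n_states, -1, dtype=np.int64)
    cycles: list[list[int]] = []
    for s in np.flatnonzero(on_cycle):
        if basin_map[s] != -1:
            continue
        orbit = [int(s)]
        cur = int(succ[s])
        while cur != s:
            orbit.append(cur)
            cur = int(succ[cur])
        c = len(cycles)
        cycles.append(_canonical_rotation(orbit))
        basin_map[orbit] = c

    # propagate basins backward through the transients
    while np.any(basin_map == -1):
        unknown = basin_map == -1
        ready = unknown & (basin_map[succ] != -1)
        if not np.any(ready):  # cannot happen: every orbit reaches a cycle
            raise RuntimeError("basin propagation stalled")
        basin_map[ready] = basin_map[succ[ready]]

    return CycleSet(cycles=cycles, basin_map=basin_map, network_hash=net.content_hash())


def perturbation_analysis(net: BooleanNetwork, cycles: CycleSet) -> np.ndarray:
    """Cycle-to-cycle transition matrix under single-bit flips of cycle states.

    For every state on cycle i and every single-gene flip, the deterministic
    orbit of the flipped state terminates in some cycle j; entry (i, j) is
    the fraction of the (state, bit) perturbations of cycle i that land in
    cycle j.  Rows sum to one; the diagonal is the return probability.
    """
    if cycles.network_hash != net.content_hash():
        raise ValueError("CycleSet does not match this network (stale enumeration)")
    n_cycles = len(cycles.cycles)
    mat = np.zeros((n_cycles, n_cycles), dtype=float)
    for i, cyc in enumerate(cycles.cycles):
        count = 0
        for code in cyc:
            for bit in range(net.N):
                flipped = code ^ (1 << bit)
                mat[i, cycles.basin_map[flipped]] += 1
                count += 1
        mat[i] /= count
    return mat
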