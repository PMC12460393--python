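"""Bernoulli schemes and shift spaces: the noise models that drive cocycles.

A Bernoulli scheme is the shift map on sequences of i.i.d. symbols drawn
from a positive probability vector (p_1, ..., p_n), equipped with the
product measure on cylinder sets: the measure of the set of sequences
showing the word (a_1, ..., a_r) from position z onward is
prod_i p_{a_i}, independently of z.  The shift preserves that measure,
which is what makes the scheme a legitimate stationary noise model.

Sequences are conceptually infinite.  We represent a realization by an
optional finite materialized window plus counter-based lazy extension: the
symbol at index i is a pure function of (scheme, seed, i), so reading
symbols in any order, or extending the window, can never change a value
already observed.  Symbols are 1-based (values in {1, ..., n}).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._hash import index_uniforms, mix_key
from .core import AutonomousSystem, AxiomReport
from .timesets import TimeStructure

__all__ = [
    "BernoulliScheme",
    "SymbolSequence",
    "CylinderSpec",
    "shift",
    "cylinder_measure",
    "sample_path",
    "check_measure_preservation",
    "MeasurePreservationReport",
    "shift_system",
]


@dataclass(frozen=True)
class BernoulliScheme:
    """An i.i.d. symbol source with probability vector p and shift dynamics.

    ``sided`` selects the time set: "two" gives the invertible shift on
    bi-infinite sequences (time set Z), "one" the forward-only shift on
    one-sided sequences (time set Z>=0).
    """

    p: tuple
    sided: str = "one"

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", tuple(p.tolist()))
        if p.ndim != 1 or p.size < 1:
            raise ValueError("p must be a nonempty probability vector")
        if np.any(p <= 0):
            raise ValueError("all symbol probabilities must be positive")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1 (got {p.sum()!r})")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")

    @property
    def n(self) -> int:
        return len(self.p)

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(np.asarray(self.p, dtype=float))

    def symbols_at(self, seed: int, indices) -> np.ndarray:
        """Symbols (1-based) at the given indices of the realization ``seed``."""
        u = index_uniforms(mix_key(0x5E9, seed), indices)
        return np.searchsorted(self.cumulative, u, side="right").astype(np.int64) + 1


@dataclass
class SymbolSequence:
    """One realization omega of a symbol process, lazily materializable.

    Reading index ``m`` resolves to base index ``m + shift_offset``; a shift
    of the sequence only moves this offset.  If the base index lies in the
    explicit window the stored symbol is returned; otherwise the symbol is
    generated deterministically from (scheme, seed, base index).  A window
    flagged ``periodic`` tiles the whole index range (used for hand-crafted
    periodic sequences).
    """

    n: int
    sided: str = "one"
    scheme: Optional[BernoulliScheme] = None
    seed: Optional[int] = None
    window_offset: int = 0
    window: Optional[tuple] = None
    periodic: bool = False
    shift_offset: int = 0

    def __post_init__(self) -> None:
        if self.window is not None:
            w = np.asarray(self.window, dtype=np.int64)
            if w.size and (w.min() < 1 or w.max() > self.n):
                raise ValueError(f"window symbols must lie in 1..{self.n}")
            self.window = tuple(int(v) for v in w)
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")

    def read(self, m: int) -> int:
        return int(self.read_block(np.asarray([m]))[0])

    def read_block(self, indices) -> np.ndarray:
        idx = np.asarray(indices, dtype=np.int64)
        if self.sided == "one" and np.any(idx < 0):
            raise IndexError("one-sided sequence rejects negative indices")
        base = idx + self.shift_offset
        out = np.empty(base.shape, dtype=np.int64)
        resolved = np.zeros(base.shape, dtype=bool)
        if self.window is not None:
            w = np.asarray(self.window, dtype=np.int64)
            if self.periodic:
                out[:] = w[(base - self.window_offset) % len(w)]
                return out
            inside = (base >= self.window_offset) & (base < self.window_offset + len(w))
            out[inside] = w[base[inside] - self.window_offset]
            resolved |= inside
        if not np.all(resolved):
            if self.scheme is None or self.seed is None:
                raise IndexError("index outside materialized window and no scheme/seed for lazy extension")
            need = ~resolved
            out[need] = self.scheme.symbols_at(self.seed, base[need])
        return out

    def materialize(self, start: int, stop: int) -> np.ndarray:
        """Symbols at indices start..stop-1 (read-only convenience)."""
        return self.read_block(np.arange(start, stop))

    def shifted(self, k: int) -> "SymbolSequence":
        if self.sided == "one" and k < 0:
            raise ValueError("one-sided sequences only shift forward (k >= 0)")
        return SymbolSequence(n=self.n, sided=self.sided, scheme=self.scheme,
                              seed=self.seed, window_offset=self.window_offset,
                              window=self.window, periodic=self.periodic,
                              shift_offset=self.shift_offset + int(k))


@dataclass(frozen=True)
class CylinderSpec:
    """The cylinder set C_z[(a_1, ..., a_r)]: sequences with word a at z.

    An empty word (r = 0) denotes the full sequence space.
    """

    z: int = 0
    word: tuple = ()

    def validate(self, scheme: BernoulliScheme) -> None:
        if scheme.sided == "one" and self.z < 0:
            raise ValueError("one-sided scheme: cylinder start index must be >= 0")
        for a in self.word:
            if not (1 <= int(a) <= scheme.n):
                raise ValueError(f"cylinder symbol {a} outside alphabet 1..{scheme.n}")


def shift(seq: SymbolSequence, k: int) -> SymbolSequence:
    """The k-fold left shift: the result reads index m as seq read m + k."""
    return seq.shifted(k)


def cylinder_measure(scheme: BernoulliScheme, cyl: CylinderSpec) -> float:
    """Product measure of a cylinder set: prod_i p_{a_i}, independent of z."""
    cyl.validate(scheme)
    p = np.asarray(scheme.p, dtype=float)
    out = 1.0
    for a in cyl.word:
        out *= p[int(a) - 1]
    return out


def sample_path(scheme: BernoulliScheme, window: range, seed: int) -> SymbolSequence:
    """A seeded realization with the given index window materialized.

    The materialized symbols coincide with what lazy extension of the same
    (scheme, seed) would produce, so reading beyond the window is consistent.
    """
    idx = np.asarray(list(window), dtype=np.int64)
    if idx.size == 0:
        raise ValueError("window must be nonempty")
    if scheme.sided == "one" and idx.min() < 0:
        raise ValueError("one-sided scheme: window indices must be >= 0")
    symbols = scheme.symbols_at(seed, idx)
    return SymbolSequence(n=scheme.n, sided=scheme.sided, scheme=scheme, seed=seed,
                          window_offset=int(idx.min()), window=tuple(int(v) for v in symbols))


@dataclass
class MeasurePreservationReport:
    """Empirical and analytic sides of the shift-invariance of the measure.

    The identity theta_t^{-1}(C_z[w]) = C_{z+t}[w] makes the analytic check
    exact: both cylinder measures come from the same product formula.  The
    empirical side estimates P(sigma^t(omega) in C) over seeded paths and
    reports the binomial z-score of the deviation.
    """

    analytic_measure: float
    shifted_measure: float
    empirical_frequency: float
    n_paths: int
    z_score: float
    z_threshold: float = 4.0

    @property
    def passed(self) -> bool:
        return self.analytic_measure == self.shifted_measure and abs(self.z_score) <= self.z_threshold

    def to_dict(self) -> dict:
        return {
            "analytic_measure": self.analytic_measure,
            "shifted_measure": self.shifted_measure,
            "empirical_frequency": self.empirical_frequency,
            "n_paths": self.n_paths,
            "z_score": self.z_score,
            "verdict": "pass" if self.passed else "fail",
        }


def check_measure_preservation(scheme: BernoulliScheme, cyl: CylinderSpec, t: int,
                               n_paths: int, seed: int,
                               z_threshold: float = 4.0) -> MeasurePreservationReport:
    """Check that the t-fold shift preserves the cylinder measure.

    ``{omega : sigma^t(omega) in C_z[w]}`` equals ``C_{z+t}[w]``, whose
    measure is again the product formula; the empirical frequency over
    ``n_paths`` independent seeded realizations is compared to it.
    """
    cyl.validate(scheme)
    if scheme.sided == "one" and t < 0:
        raise ValueError("one-sided scheme: shift exponent must be >= 0")
    if scheme.sided == "one" and cyl.z + t < 0:
        raise ValueError("shifted cylinder start index out of range for one-sided scheme")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    q = cylinder_measure(scheme, cyl)
    q_shifted = cylinder_measure(scheme, CylinderSpec(z=cyl.z + t, word=cyl.word))

    r = len(cyl.word)
    if r == 0:
        freq = 1.0
    else:
        # sigma^t(omega)(m) = omega(m + t): the event reads omega at z+t .. z+t+r-1
        idx = np.arange(cyl.z + t, cyl.z + t + r, dtype=np.int64)
        word = np.asarray(cyl.word, dtype=np.int64)
        path_ids = np.arange(n_paths, dtype=np.int64)
        keys = np.asarray([mix_key(0x5E9, mix_key(seed, int(j))) for j in path_ids],
                          dtype=np.uint64)
        # vectorized (path x index) uniforms via the same per-index construction
        hits = np.ones(n_paths, dtype=bool)
        cum = scheme.cumulative
        for j_pos, i in enumerate(idx):
            # per-path symbol at index i: hash keyed by the path's key
            z64 = index_uniforms_keys(keys, int(i))
            sym = np.searchsorted(cum, z64, side="right") + 1
            hits &= sym == word[j_pos]
        freq = float(hits.mean())

    if q in (0.0, 1.0):
        z = 0.0 if freq == q else float("inf")
    else:
        se = np.sqrt(q * (1.0 - q) / n_paths)
        z = (freq - q) / se
    return MeasurePreservationReport(analytic_measure=q, shifted_measure=q_shifted,
                                     empirical_frequency=freq, n_paths=n_paths,
                                     z_score=float(z), z_threshold=z_threshold)


def index_uniforms_keys(keys: np.ndarray, index: int) -> np.ndarray:
    """Uniforms at one index across many realization keys (vectorized)."""
    from ._hash import _GOLDEN, _splitmix64
    keys = np.asarray(keys, dtype=np.uint64)
    idx = np.full(keys.shape, np.int64(index)).astype(np.uint64)
    z = _splitmix64(idx * _GOLDEN ^ keys)
    return (z >> np.uint64(11)).astype(np.float64) * (1.0 / (1 << 53))


def shift_system(scheme: BernoulliScheme, window: int = 16, base_seed: int = 0) -> AutonomousSystem:
    """The shift as an autonomous system on symbol sequences.

    States are :class:`SymbolSequence` realizations; equality of two
    sequences is measured by comparing a finite index window, which is all a
    desk-scale check can observe.  Time is discrete (integers); two-sided
    schemes make the shift invertible.
    """
    lo = -window if scheme.sided == "two" else 0

    def sampler(rng: np.random.Generator, n: int):
        seeds = rng.integers(0, 2**31 - 1, size=n)
        return [sample_path(scheme, range(lo, window), int(s)) for s in seeds]

    def metric(a: SymbolSequence, b: SymbolSequence) -> float:
        idx = np.arange(max(lo, 0), window // 2)
        return float(np.max(np.abs(a.read_block(idx) - b.read_block(idx))))

    return AutonomousSystem(
        dim=1,
        theta=lambda k, seq: seq.shifted(int(k)),
        time=TimeStructure(kind="discrete", t0=0, span=4),
        state_sampler=sampler,
        invertible=(scheme.sided == "two"),
        metric=metric,
        norm=None,
        name=f"bernoulli_shift_n{scheme.n}",
    )
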