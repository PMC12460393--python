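"""Time sets, durations, and duration lengths.

A dynamical system here is always clocked by a time set T (a subinterval of
the reals, or of the integers), the set D of ordered pairs (s, t) with
s <= t ("durations"), and the set L of duration lengths l = t - s, which is
closed under addition.  The structure below records which concrete case is
in play and provides seeded samplers of times, durations, and lengths for
the executable axiom checks: the checks are sample-based, so the time
structure is also a sampling contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeStructure"]


@dataclass(frozen=True)
class TimeStructure:
    """A concrete time set T = [t0, inf) over the reals or integers.

    Parameters
    ----------
    kind:
        ``"continuous"`` (T a real interval) or ``"discrete"`` (T integer).
    t0:
        Lower bound (origin) of the time set.
    has_identity:
        Whether the duration-length set L contains the identity 0.  All
        concrete cases here do; the flag exists so the identity axiom can
        be skipped for a pure (non-monoid) semigroup.
    span:
        Width of the window [t0, t0 + span] from which times and the window
        [0, span] from which duration lengths are sampled during axiom
        checks.  Must be positive: a zero-width sampling range would make
        every check pass vacuously.
    """

    kind: str = "continuous"
    t0: float = 0.0
    has_identity: bool = True
    span: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "discrete"):
            raise ValueError(f"kind must be 'continuous' or 'discrete', got {self.kind!r}")
        if not self.span > 0:
            raise ValueError("sampling span must be positive (zero-length ranges are degenerate)")
        if self.kind == "discrete" and self.span < 1:
            raise ValueError("discrete time structure needs span >= 1")

    # -- seeded samplers ---------------------------------------------------

    def sample_lengths(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n duration lengths in L ∩ [0, span]."""
        if self.kind == "discrete":
            return rng.integers(0, int(self.span) + 1, size=n).astype(float)
        return rng.uniform(0.0, self.span, size=n)

    def sample_times(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """n time points in T ∩ [t0, t0 + span]."""
        return self.t0 + self.sample_lengths(rng, n)

    def sample_durations(self, rng: np.random.Generator, n: int):
        """n durations (s, t) with s <= t, both within the sampling window."""
        s = self.sample_times(rng, n)
        t = s + self.sample_lengths(rng, n)
        return s, t

    def contains_length(self, l: float) -> bool:
        if l < 0:
            return False
        if self.kind == "discrete" and l != int(l):
            return False
        return True
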