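"""Deterministic dynamical systems and their axioms as executable checks.

Three formalisms are implemented:

* :class:`AutonomousSystem` — an evolution map theta(l, x) indexed by
  duration length only, obeying the identity and semigroup axioms
  ``theta(0, x) = x`` and ``theta(l + m, x) = theta(m, theta(l, x))``.
* :class:`Process` — a nonautonomous two-parameter map phi((s, t), x)
  indexed by initial and final time points, obeying the initial-value and
  causality axioms ``phi((t, t), x) = x`` and
  ``phi((s, t), x) = phi((u, t), phi((s, u), x))`` for s <= u <= t.
* :class:`SkewProductFlow` — a cocycle phi(l, p, x) over an autonomous
  driving map theta on a parameter space P, obeying ``phi(0, p, x) = x``
  and the cocycle property
  ``phi(s + t, p, x) = phi(t, theta(s, p), phi(s, p, x))``.

The axioms are verified on seeded samples of tuples, not symbolically:
evolution maps are opaque callables, so :func:`check_axioms` draws
reproducible (time, state) tuples and reports the worst relative residual.
The conversions between formalisms mirror the standard constructions: a
time-translation-invariant process collapses to a duration-length map
(:func:`duration_length_form`), any process embeds in a skew-product flow
driven by time itself (:func:`process_to_skew`), and a skew-product flow is
an autonomous system on the extended space P x X (:func:`skew_to_autonomous`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence

import numpy as np

from .timesets import TimeStructure

__all__ = [
    "AutonomousSystem",
    "Process",
    "SkewProductFlow",
    "AxiomReport",
    "check_axioms",
    "evolve_autonomous",
    "evolve_process",
    "evolve_skew",
    "duration_length_form",
    "process_to_skew",
    "skew_to_autonomous",
]


def _sup_norm(x) -> float:
    arr = np.asarray(x, dtype=float)
    return float(np.max(np.abs(arr))) if arr.size else 0.0


def _default_metric(a, b) -> float:
    return _sup_norm(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def _box_sampler(lo, hi, dim):
    lo = np.broadcast_to(np.asarray(lo, dtype=float), (dim,))
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (dim,))

    def sample(rng: np.random.Generator, n: int):
        return [rng.uniform(lo, hi) for _ in range(n)]

    return sample


@dataclass
class AutonomousSystem:
    """An autonomous system (X, L, theta) with evolution map ``theta(l, x)``.

    ``theta`` must be a pure function of a scalar duration length and a
    state.  States are finite real vectors by default, but any state type
    works if ``state_sampler`` and ``metric`` are supplied (the shift map on
    symbol sequences uses this).
    """

    dim: int
    theta: Callable[[float, Any], Any]
    time: TimeStructure = field(default_factory=TimeStructure)
    state_sampler: Optional[Callable[[np.random.Generator, int], Sequence]] = None
    bounds: Optional[tuple] = None  # (lo, hi) box, checked on evolve
    invertible: bool = False
    metric: Callable[[Any, Any], float] = _default_metric
    norm: Optional[Callable[[Any], float]] = _sup_norm
    name: str = ""

    def __post_init__(self) -> None:
        if self.state_sampler is None:
            lo, hi = self.bounds if self.bounds is not None else (-1.0, 1.0)
            self.state_sampler = _box_sampler(lo, hi, self.dim)

    def evolve(self, l: float, x):
        if l < 0 and not self.invertible:
            raise ValueError(f"negative duration length {l} on a forward-only system")
        if self.time.kind == "discrete" and l != int(l):
            raise ValueError(f"non-integer duration length {l} on a discrete-time system")
        if self.bounds is not None:
            lo, hi = self.bounds
            xa = np.asarray(x, dtype=float)
            if np.any(xa < lo) or np.any(xa > hi):
                raise ValueError(f"state {x} outside declared bounds {self.bounds}")
        return self.theta(l, x)


@dataclass
class Process:
    """A nonautonomous process (X, D, phi) with map ``phi((s, t), x)``."""

    dim: int
    phi: Callable[[float, float, Any], Any]  # called as phi(s, t, x)
    time: TimeStructure = field(default_factory=TimeStructure)
    state_sampler: Optional[Callable[[np.random.Generator, int], Sequence]] = None
    bounds: Optional[tuple] = None
    metric: Callable[[Any, Any], float] = _default_metric
    norm: Optional[Callable[[Any], float]] = _sup_norm
    name: str = ""

    def __post_init__(self) -> None:
        if self.state_sampler is None:
            lo, hi = self.bounds if self.bounds is not None else (-1.0, 1.0)
            self.state_sampler = _box_sampler(lo, hi, self.dim)

    def evolve(self, s: float, t: float, x):
        if t < s:
            raise ValueError(f"(s, t) = ({s}, {t}) is not a duration: need s <= t")
        return self.phi(s, t, x)


@dataclass
class SkewProductFlow:
    """A cocycle ``phi(l, p, x)`` on fibre X over a driving map ``theta(l, p)``.

    ``param_dim`` is the dimension of P when parameters are real vectors;
    it is only needed by :func:`skew_to_autonomous`.  ``driving_theta_inv``,
    when given, evolves parameters backward (theta(-l, p)) and enables
    pullback constructions.
    """

    dim: int
    phi: Callable[[float, Any, Any], Any]
    driving_theta: Callable[[float, Any], Any]
    param_sampler: Callable[[np.random.Generator, int], Sequence]
    time: TimeStructure = field(default_factory=TimeStructure)
    state_sampler: Optional[Callable[[np.random.Generator, int], Sequence]] = None
    bounds: Optional[tuple] = None
    param_dim: int = 1
    driving_theta_inv: Optional[Callable[[float, Any], Any]] = None
    metric: Callable[[Any, Any], float] = _default_metric
    norm: Optional[Callable[[Any], float]] = _sup_norm
    name: str = ""

    def __post_init__(self) -> None:
        if self.state_sampler is None:
            lo, hi = self.bounds if self.bounds is not None else (-1.0, 1.0)
            self.state_sampler = _box_sampler(lo, hi, self.dim)

    def evolve(self, l: float, p, x):
        if l < 0:
            raise ValueError(f"negative duration length {l} on a forward-only cocycle")
        return self.driving_theta(l, p), self.phi(l, p, x)


@dataclass
class AxiomReport:
    """Outcome of one sampled axiom check."""

    axiom: str
    n: int
    max_residual: float
    tol: float
    passed: bool
    witness: Optional[tuple] = None
    error: Optional[str] = None

    @property
    def verdict(self) -> str:
        return "pass" if self.passed else "fail"

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, tuple):
                return [_clean(u) for u in v]
            return v

        return {
            "axiom": self.axiom,
            "n": self.n,
            "max_residual": self.max_residual,
            "tol": self.tol,
            "verdict": self.verdict,
            "witness": _clean(self.witness),
            "error": self.error,
        }


def _run_residual_check(axiom: str, tuples, lhs_rhs, metric, norm, tol: float) -> AxiomReport:
    """Evaluate lhs/rhs over sampled tuples, track the worst relative residual.

    Residuals are relative: |lhs - rhs| <= tol * (1 + |lhs|).
    """
    worst = -1.0
    witness = None
    n = 0
    for tup in tuples:
        n += 1
        try:
            lhs, rhs = lhs_rhs(*tup)
        except Exception as exc:  # evolution map raised: record as failure
            return AxiomReport(axiom, n, float("inf"), tol, False, witness=tup, error=repr(exc))
        scale = 1.0 + (norm(lhs) if norm is not None else 0.0)
        resid = metric(lhs, rhs) / scale
        if resid > worst:
            worst = resid
            witness = tup
    return AxiomReport(axiom, n, worst, tol, worst <= tol, witness=witness)


def check_axioms(system, n_samples: int = 1000, seed: int = 0, tol: float = 1e-9,
                 axioms: Optional[Sequence[str]] = None) -> list[AxiomReport]:
    """Verify the applicable axioms of a system on seeded sample tuples.

    Which axioms apply depends on the formalism: identity and semigroup for
    an :class:`AutonomousSystem`; initial value and causality for a
    :class:`Process` (with time-translation invariance available on request
    via ``axioms=[..., "translation_invariance"]`` — it is *not* an axiom of
    a process, but passing it is what licenses the duration-length form);
    identity and the cocycle property for a :class:`SkewProductFlow`.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    reports: list[AxiomReport] = []

    if isinstance(system, AutonomousSystem):
        selected = axioms or (["identity", "semigroup"] if system.time.has_identity else ["semigroup"])
        xs = system.state_sampler(rng, n_samples)
        ls = system.time.sample_lengths(rng, n_samples)
        ms = system.time.sample_lengths(rng, n_samples)
        if "identity" in selected:
            reports.append(_run_residual_check(
                "identity", ((x,) for x in xs),
                lambda x: (system.theta(0 if system.time.kind == "discrete" else 0.0, x), x),
                system.metric, system.norm, tol))
        if "semigroup" in selected:
            reports.append(_run_residual_check(
                "semigroup", zip(ls, ms, xs),
                lambda l, m, x: (system.theta(l + m, x), system.theta(m, system.theta(l, x))),
                system.metric, system.norm, tol))
        return reports

    if isinstance(system, Process):
        selected = axioms or ["initial_value", "causality"]
        xs = system.state_sampler(rng, n_samples)
        ts = system.time.sample_times(rng, n_samples)
        l1 = system.time.sample_lengths(rng, n_samples)
        l2 = system.time.sample_lengths(rng, n_samples)
        deltas = system.time.sample_lengths(rng, n_samples)
        if "initial_value" in selected:
            reports.append(_run_residual_check(
                "initial_value", zip(ts, xs),
                lambda t, x: (system.phi(t, t, x), x),
                system.metric, system.norm, tol))
        if "causality" in selected:
            reports.append(_run_residual_check(
                "causality", zip(ts, l1, l2, xs),
                lambda s, a, b, x: (system.phi(s, s + a + b, x),
                                    system.phi(s + a, s + a + b, system.phi(s, s + a, x))),
                system.metric, system.norm, tol))
        if "translation_invariance" in selected:
            reports.append(_run_residual_check(
                "translation_invariance", zip(ts, l1, deltas, xs),
                lambda s, l, d, x: (system.phi(s, s + l, x), system.phi(s + d, s + d + l, x)),
                system.metric, system.norm, tol))
        return reports

    if isinstance(system, SkewProductFlow):
        selected = axioms or ["identity", "cocycle"]
        xs = system.state_sampler(rng, n_samples)
        ps = system.param_sampler(rng, n_samples)
        ss = system.time.sample_lengths(rng, n_samples)
        ls = system.time.sample_lengths(rng, n_samples)
        if "identity" in selected:
            reports.append(_run_residual_check(
                "identity", zip(ps, xs),
                lambda p, x: (system.phi(0 if system.time.kind == "discrete" else 0.0, p, x), x),
                system.metric, system.norm, tol))
        if "cocycle" in selected:
            reports.append(_run_residual_check(
                "cocycle", zip(ss, ls, ps, xs),
                lambda s, t, p, x: (system.phi(s + t, p, x),
                                    system.phi(t, system.driving_theta(s, p), system.phi(s, p, x))),
                system.metric, system.norm, tol))
        return reports

    raise TypeError(f"cannot check axioms of {type(system).__name__}")


# -- thin functional aliases over the dataclass methods ----------------------

def evolve_autonomous(sys: AutonomousSystem, l: float, x):
    """theta(l, x)."""
    return sys.evolve(l, x)


def evolve_process(proc: Process, s: float, t: float, x):
    """phi((s, t), x); requires s <= t."""
    return proc.evolve(s, t, x)


def evolve_skew(flow: SkewProductFlow, l: float, p, x):
    """Drive parameter and fibre together: (theta(l, p), phi(l, p, x))."""
    return flow.evolve(l, p, x)


# -- conversions between formalisms ------------------------------------------

def duration_length_form(proc: Process, n_samples: int = 200, seed: int = 0,
                         tol: float = 1e-9) -> AutonomousSystem:
    """Collapse a time-translation-invariant process to theta(l, x).

    The construction theta(l, x) := phi((s, s + l), x) is only well defined
    when phi((s, t), x) depends on (s, t) through t - s alone, so the
    translation-invariance check is run first and the conversion refused
    (with the worst witness) if it fails.
    """
    report = check_axioms(proc, n_samples=n_samples, seed=seed, tol=tol,
                          axioms=["translation_invariance"])[0]
    if not report.passed:
        raise ValueError(
            "process is not time-translation invariant; duration-length form is "
            f"ill-defined (residual {report.max_residual:.3g} at witness {report.witness})")
    s0 = proc.time.t0

    def theta(l, x, _s0=s0, _phi=proc.phi):
        return _phi(_s0, _s0 + l, x)

    return AutonomousSystem(dim=proc.dim, theta=theta, time=proc.time,
                            state_sampler=proc.state_sampler, bounds=proc.bounds,
                            metric=proc.metric, norm=proc.norm,
                            name=f"{proc.name or 'process'}:duration_length_form")


def process_to_skew(proc: Process) -> SkewProductFlow:
    """Embed a process in a skew-product flow driven by time itself.

    P := T with driving theta(l, s) = s + l, and cocycle
    phi(l, s, x) := proc((s, s + l), x).  The cocycle property of the result
    is exactly the causality of the process.
    """
    def phi(l, p, x, _phi=proc.phi):
        return _phi(p, p + l, x)

    def param_sampler(rng, n, _time=proc.time):
        return list(_time.sample_times(rng, n))

    return SkewProductFlow(dim=proc.dim, phi=phi,
                           driving_theta=lambda l, p: p + l,
                           driving_theta_inv=lambda l, p: p - l,
                           param_sampler=param_sampler,
                           time=proc.time, state_sampler=proc.state_sampler,
                           bounds=proc.bounds, param_dim=1,
                           metric=proc.metric, norm=proc.norm,
                           name=f"{proc.name or 'process'}:as_skew")


def skew_to_autonomous(flow: SkewProductFlow) -> AutonomousSystem:
    """The associated autonomous system on P x X.

    eta(l, (p, x)) := (theta(l, p), phi(l, p, x)); its semigroup property is
    equivalent to the cocycle property of the input.  Requires real-vector
    parameters (dimension ``flow.param_dim``) so states can be concatenated.
    """
    dp = flow.param_dim

    def eta(l, z, _flow=flow, _dp=dp):
        z = np.asarray(z, dtype=float)
        p, x = z[:_dp], z[_dp:]
        if _dp == 1:
            p_out = _flow.driving_theta(l, float(p[0]))
            x_out = _flow.phi(l, float(p[0]), x if x.size > 1 else float(x[0]))
        else:
            p_out = _flow.driving_theta(l, p)
            x_out = _flow.phi(l, p, x)
        return np.concatenate([np.atleast_1d(np.asarray(p_out, dtype=float)),
                               np.atleast_1d(np.asarray(x_out, dtype=float))])

    def sampler(rng, n, _flow=flow):
        ps = _flow.param_sampler(rng, n)
        xs = _flow.state_sampler(rng, n)
        return [np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)),
                                np.atleast_1d(np.asarray(x, dtype=float))])
                for p, x in zip(ps, xs)]

    return AutonomousSystem(dim=dp + flow.dim, theta=eta, time=flow.time,
                            state_sampler=sampler,
                            name=f"{flow.name or 'skew'}:as_autonomous")
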