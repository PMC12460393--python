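"""Attractor estimation via directed Hausdorff distances on point clouds.

The attractor definitions quantify over bounded sets; the desk-scale
surrogate used throughout is a finite point cloud sampled from such a set,
with attraction measured by the directed (nonsymmetric) Hausdorff distance

    d_H(V, W) = sup_{v in V} inf_{w in W} d(v, w),

computed exactly over the finite clouds.  Global attractors are estimated
by iterating a cloud forward; forward attraction tracks a moving family of
fibres; pullback attraction evolves a fixed bounded cloud from
progressively earlier start times to a fixed target time; the random
pullback estimate composes the past symbols of a two-sided driving
realization, mirroring the pullback construction for random attractors.
Verdicts are three-valued because pullback limits are asymptotic: a run
that is still contracting at the deepest horizon is "inconclusive", not a
failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core import AutonomousSystem, Process, SkewProductFlow
from .random_systems import RandomMapSystem
from .driving import SymbolSequence

__all__ = [
    "PointCloudSet",
    "NonautonomousSetFibres",
    "ConvergenceReport",
    "directed_hausdorff",
    "estimate_global_attractor",
    "forward_convergence",
    "pullback_convergence",
    "random_pullback_estimate",
    "transient_length",
]


@dataclass
class PointCloudSet:
    """A finite, nonempty set of states in R^n with the Euclidean metric."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[0] == 0:
            raise ValueError("a point cloud must contain at least one point")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def deduplicated(self, tol: float = 1e-6) -> "PointCloudSet":
        """Greedy deduplication: keep points farther than tol from kept ones."""
        kept: list[np.ndarray] = []
        for p in self.points:
            if not kept or np.min(np.linalg.norm(np.asarray(kept) - p, axis=1)) > tol:
                kept.append(p)
        return PointCloudSet(np.asarray(kept))

    def diameter(self) -> float:
        if self.n_points == 1:
            return 0.0
        return float(np.max(cdist(self.points, self.points)))

    @classmethod
    def from_interval(cls, lo: float, hi: float, n: int, dim: int = 1,
                      seed: Optional[int] = None) -> "PointCloudSet":
        if seed is None:
            pts = np.linspace(lo, hi, n)[:, None] * np.ones((1, dim))
        else:
            pts = np.random.default_rng(seed).uniform(lo, hi, size=(n, dim))
        return cls(pts)


@dataclass
class NonautonomousSetFibres:
    """A candidate nonautonomous set: fibre label -> point cloud."""

    fibres: dict

    def __post_init__(self) -> None:
        for label, cloud in self.fibres.items():
            if not isinstance(cloud, PointCloudSet):
                self.fibres[label] = PointCloudSet(cloud)

    def fibre(self, label) -> PointCloudSet:
        if label not in self.fibres:
            raise KeyError(f"no fibre at label {label!r}")
        return self.fibres[label]


@dataclass
class ConvergenceReport:
    """Distances along a convergence run plus a three-valued verdict."""

    history: list  # list of (index value, distance)
    tol: float
    verdict: str  # pass | fail | inconclusive
    final_distance: float = field(init=False)
    monotone: bool = field(init=False)
    message: str = ""
    invariance_residual: Optional[float] = None

    def __post_init__(self) -> None:
        dists = [d for _, d in self.history]
        self.final_distance = dists[-1] if dists else float("nan")
        self.monotone = all(b <= a + 1e-15 for a, b in zip(dists, dists[1:]))

    def to_dict(self) -> dict:
        return {
            "history": [[float(i), float(d)] for i, d in self.history],
            "tol": self.tol,
            "verdict": self.verdict,
            "final_distance": self.final_distance,
            "monotone": self.monotone,
            "message": self.message,
            "invariance_residual": self.invariance_residual,
        }


def directed_hausdorff(V: PointCloudSet, W: PointCloudSet) -> float:
    """max over V of the distance to the nearest point of W (not symmetric)."""
    if not isinstance(V, PointCloudSet):
        V = PointCloudSet(V)
    if not isinstance(W, PointCloudSet):
        W = PointCloudSet(W)
    if V.dim != W.dim:
        raise ValueError(f"dimension mismatch: {V.dim} vs {W.dim}")
    return float(np.max(np.min(cdist(V.points, W.points), axis=1)))


def _symmetric_hausdorff(V: PointCloudSet, W: PointCloudSet) -> float:
    return max(directed_hausdorff(V, W), directed_hausdorff(W, V))


def _evolve_cloud(evolve, cloud: PointCloudSet) -> PointCloudSet:
    out = [np.atleast_1d(np.asarray(evolve(x if x.size > 1 else float(x[0])), dtype=float))
           for x in cloud.points]
    return PointCloudSet(np.stack(out))


def estimate_global_attractor(sys: AutonomousSystem, B0: PointCloudSet, t_max: float,
                              n_steps: int = 30, tol: float = 1e-6,
                              dedup_tol: float = 1e-6,
                              divergence_bound: float = 1e8):
    """Iterate a bounded cloud forward and take the terminal cloud as A.

    Reports d_H(theta(t, B0), A_est) along the run plus the invariance
    residual of one extra step (a global attractor is strictly invariant,
    so both directed distances between A_est and its one-step image should
    vanish).  If the cloud escapes ``divergence_bound`` the verdict is
    "no bounded attractor found".
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    dt = t_max / n_steps
    clouds = [B0]
    cloud = B0
    for _ in range(n_steps):
        cloud = _evolve_cloud(lambda x: sys.evolve(dt, x), cloud)
        clouds.append(cloud)
        if not np.all(np.isfinite(cloud.points)) or np.max(np.abs(cloud.points)) > divergence_bound:
            report = ConvergenceReport(history=[(0.0, float("inf"))], tol=tol, verdict="fail",
                                       message="no bounded attractor found: cloud diverged")
            return cloud, report
    A_est = cloud.deduplicated(dedup_tol)
    history = [(k * dt, directed_hausdorff(c, A_est)) for k, c in enumerate(clouds)]
    stepped = _evolve_cloud(lambda x: sys.evolve(dt, x), A_est)
    inv_resid = max(directed_hausdorff(stepped, A_est), directed_hausdorff(A_est, stepped))
    # convergence is judged by the distance of the penultimate cloud to A_est
    settled = history[-2][1] if len(history) > 1 else history[-1][1]
    if settled <= tol and inv_resid <= max(tol, 10 * dedup_tol):
        verdict = "pass"
    elif history[-1][1] <= history[0][1]:
        verdict = "inconclusive"
    else:
        verdict = "fail"
    report = ConvergenceReport(history=history, tol=tol, verdict=verdict,
                               invariance_residual=inv_resid)
    return A_est, report


def forward_convergence(flow, B: PointCloudSet, start, candidate: NonautonomousSetFibres,
                        horizon: Sequence, tol: float = 1e-6) -> ConvergenceReport:
    """Track d_H(evolved B, candidate fibre) as time runs forward.

    For a :class:`Process`, ``start`` is the initial time s and the
    candidate must have a fibre at each horizon time t (distance
    d_H(phi((s, t), B), A_t)).  For a :class:`SkewProductFlow`, ``start``
    is the initial parameter p and the candidate fibres are keyed by the
    horizon entries themselves (the caller aligns them with theta(t, p)).
    """
    history = []
    for t in horizon:
        if isinstance(flow, Process):
            evolved = _evolve_cloud(lambda x: flow.evolve(start, t, x), B)
        elif isinstance(flow, SkewProductFlow):
            evolved = _evolve_cloud(lambda x: flow.phi(t, start, x), B)
        else:
            raise TypeError("forward_convergence needs a Process or SkewProductFlow")
        history.append((t, directed_hausdorff(evolved, candidate.fibre(t))))
    final = history[-1][1]
    if final <= tol:
        verdict = "pass"
    elif final < history[0][1]:
        verdict = "inconclusive"
    else:
        verdict = "fail"
    return ConvergenceReport(history=history, tol=tol, verdict=verdict)


def pullback_convergence(flow, B: PointCloudSet, target, starts: Sequence,
                         tol: float = 1e-6, dedup_tol: float = 1e-6,
                         divergence_bound: float = 1e8):
    """Estimate the pullback fibre at ``target`` from receding start times.

    ``starts`` must recede strictly into the past (each earlier than the
    last).  The fibre estimate is the cloud evolved from the earliest
    start; the report lists the symmetric Hausdorff distance between
    successive clouds, which should shrink when a pullback attractor fibre
    exists at the target.
    """
    starts = list(starts)
    if any(b >= a for a, b in zip(starts, starts[1:])):
        raise ValueError("starts must recede strictly toward the past")
    if any(s > target for s in starts):
        raise ValueError("all starts must be <= target")
    clouds = []
    for s in starts:
        if isinstance(flow, Process):
            cloud = _evolve_cloud(lambda x: flow.evolve(s, target, x), B)
        elif isinstance(flow, SkewProductFlow):
            if flow.driving_theta_inv is None:
                raise ValueError("skew-product pullback needs an invertible driving system")
            l = target - s
            p_past = flow.driving_theta_inv(l, target)
            cloud = _evolve_cloud(lambda x: flow.phi(l, p_past, x), B)
        else:
            raise TypeError("pullback_convergence needs a Process or SkewProductFlow")
        clouds.append(cloud)
    history = [(starts[0], float("nan"))]
    diverged = False
    for s, prev, cur in zip(starts[1:], clouds, clouds[1:]):
        history.append((s, _symmetric_hausdorff(cur, prev)))
        if np.max(np.abs(cur.points)) > divergence_bound:
            diverged = True
    history = history[1:] if len(history) > 1 else history
    final_cloud = clouds[-1].deduplicated(dedup_tol)
    dists = [d for _, d in history if np.isfinite(d)]
    if diverged:
        verdict = "fail"
    elif dists and dists[-1] <= tol:
        verdict = "pass"
    elif len(dists) >= 2 and dists[-1] < dists[0]:
        verdict = "inconclusive"  # still contracting, horizon too shallow
    else:
        verdict = "fail"
    report = ConvergenceReport(history=history, tol=tol, verdict=verdict,
                               message="clouds grew under pullback" if diverged else "")
    return final_cloud, report


def random_pullback_estimate(rms: RandomMapSystem, omega_seed: int, depths: Sequence[int],
                             B: PointCloudSet, tol: float = 1e-9,
                             dedup_tol: float = 1e-9):
    """Estimate the random pullback attractor fibre A(omega) at index 0.

    For each depth k the cloud B is pushed through the k past symbols
    omega(-k), ..., omega(-1) of a fixed two-sided driving realization,
    i.e. phi(k, theta(-k, omega), B).  For a contracting family of maps the
    clouds converge to the attractor fibre at the present.
    """
    if rms.scheme.sided != "two":
        raise ValueError("random pullback needs a two-sided driving scheme (a past)")
    omega = SymbolSequence(n=rms.scheme.n, sided="two", scheme=rms.scheme, seed=omega_seed)
    clouds = []
    for k in depths:
        if k < 0:
            raise ValueError("depths must be nonnegative")
        cloud = B
        for i in range(-int(k), 0):
            sym = omega.read(i)
            cloud = _evolve_cloud(lambda x, _s=sym: rms.apply(_s, x), cloud)
        clouds.append((int(k), cloud))
    history = []
    for (k_prev, prev), (k_cur, cur) in zip(clouds, clouds[1:]):
        history.append((k_cur, _symmetric_hausdorff(cur, prev)))
    if not history:
        history = [(clouds[0][0], float("nan"))]
    final_cloud = clouds[-1][1].deduplicated(dedup_tol)
    dists = [d for _, d in history if np.isfinite(d)]
    if dists and dists[-1] <= tol:
        verdict = "pass"
    elif len(dists) >= 2 and dists[-1] < dists[0]:
        verdict = "inconclusive"  # still contracting, horizon too shallow
    else:
        verdict = "fail"
    report = ConvergenceReport(history=history, tol=tol, verdict=verdict,
                               message="" if verdict != "fail" else
                               "cloud separation grows with depth: maps are not contracting")
    return final_cloud, report


def transient_length(times: Sequence[float], states: np.ndarray,
                     reference_sets: Sequence[PointCloudSet], radius: float):
    """Segment a trajectory into residences near reference sets.

    The trajectory is "in" set i while its directed distance to the set is
    at most ``radius``.  Residences are returned as (set index, entry time,
    exit time or None when still inside at the end); long transients show
    up as long residences in sets that are eventually left.  Reference
    sets closer than 2 * radius to each other would make membership
    ambiguous and raise instead.
    """
    times = np.asarray(times, dtype=float)
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if states.shape[0] != times.shape[0]:
        states = states.T
    if np.any(np.diff(times) < 0):
        raise ValueError("trajectory must be time-sorted")
    refs = [s if isinstance(s, PointCloudSet) else PointCloudSet(s) for s in reference_sets]
    for i in range(len(refs)):
        for j in range(i + 1, len(refs)):
            gap = float(np.min(cdist(refs[i].points, refs[j].points)))
            if gap < 2 * radius:
                raise ValueError(
                    f"reference sets {i} and {j} overlap at radius {radius}: "
                    f"separation {gap:.3g} < {2 * radius:.3g}")
    membership = np.full(times.shape[0], -1, dtype=int)
    for i, ref in enumerate(refs):
        d = np.min(cdist(states, ref.points), axis=1)
        membership[d <= radius] = i
    residences = []
    current = -1
    entry = None
    for k, m in enumerate(membership):
        if m != current:
            if current != -1:
                residences.append((current, entry, float(times[k])))
            current = int(m)
            entry = float(times[k])
    if current != -1:
        residences.append((current, entry, None))
    return residences
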