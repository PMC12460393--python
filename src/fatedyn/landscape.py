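"""Continuous gene-regulatory dynamics and quasi-potential landscapes.

The chain implemented here runs from a reaction network to a landscape:

1.  A mass-action reaction network induces the species formation rate
    f(s) = sum_j k_j prod_i x_i^{nu_ij} (nu'_j - nu_j), the drift of the
    deterministic GRN ODE ds/dt = f(s).
2.  Stable cell states are the hyperbolic fixed points f(x*) = 0 whose
    Jacobian has only eigenvalues with negative real part.
3.  Molecular noise enters through the SDE
    dx = f(x) dt + g(x) dW_t with increment covariance
    E[dW_t dW_s] = eps * delta(t - s); ensembles of Euler-Maruyama paths
    stand in for a population of cells.
4.  The stationary population profile rho(x) yields the quasi-potential
    U_q(x) = -ln rho(x) (proportionality constant fixed to 1, minimum
    shifted to 0); its local minima are the "valleys" identified with cell
    fates, and a fate transition is a path's passage from one valley
    neighbourhood to another.
5.  Forward and backward transition paths can only coincide when the drift
    is a gradient field and the diffusion is constant; ``gradient_check``
    tests exactly that time-reversible form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp
from scipy.ndimage import minimum_filter

__all__ = [
    "ReactionNetwork",
    "SDEModel",
    "TrajectoryEnsemble",
    "DensityGrid",
    "QuasiPotentialGrid",
    "FixedPointReport",
    "FixedPoint",
    "Valley",
    "TransitionEvent",
    "species_formation_rate",
    "integrate_ode",
    "find_fixed_points",
    "simulate_sde",
    "estimate_density",
    "quasipotential",
    "find_valleys",
    "detect_transitions",
    "gradient_check",
    "GradientCheckReport",
]


# ---------------------------------------------------------------------------
# reaction networks

@dataclass
class ReactionNetwork:
    """A mass-action reaction network on N species.

    Each reaction j carries a reactant stoichiometry vector nu_j, a product
    stoichiometry vector nu'_j (nonnegative integers), and a rate constant
    k_j > 0; its mass-action rate at state x is k_j * prod_i x_i^{nu_ij}
    with the convention 0^0 = 1.
    """

    species: Sequence[str]
    reactions: Sequence[dict]  # {"nu": [...], "nu_prime": [...], "k": float}

    def __post_init__(self) -> None:
        N = len(self.species)
        for r in self.reactions:
            nu = np.asarray(r["nu"], dtype=float)
            nup = np.asarray(r["nu_prime"], dtype=float)
            if nu.shape != (N,) or nup.shape != (N,):
                raise ValueError("stoichiometry vectors must have one entry per species")
            if np.any(nu < 0) or np.any(nup < 0) or np.any(nu != nu.astype(int)) \
                    or np.any(nup != nup.astype(int)):
                raise ValueError("stoichiometries must be nonnegative integers")
            if not r["k"] > 0:
                raise ValueError("rate constants must be positive")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def rate(self, s) -> np.ndarray:
        return species_formation_rate(self, s)


def species_formation_rate(net: ReactionNetwork, s, allow_negative: bool = False) -> np.ndarray:
    """Net mass-action formation rate of every species at state s."""
    x = np.asarray(s, dtype=float)
    if x.shape != (net.n_species,):
        raise ValueError(f"state must have {net.n_species} entries, got shape {x.shape}")
    if not allow_negative and np.any(x < 0):
        raise ValueError("negative abundance (pass allow_negative=True to evaluate anyway)")
    out = np.zeros(net.n_species)
    for r in net.reactions:
        nu = np.asarray(r["nu"], dtype=float)
        nup = np.asarray(r["nu_prime"], dtype=float)
        propensity = r["k"] * np.prod(np.power(x, nu))  # 0**0 == 1 under numpy
        out += propensity * (nup - nu)
    return out


def integrate_ode(rate: Callable[[np.ndarray], np.ndarray], x0, t_grid,
                  rtol: float = 1e-10, atol: float = 1e-12,
                  method: str = "DOP853") -> np.ndarray:
    """Solve ds/dt = rate(s) on the given grid; returns (len(t_grid), d)."""
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    sol = solve_ivp(lambda t, y: np.atleast_1d(np.asarray(rate(y), dtype=float)),
                    (t_grid[0], t_grid[-1]), x0, t_eval=t_grid,
                    rtol=rtol, atol=atol, method=method)
    if not sol.success:
        last = sol.t[-1] if sol.t.size else t_grid[0]
        raise RuntimeError(f"ODE integration failed after t = {last}: {sol.message}")
    return sol.y.T


# ---------------------------------------------------------------------------
# fixed points

@dataclass
class FixedPoint:
    location: np.ndarray
    eigenvalues: np.ndarray
    classification: str  # stable | unstable | nonhyperbolic
    residual: float


@dataclass
class FixedPointReport:
    points: list

    def stable(self) -> list:
        return [p for p in self.points if p.classification == "stable"]

    def locations(self) -> np.ndarray:
        return np.stack([p.location for p in self.points]) if self.points else np.empty((0,))


def _fd_jacobian(f: Callable, x: np.ndarray, h_scale: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    d = x.size
    J = np.empty((d, d))
    for j in range(d):
        h = h_scale * (1.0 + abs(x[j]))
        e = np.zeros(d)
        e[j] = h
        J[:, j] = (np.atleast_1d(f(x + e)) - np.atleast_1d(f(x - e))) / (2 * h)
    return J


def find_fixed_points(rate: Callable, guesses: Sequence, tol: float = 1e-9,
                      jac: Optional[Callable] = None, eig_tol: float = 1e-6,
                      dedup_tol: float = 1e-6) -> FixedPointReport:
    """Root-find f(x*) = 0 from each guess and classify by the Jacobian.

    Stability follows the eigenvalue-real-part criterion: all real parts
    below -eig_tol is stable, any above +eig_tol unstable, otherwise
    nonhyperbolic.  Guesses that converge to the same root (within
    ``dedup_tol``) are merged; guesses that fail to converge are dropped.
    """
    if not len(guesses):
        raise ValueError("at least one guess is required")
    f = lambda x: np.atleast_1d(np.asarray(rate(np.atleast_1d(x)), dtype=float))
    points: list[FixedPoint] = []
    for g in guesses:
        g = np.atleast_1d(np.asarray(g, dtype=float))
        sol = optimize.root(f, g, tol=tol * 1e-2 if tol > 0 else None)
        if not sol.success:
            continue
        x_star = np.atleast_1d(sol.x)
        resid = float(np.max(np.abs(f(x_star))))
        if resid > tol:
            continue
        if points and min(np.linalg.norm(p.location - x_star) for p in points) <= dedup_tol:
            continue
        J = np.asarray(jac(x_star), dtype=float) if jac is not None else _fd_jacobian(f, x_star)
        eig = np.linalg.eigvals(J)
        re = eig.real
        if np.all(re < -eig_tol):
            cls = "stable"
        elif np.any(np.abs(re) <= eig_tol):
            cls = "nonhyperbolic"
        else:
            cls = "unstable"
        points.append(FixedPoint(location=x_star, eigenvalues=eig, classification=cls,
                                 residual=resid))
    points.sort(key=lambda p: tuple(p.location))
    return FixedPointReport(points=points)


# ---------------------------------------------------------------------------
# SDE simulation

@dataclass
class SDEModel:
    """dx = f(x; t) dt + g(x; t) dW_t with E[dW_t dW_s] = eps * delta(t - s).

    ``drift`` and ``diffusion`` are called with a state array of shape
    (n_paths, dim) and the time, and must broadcast accordingly; the
    diffusion may return a scalar, a (n_paths, dim) array (diagonal), or a
    (n_paths, dim, dim) array (full matrix).  The noise strength ``eps``
    scales the increment variance: increment = g(x, t) * sqrt(eps * dt) * xi
    with xi standard normal (Ito / Euler-Maruyama convention).

    ``nonneg`` selects the boundary policy for gene-expression state
    spaces: "reflect" clips paths at 0 (counting the clips), "none" leaves
    paths on all of R^d.
    """

    drift: Callable
    diffusion: Callable
    eps: float = 1.0
    dim: int = 1
    theta: Optional[dict] = None
    nonneg: str = "none"
    potential: Optional[Callable] = None  # scalar U with drift = -grad U, if declared
    name: str = ""

    def __post_init__(self) -> None:
        if self.eps < 0:
            raise ValueError("noise strength eps must be >= 0")
        if self.nonneg not in ("reflect", "none"):
            raise ValueError("nonneg policy must be 'reflect' or 'none'")


@dataclass
class TrajectoryEnsemble:
    """Paths of shape (n_paths, n_times, dim) on a strictly increasing grid."""

    t: np.ndarray
    paths: np.ndarray
    seed: Optional[int] = None
    model: Optional[SDEModel] = None
    clip_count: int = 0
    flagged: Optional[np.ndarray] = None  # paths that went nonfinite

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.paths = np.asarray(self.paths, dtype=float)
        if self.paths.ndim != 3:
            raise ValueError("paths must have shape (n_paths, n_times, dim)")
        if self.paths.shape[1] != self.t.size:
            raise ValueError("time grid and path length disagree")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.flagged is None:
            self.flagged = np.zeros(self.paths.shape[0], dtype=bool)

    @property
    def n_paths(self) -> int:
        return self.paths.shape[0]

    @property
    def dim(self) -> int:
        return self.paths.shape[2]

    def to_dataframe(self):
        import pandas as pd
        n_paths, n_t, d = self.paths.shape
        recs = {
            "path_id": np.repeat(np.arange(n_paths), n_t),
            "t": np.tile(self.t, n_paths),
        }
        flat = self.paths.reshape(n_paths * n_t, d)
        for j in range(d):
            recs[f"x_{j + 1}"] = flat[:, j]
        return pd.DataFrame(recs)


def simulate_sde(model: SDEModel, x0, t_grid, n_paths: int, seed: int) -> TrajectoryEnsemble:
    """Euler-Maruyama: x_{k+1} = x_k + f dt + g sqrt(eps dt) xi, seeded.

    ``x0`` may be a single state (broadcast to all paths) or one state per
    path.  Paths that go nonfinite are frozen and flagged; the run
    continues for the rest of the ensemble.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    d = model.dim
    x0 = np.asarray(x0, dtype=float)
    if x0.ndim <= 1:
        X = np.broadcast_to(np.atleast_1d(x0), (n_paths, d)).copy()
    else:
        if x0.shape != (n_paths, d):
            raise ValueError(f"per-path x0 must have shape ({n_paths}, {d})")
        X = x0.copy()
    rng = np.random.default_rng(seed)
    out = np.empty((n_paths, t_grid.size, d))
    out[:, 0] = X
    alive = np.ones(n_paths, dtype=bool)
    clip_count = 0
    for k in range(t_grid.size - 1):
        dt = t_grid[k + 1] - t_grid[k]
        xi = rng.standard_normal((n_paths, d))
        f = np.broadcast_to(np.asarray(model.drift(X, t_grid[k]), dtype=float), (n_paths, d))
        g = np.asarray(model.diffusion(X, t_grid[k]), dtype=float)
        amp = np.sqrt(model.eps * dt)
        if g.ndim == 3:  # full diffusion matrix per path
            noise = np.einsum("pij,pj->pi", g, xi) * amp
        else:
            noise = np.broadcast_to(g, (n_paths, d)) * xi * amp
        X_new = X + f * dt + noise
        if model.nonneg == "reflect":
            below = X_new < 0
            clip_count += int(np.sum(below))
            X_new = np.where(below, 0.0, X_new)
        bad = ~np.all(np.isfinite(X_new), axis=1)
        newly_bad = bad & alive
        alive &= ~bad
        X = np.where(alive[:, None], X_new, X)
        out[:, k + 1] = np.where(alive[:, None], X_new, out[:, k])
        out[newly_bad, k + 1] = np.nan
    flagged = ~alive
    if np.any(flagged):
        warnings.warn(f"{int(flagged.sum())} path(s) went nonfinite and were frozen")
    return TrajectoryEnsemble(t=t_grid, paths=out, seed=seed, model=model,
                              clip_count=clip_count, flagged=flagged)


# ---------------------------------------------------------------------------
# density, quasi-potential, valleys, transitions

@dataclass
class DensityGrid:
    """Histogram density on a regular grid, normalized to integrate to 1."""

    edges: list  # one edge array per dimension
    rho: np.ndarray
    n_samples: int

    @property
    def centers(self) -> list:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    @property
    def bin_volume(self) -> float:
        return float(np.prod([e[1] - e[0] for e in self.edges]))

    def integral(self) -> float:
        return float(self.rho.sum() * self.bin_volume)


def estimate_density(ens: TrajectoryEnsemble, time_index: Optional[int] = None,
                     burn_in: Optional[float] = None, bins=64,
                     ranges=None) -> DensityGrid:
    """Histogram estimate of the population profile rho.

    Either a single ``time_index`` (the profile rho(x, t) of the ensemble
    at that time) or a ``burn_in`` fraction (pool all samples after the
    burn-in, estimating the stationary rho(x)) must be given.
    """
    if (time_index is None) == (burn_in is None):
        raise ValueError("give exactly one of time_index or burn_in")
    good = ~ens.flagged
    if time_index is not None:
        samples = ens.paths[good, time_index, :]
    else:
        if not 0 <= burn_in < 1:
            raise ValueError("burn_in must be a fraction in [0, 1)")
        k0 = int(np.ceil(burn_in * ens.t.size))
        samples = ens.paths[good, k0:, :].reshape(-1, ens.dim)
    samples = samples[np.all(np.isfinite(samples), axis=1)]
    if samples.shape[0] == 0:
        raise ValueError("no samples selected")
    hist, edges = np.histogramdd(samples, bins=bins, range=ranges, density=True)
    return DensityGrid(edges=[np.asarray(e) for e in edges], rho=hist,
                       n_samples=samples.shape[0])


@dataclass
class Valley:
    """A local minimum of the quasi-potential (a candidate cell fate)."""

    location: np.ndarray
    index: tuple
    depth: float  # U_q at the minimum


@dataclass
class QuasiPotentialGrid:
    """U_q = -ln max(rho, floor), shifted so min U_q = 0."""

    edges: list
    rho: np.ndarray
    U: np.ndarray
    floor: float
    n_samples: int

    @property
    def centers(self) -> list:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]


def quasipotential(density: DensityGrid, floor: Optional[float] = None) -> QuasiPotentialGrid:
    """Quasi-potential of a normalized density.

    The regularization floor keeps U_q finite on empty bins; its default,
    0.1 / (n_samples * bin volume), is a tenth of the density a single
    sample would contribute, so it only matters where the histogram saw
    essentially nothing.
    """
    if floor is None:
        floor = 0.1 / (density.n_samples * density.bin_volume)
    if not floor > 0:
        raise ValueError("regularization floor must be positive")
    integral = density.integral()
    if abs(integral - 1.0) > 1e-6:
        raise ValueError(f"density must integrate to 1 (got {integral})")
    U = -np.log(np.maximum(density.rho, floor))
    U = U - U.min()
    return QuasiPotentialGrid(edges=density.edges, rho=density.rho, U=U,
                              floor=floor, n_samples=density.n_samples)


def find_valleys(qp: QuasiPotentialGrid, min_separation: float = 0.0) -> list[Valley]:
    """Strict discrete local minima of U_q, merged within ``min_separation``.

    A grid point is a valley when its U_q is strictly smaller than all grid
    neighbours (the discrete analogue of a vanishing gradient with locally
    increasing neighbourhood).  A constant landscape has no strict minima:
    an empty list is returned with a degeneracy warning.
    """
    U = qp.U
    if np.ptp(U) == 0:
        warnings.warn("quasi-potential is constant: no valleys identifiable (degenerate)")
        return []
    footprint = np.ones((3,) * U.ndim, dtype=bool)
    footprint[(1,) * U.ndim] = False
    neighbour_min = minimum_filter(U, footprint=footprint, mode="nearest")
    minima_idx = np.argwhere(U < neighbour_min)
    centers = qp.centers
    candidates = [Valley(location=np.asarray([centers[d][i] for d, i in enumerate(idx)]),
                         index=tuple(int(i) for i in idx), depth=float(U[tuple(idx)]))
                  for idx in minima_idx]
    candidates.sort(key=lambda v: v.depth)
    kept: list[Valley] = []
    for v in candidates:
        if all(np.linalg.norm(v.location - w.location) > min_separation for w in kept):
            kept.append(v)
    kept.sort(key=lambda v: tuple(v.location))
    return kept


@dataclass
class TransitionEvent:
    """A fate transition: a path leaves valley i and settles in valley j."""

    path_id: int
    source: int
    destination: int
    exit_time: float
    entry_time: float

    def __post_init__(self) -> None:
        if self.source == self.destination:
            raise ValueError("a transition needs distinct source and destination valleys")
        if self.entry_time < self.exit_time:
            raise ValueError("entry time must be >= exit time")


def detect_transitions(ens: TrajectoryEnsemble, valleys: Sequence[Valley],
                       radius: float) -> list[TransitionEvent]:
    """Valley-to-valley passages of every path in the ensemble.

    A path is a member of valley i while within ``radius`` of its location;
    an event is emitted when the membership changes from i to j != i, with
    the time it left i's neighbourhood and the time it entered j's.
    Overlapping valley neighbourhoods (centres closer than 2 * radius)
    would make membership ambiguous and raise instead.
    """
    if len(valleys) < 2:
        return []
    locs = np.stack([v.location for v in valleys])
    for i in range(len(valleys)):
        for j in range(i + 1, len(valleys)):
            if np.linalg.norm(locs[i] - locs[j]) < 2 * radius:
                raise ValueError(
                    f"valleys {i} and {j} overlap at radius {radius}")
    events: list[TransitionEvent] = []
    for pid in range(ens.n_paths):
        if ens.flagged[pid]:
            continue
        traj = ens.paths[pid]  # (n_t, d)
        dists = np.linalg.norm(traj[:, None, :] - locs[None, :, :], axis=2)
        nearest = np.argmin(dists, axis=1)
        inside = dists[np.arange(traj.shape[0]), nearest] <= radius
        member = np.where(inside, nearest, -1)
        last_valley = -1
        exit_time = None
        for k, m in enumerate(member):
            if m == -1:
                continue
            if last_valley == -1:
                last_valley = int(m)
            elif m != last_valley:
                events.append(TransitionEvent(path_id=pid, source=last_valley,
                                              destination=int(m),
                                              exit_time=float(exit_time),
                                              entry_time=float(ens.t[k])))
                last_valley = int(m)
            exit_time = float(ens.t[k])
    return events


# ---------------------------------------------------------------------------
# time-reversible form check

@dataclass
class GradientCheckReport:
    constant_diffusion: bool
    gradient_drift: bool
    max_diffusion_variation: float
    max_jacobian_asymmetry: float
    tol: float

    @property
    def reversible_form(self) -> bool:
        return self.constant_diffusion and self.gradient_drift

    @property
    def verdict(self) -> str:
        return "time-reversible form" if self.reversible_form else "irreversible form"


def gradient_check(model: SDEModel, probes: Sequence, tol: float = 1e-6) -> GradientCheckReport:
    """Test the time-reversible form: gradient drift and constant diffusion.

    Forward and backward transition paths between valleys can only coincide
    when the drift is a (negative) gradient field and the diffusion is
    state-independent.  Diffusion constancy is checked by comparing g across
    the probe states; the gradient property via symmetry of the
    finite-difference Jacobian of f (equality of mixed partials).  Every
    smooth one-dimensional drift is a gradient, so d = 1 passes that clause
    automatically.
    """
    probes = [np.atleast_1d(np.asarray(p, dtype=float)) for p in probes]
    if not probes:
        raise ValueError("at least one probe state is required")
    d = model.dim

    def g_at(x):
        return np.asarray(model.diffusion(x[None, :], 0.0), dtype=float).ravel()

    g0 = g_at(probes[0])
    g_var = max(float(np.max(np.abs(g_at(x) - g0))) for x in probes)

    def f_single(x):
        return np.asarray(model.drift(x[None, :], 0.0), dtype=float).reshape(d)

    if d == 1:
        asym = 0.0
    else:
        asym = 0.0
        for x in probes:
            J = _fd_jacobian(f_single, x)
            asym = max(asym, float(np.max(np.abs(J - J.T))))
    return GradientCheckReport(constant_diffusion=g_var <= tol,
                               gradient_drift=asym <= tol,
                               max_diffusion_variation=g_var,
                               max_jacobian_asymmetry=asym, tol=tol)
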