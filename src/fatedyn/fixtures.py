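"""Registry of built-in worked-example systems.

Every fixture is a small, closed-form system whose behaviour is known
exactly, used both as documentation and as the substrate of the executable
axiom checks: exponential growth (the canonical autonomous system), the
aging-growth population (a genuinely nonautonomous process and its
skew-product form), the shift on symbol sequences with a fair-coin
Bernoulli scheme, random map compositions (a quadratic/halving pair and an
affine contraction with a known pullback limit), an Ornstein-Uhlenbeck
model and a double-well landscape model, a birth-death reaction network,
and a two-gene Boolean network with a single four-state cycle.
"""

from __future__ import annotations

import numpy as np

from .boolean import BooleanNetwork
from .core import AutonomousSystem, Process, SkewProductFlow
from .driving import BernoulliScheme, shift_system
from .landscape import ReactionNetwork, SDEModel
from .random_systems import RandomMapSystem
from .timesets import TimeStructure

__all__ = ["FIXTURES", "load_fixture", "list_fixtures", "fixture_description",
           "random_map_system_from_spec", "load_system_spec"]


def _positive_sampler(lo: float = 0.1, hi: float = 10.0):
    def sample(rng: np.random.Generator, n: int):
        return [np.asarray([v]) for v in rng.uniform(lo, hi, size=n)]
    return sample


def _exp_growth() -> AutonomousSystem:
    return AutonomousSystem(
        dim=1,
        theta=lambda l, x: np.asarray(x, dtype=float) * np.exp(l),
        time=TimeStructure(kind="continuous", t0=0.0, span=3.0),
        state_sampler=_positive_sampler(),
        name="exp_growth",
    )


def _aging_growth_process() -> Process:
    # growth f'(t) = f(t)/t on T = [1, inf): phi((s,t), x) = (t/s) x
    return Process(
        dim=1,
        phi=lambda s, t, x: (t / s) * np.asarray(x, dtype=float),
        time=TimeStructure(kind="continuous", t0=1.0, span=5.0),
        state_sampler=_positive_sampler(),
        name="aging_growth_process",
    )


def _aging_growth_skew() -> SkewProductFlow:
    # same dynamics driven by time itself: phi(l, p, x) = ((l+p)/p) x, theta(l, p) = l + p
    def param_sampler(rng: np.random.Generator, n: int):
        return list(rng.uniform(0.5, 5.0, size=n))

    return SkewProductFlow(
        dim=1,
        phi=lambda l, p, x: ((l + p) / p) * np.asarray(x, dtype=float),
        driving_theta=lambda l, p: l + p,
        driving_theta_inv=lambda l, p: p - l,
        param_sampler=param_sampler,
        time=TimeStructure(kind="continuous", t0=0.0, span=5.0),
        state_sampler=_positive_sampler(),
        param_dim=1,
        name="aging_growth_skew",
    )


def _relax_process() -> Process:
    # x' = -x + 1 solved exactly: phi((s,t), x) = 1 + (x - 1) e^{-(t-s)}
    def sampler(rng: np.random.Generator, n: int):
        return [np.asarray([v]) for v in rng.uniform(-5.0, 5.0, size=n)]

    return Process(
        dim=1,
        phi=lambda s, t, x: 1.0 + (np.asarray(x, dtype=float) - 1.0) * np.exp(-(t - s)),
        time=TimeStructure(kind="continuous", t0=0.0, span=5.0),
        state_sampler=sampler,
        name="relax_process",
    )


def _shift_space() -> AutonomousSystem:
    return shift_system(BernoulliScheme(p=(0.5, 0.5), sided="two"))


def _bernoulli_2() -> BernoulliScheme:
    return BernoulliScheme(p=(0.5, 0.5), sided="two")


def _random_quadratic_halving() -> RandomMapSystem:
    return RandomMapSystem(
        maps=[lambda x: np.asarray(x, dtype=float) / 2.0,
              lambda x: np.asarray(x, dtype=float) ** 2],
        domain=(0.0, 1.0),
        scheme=BernoulliScheme(p=(0.5, 0.5), sided="one"),
        name="random_quadratic_halving",
    )


def _affine_random_contraction() -> RandomMapSystem:
    # x -> x/2 + b/2 with b in {0, 1}: pullback limit sum_{k>=1} 2^{-k} b(-k)
    return RandomMapSystem(
        maps=[lambda x: np.asarray(x, dtype=float) / 2.0,
              lambda x: np.asarray(x, dtype=float) / 2.0 + 0.5],
        domain=(0.0, 1.0),
        scheme=BernoulliScheme(p=(0.5, 0.5), sided="two"),
        name="affine_random_contraction",
    )


def _ou_process() -> SDEModel:
    return SDEModel(drift=lambda x, t: -x, diffusion=lambda x, t: 1.0, eps=2.0,
                    dim=1, nonneg="none",
                    potential=lambda x: 0.5 * np.sum(np.asarray(x) ** 2, axis=-1),
                    name="ou_process")


def _double_well() -> SDEModel:
    return SDEModel(drift=lambda x, t: x - x ** 3, diffusion=lambda x, t: 1.0, eps=0.5,
                    dim=1, nonneg="none",
                    potential=lambda x: np.sum(np.asarray(x) ** 4 / 4 - np.asarray(x) ** 2 / 2,
                                               axis=-1),
                    name="double_well")


def _birth_death() -> ReactionNetwork:
    return ReactionNetwork(species=["A"],
                           reactions=[{"nu": [0], "nu_prime": [1], "k": 2.0},
                                      {"nu": [1], "nu_prime": [0], "k": 1.0}])


def _net2_k1() -> BooleanNetwork:
    # g1' = NOT g2, g2' = g1: a single 4-cycle through all states
    return BooleanNetwork(N=2, K=1,
                          inputs=np.asarray([[1], [0]]),
                          tables=np.asarray([[1, 0], [0, 1]]),
                          seed=None)


FIXTURES: dict = {
    "exp_growth": (_exp_growth,
                   "autonomous exponential growth theta(l, x) = x e^l on (0, inf)"),
    "aging_growth_process": (_aging_growth_process,
                             "nonautonomous growing population phi((s,t), x) = (t/s) x"),
    "aging_growth_skew": (_aging_growth_skew,
                          "skew-product form of the aging growth: phi(l,p,x) = ((l+p)/p) x, theta(l,p)=l+p"),
    "relax_process": (_relax_process,
                      "linear relaxation x' = -x + 1 as a process (pullback target {1})"),
    "shift_space": (_shift_space,
                    "left shift on bi-infinite binary sequences as an autonomous system"),
    "bernoulli_2": (_bernoulli_2,
                    "two-sided fair-coin Bernoulli scheme p = (1/2, 1/2)"),
    "random_quadratic_halving": (_random_quadratic_halving,
                                 "random composition of x/2 and x^2 on [0, 1] driven one-sided"),
    "affine_random_contraction": (_affine_random_contraction,
                                  "random affine contraction x/2 + b/2, b in {0,1}, two-sided driving"),
    "ou_process": (_ou_process,
                   "Ornstein-Uhlenbeck SDE: drift -x, unit diffusion, noise strength 2"),
    "double_well": (_double_well,
                    "double-well landscape SDE: drift x - x^3, unit diffusion, noise strength 0.5"),
    "birth_death": (_birth_death,
                    "birth-death reaction network: 0 -> A at rate 2, A -> 0 at rate 1"),
    "net2_k1": (_net2_k1,
                "two-gene Boolean network g1' = NOT g2, g2' = g1 (one 4-cycle)"),
}


def load_fixture(name: str):
    """Build a registered fixture by name; unknown names list the registry."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}")
    builder, _ = FIXTURES[name]
    return builder()


def fixture_description(name: str) -> str:
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(sorted(FIXTURES))}")
    return FIXTURES[name][1]


def list_fixtures() -> list[str]:
    return sorted(FIXTURES)


# ---------------------------------------------------------------------------
# JSON dialect loaders

def random_map_system_from_spec(spec: dict) -> RandomMapSystem:
    """Build a RandomMapSystem from {"maps": [...], "domain": [lo, hi], "p": [...]}.

    Map entries: {"kind": "affine", "a": ..., "b": ...} for x -> a x + b, or
    {"kind": "power", "exponent": q} for x -> x^q.
    """
    maps = []
    for m in spec["maps"]:
        if m["kind"] == "affine":
            a, b = float(m["a"]), float(m["b"])
            maps.append(lambda x, _a=a, _b=b: _a * np.asarray(x, dtype=float) + _b)
        elif m["kind"] == "power":
            q = float(m["exponent"])
            maps.append(lambda x, _q=q: np.asarray(x, dtype=float) ** _q)
        else:
            raise ValueError(f"unknown map kind {m['kind']!r}")
    lo, hi = spec.get("domain", (0.0, 1.0))
    p = spec.get("p", [1.0 / len(maps)] * len(maps))
    sided = spec.get("sided", "one")
    return RandomMapSystem(maps=maps, domain=(float(lo), float(hi)),
                           scheme=BernoulliScheme(p=tuple(p), sided=sided))


def load_system_spec(spec: dict):
    """Load {"kind": ..., "fixture": name} or an inline random-map spec."""
    if "fixture" in spec:
        return load_fixture(spec["fixture"])
    if spec.get("kind") == "random_maps":
        return random_map_system_from_spec(spec)
    raise ValueError("spec must name a fixture or inline a 'random_maps' system")
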