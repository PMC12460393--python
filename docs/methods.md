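# Methods

This note documents the models implemented in `fatedyn`, the conventions
and parameters they depend on, what the built-in synthetic systems do and
do not exercise, and the numerical choices made where the design was
genuinely open.

## Time structures and sampled axiom checks

All systems are clocked by a concrete time set `T = [t0, ∞)` over the
reals or the integers, with durations `(s, t)`, `s ≤ t`, and duration
lengths `l = t − s` forming the nonnegative cone of an additive semigroup
(`TimeStructure`). Abstract totally ordered semigroups beyond these two
cases are deliberately out of scope: every worked example lives in `ℝ` or
`ℤ`, and an abstract-semigroup layer would add machinery without an
executable payoff.

Axioms are verified *by sampling*, not symbolically, because evolution
maps are opaque callables. `check_axioms` draws `n` tuples (default 1000)
from a seeded `numpy` generator over the structure's sampling window
(`[t0, t0 + span]`, default span 5 — wide enough to exercise nonlinearity,
narrow enough that exponential fixtures stay within floating range) and
reports the worst *relative* residual `|lhs − rhs| / (1 + |lhs|)` with the
witness tuple. The default tolerance 1e−9 is seven orders above double
round-off, so an axiom that holds analytically passes with residual
`~1e−16` while any structural violation (e.g. `(t+s)² ≠ t² + s²`) fails by
many orders. Zero-width sampling windows are a configuration error rather
than a vacuous pass.

Time-translation invariance is *not* an axiom of a process — genuinely
nonautonomous processes must fail it — so it is checked only on request,
and passing it is exactly the precondition for the duration-length
conversion `θ(l, x) := φ((s, s+l), x)`, which is otherwise ill-defined and
refused with a witness.

Backward time is supported only where the system declares it
(two-sided shift schemes; the optional inverse driving map of a
skew-product flow); everything else is forward-only, matching the fact
that cocycles are often defined only on the nonnegative cone.

## Bernoulli driving and counter-based realizations

The driving noise model is the Bernoulli scheme: i.i.d. symbols with a
positive probability vector `p` (validated to sum to 1 within 1e−12), the
left shift as dynamics, and the product measure on cylinder sets. Symbol
sequences are conceptually infinite but a cocycle only ever reads finitely
many entries, so a realization is represented by an optional materialized
window plus *counter-based* lazy extension: the symbol at index `i` is a
pure function of `(scheme, seed, i)` through a splitmix64-style integer
hash mapped through the inverse CDF of `p`. This construction is the one
design point where a hand-rolled primitive replaces a library generator:
sequential generators (PCG64 etc.) produce values in draw order, so
extending a window in a different order would change already-observed
symbols and break the consistency invariant the cocycle checks rely on.
The hash is vectorized over uint64 arrays (wraparound is the intended
modular arithmetic) and its output passes the marginal-frequency checks at
`n = 10^5` with four-standard-error bands.

Measure preservation of the shift is checked two ways: analytically — the
preimage of a cylinder at `z` is the cylinder at `z + t`, whose measure is
the same product, so the identity is exact by construction — and
empirically, as a binomial z-score of the frequency of
`σ^t(ω) ∈ C` over seeded paths. Statistical verdicts use a fixed z-score
threshold (default 4, i.e. a ~6e−5 false-alarm rate per check) and report
the score itself rather than a p-value, keeping pass/fail reproducible at
desk scale.

## Random dynamical systems

The canonical random system composes a finite family of self-maps of a
box, the map at each step chosen by the next driving symbol, with
`φ(0, ω, x) = x`. Because function composition is associative this cocycle
is *perfect* — the cocycle identity holds for every realization — and the
checker asserts a residual of exactly zero for such systems (tolerances
exist only for cocycles with floating-point internal state). Crude
cocycles, whose identity holds only almost surely with `s`- or
`(s,t)`-dependent exceptional sets, are excluded: almost-sure statements
over uncountable exceptional sets are not testable by finite sampling, and
we prefer an honest omission to a pretend check.

`degenerate_to_deterministic` decides noise-independence by probing
sampled `(t, x)` against pairs of independent realizations; this is a
sampled decision, not a proof, and both the probe count and tolerance are
caller-visible. Refusal carries the witness `(ω₁, ω₂, t, x)`.

Domain invariance of each map (`f_i(D) ⊆ D`) is spot-checked on 64 sampled
points at construction; continuity is not certified.

## Attractors on point clouds

Compact sets are modelled by finite point clouds and attraction by the
directed Hausdorff distance, computed exactly over the clouds via pairwise
distances. This is the desk-scale surrogate for "attracts all bounded
sets": a seeded sample of a box stands in for the box, and the sampling
error is visible in the reported distances rather than hidden.

- *Global*: iterate the cloud forward (default 30 steps), take the
  deduplicated terminal cloud as the estimate, and report both the
  convergence history and the one-step invariance residual
  `max(d_H(θ(Δ)A, A), d_H(A, θ(Δ)A))`. A cloud escaping the divergence
  bound (default 1e8) yields the verdict "no bounded attractor found".
- *Forward*: distances to a user-supplied candidate family of fibres along
  a horizon (the moving-target notion).
- *Pullback*: evolve a fixed cloud from progressively earlier starts to a
  fixed target time; successive-cloud distances should contract
  (fixed-target notion). For autonomous systems wrapped as processes this
  provably coincides with the forward estimate, and the tests assert it.
- *Random pullback*: fix a two-sided driving realization, push the cloud
  through the `k` past symbols `ω(−k)…ω(−1)` for increasing depth `k`.
  For the affine contraction `x ↦ x/2 + b_ω/2` the depth-`k` fibre is the
  truncated dyadic series `Σ_{i≤k} 2^{−i} b_{ω(−i)}`, which the estimate
  reproduces bit-for-bit (both computations are exact dyadic arithmetic
  for `k ≤ 52`).

Verdicts are three-valued: *pass* (below tolerance), *fail* (diverging or
non-contracting), *inconclusive* (still contracting at the deepest
horizon) — pullback limits are asymptotic and attractors are technically
never reached, so a shallow horizon should not masquerade as a failure.
The family of test sets for random attractors is fixed to constant-in-ω
bounded clouds; tempered families are not implemented. Random-attractor
statements are almost-sure over realizations; the estimators evaluate
single seeded realizations and small ensembles and cannot certify
almost-sure claims — an explicit limitation, not a silent approximation.

Deduplication of attractor clouds uses a 1e−6 metric tolerance by default.
`transient_length` segments a trajectory into residences within a radius
of reference sets, refusing when two sets come within `2 × radius`
(membership would be ambiguous); long transients appear as long residences
that eventually end.

## Boolean networks

Networks are the synchronous-deterministic NK model only: each of `N`
genes reads `K` *distinct* inputs (distinctness is a documented choice;
self-inputs are allowed) through a uniformly drawn truth table. Truth
tables are indexed big-endian in the listed input order. Exhaustive
enumeration builds the full successor array on `2^N` states (refusing
above `N = 20`, ~10^6 states), peels transient states by repeated
in-degree-zero removal, walks the remaining states into cycles, and
propagates basin labels backward; the whole analysis is vectorized over
the state space and independently verified in the tests against a
per-state orbit-following oracle. Cycles are canonicalized by rotating the
lexicographically smallest state code first. Perturbations are single-bit
flips applied to cycle states (the natural reading of "return to a cycle
after perturbation"); flipping arbitrary transient states would be a
straightforward extension but is not implemented.

## Landscape chain

*Drift.* Mass-action rates follow the standard form
`f(s) = Σ_j k_j ∏_i x_i^{ν_ij} (ν'_j − ν_j)` with the `0^0 = 1`
convention, so zeroth-order reactions fire at `x = 0`. General (non
mass-action) rate functions can be supplied as plain callables wherever a
drift is accepted.

*Fixed points.* Root-finding from user guesses (scipy's hybrid solver),
deduplication within 1e−6, Jacobian by central differences with step
`1e−6 (1 + |x_j|)` unless supplied analytically. "Stable" means all
eigenvalue *real parts* below −1e−6; within ±1e−6 of zero is
"nonhyperbolic". The real-part convention covers complex spectra; an
eigenvalue criterion stated for real eigenvalues is interpreted, not
silently assumed. Time-dependent drifts are simulated but refused for
fixed-point analysis.

*SDE.* Euler–Maruyama in the Itô interpretation (Stratonovich is not
offered — the choice is declared rather than left implicit):
`x_{k+1} = x_k + f(x_k, t_k) Δt + g(x_k, t_k) √(ε Δt) ξ_k`. The noise
strength `ε` is the variance scale of the Wiener increment
(`E[dW²] = ε dt`), kept separate from the state-dependent amplitude `g` so
the `ε → 0` deterministic limit is a single parameter. `g` may be scalar,
diagonal, or a full matrix. With `g = 0` the scheme reduces *exactly*
(bitwise) to explicit Euler. Gene-expression state spaces are
nonnegative; the boundary policy is configurable ("reflect" clips at 0 and
counts clips) and the landscape fixtures, which live on all of `ℝ`, use
"none". Nonfinite paths are frozen and flagged; the run continues.

*Quasi-potential.* The population profile is a histogram (not a kernel
estimate: bandwidth choice would add a tuning knob, and the histogram's
bin width is already the resolution limit of valley identification),
normalized to integrate to 1. `U_q = −ln max(ρ, floor)` with the
proportionality constant fixed to 1 and the minimum shifted to 0 (only
differences of `U_q` are meaningful). The floor defaults to
`0.1 / (n_samples × bin volume)` — a tenth of one sample's density — so
it only regularizes bins the data never visited; near point attractors the
density is singular in the zero-noise limit and the floor keeps `U_q`
finite, with its value reported. Valleys are *strict* discrete local
minima (smaller than all grid neighbours), merged greedily by depth within
a minimum separation. The sign convention of the curvature condition at a
minimum is ambiguous as usually written (a Laplacian is positive at a
convex minimum); the implementation follows the unambiguous intent —
local minima of `U_q` — rather than the literal inequality. A constant
landscape returns no valleys plus a degeneracy warning. Note that an even
number of bins symmetric about a minimum splits it across two equal bins,
which is not strict: use odd bin counts over symmetric ranges.

*Transitions.* A path is a member of valley `i` while within a radius of
its location; an event is recorded whenever the membership changes, with
exit and entry times. Overlapping neighbourhoods raise. For the symmetric
double-well fixture, forward and backward event counts agree within
Monte-Carlo error, as they must by symmetry.

*Reversibility.* Forward and backward transition paths coincide only for
a gradient drift with constant diffusion; `gradient_check` tests diffusion
constancy across probe states and drift-Jacobian symmetry (equality of
mixed partials) by finite differences. Every smooth 1-D drift is a
gradient, so the clause is automatic at `d = 1`.

## Fixture conditions and problem sizes

The built-in fixtures *are* the study conditions, chosen once:

- Ornstein–Uhlenbeck: drift `−x`, `g = 1`, `ε = 2`, so the stationary law
  is standard normal (variance `ε/2 = 1`) and the quadratic coefficient of
  `U_q` is 0.5. Recovery runs use `dt = 0.01`, 2000 paths to `t = 10` for
  the variance and 500 paths to `t = 30` (burn-in 1/3, 61 bins on
  `[−4, 4]`) for the landscape fit — large enough that Monte-Carlo error
  sits well inside the four-standard-error bands, small enough that the
  whole chain runs in seconds.
- Double well: drift `x − x³`, `g = 1`, `ε = 0.5` (barrier `ΔU = 1/4`
  against noise `D = ε/2 = 1/4` gives a per-unit-time hopping rate of
  roughly `e^{−1}/π√2 ≈ 0.08`, i.e. abundant but not saturating
  transitions over `t = 100` with 200 paths); 51 bins on `[−2, 2]`,
  membership radius 0.3 with valleys at ±1.
- Affine random contraction: `x/2` and `x/2 + 1/2` with a fair coin,
  two-sided, whose pullback fibre is the explicit dyadic series.
- Pullback depth 30 for the relaxation process `x' = −x + 1` (distance
  decays like `e^{−k}`, hitting ~1e−13 at depth 30).

What the synthetic systems do *not* emulate: high-dimensional gene
expression spaces, state-dependent or correlated noise in the recovery
fixtures, non-stationary landscapes, measurement noise, and the discrete
molecule counts of low-copy-number kinetics. Passing tests therefore
certify the machinery — the axioms, estimators, and conventions — on
systems with known closed forms, not the biological adequacy of any
particular model.

## Known limitations

- Measurability hypotheses (joint measurability of evolution maps, the
  cylindrical σ-algebra constructions) are documented, not certified.
- Almost-sure properties of random attractors are probed on finitely many
  seeded realizations.
- Exact jump-process (Gillespie) simulation, least-action paths, and
  fluctuation–dissipation computations are out of scope; the stochastic
  layer here is the SDE.
- Attractor estimates are cloud-based and carry sampling error; no
  rigorous enclosures are computed.
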