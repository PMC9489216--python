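# Methods

## The search problem

An agent is released downwind of an odor source in a turbulent flow and
must reach it as fast as possible. At every decision step (duration
`t_s`) it chooses among six actions: move one cell up-, down-, left- or
rightwind while sniffing the ground, stay and sniff the ground, or stay
and sniff the air. Sniffing the air samples a plume that extends much
farther downwind than the ground-level plume (surface adsorption
depletes odor near the ground), at the cost of halted progress. A unit
reward is received on reaching the source; rewards are discounted at
rate `lambda` per unit time, so the value of a strategy is
`E[exp(-lambda T)]` with `T` the search time and maximizing it is
equivalent to minimizing discounted search time. The per-step discount
is `gamma = exp(-lambda t_s)`.

The agent never observes its position. It holds a belief `b(s)` over
its displacement from the source on an `(n_x, n_y)` grid and updates it
by Bayes' rule after every action/observation pair. Observations are
binary per sniff — detection or no detection — plus a deterministic
`source_found` on co-location. Detections are modeled as independent
Bernoulli draws per sniff with probability given by a static detection
rate map `r(x, y)` per modality (a memoryless model: the mean rate is
matched, spatiotemporal odor correlations are deliberately not).

## Synthetic detection-rate maps

The package generates maps in closed form rather than ingesting flow
simulations: `r(x, y) = peak * f(x) * g(y)` with `f` the indicator of
the downwind band `0 < x < x_thr` and `g` either a Gaussian of scale
`y_thr` or the indicator of a box of width `y_thr`. Matched air/ground
pairs enforce the physical ordering `x_thr_air >= x_thr_ground`,
`y_thr_air >= y_thr_ground`, so every relative isoline of the air map
contains at least the area of the ground map's. Defaults place the air
plume's reach at 60% of the prior length and the ground plume's at 10%,
with the ground modality twice as reliable in its core (peak 0.6 vs
0.3): ground odor near the source is smooth and dependable, airborne
odor sparse but far-reaching. These ratios are a modeling choice; the
empirical maps they emulate are published only as isolines.

What the generator does not emulate: temporal and spatial correlation
of detections (turbulent plumes are patchy in time), concentration
magnitudes (observations are binarized), vertical structure, and
fluctuating wind direction (a rigid "meander" rotation and an isotropic
rescaling are provided as perturbations for robustness tests). Passing
tests therefore demonstrate properties of the idealized Bernoulli
environment, not of real plumes.

Perturbations resample the base map by nearest cell: `rescale` maps
`(x, y) -> (x/m, y/m)` (multiplying both plume scales by `m`), `meander`
rotates rigidly about the source by `magnitude * sin(2 pi f t)`.

Grid conventions: `x` increases downwind, `y` crosswind; the source cell
is `origin`; downwind cell centers sit at `(i - i0 + 0.5) h` so the
band `0 < x < x_thr` covers exactly `x_thr / h` cells, crosswind centers
at `(j - j0) h` so the plume axis passes through cell centers and
crosswind profiles are exactly symmetric. Moves that would exit the grid
clamp (the state is unchanged); belief mass therefore never leaks.

The full-scale configuration is a 300 x 60 grid of 12 cm cells (18,000
states, 36 m x 7.2 m) holding a uniform 28.6 m x 3.4 m prior, with
`gamma = 0.99` and three sniffs per second, the cell size equal to the
12 cm step so the grid follows from the metric dimensions. Tests and the bundled experiments use
scaled-down versions (grids of order 60 x 21, priors of order 6 m) so a
training run takes about a minute instead of days; the methods are
identical and all directional claims are checked at that scale.

## Observation-model floor

`build_spec(detection_floor=...)` optionally clips the agent's internal
detection probabilities from below (default 0). Measured rate maps are
never exactly zero, and a hard zero makes the Bayes filter undefined the
moment a mismatched environment produces a detection the model forbids.
The robustness experiments enable a floor of 1e-3 in the agent's model
only; the environment keeps the unfloored maps. The floor is spatially
uniform and therefore uninformative — it does not change what the
policy can exploit.

## Point-based value iteration

The value function over beliefs is convex piecewise-linear and is
approximated from below by a set `H` of alpha vectors, `V(b) = max_alpha
alpha . b`, initialized with the single zero vector (an admissible lower
bound since rewards are nonnegative). Training episodes start at the
prior, pick actions uniformly at random, sample observations from the
belief predictive `P(o | b, a)`, update the belief, and perform a
Bellman backup at every visited belief; `H` is pruned after each episode
by removing componentwise-dominated vectors (tolerance 1e-12; exact
duplicates collapse to one). Episodes end early if the sampled
observation is `source_found`. The reward vector is `r_a(s) = 1` iff
action `a` moves `s` onto the source; the `source_found` branch carries
no continuation value (the found state is absorbing), which reproduces
the `Gamma_a + gamma (1 - Gamma_a) E[V]` structure of the value
recursion.

Backups never materialize the full back-projected table: with
deterministic transitions, `b . alpha_{a,o} = alpha . (b_pred *
P(o|., a))`, so selecting the maximizing member of `H` per `(a, o)` is
two matrix-vector products. The table itself (`precompute_alpha_ao`) is
kept for inspection and testing. Ties everywhere break toward the
lowest index, making training, greedy action and simulation bitwise
reproducible given seeds.

## Episode simulation and metrics

Test episodes run the greedy one-step-lookahead policy against an
environment that may differ from the agent's model (perturbed or
swapped maps); the belief filter always uses the trained model. Steps
are labeled `surge` (>= k consecutive upwind moves) or `cast` (>= k
consecutive crosswind-or-air-sniff steps), k = 3. Air-sniff rates are
fractions of steps spent on the stay-and-sniff-air action, stratified
by behavioral label or by position relative to the air plume's 10%
isoline. Excess path length is steps-to-source minus the Manhattan
distance from the start (axis-aligned moves make Manhattan the shortest
achievable). Distance-to-source stratification uses the true state —
an experimenter-side analysis, not information available to the agent.

## Marginal-value theory of the pre-detection search

Before the first detection the search is modeled analytically: the
prior of length `L_x` splits into `N ~ L_x / x_thr` patches explored in
sequence by bouts of cast-and-sniff followed by a surge of length
`x_thr` (travel time `tau = x_thr / v`). With `c(t)` the within-patch
no-detection probability, patch values satisfy the backward recursion
given in the module docstring; optimal casting times obey the
marginal-value condition `-c'(t_n) = N lambda e^{-lambda tau} V_{n+1}`,
with closed forms for exponential `c`. The recursion without belief
updates and the one with explicit Bayesian renormalization agree
identically (the survival factors telescope against the posterior
normalizations); both are implemented and the equivalence is tested to
1e-12, including for non-exponential detection laws.

The inner maximization of the general recursion locates the root of the
marginal condition by bracketed bisection on a 512-point grid refined by
Brent's method; `c'` uses a central difference when no derivative is
supplied. The undiscounted limit and the boundary value
`V_N = kappa / (N (kappa + lambda))` are covered by direct tests.

## The cast-and-sniff planner

Within a patch the agent chooses where to sniff on the crosswind axis.
A depth-`nsteps` plan is scored by expanding the detection/no-detection
recursion with terminal value zero; the telescoped form sums
`(cumulative discount) x (unnormalized survived belief . g)` over
sniffs, with `g(u) = exp(-u^2 / 2 y_thr^2)`. Plans are optimized by a
deterministic cyclic pattern search over absolute sniff positions
(61-point grid scan plus bounded 1-D refinement per coordinate, up to 5
passes): position coordinates keep each line search local, whereas
displacement coordinates couple globally and defeat simplex-type
optimizers in more than ~8 dimensions. Initializations are constant
sweeps of both handedness at several amplitudes, expanding zigzags, a
drift toward the belief's center of mass, optionally seeded random
restarts, and — during receding-horizon execution — the shifted
previous plan and its mirror. The executed strategy is the expected
expanding zigzag that sweeps the prior's width.

`c(t)` is computed exactly by marginalizing the product of per-sniff
survival factors over the target position on the discretized crosswind
axis (grid step `y_thr / 4` or finer; no Monte Carlo), so the curve and
everything fitted to it are deterministic.

Because a zigzag kills belief mass only over fresh ground, `c(t)` is a
staircase; a log-linear fit over a fixed early window is
ill-conditioned. The reported `kappa` is instead the rate of the
exponential whose discounted detection value matches the executed
curve's (its Laplace transform at `lambda`, tail-corrected below the
stopping level `c = 0.02`); the full-curve log-linear slope is reported
alongside. The depth sweep (`kappa_depth_sweep`) processes depths in
increasing order, seeding each depth with the previous depth's plan
extended by one displacement, which removes residual optimizer noise;
the whole sweep is deterministic. Under the reference configuration
(`y_thr / L_y = 1/20`, `L_y = 1`, `lambda = 0.5`, `v = 1`, `t_sniff =
0`), `kappa` rises monotonically with depth and the smallest depth
within 5% of the deep plateau (mean of depths 10-12) is 9.

## Air-only recovery experiments

The simplified agent detects odor only in the air (rectangular air map
`x_thr x y_thr`, silent ground map). Trained policies are unrolled
deterministically under permanent no-detection, which exposes the full
pre-detection structure. Cast bouts separated by less than k cells of
net upwind progress merge into one casting phase (a noisy greedy policy
fragments phases); surge length is the net upwind displacement between
consecutive phases (the initial approach and the truncated endgame fall
outside any phase pair and are excluded), cast width the crosswind
extent of a phase, and patches the number of phases. Predictions:
surge length ~ `x_thr`, cast width ~ `L_y`, `L_x = 4 x_thr` gives 4
patches, casting time non-decreasing across patches.

## Numerical choices and degenerate inputs

- Belief updates raise on zero predictive probability (model mismatch);
  batteries record such episodes as outcome `mismatch`.
- Entropy uses `x log x -> 0` at zero; units are nats.
- `isoline_extent` measures the cell-body span of the superlevel set,
  exact for aligned rectangular plumes, within one cell otherwise.
- Planner degeneracies: a prior fully covered by one sniff
  (`y_thr >= L_y`) or concentrated at the agent's position yields the
  stay plan; a single-point decay schedule yields `kappa = NaN` rather
  than a fit.
- Seeds: every stochastic component (training exploration, episode
  observation draws, optional planner restarts) takes an explicit seed;
  sub-seeds derive via `SeedSequence` and stay below 2^31.

## Known limitations

- The Bernoulli environment omits odor correlations; performance
  against realistic plumes is outside what these tests establish.
- Point-based value iteration yields a lower bound on the value
  function; greedy behavior at rarely-visited (late-search) beliefs is
  less converged at the reduced training sizes used here, which mainly
  affects the air-only per-patch casting-time profile.
- The cast planner optimizes a depth-limited objective with terminal
  value zero; very deep plans are only locally optimal (pattern search),
  though monotone improvement with depth is verified.
- Boundary clamping slightly distorts beliefs near grid edges; margins
  in the bundled configurations keep the prior away from edges.
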