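"""Grid POMDP for dual-modality olfactory search.

The latent state is the agent's displacement from the odor source on a
regular grid of ``(n_x, n_y)`` cells (state s = i * n_y + j for cell
(i, j); the source sits at the maps' ``origin`` cell). The agent cannot
observe its displacement; it holds a belief vector b(s) over all
displacements and updates it by Bayes' rule after every sniff.

Actions (fixed order)::

    0 move_upwind    (x - 1, sniff ground while moving)
    1 move_downwind  (x + 1, sniff ground)
    2 move_left      (y - 1, sniff ground)
    3 move_right     (y + 1, sniff ground)
    4 stay_sniff_ground
    5 stay_sniff_air

Observations (fixed order)::

    0 no_detection   1 detection   2 source_found

Transitions are deterministic translations of the displacement; moves
that would leave the grid clamp (state unchanged). Co-location with the
source is announced deterministically (``source_found``); elsewhere a
sniff is a Bernoulli draw with probability given by the ground map (all
ground-sniffing actions) or the air map (``stay_sniff_air``).

A unit reward is received on finding the source and future reward is
discounted by gamma = exp(-lambda * t_s) per step, so maximizing value
is equivalent to minimizing the expected discounted search time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .synthetic_plume import DetectionRateMap

__all__ = [
    "ACTIONS",
    "OBSERVATIONS",
    "MOVE_ACTIONS",
    "AIR_ACTION",
    "POMDPSpec",
    "PriorSpec",
    "build_spec",
    "default_full_scale_config",
    "transition",
    "observation_likelihood",
    "source_prob",
    "belief_update",
    "obs_predictive",
    "belief_entropy",
    "BeliefCollapseError",
]

ACTIONS = (
    "move_upwind",
    "move_downwind",
    "move_left",
    "move_right",
    "stay_sniff_ground",
    "stay_sniff_air",
)
OBSERVATIONS = ("no_detection", "detection", "source_found")
MOVE_ACTIONS = (0, 1, 2, 3)
AIR_ACTION = 5
NO_DETECTION, DETECTION, SOURCE_FOUND = 0, 1, 2

# displacement (di, dj) per action; x index i grows downwind
_ACTION_DELTAS = ((-1, 0), (1, 0), (0, -1), (0, 1), (0, 0), (0, 0))


class BeliefCollapseError(RuntimeError):
    """An observation with zero predictive probability under the belief.

    Signals a mismatch between the agent's internal likelihood model and
    the environment that generated the observation.
    """


@dataclass(frozen=True)
class POMDPSpec:
    """Immutable problem definition plus precomputed lookup tables.

    ``next_state[a]`` maps every state to its successor under action
    ``a``; ``obs_lik[a]`` is the (n_states, 3) observation likelihood
    P(o | s', a) evaluated at the *post-transition* state.
    """

    air_map: DetectionRateMap
    ground_map: DetectionRateMap
    gamma: float
    step_length: float
    step_duration: float
    next_state: np.ndarray = field(repr=False, compare=False, default=None)  # type: ignore
    obs_lik: np.ndarray = field(repr=False, compare=False, default=None)  # type: ignore

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.air_map.grid_shape

    @property
    def n_states(self) -> int:
        n_x, n_y = self.grid_shape
        return n_x * n_y

    @property
    def n_actions(self) -> int:
        return len(ACTIONS)

    @property
    def source_state(self) -> int:
        i0, j0 = self.air_map.origin
        return i0 * self.grid_shape[1] + j0

    @property
    def decay_rate(self) -> float:
        """Reward discount rate lambda (1/s) implied by gamma and t_s."""
        return -np.log(self.gamma) / self.step_duration

    def state_index(self, cell: tuple[int, int]) -> int:
        i, j = cell
        n_x, n_y = self.grid_shape
        if not (0 <= i < n_x and 0 <= j < n_y):
            raise ValueError(f"cell {cell} outside grid {self.grid_shape}")
        return i * n_y + j

    def state_cell(self, state: int) -> tuple[int, int]:
        n_y = self.grid_shape[1]
        return divmod(int(state), n_y)


def build_spec(
    air_map: DetectionRateMap,
    ground_map: DetectionRateMap,
    gamma: float = 0.99,
    step_length: float = 0.12,
    step_duration: float = 1.0 / 3.0,
    detection_floor: float = 0.0,
) -> POMDPSpec:
    """Assemble a POMDP spec from a matched pair of detection maps.

    Defaults follow the full-scale search problem: the agent sniffs three
    times per second (t_s = 1/3 s), moves 12 cm per step (one grid cell),
    and discounts reward at gamma = 0.99 per step.

    ``detection_floor`` imposes a minimum detection probability in the
    agent's internal likelihood (empirically measured rate maps are never
    exactly zero). A small floor keeps the Bayes filter well defined when
    the environment differs from the model — without it a single
    detection outside the modeled plume has zero predictive probability
    and collapses the belief.
    """
    if air_map.grid_shape != ground_map.grid_shape:
        raise ValueError(
            f"air and ground maps must share a grid; got "
            f"{air_map.grid_shape} vs {ground_map.grid_shape}"
        )
    if air_map.origin != ground_map.origin:
        raise ValueError("air and ground maps must share the source cell")
    if not 0 < gamma < 1:
        raise ValueError(f"gamma must lie in (0, 1), got {gamma}")

    n_x, n_y = air_map.grid_shape
    n = n_x * n_y
    ii, jj = np.divmod(np.arange(n), n_y)

    nxt = np.empty((len(ACTIONS), n), dtype=np.intp)
    for a, (di, dj) in enumerate(_ACTION_DELTAS):
        ti = np.clip(ii + di, 0, n_x - 1)
        tj = np.clip(jj + dj, 0, n_y - 1)
        # clamp: moves that would exit the grid leave the state unchanged
        blocked = ((ii + di) != ti) | ((jj + dj) != tj)
        nxt[a] = np.where(blocked, ii * n_y + jj, ti * n_y + tj)

    src = air_map.origin[0] * n_y + air_map.origin[1]
    ground_rate = ground_map.values.ravel()
    air_rate = air_map.values.ravel()
    lik = np.zeros((len(ACTIONS), n, 3))
    if not 0.0 <= detection_floor < 1.0:
        raise ValueError("detection_floor must lie in [0, 1)")
    for a in range(len(ACTIONS)):
        rate = air_rate if a == AIR_ACTION else ground_rate
        rate = np.clip(rate, detection_floor, 1.0)
        lik[a, :, DETECTION] = rate
        lik[a, :, NO_DETECTION] = 1.0 - rate
        lik[a, src] = (0.0, 0.0, 1.0)

    return POMDPSpec(
        air_map=air_map,
        ground_map=ground_map,
        gamma=gamma,
        step_length=step_length,
        step_duration=step_duration,
        next_state=nxt,
        obs_lik=lik,
    )


def default_full_scale_config() -> dict:
    """Geometry of the full-scale problem: 300 x 60 cells of 12 cm.

    A 36 m x 7.2 m displacement grid (18,000 states) holding a uniform
    prior of 28.6 m x 3.4 m, with the source placed a quarter of the way
    downwind. Returned as a plain dict so callers can build maps and a
    spec from it.
    """
    return {
        "grid_shape": (300, 60),
        "cell_size": 0.12,
        "gamma": 0.99,
        "step_length": 0.12,
        "step_duration": 1.0 / 3.0,
        "prior_length": 28.6,
        "prior_width": 3.4,
    }


@dataclass(frozen=True)
class PriorSpec:
    """Uniform rectangular prior over displacement from the source.

    The support is the box x in [x_lo, x_lo + length), y centered on the
    plume axis with the given width, in meters. Cells whose centers fall
    inside the box share the mass equally.
    """

    length: float
    width: float
    x_lo: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("prior support must have positive area")

    def belief(self, spec: POMDPSpec) -> np.ndarray:
        x, y = spec.air_map.cell_centers()
        in_x = (x >= self.x_lo) & (x < self.x_lo + self.length)
        in_y = np.abs(y) <= self.width / 2.0
        mask = np.outer(in_x, in_y).ravel()
        if not mask.any():
            raise ValueError("prior support contains no grid cell")
        b = mask.astype(float)
        return b / b.sum()


def transition(spec: POMDPSpec, state: int, action: int) -> int:
    """Deterministic successor displacement under an action."""
    if not 0 <= action < spec.n_actions:
        raise ValueError(f"unknown action {action}")
    return int(spec.next_state[action, state])


def observation_likelihood(spec: POMDPSpec, state: int, action: int) -> np.ndarray:
    """P(o | s, a) over (no_detection, detection, source_found).

    At the source cell the source is found with certainty; elsewhere the
    sniff outcome is Bernoulli with the modality's map value at ``state``.
    """
    if not 0 <= action < spec.n_actions:
        raise ValueError(f"unknown action {action}")
    return spec.obs_lik[action, state].copy()


def predicted_belief(spec: POMDPSpec, belief: np.ndarray, action: int) -> np.ndarray:
    """Push the belief through the deterministic transition of ``action``."""
    return np.bincount(
        spec.next_state[action], weights=belief, minlength=spec.n_states
    )


def source_prob(spec: POMDPSpec, belief: np.ndarray, action: int) -> float:
    """Gamma_a: probability of landing on the source by taking ``action``."""
    mass = belief[spec.next_state[action] == spec.source_state]
    return float(mass.sum())


def obs_predictive(spec: POMDPSpec, belief: np.ndarray, action: int) -> np.ndarray:
    """P(o | b, a) over the three observations; sums to one."""
    bp = predicted_belief(spec, belief, action)
    return bp @ spec.obs_lik[action]


def belief_update(
    spec: POMDPSpec, belief: np.ndarray, action: int, observation: int
) -> np.ndarray:
    """Bayes posterior b'(s') after acting and observing.

    b'(s') is proportional to P(o | s', a) * sum_s T(s' | s, a) b(s).
    ``source_found`` collapses the belief onto the source cell.
    """
    bp = predicted_belief(spec, belief, action)
    post = bp * spec.obs_lik[action, :, observation]
    norm = post.sum()
    if norm <= 0.0:
        raise BeliefCollapseError(
            f"observation {OBSERVATIONS[observation]!r} after action "
            f"{ACTIONS[action]!r} has zero probability under the current "
            "belief: the internal model cannot explain the environment"
        )
    return post / norm


def belief_entropy(belief: np.ndarray) -> float:
    """Shannon entropy -sum b log b of the belief, in nats."""
    return float(-xlogy(belief, belief).sum())
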