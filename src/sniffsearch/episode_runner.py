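"""Simulate test episodes of a trained agent and orchestrate batteries.

At test time the agent holds its trained likelihood model (the maps in
the spec) while the *environment* draws observations from possibly
different maps — identical by default, perturbed (rescaled, meandering,
swapped) in robustness evaluations. Each step: greedy action from the
belief, deterministic move of the true displacement, Bernoulli sniff at
the true position, Bayes update of the belief. An episode ends when the
agent steps onto the source (``source_found``) or after ``max_steps``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pomdp_model as pm
from .pomdp_model import BeliefCollapseError, POMDPSpec
from .perseus_solver import AlphaSet, greedy_action, value_of
from .synthetic_plume import DetectionRateMap

__all__ = ["Trajectory", "run_episode", "run_battery", "robustness_eval"]


@dataclass
class Trajectory:
    """Time-ordered record of one episode.

    Arrays have one entry per step: the true displacement *after* the
    move, the action, the observation, the post-update belief entropy and
    value, and whether the action was an air sniff. ``outcome`` is
    ``"found"``, ``"timeout"``, or ``"mismatch"`` (belief collapse under
    a perturbed environment).
    """

    states: np.ndarray  # (n_steps, 2) int cells
    actions: np.ndarray
    observations: np.ndarray
    entropy: np.ndarray
    value: np.ndarray
    start_state: tuple[int, int]
    outcome: str
    seed: int

    def __post_init__(self) -> None:
        n = len(self.actions)
        if not (len(self.states) == len(self.observations) == len(self.entropy) == n):
            raise ValueError("trajectory arrays must have equal length")
        found_last = n > 0 and self.observations[-1] == pm.SOURCE_FOUND
        if (self.outcome == "found") != found_last:
            raise ValueError("outcome 'found' requires terminal source_found")

    def __len__(self) -> int:
        return len(self.actions)

    @property
    def n_steps(self) -> int:
        return len(self.actions)

    @property
    def air_sniffs(self) -> np.ndarray:
        return self.actions == pm.AIR_ACTION

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_cell": self.states[:, 0],
                "y_cell": self.states[:, 1],
                "action": [pm.ACTIONS[a] for a in self.actions],
                "observation": [pm.OBSERVATIONS[o] for o in self.observations],
                "entropy": self.entropy,
                "value": self.value,
                "air_sniff": self.air_sniffs,
            }
        )


def run_episode(
    spec: POMDPSpec,
    H: AlphaSet,
    prior: np.ndarray,
    start_state: tuple[int, int],
    max_steps: int = 1000,
    seed: int = 0,
    env_maps: tuple[DetectionRateMap, DetectionRateMap] | None = None,
) -> Trajectory:
    """Run one greedy-policy episode from a true start displacement.

    ``env_maps = (air, ground)`` overrides the maps used to *generate*
    observations while the agent's belief updates keep using the trained
    model; pass perturbed maps for robustness tests. If the environment
    produces an observation the internal model deems impossible, the
    episode ends with outcome ``"mismatch"``.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    rng = np.random.default_rng(seed)
    env_air = env_maps[0].values.ravel() if env_maps else spec.air_map.values.ravel()
    env_ground = env_maps[1].values.ravel() if env_maps else spec.ground_map.values.ravel()

    belief = prior.copy()
    s = spec.state_index(start_state)
    states, actions, observations, entropies, values = [], [], [], [], []
    outcome = "timeout"
    for _ in range(max_steps):
        a = greedy_action(belief, H, spec)
        s = pm.transition(spec, s, a)
        if s == spec.source_state:
            o = pm.SOURCE_FOUND
        else:
            rate = env_air[s] if a == pm.AIR_ACTION else env_ground[s]
            o = pm.DETECTION if rng.random() < rate else pm.NO_DETECTION
        states.append(spec.state_cell(s))
        actions.append(a)
        observations.append(o)
        try:
            belief = pm.belief_update(spec, belief, a, o)
        except BeliefCollapseError:
            entropies.append(np.nan)
            values.append(np.nan)
            outcome = "mismatch"
            break
        entropies.append(pm.belief_entropy(belief))
        values.append(value_of(belief, H))
        if o == pm.SOURCE_FOUND:
            outcome = "found"
            break
    return Trajectory(
        states=np.array(states, dtype=int).reshape(-1, 2),
        actions=np.array(actions, dtype=int),
        observations=np.array(observations, dtype=int),
        entropy=np.array(entropies, dtype=float),
        value=np.array(values, dtype=float),
        start_state=tuple(start_state),
        outcome=outcome,
        seed=seed,
    )


def _episode_seed(base_seed: int, realization: int) -> int:
    """Stable sub-seed below 2**31 for one (seed, realization) pair."""
    ss = np.random.SeedSequence([int(base_seed), int(realization)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_battery(
    spec: POMDPSpec,
    H: AlphaSet,
    prior: np.ndarray,
    starts: list[tuple[int, int]],
    seeds: list[int],
    n_realizations: int,
    max_steps: int = 1000,
    env_maps: tuple[DetectionRateMap, DetectionRateMap] | None = None,
    keep_trajectories: bool = False,
):
    """Full cross of starts x seeds x realizations of greedy episodes.

    Returns a tidy DataFrame with one row per episode (start, seed,
    realization, steps, outcome, air-sniff count); with
    ``keep_trajectories`` also returns the list of Trajectory objects in
    row order.
    """
    if not starts:
        raise ValueError("at least one start state is required")
    rows, trajs = [], []
    for start in starts:
        for seed in seeds:
            for real in range(n_realizations):
                traj = run_episode(
                    spec,
                    H,
                    prior,
                    start,
                    max_steps=max_steps,
                    seed=_episode_seed(seed, real),
                    env_maps=env_maps,
                )
                rows.append(
                    {
                        "start_x": start[0],
                        "start_y": start[1],
                        "seed": seed,
                        "realization": real,
                        "steps": traj.n_steps,
                        "outcome": traj.outcome,
                        "air_sniffs": int(traj.air_sniffs.sum()),
                    }
                )
                if keep_trajectories:
                    trajs.append(traj)
    table = pd.DataFrame(rows)
    return (table, trajs) if keep_trajectories else table


def robustness_eval(
    H: AlphaSet,
    spec: POMDPSpec,
    perturbations: dict[str, tuple[DetectionRateMap, DetectionRateMap]],
    prior: np.ndarray,
    starts: list[tuple[int, int]],
    seeds: list[int],
    n_realizations: int,
    max_steps: int = 1000,
) -> pd.DataFrame:
    """Test a fixed policy against perturbed environments.

    The agent keeps the (now inaccurate) likelihood model it was trained
    with; each named perturbation supplies the (air, ground) maps the
    environment actually draws detections from. Returns one row per
    perturbation with success rate and mean steps of successful episodes.
    """
    rows = []
    for name, maps in perturbations.items():
        table = run_battery(
            spec, H, prior, starts, seeds, n_realizations,
            max_steps=max_steps, env_maps=maps,
        )
        found = table[table.outcome == "found"]
        rows.append(
            {
                "perturbation": name,
                "n_episodes": len(table),
                "success_rate": len(found) / len(table),
                "mean_steps_found": found.steps.mean() if len(found) else np.nan,
                "mean_air_sniffs": table.air_sniffs.mean(),
            }
        )
    return pd.DataFrame(rows)
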