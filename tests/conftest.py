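"""Shared fixtures: toy and scaled-down search environments.

Session-scoped fixtures train policies once and share them between the
unit and acceptance tests. The "scaled" environment is a reduced version
of the full search problem (6 m prior instead of 28.6 m, coarser
training) that keeps the qualitative structure: an air plume reaching
60% of the prior length, a ground plume reaching 10%, and a start far
downwind of both.
"""

from __future__ import annotations

import numpy as np
import pytest

from sniffsearch import pomdp_model as pm
from sniffsearch import perseus_solver as ps
from sniffsearch.episode_runner import run_battery
from sniffsearch.synthetic_plume import (
    DetectionRateMap,
    PlumeParams,
    default_pair_params,
    make_dns_like_pair,
)

SCALED = {
    "prior_length": 6.0,
    "prior_width": 2.4,
    "cell_size": 0.12,
    "grid_shape": (60, 21),
    "origin": (5, 10),
    "gamma": 0.98,
    "n_episodes": 40,
    "points_per_episode": 60,
    "train_seed": 7,
    "starts": [(50, 10), (50, 13), (50, 5)],  # x = 45 cells downwind; y 0, +0.36, -0.6 m
    "battery_seeds": [0, 1],
    "n_realizations": 8,
    "max_steps": 500,
}


@pytest.fixture(scope="session")
def scaled_env():
    """Dual-modality spec + prior belief at desk scale."""
    air, ground = default_pair_params(SCALED["prior_length"])
    air_map, ground_map = make_dns_like_pair(
        air, ground, SCALED["grid_shape"], SCALED["cell_size"], origin=SCALED["origin"]
    )
    spec = pm.build_spec(air_map, ground_map, gamma=SCALED["gamma"])
    prior = pm.PriorSpec(
        length=SCALED["prior_length"], width=SCALED["prior_width"]
    ).belief(spec)
    return spec, prior


@pytest.fixture(scope="session")
def scaled_policy(scaled_env):
    spec, prior = scaled_env
    H = ps.train(
        spec,
        prior,
        n_episodes=SCALED["n_episodes"],
        points_per_episode=SCALED["points_per_episode"],
        seed=SCALED["train_seed"],
    )
    return H


@pytest.fixture(scope="session")
def scaled_battery(scaled_env, scaled_policy):
    """Full-agent test battery with trajectories, shared across tests."""
    spec, prior = scaled_env
    table, trajs = run_battery(
        spec,
        scaled_policy,
        prior,
        starts=SCALED["starts"],
        seeds=SCALED["battery_seeds"],
        n_realizations=SCALED["n_realizations"],
        max_steps=SCALED["max_steps"],
        keep_trajectories=True,
    )
    return table, trajs


@pytest.fixture(scope="session")
def ground_only_env():
    """Ablation: the air modality is uninformative (air map identically 0)."""
    air, ground = default_pair_params(SCALED["prior_length"])
    air_map, ground_map = make_dns_like_pair(
        air, ground, SCALED["grid_shape"], SCALED["cell_size"], origin=SCALED["origin"]
    )
    silent_air = DetectionRateMap(
        values=np.zeros(air_map.grid_shape),
        cell_size=air_map.cell_size,
        origin=air_map.origin,
        modality="air",
    )
    spec = pm.build_spec(silent_air, ground_map, gamma=SCALED["gamma"])
    prior = pm.PriorSpec(
        length=SCALED["prior_length"], width=SCALED["prior_width"]
    ).belief(spec)
    return spec, prior


@pytest.fixture(scope="session")
def ground_only_battery(ground_only_env):
    spec, prior = ground_only_env
    H = ps.train(
        spec,
        prior,
        n_episodes=SCALED["n_episodes"],
        points_per_episode=SCALED["points_per_episode"],
        seed=SCALED["train_seed"],
    )
    table, trajs = run_battery(
        spec,
        H,
        prior,
        starts=SCALED["starts"],
        seeds=SCALED["battery_seeds"],
        n_realizations=SCALED["n_realizations"],
        max_steps=SCALED["max_steps"],
        keep_trajectories=True,
    )
    return table, trajs


# air-only recovery experiments: prior length fixed at four plume
# lengths, three plume-range / prior-width settings
AIR_ONLY_SETTINGS = [
    {"x_thr": 1.2, "y_thr": 0.3, "L_y": 1.5},
    {"x_thr": 1.5, "y_thr": 0.3, "L_y": 1.2},
    {"x_thr": 0.9, "y_thr": 0.3, "L_y": 1.8},
]
AIR_ONLY_COMMON = {
    "cell_size": 0.15,
    "gamma": 0.995,
    "peak_rate": 0.9,
    "n_episodes": 40,
    "points_per_episode": 60,
    "seeds": (0, 1),
    "max_steps": 600,
}


@pytest.fixture(scope="session")
def air_only_summaries():
    """Cast-surge structure of trained air-only agents, one per setting."""
    from sniffsearch.mvt_theory import simplified_pomdp_summary

    out = []
    for setting in AIR_ONLY_SETTINGS:
        out.append(
            simplified_pomdp_summary(
                x_thr=setting["x_thr"],
                y_thr=setting["y_thr"],
                L_x=4 * setting["x_thr"],
                L_y=setting["L_y"],
                **AIR_ONLY_COMMON,
            )
        )
    return out


# ---------------------------------------------------------------------------
# tiny environments for exact oracles
# ---------------------------------------------------------------------------


def tiny_spec(n_x=2, n_y=1, air_rates=None, ground_rates=None, gamma=0.8,
              origin=(0, 0)):
    """Hand-built POMDP on an n_x-by-n_y grid with explicit rate maps."""
    air_vals = np.zeros((n_x, n_y)) if air_rates is None else np.asarray(air_rates, float)
    ground_vals = (
        np.zeros((n_x, n_y)) if ground_rates is None else np.asarray(ground_rates, float)
    )
    air = DetectionRateMap(values=air_vals, cell_size=1.0, origin=origin, modality="air")
    ground = DetectionRateMap(
        values=ground_vals, cell_size=1.0, origin=origin, modality="ground"
    )
    return pm.build_spec(air, ground, gamma=gamma, step_length=1.0, step_duration=1.0)


@pytest.fixture
def two_state_spec():
    """2-state corridor: source at cell 0, informative air sniff at cell 1."""
    return tiny_spec(n_x=2, n_y=1, air_rates=[[0.0], [0.6]],
                     ground_rates=[[0.0], [0.2]], gamma=0.8)


@pytest.fixture
def toy_dual_env():
    """Small dual-modality environment for fast behavioral tests."""
    air = PlumeParams(x_thr=1.2, y_thr=0.3, peak_rate=0.3)
    ground = PlumeParams(x_thr=0.36, y_thr=0.15, peak_rate=0.6)
    air_map, ground_map = make_dns_like_pair(air, ground, (30, 11), 0.12)
    spec = pm.build_spec(air_map, ground_map, gamma=0.97)
    prior = pm.PriorSpec(length=2.4, width=1.0).belief(spec)
    return spec, prior
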