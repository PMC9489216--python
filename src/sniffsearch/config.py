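"""YAML/JSON configuration for building specs, priors and maps.

A configuration file describes the grid geometry, the two plume
parameter sets, the discount and the prior; :func:`load_config` turns it
into the in-memory objects the solver and runner consume. Example::

    grid_shape: [120, 31]
    cell_size: 0.12
    gamma: 0.98
    step_length: 0.12
    step_duration: 0.3333
    air:    {x_thr: 8.0, y_thr: 0.6, peak_rate: 0.3}
    ground: {x_thr: 1.5, y_thr: 0.3, peak_rate: 0.3}
    prior:  {length: 10.0, width: 2.4}
    train:  {n_episodes: 40, points_per_episode: 60, seed: 0}
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .pomdp_model import POMDPSpec, PriorSpec, build_spec
from .synthetic_plume import PlumeParams, make_dns_like_pair

__all__ = ["load_config"]


def load_config(path: str | Path) -> dict:
    """Parse a config file into {spec, prior, prior_belief, train, raw}."""
    raw = yaml.safe_load(Path(path).read_text())
    air = PlumeParams(**raw["air"])
    ground = PlumeParams(**raw["ground"])
    air_map, ground_map = make_dns_like_pair(
        air,
        ground,
        grid_shape=tuple(raw["grid_shape"]),
        cell_size=float(raw["cell_size"]),
        origin=tuple(raw["origin"]) if "origin" in raw else None,
    )
    spec = build_spec(
        air_map,
        ground_map,
        gamma=float(raw.get("gamma", 0.99)),
        step_length=float(raw.get("step_length", 0.12)),
        step_duration=float(raw.get("step_duration", 1.0 / 3.0)),
    )
    prior = PriorSpec(**raw["prior"])
    return {
        "spec": spec,
        "prior": prior,
        "prior_belief": prior.belief(spec),
        "train": raw.get("train", {}),
        "raw": raw,
    }
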