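"""Quantify alternation: cast/surge segmentation and air-sniff statistics.

Trained agents interleave persistent upwind runs ("surges") with
persistent crosswind excursions punctuated by paused air sniffs
("casts"). These metrics segment trajectories into those behavioral
modes, measure how often the agent pauses to sniff the air in each mode
and at each distance from the source, and summarize path efficiency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import pomdp_model as pm
from .episode_runner import Trajectory
from .synthetic_plume import DetectionRateMap

__all__ = [
    "classify_segments",
    "air_sniff_rate",
    "rate_by_distance",
    "excess_steps",
    "excess_steps_summary",
    "entropy_value_series",
]

_UPWIND = 0  # move_upwind
_CROSSWIND = (2, 3)  # move_left, move_right


def _run_labels(member: np.ndarray, k: int) -> np.ndarray:
    """True at steps lying in a run of >= k consecutive member steps."""
    out = np.zeros(len(member), dtype=bool)
    start = None
    for t, m in enumerate(np.append(member, False)):
        if m and start is None:
            start = t
        elif not m and start is not None:
            if t - start >= k:
                out[start:t] = True
            start = None
    return out


def classify_segments(traj: Trajectory, k: int = 3) -> np.ndarray:
    """Per-step behavioral labels in {"surge", "cast", "other"}.

    A step is a *surge* if it lies in a run of at least k consecutive
    upwind moves, and a *cast* if it lies in a run of at least k
    consecutive steps each of which is a crosswind move or an air sniff.
    The two run types are built from disjoint action sets, so no step
    qualifies for both; a cast label would take precedence if it did.
    k = 3 is the conventional choice and results are insensitive to it.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    actions = traj.actions
    upwind = actions == _UPWIND
    castlike = np.isin(actions, _CROSSWIND) | (actions == pm.AIR_ACTION)
    surge = _run_labels(upwind, k)
    cast = _run_labels(castlike, k)
    labels = np.full(len(actions), "other", dtype=object)
    labels[surge] = "surge"
    labels[cast] = "cast"  # precedence: cast overrides (never overlaps in fact)
    return labels


def air_sniff_rate(traj: Trajectory, mask: np.ndarray | None = None) -> float:
    """Fraction of (masked) steps on which the agent paused to sniff the air."""
    air = traj.air_sniffs
    if mask is None:
        mask = np.ones(len(air), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no steps")
    return float(air[mask].mean())


def rate_by_distance(
    trajs: list[Trajectory],
    spec: pm.POMDPSpec,
    bins: np.ndarray | None = None,
    air_map: DetectionRateMap | None = None,
    isoline_level: float = 0.1,
) -> pd.Series:
    """Air-sniff rate stratified by true distance to the source.

    With ``bins`` (edges in m), steps are pooled across trajectories into
    Euclidean distance-to-source bins. With ``air_map`` instead, steps
    are split into inside/outside the map's ``isoline_level`` superlevel
    set (the airborne-plume footprint). Strata with no steps are NaN.
    """
    if (bins is None) == (air_map is None):
        raise ValueError("provide exactly one of bins or air_map")
    cells = np.vstack([t.states for t in trajs])
    air = np.concatenate([t.air_sniffs for t in trajs])
    i0, j0 = spec.air_map.origin
    h = spec.air_map.cell_size

    if air_map is not None:
        inside = air_map.values[cells[:, 0], cells[:, 1]] >= (
            isoline_level * air_map.values.max()
        )
        return pd.Series(
            {
                "inside_plume": air[inside].mean() if inside.any() else np.nan,
                "outside_plume": air[~inside].mean() if (~inside).any() else np.nan,
            }
        )

    dist = h * np.hypot(cells[:, 0] - i0, cells[:, 1] - j0)
    idx = np.digitize(dist, bins) - 1
    out = {}
    for b in range(len(bins) - 1):
        sel = idx == b
        label = f"[{bins[b]:g}, {bins[b + 1]:g})"
        out[label] = air[sel].mean() if sel.any() else np.nan
    return pd.Series(out)


def excess_steps(traj: Trajectory, spec: pm.POMDPSpec) -> int:
    """Steps taken minus the shortest possible step count to the source.

    With axis-aligned unit moves the shortest path from the start
    displacement is its Manhattan length in cells. Only defined for
    episodes that found the source.
    """
    if traj.outcome != "found":
        raise ValueError("excess steps is defined only for successful episodes")
    i0, j0 = spec.air_map.origin
    si, sj = traj.start_state
    manhattan = abs(si - i0) + abs(sj - j0)
    return int(traj.n_steps - manhattan)


def excess_steps_summary(
    trajs: list[Trajectory], spec: pm.POMDPSpec
) -> pd.Series:
    """Median, quartiles, deciles and outlier threshold of excess steps.

    Timeout episodes are excluded. Outliers exceed the 75th percentile
    plus 1.5 interquartile ranges.
    """
    vals = np.array(
        [excess_steps(t, spec) for t in trajs if t.outcome == "found"], dtype=float
    )
    if len(vals) == 0:
        return pd.Series(dtype=float)
    q10, q25, q50, q75, q90 = np.percentile(vals, [10, 25, 50, 75, 90])
    return pd.Series(
        {
            "n": len(vals),
            "median": q50,
            "q25": q25,
            "q75": q75,
            "q10": q10,
            "q90": q90,
            "outlier_threshold": q75 + 1.5 * (q75 - q25),
        }
    )


def entropy_value_series(traj: Trajectory) -> pd.DataFrame:
    """Belief entropy (nats) and value per step, with detections flagged."""
    return pd.DataFrame(
        {
            "step": np.arange(traj.n_steps),
            "entropy": traj.entropy,
            "value": traj.value,
            "detection": traj.observations == pm.DETECTION,
        }
    )
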