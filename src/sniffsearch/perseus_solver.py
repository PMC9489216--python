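"""Point-based value iteration with alpha vectors (Perseus-style).

The value function of a POMDP is convex and piecewise linear in the
belief, so it can be approximated from below by a finite set H of
hyperplanes ("alpha vectors"): V(b) = max_{alpha in H} alpha . b.
Training grows H by simulating random-exploration belief sequences from
the prior and performing a Bellman *backup* at every collected belief;
componentwise-dominated vectors are pruned after each episode.

Reward structure: taking action a from state s yields reward 1 exactly
when the successor is the source cell, after which the search ends
(the found state is absorbing with zero continuation). The Bellman
equation on beliefs is therefore

    V(b) = max_a { Gamma_a(b) + gamma * sum_{o != found} P(o|b,a) V(b^{a,o}) }

with Gamma_a the probability of stepping onto the source. Values lie in
[0, 1], so the single all-zero vector is an admissible initial H.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import pomdp_model as pm
from .pomdp_model import POMDPSpec

__all__ = [
    "AlphaSet",
    "value_of",
    "precompute_alpha_ao",
    "backup",
    "prune",
    "train",
    "greedy_action",
    "reward_vectors",
]

_PRUNE_TOL = 1e-12


@dataclass
class AlphaSet:
    """A set of value hyperplanes.

    ``vectors`` is an (n_alpha, n_states) array; ``actions[k]`` records
    the action that generated vector k (the greedy action at the belief
    it was backed up from).
    """

    vectors: np.ndarray
    actions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if self.actions is None:
            self.actions = np.zeros(len(self.vectors), dtype=np.intp)
        else:
            self.actions = np.asarray(self.actions, dtype=np.intp)
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("alpha vectors must be finite")
        if len(self.actions) != len(self.vectors):
            raise ValueError("one generating action per vector is required")

    def __len__(self) -> int:
        return len(self.vectors)

    @classmethod
    def initial(cls, n_states: int) -> "AlphaSet":
        """The admissible lower bound for nonnegative rewards: alpha = 0."""
        return cls(vectors=np.zeros((1, n_states)))

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        import json

        path = Path(path)
        np.savez_compressed(path, vectors=self.vectors, actions=self.actions)
        if meta is not None:
            Path(str(path) + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "AlphaSet":
        with np.load(path) as data:
            return cls(vectors=data["vectors"], actions=data["actions"])


def reward_vectors(spec: POMDPSpec) -> np.ndarray:
    """r_a(s) = 1 if action a moves s onto the source, else 0; (n_a, n_s)."""
    return (spec.next_state == spec.source_state).astype(float)


def value_of(belief: np.ndarray, H: AlphaSet) -> float:
    """V(b) = max over hyperplanes of alpha . b (ties: lowest index)."""
    if len(H) == 0:
        raise ValueError("alpha set is empty")
    return float(np.max(H.vectors @ belief))


def precompute_alpha_ao(H: AlphaSet, spec: POMDPSpec) -> np.ndarray:
    """Back-projected hyperplanes alpha_{a,o}(s), shape (n_alpha, n_a, 2, n_s).

    alpha_{a,o}(s) = sum_{s'} alpha(s') P(o|s',a) T(s'|s,a); with the
    deterministic transition this is alpha(s_a') P(o|s_a',a) at
    s_a' = next(s, a). Only the two non-terminal observations appear:
    ``source_found`` ends the search with zero continuation. Must be
    recomputed whenever H changes.
    """
    n_alpha, n = len(H), spec.n_states
    table = np.empty((n_alpha, spec.n_actions, 2, n))
    for a in range(spec.n_actions):
        nxt = spec.next_state[a]
        proj = H.vectors[:, nxt]  # (n_alpha, n)
        for o in (pm.NO_DETECTION, pm.DETECTION):
            table[:, a, o] = proj * spec.obs_lik[a, nxt, o]
    return table


def _backup_vector(H: AlphaSet, belief: np.ndarray, spec: POMDPSpec, r: np.ndarray):
    """Best backed-up hyperplane at ``belief``; returns (vector, action, value).

    Uses the identity b . alpha_{a,o} = (alpha restricted to successors)
    . (b_pred * P(o|.,a)) to select the maximizing member of H per (a, o)
    without materializing the full alpha_{a,o} table.
    """
    best_val, best_vec, best_a = -np.inf, None, -1
    for a in range(spec.n_actions):
        nxt = spec.next_state[a]
        bp = pm.predicted_belief(spec, belief, a)
        vec = r[a].copy()
        for o in (pm.NO_DETECTION, pm.DETECTION):
            w = bp * spec.obs_lik[a, :, o]
            k = int(np.argmax(H.vectors @ w))
            vec += spec.gamma * H.vectors[k, nxt] * spec.obs_lik[a, nxt, o]
        val = float(vec @ belief)
        if val > best_val:
            best_val, best_vec, best_a = val, vec, a
    return best_vec, best_a, best_val


def backup(H: AlphaSet, belief: np.ndarray, spec: POMDPSpec) -> AlphaSet:
    """Bellman backup at one belief; returns H with the new vector appended.

    The appended vector alpha_a^b = r_a + gamma * sum_o argmax_{alpha_{a,o}}
    b . alpha_{a,o} (a chosen greedily) never decreases V(b).
    """
    r = reward_vectors(spec)
    vec, a, _ = _backup_vector(H, belief, spec, r)
    return AlphaSet(
        vectors=np.vstack([H.vectors, vec]),
        actions=np.append(H.actions, a),
    )


def prune(H: AlphaSet, tol: float = _PRUNE_TOL) -> AlphaSet:
    """Drop hyperplanes componentwise-dominated by another member of H.

    Vector v is removed when some other vector w satisfies v <= w + tol
    in every component; of exact duplicates the earliest is kept. The
    upper envelope max_alpha alpha . b is unchanged for every belief.
    """
    A = H.vectors
    n_alpha = len(A)
    keep = np.ones(n_alpha, dtype=bool)
    idx = np.arange(n_alpha)
    for i in range(n_alpha):
        le = np.all(A[i] <= A + tol, axis=1)  # i below-or-equal j everywhere
        dup = le & np.all(A <= A[i] + tol, axis=1)
        # of exact duplicates only the earliest survives
        dominators = le & keep & (idx != i) & ~(dup & (idx > i))
        if dominators.any():
            keep[i] = False
    if keep.all():
        return H
    return AlphaSet(vectors=A[keep], actions=H.actions[keep])


def greedy_action(belief: np.ndarray, H: AlphaSet, spec: POMDPSpec) -> int:
    """One-step lookahead policy: argmax_a of Gamma_a + gamma E_o V(b^{a,o}).

    Ties break toward the lowest action index, so behavior is
    deterministic given the belief and H.
    """
    best_q, best_a = -np.inf, 0
    for a in range(spec.n_actions):
        bp = pm.predicted_belief(spec, belief, a)
        q = float(bp[spec.source_state])
        for o in (pm.NO_DETECTION, pm.DETECTION):
            w = bp * spec.obs_lik[a, :, o]
            p_o = w.sum()
            if p_o > 0.0:
                # value_of(b^{a,o}) * P(o|b,a) = max_alpha alpha . w
                q += spec.gamma * float(np.max(H.vectors @ w))
        if q > best_q + 1e-15:
            best_q, best_a = q, a
    return best_a


def train(
    spec: POMDPSpec,
    prior: np.ndarray,
    n_episodes: int = 320,
    points_per_episode: int = 100,
    seed: int = 0,
    history: list | None = None,
) -> AlphaSet:
    """Grow an alpha-vector set by random-exploration point-based backups.

    Each training episode starts from the prior belief, picks actions
    uniformly at random, samples observations from the belief predictive
    P(o | b, a), updates the belief by Bayes' rule, and backs up H at
    every new belief. Episodes end early when the sampled observation is
    ``source_found``. H is pruned after every episode. Fully reproducible
    given ``seed``. If ``history`` is a list, (episode, len(H)) pairs are
    appended after each episode for monitoring.
    """
    rng = np.random.default_rng(seed)
    H = AlphaSet.initial(spec.n_states)
    for ep in range(n_episodes):
        belief = prior.copy()
        for _ in range(points_per_episode):
            a = int(rng.integers(spec.n_actions))
            p = pm.obs_predictive(spec, belief, a)
            o = int(rng.choice(3, p=p / p.sum()))
            if o == pm.SOURCE_FOUND:
                break
            belief = pm.belief_update(spec, belief, a, o)
            H = backup(H, belief, spec)
        H = prune(H)
        if history is not None:
            history.append((ep, len(H)))
    return H
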