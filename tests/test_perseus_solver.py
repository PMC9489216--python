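"""Alpha-vector value iteration against exact oracles on tiny problems.

Oracles
-------
dense_belief_vi
    Exact value iteration on a fine discretization of the belief simplex
    of a 2-state POMDP (1-D grid, linear interpolation), independent of
    the alpha-vector machinery.
expectimax
    Depth-limited exhaustive expansion of the Bellman tree for the value
    of each action; with a tail bound gamma^d / (1 - gamma) it certifies
    the greedy action whenever the decision margin exceeds the bound.
"""

import numpy as np
import pytest

from sniffsearch import pomdp_model as pm
from sniffsearch import perseus_solver as ps

from conftest import tiny_spec


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def dense_belief_vi(spec, n_grid=2001, tol=1e-10, max_iter=10_000):
    """Value iteration on the 1-D belief simplex of a 2-state POMDP.

    Belief parameterized by q = P(state 1); returns (grid, values) so
    V(q) is evaluated by linear interpolation. Vectorized over the grid:
    for 2 states both the predictive probability and the posterior are
    affine / rational-linear in q.
    """
    assert spec.n_states == 2
    qs = np.linspace(0.0, 1.0, n_grid)
    V = np.zeros(n_grid)
    r = ps.reward_vectors(spec)

    for _ in range(max_iter):
        best = np.full(n_grid, -np.inf)
        for a in range(spec.n_actions):
            e0, e1 = spec.next_state[a]
            val = (1 - qs) * r[a, 0] + qs * r[a, 1]
            for o in (pm.NO_DETECTION, pm.DETECTION):
                l0, l1 = spec.obs_lik[a, e0, o], spec.obs_lik[a, e1, o]
                p_o = (1 - qs) * l0 + qs * l1
                w1 = (1 - qs) * l0 * (e0 == 1) + qs * l1 * (e1 == 1)
                pos = p_o > 1e-14
                q_post = np.zeros(n_grid)
                q_post[pos] = w1[pos] / p_o[pos]
                val = val + spec.gamma * p_o * np.interp(q_post, qs, V) * pos
            best = np.maximum(best, val)
        if np.max(np.abs(best - V)) < tol:
            return qs, best
        V = best
    raise RuntimeError("dense VI did not converge")


def expectimax_value(spec, b, action, depth, r):
    """Exact depth-limited value of taking `action` from belief b."""
    bp = np.bincount(spec.next_state[action], weights=b, minlength=spec.n_states)
    val = float(b @ r[action])
    if depth > 1:
        for o in (pm.NO_DETECTION, pm.DETECTION):
            w = bp * spec.obs_lik[action, :, o]
            p_o = w.sum()
            if p_o > 1e-14:
                post = w / p_o
                cont = max(
                    expectimax_value(spec, post, a2, depth - 1, r)
                    for a2 in range(spec.n_actions)
                )
                val += spec.gamma * p_o * cont
    return val


# ---------------------------------------------------------------------------
# basic operations
# ---------------------------------------------------------------------------


class TestValueOf:
    def test_upper_envelope(self):
        H = ps.AlphaSet(vectors=[[1.0, 0.0], [0.0, 1.0]])
        assert ps.value_of(np.array([0.3, 0.7]), H) == pytest.approx(0.7)

    def test_singleton_dot_product(self):
        H = ps.AlphaSet(vectors=[[0.2, 0.9]])
        b = np.array([0.4, 0.6])
        assert ps.value_of(b, H) == pytest.approx(0.2 * 0.4 + 0.9 * 0.6)

    def test_point_mass_picks_componentwise_max(self):
        H = ps.AlphaSet(vectors=[[0.1, 0.8], [0.5, 0.2]])
        b = np.array([1.0, 0.0])
        assert ps.value_of(b, H) == pytest.approx(0.5)


class TestPrecomputeAlphaAo:
    def test_delta_transition_identity(self, two_state_spec):
        spec = two_state_spec
        H = ps.AlphaSet(vectors=np.random.default_rng(0).normal(size=(3, 2)))
        table = ps.precompute_alpha_ao(H, spec)
        for k in range(3):
            for a in range(spec.n_actions):
                for o in (0, 1):
                    nxt = spec.next_state[a]
                    expected = H.vectors[k, nxt] * spec.obs_lik[a, nxt, o]
                    assert np.allclose(table[k, a, o], expected)

    def test_zero_alpha_gives_zero_table(self, two_state_spec):
        H = ps.AlphaSet.initial(2)
        assert np.all(ps.precompute_alpha_ao(H, two_state_spec) == 0)


class TestPrune:
    def test_dominated_vector_removed(self):
        H = ps.AlphaSet(vectors=[[1.0, 1.0], [0.5, 0.5]])
        assert np.array_equal(ps.prune(H).vectors, [[1.0, 1.0]])

    def test_undominated_pair_kept(self):
        H = ps.AlphaSet(vectors=[[1.0, 0.0], [0.0, 1.0]])
        assert len(ps.prune(H)) == 2

    def test_duplicates_collapse_to_one(self):
        H = ps.AlphaSet(vectors=[[0.3, 0.3], [0.3, 0.3], [0.3, 0.3]])
        assert len(ps.prune(H)) == 1

    def test_value_preserved_everywhere(self):
        rng = np.random.default_rng(3)
        H = ps.AlphaSet(vectors=rng.normal(size=(40, 4)))
        pruned = ps.prune(H)
        for _ in range(1000):
            b = rng.dirichlet(np.ones(4))
            assert ps.value_of(b, pruned) == pytest.approx(
                ps.value_of(b, H), abs=1e-9
            )


class TestBackup:
    def test_value_never_decreases_at_backed_up_belief(self, two_state_spec):
        spec = two_state_spec
        rng = np.random.default_rng(5)
        H = ps.AlphaSet.initial(2)
        for _ in range(30):
            b = rng.dirichlet(np.ones(2))
            before = ps.value_of(b, H)
            H = ps.backup(H, b, spec)
            assert ps.value_of(b, H) >= before - 1e-12

    def test_reward_dominance_next_to_source(self, two_state_spec):
        spec = two_state_spec
        b = np.array([0.0, 1.0])  # surely one cell downwind of the source
        H = ps.backup(ps.AlphaSet.initial(2), b, spec)
        assert H.actions[-1] == 0  # upwind move onto the source
        assert ps.value_of(b, H) >= pm.source_prob(spec, b, 0) - 1e-12

    def test_repeated_backup_converges_to_dense_vi(self, two_state_spec):
        spec = two_state_spec
        qs, V_oracle = dense_belief_vi(spec, n_grid=1001)
        rng = np.random.default_rng(11)
        H = ps.AlphaSet.initial(2)
        beliefs = [np.array([1 - q, q]) for q in np.linspace(0, 1, 41)]
        for _ in range(60):
            for b in beliefs:
                H = ps.backup(H, b, spec)
            H = ps.prune(H)
        b = np.array([0.55, 0.45])
        assert ps.value_of(b, H) == pytest.approx(
            np.interp(0.45, qs, V_oracle), abs=1e-6
        )

    def test_fixed_point_backup_adds_no_value(self, two_state_spec):
        spec = two_state_spec
        b = np.array([0.3, 0.7])
        H = ps.AlphaSet.initial(2)
        for _ in range(200):
            H = ps.backup(H, b, spec)
        before = ps.value_of(b, H)
        H2 = ps.backup(H, b, spec)
        assert ps.value_of(b, H2) == pytest.approx(before, abs=1e-9)


class TestGreedyAction:
    def test_moves_onto_source_when_adjacent(self, two_state_spec):
        spec = two_state_spec
        H = ps.AlphaSet.initial(2)
        b = np.array([0.0, 1.0])
        assert ps.greedy_action(b, H, spec) == 0

    def test_matches_expectimax_on_random_beliefs(self):
        spec = tiny_spec(n_x=2, n_y=1, air_rates=[[0.0], [0.6]],
                         ground_rates=[[0.0], [0.2]], gamma=0.35)
        rng = np.random.default_rng(2)
        H = ps.AlphaSet.initial(2)
        for _ in range(60):
            H = ps.backup(H, rng.dirichlet(np.ones(2)), spec)
        H = ps.prune(H)
        depth = 5
        tail = spec.gamma**depth / (1 - spec.gamma)
        r = ps.reward_vectors(spec)
        checked = 0
        for _ in range(60):
            b = rng.dirichlet(np.ones(2))
            vals = [
                expectimax_value(spec, b, a, depth, r)
                for a in range(spec.n_actions)
            ]
            order = np.argsort(vals)[::-1]
            if vals[order[0]] - vals[order[1]] <= 2 * tail:
                continue  # decision not certified at this depth
            assert ps.greedy_action(b, H, spec) == order[0]
            checked += 1
        assert checked >= 20

    def test_symmetric_belief_breaks_ties_deterministically(self):
        # symmetric maps and belief: left/right casts have equal value,
        # the lower-indexed action (move_left) must win any cast tie
        spec = tiny_spec(
            n_x=3, n_y=3,
            air_rates=np.tile([[0.2, 0.5, 0.2]], (3, 1)),
            origin=(0, 1), gamma=0.9,
        )
        b = np.zeros(spec.n_states)
        b[spec.state_index((2, 0))] = 0.5
        b[spec.state_index((2, 2))] = 0.5
        H = ps.AlphaSet.initial(spec.n_states)
        a1 = ps.greedy_action(b, H, spec)
        a2 = ps.greedy_action(b, H, spec)
        assert a1 == a2


class TestTrain:
    def test_zero_episodes_leaves_initial_set(self, two_state_spec):
        H = ps.train(two_state_spec, np.array([0.5, 0.5]), n_episodes=0)
        assert len(H) == 1 and np.all(H.vectors == 0)

    def test_same_seed_reproduces_alpha_set(self, toy_dual_env):
        spec, prior = toy_dual_env
        H1 = ps.train(spec, prior, n_episodes=3, points_per_episode=10, seed=4)
        H2 = ps.train(spec, prior, n_episodes=3, points_per_episode=10, seed=4)
        assert np.array_equal(H1.vectors, H2.vectors)
        assert np.array_equal(H1.actions, H2.actions)

    def test_corridor_policy_reaches_source_in_minimum_steps(self):
        # 5x1 corridor, detection cell adjacent to the source; the agent
        # knows its start, so the optimal plan is 4 upwind moves: the
        # shortest-path oracle is the Manhattan distance
        spec = tiny_spec(n_x=5, n_y=1, ground_rates=[[0.0], [0.9], [0.0], [0.0], [0.0]],
                         origin=(0, 0), gamma=0.9)
        prior = np.zeros(5)
        prior[4] = 1.0
        H = ps.train(spec, prior, n_episodes=20, points_per_episode=20, seed=0)
        from sniffsearch.episode_runner import run_episode

        traj = run_episode(spec, H, prior, (4, 0), max_steps=50, seed=0)
        assert traj.outcome == "found"
        assert traj.n_steps == 4

    def test_no_dominated_vectors_after_training(self, toy_dual_env):
        spec, prior = toy_dual_env
        H = ps.train(spec, prior, n_episodes=4, points_per_episode=15, seed=1)
        A = H.vectors
        for i in range(len(A)):
            dominated = np.all(A[i] <= A + 1e-12, axis=1)
            dominated[i] = False
            strict = np.any(A > A[i] + 1e-12, axis=1)
            assert not np.any(dominated & strict)

    def test_alpha_set_grows_with_episodes(self, toy_dual_env):
        spec, prior = toy_dual_env
        hist = []
        ps.train(spec, prior, n_episodes=6, points_per_episode=15, seed=2,
                 history=hist)
        sizes = [n for _, n in hist]
        assert sizes[-1] > sizes[0]


def test_alpha_set_roundtrip(tmp_path, two_state_spec):
    H = ps.backup(ps.AlphaSet.initial(2), np.array([0.4, 0.6]), two_state_spec)
    path = tmp_path / "policy.npz"
    H.save(path, meta={"note": "test"})
    back = ps.AlphaSet.load(path)
    assert np.array_equal(back.vectors, H.vectors)
    assert np.array_equal(back.actions, H.actions)
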