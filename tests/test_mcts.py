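"""Vector-UCB selection, non-dominated child pools, and the search loop."""

import itertools

import numpy as np
import pytest

from pmcts.mcts import (
    SearchConfig,
    TreeNode,
    backpropagate,
    expand,
    run_search,
    select,
    simulate,
    ucb_vector,
    unguided_sampling,
    update_child_pool,
)
from pmcts.pareto import non_dominated_filter
from pmcts.policy import BEGIN, END, TokenVocabulary, UniformPolicy


def make_node(token="C", parent=None, n_obj=2, visits=0, reward=None):
    node = TreeNode(token, parent, n_obj)
    node.n_visits = visits
    if reward is not None:
        node.reward_sum = np.asarray(reward, dtype=float)
    return node


@pytest.fixture
def toy_policy():
    policy = UniformPolicy(TokenVocabulary(["C", "O", "N", "F"]), min_length=1)
    policy.grammar_mask = False
    return policy


class TestUCBVector:
    def test_unvisited_is_infinite(self):
        child = make_node()
        assert np.all(np.isinf(ucb_vector(child, parent_visits=5, c=1.0)))

    def test_pure_exploitation(self):
        child = make_node(visits=4, reward=(2, 1))
        np.testing.assert_allclose(
            ucb_vector(child, parent_visits=10, c=1e-12), (0.5, 0.25), atol=1e-6
        )

    def test_formula(self):
        child = make_node(visits=2, reward=(1, 0))
        bonus = np.sqrt(np.log(10) / 2)
        np.testing.assert_allclose(
            ucb_vector(child, parent_visits=10, c=1.0), (0.5 + bonus, bonus)
        )

    def test_exploration_term_shared_across_objectives(self):
        child = make_node(visits=3, reward=(0.5, 0.5))
        u1 = ucb_vector(child, parent_visits=9, c=2.0)
        assert u1[0] == pytest.approx(u1[1])

    def test_invalid_parent_visits(self):
        with pytest.raises(ValueError):
            ucb_vector(make_node(visits=1, reward=(0, 0)), parent_visits=0, c=1.0)


class TestChildPool:
    def _parent_with(self, rewards, visits):
        parent = make_node("^", visits=sum(visits))
        for r, v in zip(rewards, visits):
            parent.children.append(make_node(visits=v, reward=np.asarray(r) * v, parent=parent))
        return parent

    def test_trade_off_both_kept(self):
        parent = self._parent_with([(0.9, 0.1), (0.1, 0.9)], [10, 10])
        pool = update_child_pool(parent, c=1e-9)
        assert len(pool) == 2

    def test_dominated_child_pruned(self):
        parent = self._parent_with([(1.0, 1.0), (0.5, 0.5)], [10, 10])
        pool = update_child_pool(parent, c=1e-9)
        assert pool == [parent.children[0]]

    def test_unvisited_children_dominate_pool(self):
        parent = self._parent_with([(1.0, 1.0), (0.0, 0.0)], [10, 0])
        pool = update_child_pool(parent, c=1.0)
        assert pool == [parent.children[1]]

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(4)
        parent = self._parent_with(rng.random((20, 3)), [int(v) for v in rng.integers(1, 30, 20)])
        c = 0.3
        pool = update_child_pool(parent, c=c)
        ucbs = np.stack(
            [ucb_vector(ch, parent.n_visits, c) for ch in parent.children]
        )
        expected = [parent.children[i] for i in non_dominated_filter(ucbs)]
        assert pool == expected

    def test_childless_parent_errors(self):
        with pytest.raises(ValueError):
            update_child_pool(make_node(), c=1.0)


class TestSelect:
    def test_forced_chain_is_deterministic(self):
        root = make_node(BEGIN, visits=3)
        a = make_node("C", parent=root, visits=2, reward=(1, 1))
        root.children, root.expanded = [a], True
        b = make_node("O", parent=a, visits=1, reward=(1, 1))
        a.children, a.expanded = [b], True
        for seed in range(5):
            path = select(root, c=0.5, rng=np.random.default_rng(seed))
            assert path == [root, a, b]

    def test_deterministic_for_fixed_seed(self):
        rng_build = np.random.default_rng(0)
        root = make_node(BEGIN, visits=100)
        root.expanded = True
        for i in range(4):
            root.children.append(
                make_node("C", parent=root, visits=25, reward=rng_build.random(2) * 25)
            )
        p1 = select(root, c=0.2, rng=np.random.default_rng(9))
        p2 = select(root, c=0.2, rng=np.random.default_rng(9))
        assert p1 == p2

    def test_uniform_over_two_child_pool(self):
        root = make_node(BEGIN, visits=200)
        root.expanded = True
        for reward in [(0.9, 0.1), (0.1, 0.9)]:
            root.children.append(
                make_node("C", parent=root, visits=100, reward=np.asarray(reward) * 100)
            )
        rng = np.random.default_rng(0)
        counts = [0, 0]
        for _ in range(10_000):
            path = select(root, c=1e-9, rng=rng)
            counts[root.children.index(path[1])] += 1
        assert abs(counts[0] / 10_000 - 0.5) < 0.02


class TestExpand:
    def test_floor_dominates_width(self, toy_policy):
        class Spiked(UniformPolicy):
            def _raw_distribution(self, ids):
                p = np.zeros(len(self.vocab))
                p[self.vocab.index["C"]] = 0.7
                p[self.vocab.index["O"]] = 0.3
                return p

        policy = Spiked(toy_policy.vocab, min_length=1)
        policy.grammar_mask = False
        leaf = make_node(BEGIN)
        children = expand(leaf, policy, expansion_width=3, probability_floor=1e-4)
        assert sorted(ch.token for ch in children) == ["C", "O"]

    def test_top_width_matches_full_sort(self, markov_policy):
        leaf = TreeNode(BEGIN, None, 2)
        width = 5
        children = expand(leaf, markov_policy, expansion_width=width)
        dist = markov_policy.next_token_distribution([])
        order = np.lexsort((np.arange(len(dist)), -dist))
        expected = [markov_policy.vocab.tokens[i] for i in order[:width] if dist[i] > 1e-4]
        assert [ch.token for ch in children] == expected

    def test_double_expansion_errors(self, toy_policy):
        leaf = make_node(BEGIN)
        expand(leaf, toy_policy, 2)
        with pytest.raises(ValueError):
            expand(leaf, toy_policy, 2)

    def test_terminal_not_expandable(self, toy_policy):
        with pytest.raises(ValueError):
            expand(make_node(END), toy_policy, 2)


class TestSimulate:
    def test_terminal_child_evaluates_prefix_once(
        self, toy_policy, token_count_objectives
    ):
        root = make_node(BEGIN, n_obj=2)
        c_node = make_node("C", parent=root)
        end = make_node(END, parent=c_node)
        profiles = simulate(
            end, toy_policy, token_count_objectives, 5, np.random.default_rng(0), 10
        )
        assert len(profiles) == 1
        assert profiles[0].smiles == "C"

    def test_rollout_count_and_determinism(self, toy_policy, token_count_objectives):
        root = make_node(BEGIN, n_obj=2)
        child = make_node("C", parent=root)
        a = simulate(child, toy_policy, token_count_objectives, 3, np.random.default_rng(1), 8)
        b = simulate(child, toy_policy, token_count_objectives, 3, np.random.default_rng(1), 8)
        assert len(a) == 3
        assert [p.smiles for p in a] == [p.smiles for p in b]


class TestBackpropagate:
    def test_single_reward(self):
        root = make_node(BEGIN, n_obj=3)
        mid = make_node("C", parent=root, n_obj=3)
        leaf = make_node("O", parent=mid, n_obj=3)
        backpropagate([root, mid, leaf], [np.array([1.0, 0.0, 1.0])])
        for node in (root, mid, leaf):
            assert node.n_visits == 1
            np.testing.assert_array_equal(node.reward_sum, [1, 0, 1])

    def test_multiple_rewards_summed(self):
        root = make_node(BEGIN, n_obj=2)
        backpropagate([root], [np.array([1.0, 0.0]), np.array([0.0, 0.5])])
        assert root.n_visits == 2
        np.testing.assert_array_equal(root.reward_sum, [1.0, 0.5])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            backpropagate([make_node(n_obj=2)], [np.array([1.0, 0.0, 0.0])])

    def test_empty_rewards(self):
        with pytest.raises(ValueError):
            backpropagate([make_node()], [])


def brute_force_toy_front(max_len=6, alphabet="CONF"):
    strings = [
        "".join(t)
        for length in range(1, max_len + 1)
        for t in itertools.product(alphabet, repeat=length)
    ]
    vectors = [[s.count("C") / len(s), s.count("O") / len(s)] for s in strings]
    keep = non_dominated_filter(vectors)
    return {strings[i] for i in keep}


class TestRunSearch:
    def test_zero_iterations(self, toy_policy, token_count_objectives):
        result = run_search(
            SearchConfig(n_iterations=0, seed=0), toy_policy, token_count_objectives
        )
        assert len(result.archive) == 0
        assert result.oracle_calls == 0

    def test_toy_space_pareto_recovery(self, toy_policy, token_count_objectives):
        config = SearchConfig(
            n_iterations=3000,
            exploration_c=0.7,  # enumeration needs strong exploration
            expansion_width=5,
            rollouts_per_child=1,
            max_smiles_length=6,
            seed=1,
        )
        result = run_search(config, toy_policy, token_count_objectives)
        assert set(result.archive.smiles()) == brute_force_toy_front()

    def test_same_seed_bit_identical(self, toy_policy, token_count_objectives):
        config = SearchConfig(
            n_iterations=200, expansion_width=5, max_smiles_length=6, seed=7
        )
        a = run_search(config, toy_policy, token_count_objectives)
        b = run_search(config, toy_policy, token_count_objectives)
        assert a.oracle_calls == b.oracle_calls
        assert [s for s, _, _ in a.all_sampled] == [s for s, _, _ in b.all_sampled]
        assert a.archive.entries.keys() == b.archive.entries.keys()
        for smi in a.archive.smiles():
            np.testing.assert_array_equal(
                a.archive.entries[smi][0], b.archive.entries[smi][0]
            )

    def test_archive_nondominated_throughout(self, toy_policy, token_count_objectives):
        config = SearchConfig(
            n_iterations=300, expansion_width=5, max_smiles_length=6, seed=3
        )
        result = run_search(config, toy_policy, token_count_objectives)
        mat = result.archive.vectors()
        assert non_dominated_filter(mat) == list(range(len(mat)))

    def test_oracle_budget_respected(self, toy_policy, token_count_objectives):
        config = SearchConfig(
            n_iterations=10_000,
            expansion_width=5,
            max_smiles_length=6,
            seed=0,
            max_oracle_calls=100,
        )
        result = run_search(config, toy_policy, token_count_objectives)
        assert result.oracle_calls <= 100 + config.expansion_width * config.rollouts_per_child

    def test_objective_permutation_equivariance(self, toy_policy):
        """Swapping objective order permutes archive vectors identically —
        there is no scalarization anywhere in the engine."""
        from pmcts.objectives import PropertyProfile

        class Swapped:
            n_objectives = 2
            names = ["frac_O", "frac_C"]

            def evaluate(self, smiles):
                n = len(smiles)
                if n == 0:
                    return PropertyProfile(smiles=smiles, valid=False, normalized=np.zeros(2))
                vec = np.array([smiles.count("O") / n, smiles.count("C") / n])
                return PropertyProfile(smiles=smiles, valid=True, raw={}, normalized=vec)

        from tests.helpers import TokenCountObjectives

        config = SearchConfig(
            n_iterations=400, expansion_width=5, max_smiles_length=6, seed=5
        )
        straight = run_search(config, toy_policy, TokenCountObjectives())
        swapped = run_search(config, toy_policy, Swapped())
        assert straight.archive.entries.keys() == swapped.archive.entries.keys()
        for smi in straight.archive.smiles():
            np.testing.assert_array_equal(
                straight.archive.entries[smi][0],
                swapped.archive.entries[smi][0][::-1],
            )

    def test_root_visit_conservation(self, toy_policy, token_count_objectives):
        # every reward vector propagated passes through the root exactly once:
        # total sampled records equals root visit count
        config = SearchConfig(
            n_iterations=150, expansion_width=4, max_smiles_length=6, seed=2
        )
        result = run_search(config, toy_policy, token_count_objectives)
        assert result.oracle_calls == len(result.all_sampled)


class TestUnguidedSampling:
    def test_budget_and_archive(self, toy_policy, token_count_objectives):
        result = unguided_sampling(toy_policy, token_count_objectives, 200, seed=0, max_smiles_length=6)
        assert result.oracle_calls == 200
        mat = result.archive.vectors()
        assert non_dominated_filter(mat) == list(range(len(mat)))

    def test_deterministic(self, toy_policy, token_count_objectives):
        a = unguided_sampling(toy_policy, token_count_objectives, 50, seed=4, max_smiles_length=6)
        b = unguided_sampling(toy_policy, token_count_objectives, 50, seed=4, max_smiles_length=6)
        assert [s for s, _, _ in a.all_sampled] == [s for s, _, _ in b.all_sampled]


def test_search_config_validation():
    with pytest.raises(ValueError):
        SearchConfig(exploration_c=0.0)
    with pytest.raises(ValueError):
        SearchConfig(expansion_width=0)
    with pytest.raises(ValueError):
        SearchConfig(descent="sideways")
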