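"""Pareto-guided Monte Carlo tree search over SMILES token prefixes.

The search tree's nodes are SMILES tokens; a root-to-node path spells a
molecule prefix.  Each iteration runs the classic four MCTS steps, but
every scalar quantity of single-objective MCTS is replaced by a vector
and every argmax by Pareto non-domination — no weighted sum of
objectives appears anywhere:

* selection — at each level the child pool is the set of children whose
  vector UCBs are mutually non-dominated; one pool member is drawn
  uniformly at random;
* expansion — a leaf gains one child per top-probability next token of
  the generative policy (above a probability floor);
* simulation — every fresh child is completed to full molecules by
  policy rollouts and scored into normalized objective vectors;
* backpropagation — reward *vectors* are summed into every node on the
  path.

Every valid molecule seen in simulation is offered to an unbounded
non-dominated archive (the output Pareto front).  An unguided-sampling
baseline with the same oracle accounting is provided for budget-matched
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from pmcts.pareto import (
    FingerprintSet,
    ParetoArchive,
    auto_hv_method,
    diversity,
    hypervolume,
    non_dominated_filter,
    success_rate,
)
from pmcts.policy import BEGIN, END, detokenize, rollout

__all__ = [
    "TreeNode",
    "SearchConfig",
    "RunResult",
    "ucb_vector",
    "update_child_pool",
    "select",
    "expand",
    "simulate",
    "backpropagate",
    "run_search",
    "unguided_sampling",
]


class TreeNode:
    """One token of a SMILES prefix in the search tree."""

    __slots__ = ("token", "parent", "children", "n_visits", "reward_sum", "expanded")

    def __init__(self, token: str, parent: "TreeNode | None", n_objectives: int):
        self.token = token
        self.parent = parent
        self.children: list[TreeNode] = []
        self.n_visits = 0
        self.reward_sum = np.zeros(n_objectives)
        self.expanded = False

    @property
    def is_terminal(self) -> bool:
        return self.token == END

    def prefix_tokens(self) -> list[str]:
        """Content tokens from the root to this node (sentinels excluded)."""
        toks: list[str] = []
        node: TreeNode | None = self
        while node is not None:
            if node.token not in (BEGIN, END):
                toks.append(node.token)
            node = node.parent
        return toks[::-1]

    def mean_reward(self) -> np.ndarray:
        if self.n_visits == 0:
            raise ValueError("mean reward undefined for an unvisited node")
        return self.reward_sum / self.n_visits


def ucb_vector(child: TreeNode, parent_visits: int, c: float) -> np.ndarray:
    """Vector UCB: mean reward per objective plus a shared exploration bonus.

    Component k is ``reward_sum_k / n_i + c * sqrt(ln N / n_i)`` — the
    UCB1 score applied per objective with an identical exploration term.
    An unvisited child returns +inf in every component (first-play
    urgency), guaranteeing it is simulated before exploitation resumes.
    """
    if parent_visits < 1:
        raise ValueError(f"parent visit count must be >= 1, got {parent_visits}")
    n = child.n_visits
    if n == 0:
        return np.full(child.reward_sum.shape, np.inf)
    bonus = c * np.sqrt(np.log(parent_visits) / n)
    return child.reward_sum / n + bonus


def update_child_pool(parent: TreeNode, c: float) -> list[TreeNode]:
    """The non-dominated child pool, recomputed from current statistics.

    Children whose UCB vectors are Pareto-dominated by a sibling are
    excluded.  Unvisited children carry infinite UCBs, which dominate
    every finite vector, so whenever any child is unvisited the pool is
    exactly the unvisited children.
    """
    if not parent.children:
        raise ValueError("cannot build a child pool for a childless node")
    unvisited = [ch for ch in parent.children if ch.n_visits == 0]
    if unvisited:
        return unvisited
    ucbs = np.stack(
        [ucb_vector(ch, max(parent.n_visits, 1), c) for ch in parent.children]
    )
    keep = non_dominated_filter(ucbs)
    return [parent.children[i] for i in keep]


def select(
    root: TreeNode, c: float, rng: np.random.Generator
) -> list[TreeNode]:
    """Descend from the root, drawing uniformly from each child pool,
    until an unexpanded or terminal node; returns the full path."""
    path = [root]
    node = root
    while node.expanded and node.children and not node.is_terminal:
        pool = update_child_pool(node, c)
        node = pool[int(rng.integers(len(pool)))]
        path.append(node)
    return path


def expand(
    leaf: TreeNode,
    policy,
    expansion_width: int,
    probability_floor: float = 1e-4,
) -> list[TreeNode]:
    """Create children for the top-``expansion_width`` next tokens.

    Tokens must exceed ``probability_floor``; ties break on vocabulary
    index so the child set is deterministic for a fixed policy/prefix.
    Expanding a terminal or already-expanded node is an error.
    """
    if leaf.is_terminal:
        raise ValueError("cannot expand a terminal (END) node")
    if leaf.expanded:
        raise ValueError("node already expanded")
    dist = policy.next_token_distribution(leaf.prefix_tokens())
    order = np.lexsort((np.arange(len(dist)), -dist))
    n_obj = leaf.reward_sum.shape[0]
    children = []
    for idx in order[:expansion_width]:
        if dist[idx] <= probability_floor:
            break
        children.append(TreeNode(policy.vocab.tokens[idx], leaf, n_obj))
    leaf.children = children
    leaf.expanded = True
    return children


def simulate(
    child: TreeNode,
    policy,
    objectives,
    rollouts_per_child: int,
    rng: np.random.Generator,
    max_len: int,
) -> list:
    """Complete the child's prefix to full molecules and score them.

    A terminal child evaluates exactly its prefix molecule once; other
    children get ``rollouts_per_child`` policy completions.  Returns the
    property profiles (invalid completions carry the zero vector).
    """
    prefix = child.prefix_tokens()
    if child.is_terminal or len(prefix) >= max_len:
        # nothing to roll out: evaluate exactly this molecule
        return [objectives.evaluate(detokenize(prefix))]
    profiles = []
    for _ in range(rollouts_per_child):
        tokens, _truncated = rollout(policy, prefix, max_len, rng)
        profiles.append(objectives.evaluate(detokenize(tokens)))
    return profiles


def backpropagate(path: Sequence[TreeNode], rewards: Sequence[np.ndarray]) -> None:
    """Add the reward vectors into every node on the path — no scalarization.

    Each node gains ``len(rewards)`` visits and the componentwise sum of
    the vectors.
    """
    if len(rewards) == 0:
        raise ValueError("backpropagate requires at least one reward vector")
    total = np.sum(np.asarray(rewards, dtype=float), axis=0)
    for node in path:
        if total.shape != node.reward_sum.shape:
            raise ValueError(
                f"reward dimension {total.shape[0]} does not match tree "
                f"dimension {node.reward_sum.shape[0]}"
            )
        node.n_visits += len(rewards)
        node.reward_sum = node.reward_sum + total
    return None


@dataclass
class SearchConfig:
    """Tunable knobs of the search loop.

    ``exploration_c`` is the UCB exploration constant (shared by all
    objective dimensions); ``n_iterations`` counts select/expand/
    simulate/backpropagate cycles; ``max_oracle_calls`` optionally stops
    the run once that many molecule evaluations have been spent,
    enabling budget-matched comparisons.  ``hv_report_interval = 0``
    disables intermediate metric snapshots.
    """

    n_iterations: int = 500
    exploration_c: float = 0.1
    expansion_width: int = 3
    probability_floor: float = 1e-4
    rollouts_per_child: int = 2
    max_smiles_length: int = 60
    hv_report_interval: int = 0
    seed: int = 0
    max_oracle_calls: int | None = None
    descent: str = "restart"  # {'restart', 'episode'}

    def __post_init__(self):
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")
        if self.exploration_c <= 0:
            raise ValueError("exploration_c must be > 0")
        for name in ("expansion_width", "rollouts_per_child", "max_smiles_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.descent not in ("restart", "episode"):
            raise ValueError(f"descent must be 'restart' or 'episode', got {self.descent!r}")


@dataclass
class RunResult:
    """Everything a search run produced.

    ``archive`` is the non-dominated molecule pool; ``all_sampled``
    records every evaluated molecule as (smiles, vector, iteration),
    invalid completions included with the zero vector; ``trace`` holds
    periodic metric snapshots.
    """

    archive: ParetoArchive
    all_sampled: list[tuple[str, np.ndarray, int]]
    trace: list[dict]
    config: SearchConfig
    objective_names: list[str]
    oracle_calls: int
    profiles: dict = field(default_factory=dict)  # canonical smiles -> PropertyProfile

    def unique_valid(self) -> list[str]:
        return list(self.profiles)

    def metrics(self, criteria=None, fp_radius: int = 2, fp_bits: int = 2048) -> dict:
        """Final HV / SR / Div summary.

        HV is the hypervolume of the archive front (reference at the
        origin of normalized space); SR and Div are computed over the
        unique valid molecules generated during the whole run.
        """
        out = {
            "n_molecules": len(self.profiles),
            "n_objectives": len(self.objective_names),
            "archive_size": len(self.archive),
            "oracle_calls": self.oracle_calls,
        }
        vecs = self.archive.vectors()
        n_obj = len(self.objective_names)
        out["hv_method"] = auto_hv_method(len(vecs), n_obj)
        out["hv"] = hypervolume(vecs, ref=np.zeros(n_obj)) if len(vecs) else 0.0
        if criteria:
            records = [p.raw for p in self.profiles.values()]
            out["sr"] = success_rate(records, criteria) if records else None
        else:
            out["sr"] = None
        smiles = self.unique_valid()
        if len(smiles) >= 2:
            out["div"] = diversity(
                FingerprintSet.from_smiles(smiles, radius=fp_radius, n_bits=fp_bits)
            )
        else:
            out["div"] = None
        return out


class _EvalCache:
    """Memoizes molecule evaluations by input SMILES.

    Oracle-call accounting is unaffected: every evaluation request is
    counted by the caller whether or not it hits the cache, so
    budget-matched comparisons stay fair; the cache only saves wall time
    on repeated molecules.
    """

    def __init__(self, objectives):
        self._objectives = objectives
        self._cache: dict[str, object] = {}
        self.n_objectives = objectives.n_objectives
        self.names = list(objectives.names)

    def evaluate(self, smiles: str):
        profile = self._cache.get(smiles)
        if profile is None:
            profile = self._objectives.evaluate(smiles)
            self._cache[smiles] = profile
        return profile


def _offer(result: RunResult, profile, iteration: int) -> None:
    result.all_sampled.append((profile.smiles, profile.normalized.copy(), iteration))
    if profile.valid:
        if profile.smiles not in result.profiles:
            result.profiles[profile.smiles] = profile
        result.archive.insert(profile.smiles, profile.normalized, profile.raw)


def _snapshot(result: RunResult, iteration: int) -> None:
    vecs = result.archive.vectors()
    n_obj = len(result.objective_names)
    hv = hypervolume(vecs, ref=np.zeros(n_obj)) if len(vecs) else 0.0
    result.trace.append(
        {
            "iteration": iteration,
            "hv": hv,
            "archive_size": len(result.archive),
            "oracle_calls": result.oracle_calls,
        }
    )


def run_search(config: SearchConfig, policy, objectives) -> RunResult:
    """Run the full Pareto-MCTS loop and collect the molecule archive.

    ``objectives`` is any object exposing ``evaluate(smiles) ->
    PropertyProfile``, ``n_objectives`` and ``names`` (an
    :class:`~pmcts.objectives.ObjectiveSet` or a test double).  The run
    is fully reproducible given ``config.seed``: selection and rollout
    randomness flow from independent seeded substreams.
    """
    n_obj = objectives.n_objectives
    names = list(objectives.names)
    objectives = _EvalCache(objectives)
    sel_ss, roll_ss = np.random.SeedSequence(config.seed).spawn(2)
    sel_rng = np.random.default_rng(sel_ss)
    roll_rng = np.random.default_rng(roll_ss)

    root = TreeNode(BEGIN, None, n_obj)
    result = RunResult(
        archive=ParetoArchive(n_objectives=n_obj),
        all_sampled=[],
        trace=[],
        config=config,
        objective_names=names,
        oracle_calls=0,
    )

    def budget_left() -> bool:
        return (
            config.max_oracle_calls is None
            or result.oracle_calls < config.max_oracle_calls
        )

    def _evaluate_terminal(node: TreeNode, path: list[TreeNode], iteration: int):
        profiles = simulate(
            node, policy, objectives, 1, roll_rng, config.max_smiles_length
        )
        result.oracle_calls += len(profiles)
        for p in profiles:
            _offer(result, p, iteration)
        backpropagate(path, [p.normalized for p in profiles])

    def _expand_and_simulate(node: TreeNode, path: list[TreeNode], iteration: int):
        children = expand(
            node, policy, config.expansion_width, config.probability_floor
        )
        for child in children:
            profiles = simulate(
                child,
                policy,
                objectives,
                config.rollouts_per_child,
                roll_rng,
                config.max_smiles_length,
            )
            result.oracle_calls += len(profiles)
            for p in profiles:
                _offer(result, p, iteration)
            backpropagate(path + [child], [p.normalized for p in profiles])

    n_iterations_run = 0
    for iteration in range(config.n_iterations):
        if not budget_left():
            break
        if config.descent == "restart":
            # classic MCTS cycle: select to the frontier, expand it once
            path = select(root, config.exploration_c, sel_rng)
            leaf = path[-1]
            if (
                leaf.is_terminal
                or len(leaf.prefix_tokens()) >= config.max_smiles_length
            ):
                _evaluate_terminal(leaf, path, iteration)
            else:
                _expand_and_simulate(leaf, path, iteration)
        else:
            # one molecule episode: descend from the root, expanding and
            # simulating every fresh level, until a termination symbol or
            # the length cap
            node, path = root, [root]
            while budget_left():
                if (
                    node.is_terminal
                    or len(node.prefix_tokens()) >= config.max_smiles_length
                ):
                    _evaluate_terminal(node, path, iteration)
                    break
                if not node.expanded:
                    _expand_and_simulate(node, path, iteration)
                if not node.children:
                    break
                pool = update_child_pool(node, config.exploration_c)
                node = pool[int(sel_rng.integers(len(pool)))]
                path.append(node)
        n_iterations_run += 1
        if (
            config.hv_report_interval
            and (iteration + 1) % config.hv_report_interval == 0
        ):
            _snapshot(result, iteration + 1)
    _snapshot(result, n_iterations_run)
    return result


def unguided_sampling(
    policy,
    objectives,
    n_oracle_calls: int,
    seed: int = 0,
    max_smiles_length: int = 60,
) -> RunResult:
    """Pure policy sampling baseline with identical oracle accounting.

    Draws complete molecules from the policy (no tree guidance), scores
    each, and maintains the same non-dominated archive — the control arm
    for budget-matched comparisons against :func:`run_search`.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    objectives = _EvalCache(objectives)
    result = RunResult(
        archive=ParetoArchive(n_objectives=objectives.n_objectives),
        all_sampled=[],
        trace=[],
        config=SearchConfig(n_iterations=0, seed=seed, max_smiles_length=max_smiles_length),
        objective_names=list(objectives.names),
        oracle_calls=0,
    )
    for i in range(n_oracle_calls):
        tokens, _ = rollout(policy, [], max_smiles_length, rng)
        profile = objectives.evaluate(detokenize(tokens))
        result.oracle_calls += 1
        _offer(result, profile, i)
    _snapshot(result, n_oracle_calls)
    return result
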