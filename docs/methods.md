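# Methods

## Overview

`pmcts` generates small molecules that trade off many design objectives at
once. It couples a SMILES-token generative policy with a Monte Carlo tree
search in which every scalar quantity of classical single-objective MCTS is
replaced by a vector and every argmax by Pareto non-domination. The output
is not a single "best" molecule but an unbounded archive approximating the
Pareto frontier of the objective space, evaluated by hypervolume, success
rate and internal diversity.

## The search model

The search tree is a prefix tree over SMILES tokens: the root is a
begin-of-sequence sentinel and a root-to-node path spells a molecule
prefix. Each iteration runs the four standard MCTS steps with these
vector-valued replacements:

* **Reward.** A simulated molecule is scored on all `n` objectives and the
  normalized vector `(o_1, ..., o_n)` is backpropagated unchanged — there
  is no weighted sum or other scalarization anywhere in the engine.
  Node statistics are a visit count and a componentwise reward sum.
* **Selection.** Each child carries a vector upper confidence bound whose
  component `k` is `reward_sum_k / n_i + c * sqrt(ln N / n_i)` — the UCB1
  rule applied per objective with a single shared exploration term
  (`N` parent visits, `n_i` child visits, `c` the exploration constant).
  The *child pool* is the subset of children whose UCB vectors are
  mutually non-dominated; selection draws uniformly at random from the
  pool. An unvisited child has an infinite UCB in every component and
  therefore preempts the pool (first-play urgency).
* **Expansion.** A leaf gains one child per token among the
  top-`expansion_width` next tokens of the generative policy, subject to a
  probability floor (default 1e-4).
* **Simulation.** Every fresh child is completed to full molecules by
  policy rollouts (`rollouts_per_child` each) and scored. Invalid SMILES
  receive the all-zero vector — the search is penalized for grammar
  failures — but never enter the archive.

Every valid molecule seen anywhere in simulation is offered to the
**molecule archive**, an unbounded set keyed by canonical SMILES in which
no entry Pareto-dominates another: a dominated candidate is rejected, an
accepted candidate evicts every entry it dominates, and equal vectors
coexist. Insertion order provably does not affect the final content, which
the tests check by permutation.

Two descent schedules are provided. The default (`descent="restart"`)
restarts from the root each iteration and expands one frontier node — the
classical MCTS cycle, which spreads the budget broadly. The alternative
(`descent="episode"`) descends until a termination token, expanding every
fresh level along the way, which drives the tree to full molecule depth
quickly at the cost of more strongly correlated samples. At the small
budgets used in the tests, restart mode is the better default; episode
mode becomes attractive when the budget per run is much larger than the
tree width.

## Dominance conventions

Dominance is the weak Pareto relation on maximized objectives: `a`
dominates `b` when `a >= b` componentwise with at least one strict
inequality. Equal vectors are mutually non-dominated and are all retained
both by the non-dominated filter and the archive; this matters because a
molecule set can contain distinct structures with identical scores.

## Objectives and normalization

Raw properties live on heterogeneous scales (QED in [0,1], pIC50-like
activities in 0–10, logP unbounded). Each objective is mapped onto (0, 1]
by a Gaussian desirability curve `exp(-(x-mu)^2 / (2 sigma^2))` with three
shapes: symmetric (match a target value), high-saturating (score 1 for
`x >= mu`, for properties like potency that benefit from higher values)
and low-saturating (score 1 for `x <= mu`, for properties like toxicity or
synthetic-accessibility score). After normalization every objective is a
maximization problem, which is what the dominance layer assumes. The
output is floored at 1e-300 so extreme outliers remain strictly positive
and orderable.

Built-in raw-score providers: QED, SAScore (fragment-contribution
synthetic accessibility, 1 easy – 10 hard, via the RDKit contributed
implementation), Crippen logP, molecular weight, and seeded synthetic
bioactivity surrogates. A surrogate score is a fixed random linear
projection of the molecule's 2048-bit radius-2 Morgan fingerprint — the
projection weights are drawn once from a generator seeded by the target
identifier — squashed through a tanh onto (0, 10). Surrogates are
canonicalization-invariant, deterministic across platforms, and smooth
under small structural edits (homolog pairs with Tanimoto > 0.9 shift the
score by far less than 1 unit on average). They stand in for trained QSAR
models so that the optimizer can be exercised end-to-end without any
external model artifacts; they predict nothing about real pharmacology.

The bundled seven-objective demo panel mirrors a kinase-inhibitor
multi-parameter optimization: one surrogate potency (high-saturating at
mu=8, sigma=2, threshold > 5.5), logP as a solubility proxy (symmetric at
2.5 +/- 1.5, threshold < 5), surrogate permeability and metabolic
stability (high-saturating at 7 +/- 2.5, thresholds > 4), a minimized
surrogate toxicity (low-saturating at 3 +/- 2, threshold < 5), QED
(high-saturating at 0.8 +/- 0.25, threshold > 0.6) and SAScore
(low-saturating at 2.5 +/- 1.5, threshold < 4). The mu/sigma/threshold
values were fixed when the panel was designed, from the typical ranges of
the providers on drug-like molecules.

## Generative policies

SMILES strings are tokenized by greedy longest match: bracket atoms,
two-character elements (Cl, Br), `%NN` ring labels and stereo markers are
single tokens, and unknown characters are a hard error (never a silent
split of a two-letter element). The vocabulary is induced from the
training corpus and frozen, so out-of-vocabulary generation is impossible
by construction.

Two policies implement the same next-token contract:

* a **k-order Markov chain** (default, k=3) with longest-suffix back-off
  down to the unigram distribution — training is counting, so it fits in
  seconds and needs no learning framework;
* a small **Elman recurrent network** (embedding, one tanh recurrent
  layer, softmax head) trained by backpropagation through time with Adam,
  implemented directly on NumPy. Defaults are deliberately small
  (32-dim embedding, 64 hidden units, 5 epochs); the held-out per-token
  perplexity must beat the unigram baseline, which the tests assert.

Both policies mask the END token until a minimum molecule length (default
8 tokens) and renormalize, so trivial fragments cannot dominate sampling.

### The SMILES syntax mask

Raw k-gram sampling of SMILES produces mostly invalid strings (unbalanced
rings and branches, broken aromaticity, valence errors). The policies
therefore filter every next-token distribution through an incremental
syntax state machine that tracks branch depth, open ring bonds with their
opening depth and running ring-path size, and a per-atom valence budget.
The mask enforces, among others:

* balanced parentheses and ring-bond pairing; a branch must close its own
  rings before `)`; END only in a fully closed state;
* per-atom valence caps (a saturated atom takes no further bond, branch
  or ring), with bracket atoms parsed for explicit hydrogens and charge;
* aromatic-ring construction rules: an aromatic atom off any ring path
  must immediately open a ring; ring paths are aromatically homogeneous;
  unfused aromatic rings close as six-membered rings or five-membered
  rings containing exactly one two-electron donor (o, s, or [nH]-type);
  pyridine-type `n` takes no substituent and never becomes a charged
  bridgehead; fused-ring sizes are estimated by collapsing the inner
  ring's path when it closes;
* small-molecule structural budgets (at most 3 concurrently open rings,
  5 ring openings, branch depth 5, and a soft 40-atom cap beyond which no
  new ring or branch opens) — generous bounds that every corpus string
  satisfies;
* during rollouts, a length budget that suppresses tokens whose minimal
  closure cost no longer fits before the length cap, so sampled strings
  wrap up instead of truncating.

The mask is a *local* filter, not a validity proof — kekulization of
exotic fused systems can still fail — but it lifts the order-3 Markov
validity on the fixture corpus from under 20% to roughly 95-99%, with
every training-corpus string remaining exactly reproducible (the suite
verifies that all corpus prefixes keep their true continuation legal).
It can be disabled per policy (`grammar_mask = False`), which the toy
searches over non-chemical token spaces use.

## Metrics

* **Hypervolume** is the Lebesgue measure of the region dominated by the
  front, bounded below by a reference point; the reference defaults to
  the origin of normalized space, the natural lower bound of all
  objectives. The exact value is computed by the WFG-style
  exclusive-volume recursion (with a sorted 2-d sweep as base case).
  Because the recursion cost explodes with both dimension and front size,
  the automatic dispatch switches to a seeded Monte-Carlo estimator above
  a dimension-dependent front-size cap (300 points at d=4 down to 30 at
  d=8; measured, not guessed — 7-d exact on 100 points already takes tens
  of seconds). The Monte-Carlo estimator samples uniformly in the box
  spanned by the reference and the front's componentwise maximum and is
  unbiased; it doubles as the independent oracle for the exact routine in
  the tests (agreement within three binomial standard errors).
* **Success rate** is the fraction of unique generated molecules whose
  *raw* property values satisfy every per-objective threshold strictly
  (comparisons are `>` / `<` exactly as the screening panel states them).
* **Internal diversity** is the mean of (1 - Tanimoto) over the
  n(n-1)/2 unordered distinct pairs of radius-2/2048-bit Morgan
  fingerprints. The unordered-pair reading is the conventional one; a
  sum over ordered pairs would double the value and exceed 1.

Metrics are computed over unique molecules (canonical-SMILES
deduplication); the archive hypervolume is reported for the front.

## Fixture corpus

The corpus generator assembles molecules from a fixed fragment library —
benzene, pyridine, diazine, indole and quinoline cores; alkyl, ether and
amine prefixes; hydroxyl, amino, carboxyl, halogen, nitrile, amide,
morpholine, piperazine and sulfonamide decorations — with rejection of
anything RDKit cannot sanitize, duplicates, and molecular weights outside
150-500 Da. It is deterministic given its seed and emulates the scaffold
statistics of a kinase-inhibitor screening corpus at toy scale. What it
does *not* emulate: stereochemistry, charged species, macrocycles, exotic
ring systems, and the property distributions of any real compound
collection — so green tests demonstrate the machinery works, not that the
default policy generalizes to arbitrary chemical space.

## Numerical and design choices

* **Exploration constant.** Rewards live in [0,1] and sibling mean-reward
  gaps on the demo panel are of order 0.05-0.1, so the default
  `c = 0.1` keeps the exploration bonus commensurate with the signal;
  with textbook values (c ~ 0.7) the bonus swamps the rewards, every
  child pool degenerates to "all children", and the search reduces to a
  random walk. Exhaustive-enumeration settings (the toy recovery tests)
  deliberately raise `c`, since there the goal is coverage, not focus.
* **Defaults** `expansion_width = 3` and `rollouts_per_child = 2` were
  calibrated on development seeds disjoint from every seed used in the
  test suite, favoring deeper trees and lower-variance child estimates at
  desk-scale budgets (thousands of evaluations).
* Unvisited children get infinite UCBs and are simulated immediately at
  expansion time, so every child has at least one observation before the
  pool is pruned.
* Terminal (END) nodes are evaluated directly and are closed to
  expansion; re-encountered molecules are re-offered to the archive
  (idempotent) and re-counted against the oracle budget, keeping
  budget-matched comparisons fair. A per-run memo cache avoids paying the
  RDKit cost twice for the same string.
* Duplicate molecules are counted once in success-rate and diversity
  denominators.
* All randomness flows from a single seed through named NumPy
  `SeedSequence` substreams (selection, rollout), so runs are bit
  reproducible and components are independently replayable.
* Ties in expansion (equal token probabilities) break on vocabulary
  index; archive iteration order is insertion order; neither affects any
  reported metric.

## Known limitations

* The syntax mask encodes mainstream organic SMILES; corpora rich in
  charged species, isotopes or stereocenters inside brackets will pass
  tokenization but may be over-constrained during sampling (the mask can
  be disabled).
* With seven near-independent objectives most sampled molecules are
  mutually non-dominated, so the guided-versus-unguided hypervolume gap
  at small budgets is modest and noisy; the advantage of guidance grows
  with budget and with objective landscapes whose high-reward regions are
  rare.
* The exact hypervolume recursion is exponential in the worst case; very
  large high-dimensional fronts are estimated by Monte-Carlo (the report
  always states which method produced the number).
* The recurrent policy is a minimal reference implementation; it is not
  competitive with GPU-trained language models and is sized for CPU
  minutes.
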