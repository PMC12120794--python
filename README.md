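# pmcts — Pareto-guided Monte Carlo tree search for molecular generation

`pmcts` is a multi-objective de-novo molecular design tool for the common
drug-discovery situation where a candidate must satisfy many properties at
once — potency, solubility, permeability, metabolic stability, low
toxicity, drug-likeness, synthesizability — and no weighting of those
objectives is defensible a priori. Instead of collapsing the objectives
into one score, it searches for the *Pareto frontier*: the set of
molecules none of which can be improved in one property without degrading
another.

## Method

A generative policy `p(token | prefix)` over SMILES tokens (a k-order
Markov chain with a SMILES syntax mask by default; a small recurrent
network is included) proposes molecule continuations. A Monte Carlo tree
search over token prefixes steers generation, with every scalar of
single-objective MCTS replaced by an *n*-vector:

* the reward for a simulated molecule is its vector of normalized
  objective scores, `reward = (o_1, ..., o_n)`, each mapped to (0, 1] by
  a Gaussian desirability modifier so that all objectives are maximized;
* each child node carries a vector UCB with component
  `UCB_k = r̄_k + c sqrt(ln N / n_i)`;
* selection draws uniformly from the *non-dominated child pool* — the
  children whose UCB vectors no sibling Pareto-dominates;
* every valid simulated molecule is offered to an unbounded
  non-dominated archive keyed by canonical SMILES (dominated candidates
  are rejected; accepted ones evict the entries they dominate). The
  archive is the output frontier.

Result fronts are evaluated by the hypervolume indicator HV (volume
dominated by the front above the origin of normalized space), the success
rate SR (fraction of generated molecules passing every raw-property
threshold), and internal diversity Div (mean pairwise 1 − Tanimoto over
Morgan fingerprints). See `docs/methods.md` for the full model
description and design rationale.

Bioactivity/ADMET objectives are provided as deterministic *synthetic
surrogates* (seeded random projections of Morgan fingerprints on a 0–10
pIC50-like scale), so the whole pipeline runs reproducibly with no
external models; QED, SAScore, logP and molecular weight are computed
with RDKit.

## Worked example

```bash
# 1. a reproducible 1000-molecule corpus of valid drug-like SMILES
pmcts fixture --n 1000 --seed 0 --out corpus.smi

# 2. fit the default order-3 Markov policy
pmcts train --corpus corpus.smi --kind markov --order 3 --seed 0 --out policy.json

# 3. Pareto-MCTS on the built-in 7-objective surrogate panel
pmcts run --policy policy.json --objectives demo --max-oracle-calls 2000 \
          --iterations 1000000 --seed 1 --out results/

# 4. metrics for any archive CSV
pmcts metrics --archive results/archive.csv --objectives demo
```

Step 3 prints the one-line summary

```
archive 221 molecules | hv 0.9940 | sr 0.0640 | div 0.8540 | oracle calls 2005
```

meaning: after ~2000 molecule evaluations the non-dominated archive holds
221 molecules whose front dominates ≈ 0.99 of the unit objective cube
(hypervolume against the origin); 6.4% of the unique generated molecules
pass all seven raw-property thresholds simultaneously; and the generated
set is structurally diverse (mean pairwise Tanimoto distance 0.85).
Step 4 then reports the same metrics restricted to the archived frontier
molecules, whose success rate (0.27) is far above the whole-run rate —
the search concentrates on the feasible corner of objective space.
`results/` also contains the archive CSV (canonical SMILES,
normalized objective columns, raw property columns), the full sampling
log, a metrics JSON and a run manifest with the seed and config hashes
for exact reproduction: rerunning with the same seed reproduces the
archive byte-for-byte.

The library surface mirrors the CLI — `generate_fixture_corpus`,
`train_policy`, `run_search`, `ParetoArchive`, `hypervolume`,
`success_rate`, `diversity` — see the module docstrings.

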