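"""SMILES tokenization and generative next-token policies.

Two interchangeable policy kinds sit behind one contract (a conditional
next-token distribution over a frozen vocabulary given a token prefix):

* :class:`MarkovPolicy` — a k-order Markov chain with longest-suffix
  back-off; trains in seconds from token counts and needs no learning
  framework.  This is the default policy.
* :class:`RecurrentPolicy` — a small Elman recurrent network (embedding
  + tanh recurrent layer + softmax head) trained by backpropagation
  through time with Adam, implemented directly on NumPy.

Both policies are deterministic given their training seed, emit
distributions that sum to one, never produce out-of-vocabulary tokens,
and mask the END sentinel until a configurable minimum molecule length
so that trivial one-atom outputs cannot dominate sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "BEGIN",
    "END",
    "tokenize",
    "detokenize",
    "TokenVocabulary",
    "PolicyConfig",
    "MarkovPolicy",
    "RecurrentPolicy",
    "UniformPolicy",
    "train_policy",
    "rollout",
    "unigram_perplexity",
    "policy_perplexity",
    "save_policy",
    "load_policy",
]

BEGIN = "^"
END = "$"

# single-character SMILES tokens (organic subset, bonds, branches, rings)
_SINGLE = set("BCNOPSFIbcnops123456789%0()=#-+./\\*:~")
_TWO_CHAR = ("Cl", "Br", "@@")


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into grammar tokens by greedy longest match.

    Bracket atoms (``[nH]``, ``[C@@H]``...), two-character elements
    (``Cl``, ``Br``) and two-digit ring labels (``%12``) are single
    tokens; an unrecognized character raises with its position, never
    silently splitting a two-letter element.
    """
    tokens: list[str] = []
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i)
            if j < 0:
                raise ValueError(f"unclosed bracket atom at position {i} in {smiles!r}")
            tokens.append(smiles[i : j + 1])
            i = j + 1
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise ValueError(f"malformed ring label at position {i} in {smiles!r}")
            tokens.append(smiles[i : i + 3])
            i += 3
        elif smiles[i : i + 2] in _TWO_CHAR:
            tokens.append(smiles[i : i + 2])
            i += 2
        elif ch in _SINGLE:
            tokens.append(ch)
            i += 1
        else:
            raise ValueError(f"unknown SMILES character {ch!r} at position {i} in {smiles!r}")
    return tokens


def detokenize(tokens: Sequence[str]) -> str:
    """Inverse of :func:`tokenize`; sentinels are dropped."""
    return "".join(t for t in tokens if t not in (BEGIN, END))


class TokenVocabulary:
    """Frozen ordered token set with BEGIN/END sentinels and index maps."""

    def __init__(self, tokens: Sequence[str]):
        content = [t for t in dict.fromkeys(tokens) if t not in (BEGIN, END)]
        self.tokens: list[str] = [BEGIN, END] + content
        self.index = {t: i for i, t in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate tokens in vocabulary")

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def begin_id(self) -> int:
        return 0

    @property
    def end_id(self) -> int:
        return 1

    def encode(self, tokens: Sequence[str]) -> list[int]:
        try:
            return [self.index[t] for t in tokens]
        except KeyError as exc:
            raise KeyError(f"token {exc.args[0]!r} not in vocabulary") from None

    @classmethod
    def from_corpus(cls, corpus: Sequence[str]) -> "TokenVocabulary":
        seen: dict[str, None] = {}
        for line in corpus:
            for tok in tokenize(line):
                seen[tok] = None
        return cls(sorted(seen))


@dataclass
class PolicyConfig:
    """Training configuration shared by both policy kinds.

    ``min_length`` masks END for that many leading content tokens so the
    policy cannot terminate on trivial fragments.  Recurrent fields are
    ignored by the Markov kind and vice versa.
    """

    kind: str = "markov"  # {'markov', 'recurrent'}
    min_length: int = 8
    seed: int = 0
    holdout_frac: float = 0.1
    # markov
    order: int = 3
    # recurrent
    embedding_dim: int = 32
    hidden_dim: int = 64
    epochs: int = 5
    learning_rate: float = 5e-3
    batch_size: int = 16


_BONDS = set("=#-/\\:~")


def _is_ring_digit(token: str) -> bool:
    return (len(token) == 1 and token.isdigit()) or token.startswith("%")


def _is_atom(token: str) -> bool:
    return token.startswith("[") or token in {
        "B", "C", "N", "O", "P", "S", "F", "I", "Cl", "Br",
        "b", "c", "n", "o", "p", "s", "*",
    }


def _is_aromatic_atom(token: str) -> bool:
    if token.startswith("["):
        return any(c.islower() for c in token[1:3])
    return token in {"b", "c", "n", "o", "p", "s"}


# nominal valences; aromatic atoms get the in-ring bonding capacity
# (two ring bonds counted once each plus at most one substituent for c)
_VALENCE = {
    "B": 3, "C": 4, "N": 3, "O": 2, "P": 5, "S": 6,
    "F": 1, "Cl": 1, "Br": 1, "I": 1, "*": 4,
    "b": 3, "c": 3, "n": 3, "o": 2, "p": 3, "s": 2,
}


def _atom_cap(token: str) -> tuple[int, bool]:
    """(bonding capacity, aromatic?) for an atom token; brackets account
    for explicit hydrogens and charge."""
    if not token.startswith("["):
        return _VALENCE.get(token, 4), token.islower()
    body = token[1:-1].lstrip("0123456789")
    sym = body[:2] if body[:2] in ("Cl", "Br") else body[:1]
    aromatic = sym.islower()
    cap = _VALENCE.get(sym, 4)
    rest = body[len(sym):]
    if "H" in rest:
        idx = rest.index("H")
        digits = ""
        for c in rest[idx + 1 :]:
            if c.isdigit():
                digits += c
            else:
                break
        cap -= int(digits) if digits else 1
    cap += rest.count("+") - rest.count("-")
    return max(cap, 0), aromatic


class _Scan:
    """Incremental SMILES scanner: branch stack, ring table, per-atom valence.

    ``atoms`` holds ``[capacity, bonds_used, aromatic, hetero, token,
    emission depth]`` records;
    ``open_rings`` maps digit -> ``[opening depth, ring-path atoms,
    atoms since opening, fused, opener index, hetero path atoms]`` where
    ring-path atoms counts atoms emitted at the opening depth (a
    ring-size estimate, reliable only when ``fused`` is 0).
    """

    __slots__ = (
        "depth", "open_rings", "atom_count", "ring_opens",
        "prev", "atoms", "att", "stack", "pending",
    )

    def __init__(self, tokens: Sequence[str]):
        self.depth = 0
        self.open_rings: dict[str, list] = {}
        self.atom_count = 0
        self.ring_opens = 0
        self.prev = BEGIN
        self.atoms: list[list] = []
        self.att: int | None = None
        self.stack: list[int | None] = []
        self.pending = 1
        for t in tokens:
            self._push(t)

    def _push(self, t: str) -> None:
        if t == "(":
            self.stack.append(self.att)
            self.depth += 1
        elif t == ")":
            self.att = self.stack.pop()
            self.depth -= 1
            self.pending = 1
        elif t in _BONDS:
            self.pending = 2 if t == "=" else 3 if t == "#" else 1
        elif _is_ring_digit(t):
            if t in self.open_rings:
                odepth, path, _s, _f, _op, hetero, _d = self.open_rings.pop(t)
                # an ortho-fused inner ring contributes a two-atom shared
                # edge to the enclosing ring: collapse its extra path atoms
                for state in self.open_rings.values():
                    if state[0] == odepth:
                        state[1] = max(state[1] - (path - 1), 1)
                        state[5] = max(state[5] - hetero, 0)
            else:
                # a ring opening at the same depth marks true fusion; rings
                # opened deeper (inside branches) are decorations
                for state in self.open_rings.values():
                    if state[0] == self.depth:
                        state[3] = 1
                # a donor opener ([nH]/o/s, or substituted aromatic n)
                # commits the ring to five members
                opener_donor = False
                if self.att is not None:
                    rec = self.atoms[self.att]
                    opener_donor = rec[3] or (rec[4] == "n" and rec[1] > 0)
                self.open_rings[t] = [
                    self.depth, 0, 0, 0, self.att, 0, opener_donor
                ]
                self.ring_opens += 1
            if self.att is not None:
                self.atoms[self.att][1] += 1
            self.pending = 1
        elif _is_atom(t):
            cap, aromatic = _atom_cap(t)
            used = 0
            if self.att is not None:
                self.atoms[self.att][1] += self.pending
                used = self.pending
            # two-electron aromatic donors, the atoms that carry a
            # five-membered aromatic ring (pyrrole/furan/thiophene-like)
            hetero = t in ("o", "s") or (
                aromatic and t.startswith("[") and "H" in t
            )
            self.atoms.append([cap, used, aromatic, hetero, t, self.depth])
            self.att = len(self.atoms) - 1
            self.atom_count += 1
            for state in self.open_rings.values():
                if state[0] == self.depth:
                    state[1] += 1
                    state[5] += hetero
                state[2] += 1
            self.pending = 1
        self.prev = t

    def remaining(self) -> int:
        if self.att is None:
            return 99
        cap, used = self.atoms[self.att][0], self.atoms[self.att][1]
        return cap - used


# structural budgets keeping sampled strings at small-molecule scale;
# generous relative to the fixture corpus so every corpus string stays legal
_MAX_OPEN_RINGS = 3
_MAX_RING_OPENS = 5
_MAX_DEPTH = 5
_SOFT_MAX_ATOMS = 40


def legal_token_mask(
    vocab: TokenVocabulary,
    tokens: Sequence[str],
    scan: "_Scan | None" = None,
) -> np.ndarray:
    """Boolean mask of tokens that keep the SMILES prefix chemically closable.

    Enforces balanced parentheses; ring-bond pairing with ring sizes
    bounded at six for unfused rings; bonds only where an attachment
    atom exists; per-atom valence budgets (so a saturated atom accepts
    no further branch, bond or ring); aromatic/aliphatic consistency
    along an open ring path; END only when no parenthesis or ring is
    open; and small-molecule structural budgets (open rings, total ring
    openings, branch depth, a soft atom cap that stops new ring/branch
    openings).  A strong local filter, not a full validity guarantee —
    kekulization of exotic aromatic systems is still left to the
    chemistry layer.
    """
    s = scan if scan is not None else _Scan(tokens)
    prev = s.prev
    prev_is_attachment = _is_atom(prev) or _is_ring_digit(prev)
    may_grow = s.atom_count < _SOFT_MAX_ATOMS
    remaining = s.remaining()
    ring_here = any(
        state[0] == s.depth for state in s.open_rings.values()
    )
    # a five-membered-ring donor atom ([nH]/o/s) fits only an aromatic
    # ring under construction at this depth that can still close small
    # and holds no donor yet
    azole_ok = any(
        state[0] == s.depth
        and state[1] <= 3
        and state[5] == 0
        and not state[6]
        and state[4] is not None
        and s.atoms[state[4]][2]
        for state in s.open_rings.values()
    )
    n_free_digits = sum(
        1
        for t in vocab.tokens
        if _is_ring_digit(t) and t not in s.open_rings
    )
    # an aromatic atom not sitting on an open ring path must start (or
    # join) a ring immediately
    must_ring_digit = _is_aromatic_atom(prev) and not ring_here
    # unfused rings at the current depth with six path atoms (opener
    # included): closure is due at the next attachment point
    # the last-opened open ring per depth: the one whose path count is a
    # faithful size estimate (outer rings wait for their inner ring)
    innermost: dict[int, str] = {}
    for d, state in s.open_rings.items():
        innermost[state[0]] = d
    def _due_at(state) -> int:
        # aromatic rings holding a donor close as five-membered rings
        odepth, _p, _n, _f, op, hetero, odonor = state
        if op is not None and s.atoms[op][2] and (odonor or hetero >= 1):
            return 4
        return 5

    due = {
        d
        for d, state in s.open_rings.items()
        if state[0] == s.depth
        and state[2] >= 2
        and state[1] >= _due_at(state)
        and innermost[state[0]] == d
    }
    # aromaticity the next in-path atom must carry, if constrained
    ring_aromatic = {
        s.atoms[state[4]][2]
        for state in s.open_rings.values()
        if state[0] == s.depth and state[4] is not None
    }
    # states with a saturated attachment atom, rings open and no branch
    # to pop out of are unescapable; refuse tokens that enter them
    def _traps(spend: int, rings_after: bool) -> bool:
        return remaining - spend <= 0 and s.depth == 0 and rings_after

    att_rec = s.atoms[s.att] if s.att is not None else None
    # the attachment atom sits on a still-open ring at a shallower depth:
    # one bond stays reserved for that ring's continuation
    att_reserve = int(
        att_rec is not None
        and s.depth > att_rec[5]
        and any(st[0] == att_rec[5] for st in s.open_rings.values())
    )
    # pyridine-type aromatic n whose ring is finished takes no substituent
    att_closed_n = (
        att_rec is not None and att_rec[4] == "n" and not ring_here
    )

    mask = np.zeros(len(vocab.tokens), dtype=bool)
    for i, t in enumerate(vocab.tokens):
        if t == BEGIN:
            continue
        if due and prev_is_attachment and t not in due:
            continue
        if must_ring_digit and not _is_ring_digit(t):
            continue
        if t == END:
            mask[i] = s.depth == 0 and not s.open_rings
        elif t == "(":
            # on an open ring path one bond stays reserved for the ring
            need = (2 if ring_here else 1) + att_reserve
            mask[i] = (
                (prev_is_attachment or prev == ")")
                and s.depth < _MAX_DEPTH
                and may_grow
                and remaining >= need
                and not (remaining == 1 and s.depth == 0 and s.open_rings)
                # pyridine-type aromatic n takes no substituent
                and not (att_rec is not None and att_rec[4] == "n")
            )
        elif t == ")":
            # a branch must finish its own rings before closing
            mask[i] = (
                s.depth > 0
                and (prev_is_attachment or prev == ")")
                and not ring_here
            )
        elif t in _BONDS:
            # explicit bonds never appear along an open ring path (ring
            # bonds are implicit; an explicit single bond would break
            # aromatic kekulization)
            order = 2 if t == "=" else 3 if t == "#" else 1
            mask[i] = (
                (prev_is_attachment or prev in ("(", ")"))
                and remaining >= order + att_reserve
                and not ring_here
                and not att_closed_n
            )
        elif _is_ring_digit(t):
            if t in s.open_rings:
                odepth, path, since, _fused, op, hetero, odonor = s.open_rings[t]
                ok = (
                    prev_is_attachment
                    and odepth == s.depth  # rings close where they opened
                    and innermost[odepth] == t  # no ring-bond crossings
                    and since >= 2
                    and remaining >= 1
                    and op != s.att
                    and not _traps(1, len(s.open_rings) > 1)
                    # a ring bond ending on aromatic n while another ring
                    # is still open here would create a charged bridgehead
                    and not (
                        any(
                            d2 != t and st2[0] == odepth
                            for d2, st2 in s.open_rings.items()
                        )
                        and any(
                            idx is not None and s.atoms[idx][4] == "n"
                            for idx in (op, s.att)
                        )
                    )
                )
                if ok and op is not None and s.atoms[op][2]:
                    # aromatic ring: pure six-membered, or five-membered
                    # with exactly one two-electron donor; anything else
                    # cannot kekulize
                    if odonor:
                        ok = path == 4 and hetero == 0
                    else:
                        ok = (path == 5 and hetero == 0) or (
                            path == 4 and hetero == 1
                        )
                elif ok:
                    ok = path >= 4  # five- or six-membered aliphatic rings
                mask[i] = ok
            else:
                mask[i] = (
                    prev_is_attachment
                    and len(s.open_rings) < _MAX_OPEN_RINGS
                    and s.ring_opens < _MAX_RING_OPENS
                    and may_grow
                    and remaining >= 2 + att_reserve  # opener must bond an atom
                    and n_free_digits >= 1
                    # opening a second ring on aromatic n in a fused context
                    # would make it a charged bridgehead
                    and not (
                        att_rec is not None
                        and att_rec[4] == "n"
                        and ring_here
                    )
                )
        elif _is_atom(t):
            cap, aromatic = _atom_cap(t)
            ok = (
                remaining >= s.pending + att_reserve
                and cap >= s.pending
                and not att_closed_n
            )
            if ok and cap == s.pending and (
                ring_here or (s.depth == 0 and s.open_rings)
            ):
                ok = False  # saturates with a ring still open: dead end
            if ok and ring_aromatic:
                # continuing an open ring path: aromaticity must match
                ok = {aromatic} == ring_aromatic
            if ok and aromatic and t.startswith("[") and "H" in t:
                # pyrrole-type atom: five-membered aromatic rings only
                ok = azole_ok
            if ok and t == "n" and ring_here:
                # n landing on the forced-closure slot of a fused ring
                # would become a charged bridgehead
                inner = s.open_rings.get(innermost.get(s.depth, ""), None)
                if inner is not None:
                    others = any(
                        d2 != innermost[s.depth] and st2[0] == s.depth
                        for d2, st2 in s.open_rings.items()
                    )
                    if others and inner[1] + 1 >= _due_at(inner):
                        ok = False
            if ok and aromatic and not ring_here:
                # would have to start a ring on the next step: needs budgets,
                # an unused ring digit, and free valence for the ring bond
                ok = (
                    s.ring_opens < _MAX_RING_OPENS
                    and len(s.open_rings) < _MAX_OPEN_RINGS
                    and may_grow
                    and cap - s.pending >= 2
                    and n_free_digits >= 1
                )
            mask[i] = ok
    return mask


def _syntax_state(tokens: Sequence[str]):
    """Compatibility summary: (depth, open ring digits, atom count, prev)."""
    s = _Scan(tokens)
    return s.depth, s.open_rings, s.atom_count, s.prev


class _PolicyBase:
    kind = "base"

    vocab: TokenVocabulary
    min_length: int
    grammar_mask: bool = True

    def _raw_distribution(self, prefix_ids: Sequence[int]) -> np.ndarray:
        raise NotImplementedError

    def next_token_distribution(
        self, prefix: Sequence[str], _scan: "_Scan | None" = None
    ) -> np.ndarray:
        """Probability vector over the vocabulary for the next token.

        ``prefix`` is the content-token prefix (no sentinels required; a
        leading BEGIN is tolerated).  BEGIN never receives mass; END is
        masked until ``min_length`` content tokens and floored to a small
        positive probability afterwards (where the syntax allows
        termination).  Locally illegal SMILES continuations are masked
        out when ``grammar_mask`` is on (the default).  Deterministic
        for a fixed policy and prefix; sums to 1 within 1e-9.
        """
        content = [t for t in prefix if t != BEGIN]
        ids = self.vocab.encode(content)
        p = np.asarray(self._raw_distribution(ids), dtype=float).copy()
        p[self.vocab.begin_id] = 0.0
        legal = (
            legal_token_mask(self.vocab, content, scan=_scan)
            if self.grammar_mask
            else np.ones(len(self.vocab), dtype=bool)
        )
        legal[self.vocab.begin_id] = False
        if len(content) < self.min_length:
            legal[self.vocab.end_id] = False
        p[~legal] = 0.0
        if legal[self.vocab.end_id] and len(content) >= self.min_length:
            p[self.vocab.end_id] = max(p[self.vocab.end_id], 1e-6)
        total = p.sum()
        if total <= 0:
            # model mass entirely on illegal tokens: uniform over legal ones
            p = legal.astype(float)
            total = p.sum()
        if total <= 0:
            # no legal continuation at all (pathological prefix): emit END
            p = np.zeros(len(self.vocab))
            p[self.vocab.end_id] = 1.0
            total = 1.0
        return p / total


class MarkovPolicy(_PolicyBase):
    """k-order Markov chain with longest-suffix back-off.

    The next-token distribution uses the counts of the longest context
    (up to ``order`` previous tokens, BEGIN-padded) observed in training;
    unseen contexts back off to shorter suffixes, bottoming out at the
    unigram distribution, so the distribution is never a zero vector.
    """

    kind = "markov"

    def __init__(self, vocab: TokenVocabulary, order: int = 3, min_length: int = 8):
        if order < 1:
            raise ValueError(f"order must be >= 1, got {order}")
        self.vocab = vocab
        self.order = order
        self.min_length = min_length
        # context tuple (ids) -> counts over vocab
        self.counts: dict[tuple[int, ...], np.ndarray] = {}

    def fit(self, corpus: Sequence[str]) -> "MarkovPolicy":
        V = len(self.vocab)
        for line in corpus:
            ids = self.vocab.encode(tokenize(line)) + [self.vocab.end_id]
            padded = [self.vocab.begin_id] * self.order + ids
            for pos in range(self.order, len(padded)):
                nxt = padded[pos]
                for k in range(self.order + 1):
                    ctx = tuple(padded[pos - k : pos])
                    if ctx not in self.counts:
                        self.counts[ctx] = np.zeros(V)
                    self.counts[ctx][nxt] += 1
        return self

    def _raw_distribution(self, prefix_ids: Sequence[int]) -> np.ndarray:
        padded = [self.vocab.begin_id] * self.order + list(prefix_ids)
        for k in range(self.order, -1, -1):
            ctx = tuple(padded[len(padded) - k :]) if k else ()
            c = self.counts.get(ctx)
            if c is not None and c.sum() > 0:
                return c / c.sum()
        return np.ones(len(self.vocab)) / len(self.vocab)


class UniformPolicy(_PolicyBase):
    """Uniform distribution over content tokens; used for toy searches and
    as an explicit no-information baseline."""

    kind = "uniform"

    def __init__(self, vocab: TokenVocabulary, min_length: int = 1):
        self.vocab = vocab
        self.min_length = min_length

    def _raw_distribution(self, prefix_ids: Sequence[int]) -> np.ndarray:
        return np.ones(len(self.vocab)) / len(self.vocab)


class RecurrentPolicy(_PolicyBase):
    """Single-layer Elman recurrent network over SMILES tokens.

    h_t = tanh(E[x_t] Wxh + h_{t-1} Whh + bh);  logits_t = h_t Who + bo.
    Trained with full backpropagation through time and Adam on the
    next-token cross-entropy.  Deliberately small: the point is the same
    next-token contract as the Markov policy, learned densely.
    """

    kind = "recurrent"

    def __init__(
        self,
        vocab: TokenVocabulary,
        embedding_dim: int = 32,
        hidden_dim: int = 64,
        min_length: int = 8,
        seed: int = 0,
    ):
        self.vocab = vocab
        self.min_length = min_length
        self.embedding_dim = embedding_dim
        self.hidden_dim = hidden_dim
        rng = np.random.default_rng(seed)
        V, D, H = len(vocab), embedding_dim, hidden_dim
        s = 0.1
        self.params = {
            "E": rng.normal(0, s, (V, D)),
            "Wxh": rng.normal(0, s, (D, H)),
            "Whh": rng.normal(0, s, (H, H)),
            "bh": np.zeros(H),
            "Who": rng.normal(0, s, (H, V)),
            "bo": np.zeros(V),
        }

    # -- forward / backward -------------------------------------------

    def _forward(self, ids: list[int]):
        """Run [BEGIN] + ids and return hidden states + softmax probs per step."""
        p = self.params
        seq = [self.vocab.begin_id] + list(ids)
        H = self.hidden_dim
        hs = [np.zeros(H)]
        xs, probs = [], []
        for t, tok in enumerate(seq):
            x = p["E"][tok]
            h = np.tanh(x @ p["Wxh"] + hs[-1] @ p["Whh"] + p["bh"])
            logits = h @ p["Who"] + p["bo"]
            logits -= logits.max()
            e = np.exp(logits)
            probs.append(e / e.sum())
            xs.append(tok)
            hs.append(h)
        return xs, hs, probs

    def _seq_loss_grad(self, ids: list[int]):
        """Cross-entropy of predicting ids[0..]+END; returns (loss, grads)."""
        p = self.params
        targets = list(ids) + [self.vocab.end_id]
        xs, hs, probs = self._forward(ids)
        T = len(targets)
        loss = -sum(np.log(probs[t][targets[t]] + 1e-12) for t in range(T)) / T
        g = {k: np.zeros_like(v) for k, v in p.items()}
        dh_next = np.zeros(self.hidden_dim)
        for t in range(T - 1, -1, -1):
            dlogits = probs[t].copy()
            dlogits[targets[t]] -= 1.0
            dlogits /= T
            h = hs[t + 1]
            g["Who"] += np.outer(h, dlogits)
            g["bo"] += dlogits
            dh = p["Who"] @ dlogits + dh_next
            dz = dh * (1.0 - h * h)
            g["bh"] += dz
            g["Wxh"] += np.outer(p["E"][xs[t]], dz)
            g["Whh"] += np.outer(hs[t], dz)
            g["E"][xs[t]] += p["Wxh"] @ dz
            dh_next = p["Whh"] @ dz
        return loss, g

    def fit(
        self,
        corpus: Sequence[str],
        epochs: int = 5,
        learning_rate: float = 5e-3,
        batch_size: int = 16,
        seed: int = 0,
        holdout: Sequence[str] | None = None,
        verbose: bool = False,
    ) -> list[float]:
        """Train with Adam; returns the per-epoch held-out (or training) loss,
        including the pre-training loss as element 0."""
        encoded = [self.vocab.encode(tokenize(s)) for s in corpus]
        eval_set = (
            [self.vocab.encode(tokenize(s)) for s in holdout] if holdout else encoded
        )
        rng = np.random.default_rng(seed)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(vv) for k, vv in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0

        def eval_loss():
            return float(
                np.mean([self._seq_loss_grad(ids)[0] for ids in eval_set])
            )

        curve = [eval_loss()]
        for epoch in range(epochs):
            order = rng.permutation(len(encoded))
            for start in range(0, len(order), batch_size):
                batch = [encoded[i] for i in order[start : start + batch_size]]
                grads = {k: np.zeros_like(p) for k, p in self.params.items()}
                for ids in batch:
                    _, g = self._seq_loss_grad(ids)
                    for k in grads:
                        grads[k] += g[k] / len(batch)
                step += 1
                for k in self.params:
                    m[k] = b1 * m[k] + (1 - b1) * grads[k]
                    v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                    mh = m[k] / (1 - b1**step)
                    vh = v[k] / (1 - b2**step)
                    self.params[k] -= learning_rate * mh / (np.sqrt(vh) + eps)
            curve.append(eval_loss())
            if verbose:
                print(f"epoch {epoch + 1}: loss {curve[-1]:.4f}")
        return curve

    def _raw_distribution(self, prefix_ids: Sequence[int]) -> np.ndarray:
        _, _, probs = self._forward(list(prefix_ids))
        return probs[-1]


# -- training entry point ---------------------------------------------


def train_policy(corpus: Sequence[str], config: PolicyConfig | None = None):
    """Fit a generative policy on a SMILES corpus.

    The vocabulary is induced from the corpus and frozen, so sampling can
    never emit an out-of-vocabulary token.  A held-out split checks that
    the fitted policy beats the unigram baseline in per-token perplexity;
    training is deterministic given ``config.seed``.
    """
    config = config or PolicyConfig()
    if len(corpus) == 0:
        raise ValueError("cannot train a policy on an empty corpus")
    vocab = TokenVocabulary.from_corpus(corpus)
    if config.kind == "markov":
        policy = MarkovPolicy(vocab, order=config.order, min_length=config.min_length)
        policy.fit(corpus)
        return policy
    if config.kind == "recurrent":
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(len(corpus))
        n_hold = max(1, int(len(corpus) * config.holdout_frac)) if len(corpus) > 10 else 0
        hold = [corpus[i] for i in order[:n_hold]]
        train = [corpus[i] for i in order[n_hold:]]
        policy = RecurrentPolicy(
            vocab,
            embedding_dim=config.embedding_dim,
            hidden_dim=config.hidden_dim,
            min_length=config.min_length,
            seed=config.seed,
        )
        policy.fit(
            train,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            seed=config.seed,
            holdout=hold or None,
        )
        return policy
    raise ValueError(f"unknown policy kind {config.kind!r}")


# -- perplexity baselines ---------------------------------------------


def unigram_perplexity(train_corpus: Sequence[str], eval_corpus: Sequence[str]) -> float:
    """Per-token perplexity of the add-one-smoothed unigram model."""
    vocab = TokenVocabulary.from_corpus(list(train_corpus) + list(eval_corpus))
    counts = np.ones(len(vocab))  # add-one smoothing
    for line in train_corpus:
        for i in vocab.encode(tokenize(line)) + [vocab.end_id]:
            counts[i] += 1
    p = counts / counts.sum()
    nll, n_tok = 0.0, 0
    for line in eval_corpus:
        for i in vocab.encode(tokenize(line)) + [vocab.end_id]:
            nll -= np.log(p[i])
            n_tok += 1
    return float(np.exp(nll / n_tok))


def policy_perplexity(policy: _PolicyBase, eval_corpus: Sequence[str]) -> float:
    """Per-token perplexity of a policy on a SMILES list (END included)."""
    nll, n_tok = 0.0, 0
    for line in eval_corpus:
        toks = tokenize(line)
        seq = toks + [END]
        for t in range(len(seq)):
            dist = policy.next_token_distribution(toks[:t])
            idx = policy.vocab.index[seq[t]]
            nll -= np.log(dist[idx] + 1e-12)
            n_tok += 1
    return float(np.exp(nll / n_tok))


# -- sampling ----------------------------------------------------------


def rollout(
    policy: _PolicyBase,
    prefix: Sequence[str],
    max_len: int,
    rng: np.random.Generator | int,
) -> tuple[list[str], bool]:
    """Complete a token prefix by ancestral sampling.

    Returns ``(tokens, truncated)`` where ``tokens`` is the content
    prefix extended until END was drawn (END excluded from the returned
    list) or until ``max_len`` content tokens were reached without END
    (``truncated=True``).  Reproducible given the generator state.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    tokens = [t for t in prefix if t != BEGIN]
    if max_len <= len(tokens):
        raise ValueError(f"max_len={max_len} must exceed prefix length {len(tokens)}")
    if tokens and tokens[-1] == END:
        return tokens[:-1], False
    vocab = policy.vocab
    masked = getattr(policy, "grammar_mask", False)
    scan = _Scan(tokens) if masked else None
    while len(tokens) < max_len:
        dist = policy.next_token_distribution(tokens, _scan=scan)
        if masked:
            dist = _apply_length_budget(vocab, tokens, dist, max_len, scan)
        choice = int(rng.choice(len(dist), p=dist))
        if choice == vocab.end_id:
            return tokens, False
        tokens.append(vocab.tokens[choice])
        if masked:
            scan._push(tokens[-1])
    return tokens, True


def _closure_need(token: str, depth: int, open_rings: dict) -> int:
    """Estimated tokens still required to close everything after ``token``.

    Each open parenthesis costs ~2 (content atom + close); each open ring
    needs the path atoms still missing for a five/six-membered closure
    plus its digit; bonds imply a following atom.  A deliberate
    over-estimate so sampled strings wrap up before the length cap.
    """
    ring_cost = sum(
        max(4 - state[1], 0) + 1 for state in open_rings.values()
    )
    d = depth
    extra = 0
    if token == "(":
        d += 1
        extra = 1  # a branch needs at least one atom
    elif token == ")":
        d -= 1
    elif token in _BONDS:
        extra = 1  # a bond needs a following atom
    elif _is_ring_digit(token):
        if token in open_rings:
            ring_cost -= max(4 - open_rings[token][1], 0) + 1
        else:
            ring_cost += 5  # a fresh ring: four path atoms + digit
    return 2 * d + ring_cost + extra


def _apply_length_budget(
    vocab: TokenVocabulary,
    tokens: Sequence[str],
    dist: np.ndarray,
    max_len: int,
    scan: "_Scan | None" = None,
) -> np.ndarray:
    """Suppress tokens whose minimal closure cost no longer fits in max_len.

    Keeps sampled strings closable within the length budget so that
    truncation (an automatic validity failure) stays rare.
    """
    s = scan if scan is not None else _Scan(tokens)
    depth, open_rings = s.depth, s.open_rings
    budget = max_len - len(tokens) - 1  # tokens available after the next one
    ring_here = any(state[0] == depth for state in open_rings.values())
    p = dist.copy()
    for i in np.flatnonzero(p > 0):
        t = vocab.tokens[i]
        if t in (BEGIN, END):
            continue
        need = _closure_need(t, depth, open_rings)
        if _is_aromatic_atom(t) and not ring_here:
            need += 6  # this atom commits to opening a fresh ring
        if need > budget:
            p[i] = 0.0
    total = p.sum()
    if total <= 0:
        # nothing fits: fall back to the legal token minimizing closure debt
        legal = legal_token_mask(vocab, tokens, scan=s)
        legal[vocab.begin_id] = False
        needs = [
            (_closure_need(vocab.tokens[i], depth, open_rings), i)
            for i in np.flatnonzero(legal)
        ]
        p = np.zeros_like(dist)
        p[min(needs)[1] if needs else vocab.end_id] = 1.0
        return p
    return p / total


# -- serialization -----------------------------------------------------

_FORMAT_VERSION = 1


def save_policy(policy: _PolicyBase, path) -> None:
    """Write a policy to a versioned single-file JSON archive."""
    doc: dict = {
        "format_version": _FORMAT_VERSION,
        "kind": policy.kind,
        "min_length": policy.min_length,
        "vocab": policy.vocab.tokens[2:],  # content tokens; sentinels implicit
    }
    if isinstance(policy, MarkovPolicy):
        doc["order"] = policy.order
        doc["counts"] = {
            "\x1f".join(policy.vocab.tokens[i] for i in ctx): c.tolist()
            for ctx, c in policy.counts.items()
        }
    elif isinstance(policy, RecurrentPolicy):
        doc["embedding_dim"] = policy.embedding_dim
        doc["hidden_dim"] = policy.hidden_dim
        doc["params"] = {k: v.tolist() for k, v in policy.params.items()}
    elif isinstance(policy, UniformPolicy):
        pass
    else:
        raise TypeError(f"cannot serialize policy of type {type(policy).__name__}")
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_policy(path) -> _PolicyBase:
    """Load a policy saved by :func:`save_policy`."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported policy format version {doc.get('format_version')!r}")
    vocab = TokenVocabulary(doc["vocab"])
    kind = doc["kind"]
    if kind == "markov":
        policy = MarkovPolicy(vocab, order=doc["order"], min_length=doc["min_length"])
        for key, counts in doc["counts"].items():
            ctx = tuple(vocab.index[t] for t in key.split("\x1f")) if key else ()
            policy.counts[ctx] = np.asarray(counts, dtype=float)
        return policy
    if kind == "recurrent":
        policy = RecurrentPolicy(
            vocab,
            embedding_dim=doc["embedding_dim"],
            hidden_dim=doc["hidden_dim"],
            min_length=doc["min_length"],
        )
        policy.params = {k: np.asarray(v) for k, v in doc["params"].items()}
        return policy
    if kind == "uniform":
        return UniformPolicy(vocab, min_length=doc["min_length"])
    raise ValueError(f"unknown policy kind {kind!r}")
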