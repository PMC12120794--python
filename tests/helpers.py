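"""Shared independent oracles and toy doubles used across test modules."""

import numpy as np

from pmcts.objectives import PropertyProfile


def brute_force_front(mat) -> list[int]:
    """O(n^2) double-loop non-domination oracle, independent of the library."""
    mat = np.asarray(mat, dtype=float)
    keep = []
    for i in range(len(mat)):
        dominated = False
        for j in range(len(mat)):
            if i != j and np.all(mat[j] >= mat[i]) and np.any(mat[j] > mat[i]):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return keep


class TokenCountObjectives:
    """Toy deterministic objectives over raw strings: fractions of two letters.

    Used for exhaustive-enumeration checks where chemistry would get in
    the way; any non-empty string is 'valid'.
    """

    n_objectives = 2
    names = ["frac_C", "frac_O"]

    def evaluate(self, smiles: str) -> PropertyProfile:
        n = len(smiles)
        if n == 0:
            return PropertyProfile(smiles=smiles, valid=False, normalized=np.zeros(2))
        vec = np.array([smiles.count("C") / n, smiles.count("O") / n])
        return PropertyProfile(
            smiles=smiles, valid=True, raw=dict(zip(self.names, vec)), normalized=vec
        )
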