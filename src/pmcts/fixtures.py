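"""Seeded fixture corpus generator: small drug-like molecules, no downloads.

Molecules are assembled from a fixed fragment library — benzene,
pyridine, diazine, indole and quinoline cores with alkyl/ether/amine
prefixes and common decorations (hydroxyl, amino, carboxyl, halogen,
nitrile, amide) — echoing the scaffolds that dominate kinase-inhibitor
chemistry.  Every output is RDKit-valid, canonical, unique, and the
molecular-weight distribution spans roughly 150-500 Da.  The generator
is deterministic given its seed, which makes corpora reproducible in
tests and demo runs without shipping any data file.
"""

from __future__ import annotations

import numpy as np

__all__ = ["generate_fixture_corpus"]

# two-slot templates; {0} is a prefix substituent (attached via its last
# atom), {1} an in-ring decoration
_TEMPLATES = [
    "{0}c1ccc({1})cc1",
    "{0}c1cccc({1})c1",
    "{0}c1ccnc({1})c1",
    "{0}c1ncc({1})cn1",
    "{0}c1cc({1})ncn1",
    "{0}c1ccc(-c2ccc({1})cc2)cc1",
    "{0}c1ccc(-c2ccnc({1})c2)cc1",
    "{0}c1ccc(C{1})cc1",
    "{0}c1ccc(O{1})cc1",
    "{0}c1ccc(N{1})cc1",
    "{0}c1ccc(C(=O)N{1})cc1",
    "{0}c1ccc(C(=O)O{1})cc1",
    "{0}c1ccc2c(c1)cc({1})[nH]2",
    "{0}c1ccc2c(c1)ccc({1})n2",
    "{0}c1ccc(CN({1})C)cc1",
    "{0}c1ccc(Nc2ncc({1})cn2)cc1",
    "{0}c1ccc(C(=O)Nc2ccc({1})cc2)cc1",
    "{0}c1ccc(Oc2ccc({1})cn2)cc1",
    "{0}c1ccc(NC(=O)c2ccc({1})cc2)nc1",
]

_PREFIXES = [
    "C", "CC", "CCC", "CCCC", "CC(C)", "CC(C)C",
    "OC", "OCC", "COC", "COCC", "OCCO",
    "NC", "NCC", "CNC", "CN(C)C",
    "CCN(CC)C", "OCCN(C)C",
    "FC(F)(F)", "C(=O)C", "CC(=O)N",
    "CCOC(=O)CC", "CC(C)(C)OC(=O)NCC", "OCCN(CCO)CC",
]

_DECORATIONS = [
    "C", "CC", "CCC", "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C#N", "CO", "CCO", "C(=O)O", "C(=O)OC",
    "C(F)(F)F", "C(=O)N", "CN",
    "N3CCOCC3", "N3CCN(C)CC3", "S(=O)(=O)N(C)C", "OCCN(C)C",
]


def generate_fixture_corpus(
    n: int,
    seed: int = 0,
    mw_range: tuple[float, float] = (150.0, 500.0),
) -> list[str]:
    """Generate ``n`` unique, valid, canonical SMILES.

    Candidates are drawn by seeded random template filling; anything
    that fails RDKit sanitization, falls outside ``mw_range``, or
    duplicates an earlier molecule is redrawn.  Deterministic given
    ``seed``.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors
    from rdkit import RDLogger

    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    RDLogger.DisableLog("rdApp.error")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 400 * n + 10_000
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"fixture generator exhausted {max_attempts} attempts at n={n}"
            )
        template = _TEMPLATES[int(rng.integers(len(_TEMPLATES)))]
        prefix = _PREFIXES[int(rng.integers(len(_PREFIXES)))]
        deco = _DECORATIONS[int(rng.integers(len(_DECORATIONS)))]
        smiles = template.format(prefix, deco)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            continue
        mw = Descriptors.MolWt(mol)
        if not (mw_range[0] <= mw <= mw_range[1]):
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append(canonical)
    RDLogger.EnableLog("rdApp.error")
    return out
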