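"""Molecular objectives: raw property providers and Gaussian normalization.

Every objective is described by an :class:`ObjectiveSpec`: a raw-score
provider (QED, SAScore, logP, molecular weight, or a seeded surrogate
activity model), an optimization direction, a Gaussian modifier (mu,
sigma) that maps the raw scale onto (0, 1], and a raw-scale success
threshold.  After normalization every objective is a maximization
problem, which is what the Pareto layer assumes.

Three modifier shapes are available:

* ``gaussian`` — ``exp(-(x - mu)^2 / (2 sigma^2))``, peaked at the target
  value mu (for properties that should *match* a value);
* ``max_gaussian`` — 1 for ``x >= mu``, Gaussian decay below (properties
  that benefit from higher values, e.g. potency);
* ``min_gaussian`` — 1 for ``x <= mu``, Gaussian decay above (properties
  to keep low, e.g. toxicity or synthetic-accessibility score).

The bundled bioactivity providers are deterministic synthetic surrogates:
a fixed random linear projection of the molecule's Morgan fingerprint,
squashed onto a 0-10 pIC50-like scale.  They are smooth under small
structural edits and reproducible given (target_id, seed), but they are
stand-ins for trained QSAR models, not predictors of real activity.
"""

from __future__ import annotations

import hashlib
import os
import sys
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from pmcts.pareto import SuccessCriterion

__all__ = [
    "gaussian_modifier",
    "surrogate_activity",
    "Provider",
    "builtin_providers",
    "ObjectiveSpec",
    "PropertyProfile",
    "ObjectiveSet",
    "demo_objectives",
]

_MODIFIER_KINDS = ("gaussian", "max_gaussian", "min_gaussian")


def gaussian_modifier(
    x: float, mu: float, sigma: float, kind: str = "gaussian"
) -> float:
    """Map a raw property value onto (0, 1] with a Gaussian desirability curve.

    ``gaussian`` peaks at ``mu`` and decays symmetrically; ``max_gaussian``
    saturates at 1 for ``x >= mu``; ``min_gaussian`` saturates at 1 for
    ``x <= mu``.  ``sigma`` (raw units) sets the decay width and must be
    positive.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if not np.isfinite(x):
        raise ValueError(f"raw value must be finite, got {x}")
    if kind not in _MODIFIER_KINDS:
        raise ValueError(f"unknown modifier kind {kind!r}; choose from {_MODIFIER_KINDS}")
    if kind == "max_gaussian" and x >= mu:
        return 1.0
    if kind == "min_gaussian" and x <= mu:
        return 1.0
    z = (x - mu) / sigma
    # floored so extreme outliers stay strictly positive (and orderable)
    return float(max(np.exp(-0.5 * z * z), 1e-300))


# -- surrogate activity ------------------------------------------------

_FP_BITS = 2048
_FP_RADIUS = 2


def _stable_seed(*parts) -> int:
    digest = hashlib.sha256("|".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


_weight_cache: dict[tuple[str, int], np.ndarray] = {}


def _surrogate_weights(target_id: str, seed: int) -> np.ndarray:
    key = (target_id, seed)
    if key not in _weight_cache:
        rng = np.random.default_rng(_stable_seed("surrogate", target_id, seed))
        _weight_cache[key] = rng.standard_normal(_FP_BITS)
    return _weight_cache[key]


def _morgan_onbits(mol) -> np.ndarray:
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=_FP_RADIUS, fpSize=_FP_BITS
    )
    return np.asarray(gen.GetFingerprint(mol).GetOnBits(), dtype=int)


def surrogate_activity(smiles: str, target_id: str, seed: int = 0) -> float:
    """Deterministic synthetic bioactivity score on a 0-10 pIC50-like scale.

    The score is a fixed random linear projection (seeded by
    ``target_id`` and ``seed``) of the molecule's Morgan fingerprint,
    squashed through a tanh onto (0, 10).  It is invariant to SMILES
    spelling (the molecule is canonicalized first) and varies smoothly
    with structure: close analogs receive close scores.  This is a
    synthetic stand-in for a trained QSAR model.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return _surrogate_score(mol, target_id, seed)


def _surrogate_score(mol, target_id: str, seed: int) -> float:
    onbits = _morgan_onbits(mol)
    if onbits.size == 0:
        return 5.0
    w = _surrogate_weights(target_id, seed)
    m = float(np.mean(w[onbits]))
    return 5.0 + 5.0 * float(np.tanh(2.5 * m))


# -- provider registry -------------------------------------------------


@dataclass(frozen=True)
class Provider:
    """A raw-property provider: RDKit mol -> float, with its native range."""

    name: str
    fn: Callable
    lo: float
    hi: float
    doc: str


_sascorer = None


def _sascore(mol) -> float:
    # fragment-contribution synthetic accessibility, 1 (easy) .. 10 (hard)
    global _sascorer
    if _sascorer is None:
        from rdkit.Chem import RDConfig

        sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
        import sascorer

        _sascorer = sascorer
    return float(_sascorer.calculateScore(mol))


def _qed(mol) -> float:
    from rdkit.Chem import QED

    return float(QED.qed(mol))


def _logp(mol) -> float:
    from rdkit.Chem import Descriptors

    return float(Descriptors.MolLogP(mol))


def _molwt(mol) -> float:
    from rdkit.Chem import Descriptors

    return float(Descriptors.MolWt(mol))


def builtin_providers(seed: int = 0) -> dict[str, Provider]:
    """Registry of built-in raw-score providers.

    ``surrogate:<target_id>`` resolves to the seeded synthetic activity
    model for that target; the other names are RDKit descriptors.
    """
    return {
        "qed": Provider("qed", _qed, 0.0, 1.0, "quantitative estimate of drug-likeness; maximize"),
        "sascore": Provider("sascore", _sascore, 1.0, 10.0, "synthetic accessibility, 1 easy .. 10 hard; minimize"),
        "logp": Provider("logp", _logp, -5.0, 10.0, "Crippen octanol-water logP; target-match"),
        "molecular_weight": Provider("molecular_weight", _molwt, 0.0, 1500.0, "average molecular weight, Da; target-match"),
    }


def resolve_provider(name: str, seed: int = 0) -> Provider:
    if name.startswith("surrogate:"):
        target = name.split(":", 1)[1]
        if not target:
            raise KeyError("surrogate provider needs a target id, e.g. 'surrogate:egfr'")
        return Provider(
            name,
            lambda mol, _t=target, _s=seed: _surrogate_score(mol, _t, _s),
            0.0,
            10.0,
            f"synthetic surrogate activity for target {target!r}, pIC50-like 0-10",
        )
    registry = builtin_providers(seed)
    if name not in registry:
        raise KeyError(
            f"unknown provider {name!r}; known: {sorted(registry)} or 'surrogate:<target>'"
        )
    return registry[name]


# -- objective specs ---------------------------------------------------


@dataclass(frozen=True)
class ObjectiveSpec:
    """One objective: provider, direction, Gaussian modifier, SR threshold."""

    name: str
    provider: str
    direction: str = "maximize"  # {'maximize', 'minimize'}
    mu: float = 0.0
    sigma: float = 1.0
    modifier: str = "gaussian"
    threshold: float | None = None
    threshold_sense: str = "gt"  # {'gt', 'lt'}

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"objective {self.name!r}: sigma must be > 0")
        if self.direction not in ("maximize", "minimize"):
            raise ValueError(f"objective {self.name!r}: bad direction {self.direction!r}")
        if self.modifier not in _MODIFIER_KINDS:
            raise ValueError(f"objective {self.name!r}: bad modifier {self.modifier!r}")
        if self.threshold_sense not in ("gt", "lt"):
            raise ValueError(f"objective {self.name!r}: bad threshold_sense")

    def normalize(self, raw: float) -> float:
        return gaussian_modifier(raw, self.mu, self.sigma, self.modifier)


@dataclass
class PropertyProfile:
    """Raw property values and the normalized objective vector for one molecule.

    ``raw`` and ``normalized`` share the objective ordering of the spec
    list.  An unparsable SMILES yields ``valid=False`` with the all-zeros
    normalized vector, so grammar failures are penalized rather than
    silently dropped; such profiles never enter the Pareto archive.
    """

    smiles: str
    valid: bool
    raw: dict[str, float] = field(default_factory=dict)
    normalized: np.ndarray = field(default_factory=lambda: np.zeros(0))


class ObjectiveSet:
    """An ordered list of objectives with resolved providers.

    Provider names are resolved once at construction, so a misspelled
    provider fails at spec-load time rather than per molecule.
    """

    def __init__(self, specs: Sequence[ObjectiveSpec], seed: int = 0):
        if not specs:
            raise ValueError("ObjectiveSet requires at least one objective")
        self.specs = list(specs)
        self.seed = seed
        self._providers = [resolve_provider(s.provider, seed) for s in self.specs]

    @property
    def n_objectives(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def criteria(self) -> list[SuccessCriterion]:
        return [
            SuccessCriterion(s.name, s.threshold, s.threshold_sense)
            for s in self.specs
            if s.threshold is not None
        ]

    def evaluate(self, smiles: str) -> PropertyProfile:
        """Score one SMILES: raw values per provider, normalized vector.

        Pure and deterministic: identical inputs give identical profiles.
        """
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return PropertyProfile(
                smiles=smiles,
                valid=False,
                normalized=np.zeros(self.n_objectives),
            )
        canonical = Chem.MolToSmiles(mol)
        raw = {}
        normalized = np.empty(self.n_objectives)
        for k, (spec, prov) in enumerate(zip(self.specs, self._providers)):
            value = float(prov.fn(mol))
            raw[spec.name] = value
            normalized[k] = spec.normalize(value)
        return PropertyProfile(
            smiles=canonical, valid=True, raw=raw, normalized=normalized
        )

    def evaluate_many(self, smiles_list: Sequence[str]) -> list[PropertyProfile]:
        return [self.evaluate(s) for s in smiles_list]

    # -- config file round-trip ---------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "objectives": [
                {
                    "name": s.name,
                    "provider": s.provider,
                    "direction": s.direction,
                    "mu": s.mu,
                    "sigma": s.sigma,
                    "modifier": s.modifier,
                    "threshold": s.threshold,
                    "threshold_sense": s.threshold_sense,
                }
                for s in self.specs
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, cfg: Mapping, seed: int | None = None) -> "ObjectiveSet":
        specs = [
            ObjectiveSpec(
                name=o["name"],
                provider=o["provider"],
                direction=o.get("direction", "maximize"),
                mu=float(o.get("mu", 0.0)),
                sigma=float(o.get("sigma", 1.0)),
                modifier=o.get("modifier", "gaussian"),
                threshold=None if o.get("threshold") is None else float(o["threshold"]),
                threshold_sense=o.get("threshold_sense", "gt"),
            )
            for o in cfg["objectives"]
        ]
        return cls(specs, seed=int(cfg.get("seed", 0)) if seed is None else seed)

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "ObjectiveSet":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_dict(cfg, seed=seed)


def demo_objectives(seed: int = 0) -> ObjectiveSet:
    """Seven-objective demo panel: activity, ADMET-style surrogates, QED, SAScore.

    Mirrors a kinase-inhibitor multi-parameter optimization setting —
    one potency objective, solubility (logP as proxy), permeability and
    metabolic-stability surrogates, a minimized toxicity surrogate, and
    the two computable desirability scores (QED maximized, SAScore
    minimized).  The bioactivity/ADMET entries are synthetic surrogate
    models, so this panel exercises the optimizer, not real pharmacology.
    """
    specs = [
        ObjectiveSpec("egfr_activity", "surrogate:egfr", "maximize",
                      mu=8.0, sigma=2.0, modifier="max_gaussian",
                      threshold=5.5, threshold_sense="gt"),
        ObjectiveSpec("solubility_logp", "logp", "maximize",
                      mu=2.5, sigma=1.5, modifier="gaussian",
                      threshold=5.0, threshold_sense="lt"),
        ObjectiveSpec("permeability", "surrogate:permeability", "maximize",
                      mu=7.0, sigma=2.5, modifier="max_gaussian",
                      threshold=4.0, threshold_sense="gt"),
        ObjectiveSpec("metabolic_stability", "surrogate:metabolic_stability",
                      "maximize", mu=7.0, sigma=2.5, modifier="max_gaussian",
                      threshold=4.0, threshold_sense="gt"),
        ObjectiveSpec("toxicity", "surrogate:toxicity", "minimize",
                      mu=3.0, sigma=2.0, modifier="min_gaussian",
                      threshold=5.0, threshold_sense="lt"),
        ObjectiveSpec("qed", "qed", "maximize",
                      mu=0.8, sigma=0.25, modifier="max_gaussian",
                      threshold=0.6, threshold_sense="gt"),
        ObjectiveSpec("sascore", "sascore", "minimize",
                      mu=2.5, sigma=1.5, modifier="min_gaussian",
                      threshold=4.0, threshold_sense="lt"),
    ]
    return ObjectiveSet(specs, seed=seed)
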