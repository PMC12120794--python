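"""Pareto dominance, non-dominated archives, and front-quality metrics.

All objective vectors handled here live in normalized space where every
component is to be *maximized* (the objectives module maps raw properties
onto (0, 1] before anything reaches this layer).  Dominance is the weak
Pareto relation: ``a`` dominates ``b`` when ``a >= b`` in every component
and ``a > b`` in at least one, so equal vectors never dominate each other
and duplicates of a frontier point are all retained.

Front quality is summarized by three metrics:

* hypervolume — Lebesgue measure of the region dominated by the front,
  bounded below by a reference point (default: the origin of normalized
  space);
* success rate — fraction of molecules whose *raw* property values clear
  every per-objective threshold simultaneously;
* internal diversity — mean pairwise (1 - Tanimoto) over circular
  (Morgan) fingerprints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "dominates",
    "non_dominated_filter",
    "ParetoArchive",
    "ArchiveChange",
    "SuccessCriterion",
    "success_rate",
    "FingerprintSet",
    "diversity",
    "hypervolume",
    "hypervolume_mc",
    "metrics_report",
]


def _as_vector(v: Sequence[float], name: str = "vector") -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} has non-finite components: {arr}")
    return arr


def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """Return True iff ``a`` Pareto-dominates ``b`` (maximization).

    ``a`` dominates ``b`` when it is at least as large in every component
    and strictly larger in at least one.  Equal vectors are mutually
    non-dominated; the relation is irreflexive and transitive.
    """
    av = _as_vector(a, "a")
    bv = _as_vector(b, "b")
    if av.shape[0] != bv.shape[0]:
        raise ValueError(
            f"dimension mismatch: a has {av.shape[0]} components, b has {bv.shape[0]}"
        )
    return bool(np.all(av >= bv) and np.any(av > bv))


def non_dominated_filter(vectors: Sequence[Sequence[float]]) -> list[int]:
    """Indices of all vectors not dominated by any other vector.

    Exact duplicates of a non-dominated vector are all retained.  The
    result is never empty for non-empty input and is returned in
    ascending index order.
    """
    if len(vectors) == 0:
        raise ValueError("non_dominated_filter requires a non-empty list of vectors")
    mat = np.asarray(vectors, dtype=float)
    if mat.ndim != 2:
        raise ValueError("vectors must share a uniform dimension")
    if not np.all(np.isfinite(mat)):
        raise ValueError("vectors contain non-finite components")
    n = mat.shape[0]
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if not keep[i]:
            continue
        # j dominates i: j >= i everywhere with at least one strict gain
        ge = np.all(mat >= mat[i], axis=1)
        gt = np.any(mat > mat[i], axis=1)
        if np.any(ge & gt):
            keep[i] = False
    return [int(i) for i in np.flatnonzero(keep)]


@dataclass
class ArchiveChange:
    """Outcome of offering one candidate to a :class:`ParetoArchive`."""

    accepted: bool
    removed: list[str] = field(default_factory=list)
    reason: str = ""


class ParetoArchive:
    """Unbounded archive of mutually non-dominated molecules.

    Entries are keyed by canonical SMILES, so a molecule can appear at
    most once regardless of how many times (or in which SMILES spelling)
    it is sampled.  Offering a candidate that is dominated by any current
    entry leaves the archive unchanged; an accepted candidate evicts every
    entry it dominates.  The archive therefore satisfies pairwise
    non-domination after every insertion, and its final content does not
    depend on insertion order.
    """

    def __init__(self, n_objectives: int | None = None):
        self.n_objectives = n_objectives
        self._entries: dict[str, tuple[np.ndarray, dict]] = {}
        self._matrix: np.ndarray | None = None  # stacked vectors cache

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, smiles: str) -> bool:
        return smiles in self._entries

    def __iter__(self):
        return iter(self._entries.items())

    @property
    def entries(self) -> dict[str, tuple[np.ndarray, dict]]:
        return dict(self._entries)

    def vectors(self) -> np.ndarray:
        """All archived objective vectors as an (n_entries, n_objectives) array."""
        if not self._entries:
            return np.empty((0, self.n_objectives or 0))
        if self._matrix is None or self._matrix.shape[0] != len(self._entries):
            self._matrix = np.stack([vec for vec, _ in self._entries.values()])
        return self._matrix

    def smiles(self) -> list[str]:
        return list(self._entries)

    def insert(
        self,
        smiles: str,
        vector: Sequence[float],
        raw: Mapping[str, float] | None = None,
    ) -> ArchiveChange:
        """Offer one (canonical SMILES, normalized vector) candidate.

        Returns an :class:`ArchiveChange` saying whether the candidate was
        accepted and which previously archived SMILES it evicted.
        Re-offering an existing key with an identical vector is a no-op.
        """
        vec = _as_vector(vector, "vector")
        if self.n_objectives is None:
            self.n_objectives = vec.shape[0]
        elif vec.shape[0] != self.n_objectives:
            raise ValueError(
                f"dimension mismatch: archive holds {self.n_objectives}-d vectors, "
                f"candidate has {vec.shape[0]}"
            )
        existing = self._entries.get(smiles)
        if existing is not None and np.array_equal(existing[0], vec):
            return ArchiveChange(accepted=True, removed=[], reason="duplicate")
        if self._entries:
            keys = list(self._entries)
            mat = self.vectors()
            ge = np.all(mat >= vec, axis=1)
            gt = np.any(mat > vec, axis=1)
            dominating = ge & gt
            if existing is not None:
                dominating[keys.index(smiles)] = False
            if np.any(dominating):
                by = keys[int(np.flatnonzero(dominating)[0])]
                return ArchiveChange(accepted=False, reason=f"dominated by {by}")
            beaten = np.all(vec >= mat, axis=1) & np.any(vec > mat, axis=1)
            removed = [
                keys[i] for i in np.flatnonzero(beaten) if keys[i] != smiles
            ]
            for key in removed:
                del self._entries[key]
        else:
            removed = []
        self._entries[smiles] = (vec, dict(raw or {}))
        self._matrix = None
        return ArchiveChange(accepted=True, removed=removed, reason="accepted")

    # -- serialization -------------------------------------------------

    def to_dataframe(
        self, objective_names: Sequence[str] | None = None
    ) -> pd.DataFrame:
        n = self.n_objectives or 0
        names = list(objective_names) if objective_names else [
            f"obj_{k}" for k in range(n)
        ]
        rows = []
        for smi, (vec, raw) in self._entries.items():
            row: dict[str, object] = {"smiles": smi}
            for name, val in zip(names, vec):
                row[name] = val
            for key, val in raw.items():
                row[f"raw_{key}"] = val
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path, objective_names: Sequence[str] | None = None) -> None:
        self.to_dataframe(objective_names).to_csv(
            path, index=False, float_format="%.12g"
        )

    @classmethod
    def from_csv(cls, path) -> "ParetoArchive":
        df = pd.read_csv(path)
        obj_cols = [
            c for c in df.columns if c != "smiles" and not c.startswith("raw_")
        ]
        raw_cols = [c for c in df.columns if c.startswith("raw_")]
        archive = cls(n_objectives=len(obj_cols))
        for _, row in df.iterrows():
            vec = np.asarray([row[c] for c in obj_cols], dtype=float)
            raw = {c[len("raw_"):]: float(row[c]) for c in raw_cols}
            archive._entries[str(row["smiles"])] = (vec, raw)
        return archive


# -- success rate ------------------------------------------------------


@dataclass(frozen=True)
class SuccessCriterion:
    """One per-objective acceptance threshold on the raw property scale.

    ``sense`` is ``"gt"`` (value must exceed the threshold strictly) or
    ``"lt"`` (value must fall strictly below it).
    """

    name: str
    threshold: float
    sense: str = "gt"

    def __post_init__(self):
        if self.sense not in ("gt", "lt"):
            raise ValueError(f"sense must be 'gt' or 'lt', got {self.sense!r}")
        if not math.isfinite(self.threshold):
            raise ValueError(f"threshold for {self.name!r} must be finite")

    def passes(self, value: float) -> bool:
        return value > self.threshold if self.sense == "gt" else value < self.threshold


def success_rate(
    raw_records: Sequence[Mapping[str, float]],
    criteria: Sequence[SuccessCriterion],
) -> float:
    """Fraction of records satisfying every criterion simultaneously.

    Comparisons are strict and applied to raw (unnormalized) property
    values.  A record missing a required property is an error, as is an
    empty record list (the proportion would be undefined).
    """
    if len(raw_records) == 0:
        raise ValueError("success_rate is undefined for an empty record list")
    n_pass = 0
    for idx, record in enumerate(raw_records):
        ok = True
        for crit in criteria:
            if crit.name not in record:
                raise KeyError(
                    f"record {idx} is missing property {crit.name!r}"
                )
            if not crit.passes(float(record[crit.name])):
                ok = False
                break
        n_pass += ok
    return n_pass / len(raw_records)


# -- diversity ---------------------------------------------------------


class FingerprintSet:
    """Circular (Morgan) fingerprints for a molecule set.

    Holds RDKit bit vectors of uniform length; radius and bit length are
    configurable (defaults: radius 2, 2048 bits — the common ECFP4-like
    setting).
    """

    def __init__(self, bitvectors: Sequence):
        self.bitvectors = list(bitvectors)
        if len({bv.GetNumBits() for bv in self.bitvectors}) > 1:
            raise ValueError("all fingerprints must have the same bit length")

    def __len__(self) -> int:
        return len(self.bitvectors)

    @classmethod
    def from_smiles(
        cls, smiles: Iterable[str], radius: int = 2, n_bits: int = 2048
    ) -> "FingerprintSet":
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator

        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        fps = []
        for smi in smiles:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                raise ValueError(f"invalid SMILES for fingerprinting: {smi!r}")
            fps.append(gen.GetFingerprint(mol))
        return cls(fps)


def diversity(fps: FingerprintSet) -> float:
    """Internal diversity: mean (1 - Tanimoto) over unordered distinct pairs.

    Bounded in [0, 1]; 0 when all fingerprints are identical, 1 when all
    pairs are disjoint.  Requires at least two molecules.
    """
    from rdkit.DataStructs import BulkTanimotoSimilarity

    n = len(fps)
    if n < 2:
        raise ValueError(f"diversity requires at least 2 molecules, got {n}")
    sim_total = 0.0
    for i in range(n - 1):
        sims = BulkTanimotoSimilarity(fps.bitvectors[i], fps.bitvectors[i + 1 :])
        sim_total += float(np.sum(sims))
    n_pairs = n * (n - 1) / 2
    return 1.0 - sim_total / n_pairs


# -- hypervolume -------------------------------------------------------


def _validate_front(
    front: Sequence[Sequence[float]], ref: Sequence[float] | None
) -> tuple[np.ndarray, np.ndarray]:
    if len(front) == 0:
        if ref is None:
            raise ValueError("empty front requires an explicit reference point")
        return np.empty((0, len(ref))), _as_vector(ref, "ref")
    mat = np.asarray(front, dtype=float)
    if mat.ndim != 2:
        raise ValueError("front points must share a uniform dimension")
    if not np.all(np.isfinite(mat)):
        raise ValueError("front contains non-finite components")
    rv = (
        np.zeros(mat.shape[1])
        if ref is None
        else _as_vector(ref, "ref")
    )
    if rv.shape[0] != mat.shape[1]:
        raise ValueError(
            f"reference point has {rv.shape[0]} components, front points have "
            f"{mat.shape[1]}"
        )
    if np.any(mat < rv):
        bad = int(np.flatnonzero(np.any(mat < rv, axis=1))[0])
        raise ValueError(
            f"front point {mat[bad].tolist()} lies below the reference point "
            f"{rv.tolist()} in at least one component"
        )
    return mat, rv


def _hv2d(points: np.ndarray, ref: np.ndarray) -> float:
    # sweep in decreasing x; each point adds a strip above the best y so far
    order = np.argsort(-points[:, 0])
    pts = points[order]
    hv = 0.0
    y_best = ref[1]
    for x, y in pts:
        if y > y_best:
            hv += (x - ref[0]) * (y - y_best)
            y_best = y
    return hv


def _wfg(points: np.ndarray, ref: np.ndarray) -> float:
    """Exact hypervolume by the WFG exclusive-volume recursion."""
    if points.shape[0] == 0:
        return 0.0
    if points.shape[1] == 1:
        return float(np.max(points[:, 0]) - ref[0])
    if points.shape[1] == 2:
        return _hv2d(points, ref)
    # sort by first coordinate descending: limit sets shrink faster
    order = np.argsort(-points[:, 0])
    pts = points[order]
    hv = 0.0
    for i in range(pts.shape[0]):
        p = pts[i]
        box = float(np.prod(p - ref))
        rest = pts[i + 1 :]
        if rest.shape[0]:
            limited = np.minimum(rest, p)
            idx = non_dominated_filter(limited)
            hv += box - _wfg(limited[idx], ref)
        else:
            hv += box
    return hv


# largest non-dominated front size for which the exact recursion stays
# fast, by dimension; beyond these the seeded Monte-Carlo estimate is used
_EXACT_HV_CAPS = {4: 300, 5: 120, 6: 60, 7: 40, 8: 30}


def auto_hv_method(n_points: int, n_objectives: int) -> str:
    """'exact' or 'mc', as the auto dispatch in :func:`hypervolume` decides."""
    if n_objectives <= 3:
        return "exact"
    return "exact" if n_points <= _EXACT_HV_CAPS.get(n_objectives, 30) else "mc"


def hypervolume(
    front: Sequence[Sequence[float]],
    ref: Sequence[float] | None = None,
    method: str = "auto",
    mc_samples: int = 1_000_000,
    mc_seed: int = 0,
) -> float:
    """Hypervolume dominated by ``front`` relative to ``ref`` (maximization).

    The exact value is the Lebesgue measure of the union of axis-aligned
    boxes ``[ref, p]`` over front points ``p``; dominated input points do
    not change the result.  ``ref`` defaults to the origin, the natural
    lower bound of normalized objective space.

    ``method`` is ``"exact"`` (WFG-style dimension-sweep recursion),
    ``"mc"`` (seeded Monte-Carlo estimate, see :func:`hypervolume_mc`), or
    ``"auto"``: exact up to a dimension-dependent front-size cap (the
    recursion cost grows steeply with both size and dimension),
    Monte-Carlo beyond it.
    """
    mat, rv = _validate_front(front, ref)
    if mat.shape[0] == 0:
        return 0.0
    mat = mat[non_dominated_filter(mat)]
    d, n = mat.shape[1], mat.shape[0]
    if method == "auto":
        method = auto_hv_method(n, d)
    if method == "exact":
        if d <= 2:
            return _hv2d(mat, rv) if d == 2 else float(np.max(mat[:, 0]) - rv[0])
        return _wfg(mat, rv)
    if method == "mc":
        return hypervolume_mc(mat, rv, n_samples=mc_samples, seed=mc_seed)
    raise ValueError(f"unknown hypervolume method {method!r}")


def hypervolume_mc(
    front: Sequence[Sequence[float]],
    ref: Sequence[float] | None = None,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo hypervolume estimate on the box [ref, upper_bound].

    Samples uniformly in the axis-aligned box spanned by ``ref`` and the
    componentwise maximum of the front, counts the dominated fraction,
    and scales by the box volume — an unbiased estimator, deterministic
    for a fixed seed.  Serves as the independent cross-check for the
    exact routine in higher dimensions.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    mat, rv = _validate_front(front, ref)
    if mat.shape[0] == 0:
        return 0.0
    upper = np.max(mat, axis=0)
    box_vol = float(np.prod(upper - rv))
    if box_vol == 0.0:
        return 0.0
    rng = np.random.default_rng(seed)
    n_dominated = 0
    chunk = 65_536
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        samples = rng.uniform(rv, upper, size=(m, mat.shape[1]))
        # dominated if some front point >= sample in every coordinate
        dominated = np.zeros(m, dtype=bool)
        for p in mat:
            dominated |= np.all(samples <= p, axis=1)
        n_dominated += int(np.sum(dominated))
        remaining -= m
    return box_vol * n_dominated / n_samples


def metrics_report(
    smiles: Sequence[str],
    vectors: Sequence[Sequence[float]],
    raw_records: Sequence[Mapping[str, float]] | None = None,
    criteria: Sequence[SuccessCriterion] | None = None,
    ref: Sequence[float] | None = None,
    fp_radius: int = 2,
    fp_bits: int = 2048,
) -> dict:
    """HV / SR / Div summary for a molecule set with normalized vectors.

    HV is computed on the non-dominated subset of ``vectors``; SR needs
    ``raw_records`` and ``criteria`` (reported as None otherwise); Div
    needs at least two fingerprintable molecules.
    """
    mat = np.asarray(vectors, dtype=float)
    n_obj = mat.shape[1] if mat.ndim == 2 else 0
    d = {"n_molecules": len(smiles), "n_objectives": n_obj}
    n_front = len(non_dominated_filter(mat))
    d["hv_method"] = auto_hv_method(n_front, n_obj)
    d["hv"] = hypervolume(mat, ref=ref)
    if raw_records is not None and criteria:
        d["sr"] = success_rate(raw_records, criteria)
    else:
        d["sr"] = None
    if len(smiles) >= 2:
        d["div"] = diversity(
            FingerprintSet.from_smiles(smiles, radius=fp_radius, n_bits=fp_bits)
        )
    else:
        d["div"] = None
    return d
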