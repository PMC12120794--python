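"""Readers, writers and run manifests.

File formats are deliberately plain: SMILES corpora are one-per-line
text (``#`` comments, optional whitespace-separated name), tables are
UTF-8 CSV with a header row and 12-significant-digit floats, metrics
and manifests are JSON.  Everything written by a search run can be read
back by the metrics command.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import asdict, dataclass
from typing import NamedTuple, Sequence

import pandas as pd

from pmcts.policy import tokenize

__all__ = [
    "SmilesRecord",
    "read_smiles_file",
    "write_smiles_file",
    "write_json",
    "read_json",
    "sha256_file",
    "RunManifest",
    "write_sampled_csv",
]

logger = logging.getLogger("pmcts")


class SmilesRecord(NamedTuple):
    smiles: str
    name: str | None
    line_number: int


def read_smiles_file(path, strict: bool = False) -> list[SmilesRecord]:
    """Read a .smi / plain-text SMILES file.

    Blank lines and ``#`` comments are skipped; an optional second
    whitespace-separated field becomes the record name.  Lines that do
    not tokenize as SMILES are skipped with a logged warning (or raise,
    in strict mode).  Line numbers are 1-based.
    """
    records: list[SmilesRecord] = []
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            smiles = fields[0]
            name = fields[1] if len(fields) > 1 else None
            try:
                tokenize(smiles)
            except ValueError as exc:
                if strict:
                    raise ValueError(f"{path}:{lineno}: {exc}") from None
                n_bad += 1
                logger.warning("%s:%d: skipping untokenizable line (%s)", path, lineno, exc)
                continue
            records.append(SmilesRecord(smiles, name, lineno))
    if n_bad:
        logger.warning("%s: skipped %d untokenizable line(s)", path, n_bad)
    if not records:
        logger.warning("%s: no SMILES records found", path)
    return records


def write_smiles_file(path, records: Sequence) -> None:
    """Write SMILES (strings or :class:`SmilesRecord`) one per line."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, SmilesRecord):
                line = rec.smiles if rec.name is None else f"{rec.smiles} {rec.name}"
            else:
                line = str(rec)
            fh.write(line + "\n")


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one search run; written atomically at run end."""

    seed: int
    config: dict
    objective_spec_hash: str
    policy_fingerprint: str
    oracle_calls: int
    started_at: str
    finished_at: str
    tool_version: str

    def write(self, path) -> None:
        payload = asdict(self)
        directory = os.path.dirname(os.path.abspath(path)) or "."
        fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
                fh.write("\n")
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise


def write_sampled_csv(path, all_sampled, objective_names: Sequence[str]) -> None:
    """Write the full sampling log: smiles, iteration, normalized vector."""
    rows = []
    for smiles, vec, iteration in all_sampled:
        row = {"smiles": smiles, "iteration": iteration}
        for name, val in zip(objective_names, vec):
            row[name] = val
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
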