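"""Reading and writing ``.smi`` line files and run manifests.

The ``.smi`` dialect: one record per line, first whitespace-separated field
is the SMILES string, an optional second field is an identifier; blank
lines are skipped.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .chemspace import MoleculeRecord


class SmilesFileError(ValueError):
    pass


def read_smiles_file(path: str | Path, validate: bool = False) -> list[MoleculeRecord]:
    """Parse a ``.smi`` file into molecule records.

    With ``validate=False`` the SMILES field is stored as-is (heavy-atom
    count unset); with ``validate=True`` every line is canonicalized and a
    malformed line raises with its line number.
    """
    records: list[MoleculeRecord] = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        smiles = fields[0]
        mol_id = fields[1] if len(fields) > 1 else None
        if validate:
            try:
                records.append(MoleculeRecord.from_smiles(smiles, mol_id))
            except ValueError as exc:
                raise SmilesFileError(f"{path}:{lineno}: {exc}") from None
        else:
            records.append(MoleculeRecord(smiles, 0, mol_id))
    return records


def write_smiles_file(records: Sequence, path: str | Path) -> None:
    """Write records (or bare strings) one per line, id as a second column."""
    lines = []
    for r in records:
        if isinstance(r, str):
            lines.append(r)
        elif getattr(r, "id", None):
            lines.append(f"{r.canonical_smiles} {r.id}")
        else:
            lines.append(r.canonical_smiles)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
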