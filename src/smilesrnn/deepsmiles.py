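"""DeepSMILES encoding and decoding.

DeepSMILES is a SMILES syntax variant that changes how rings and branches
are written:

* **rings** — the paired ring-closure digits of SMILES are replaced by a
  single number at the closing site giving the distance (along the atom
  stack, equal to the ring size for ordinary rings) back to the opening
  atom; the opening digit disappears.  Benzene ``c1ccccc1`` becomes
  ``cccccc6``.
* **branches** — opening parentheses disappear; a run of ``N`` closing
  parentheses pops ``N`` atoms off the atom stack, returning to the
  attachment atom.  ``CC(C)C`` becomes ``CCC)C``.

Both transformations are defined on an atom stack that mirrors the "previous
atom" state of a SMILES reader.  The decoder rebuilds the molecular graph
directly (bonds default to single unless both partners are aromatic, in
which case they are aromatic) and returns an RDKit-written SMILES, so a
round trip recovers the same molecule though not necessarily the same
string.
"""

from __future__ import annotations

from rdkit import Chem

from .tokenizer import BEGIN_TOKEN, END_TOKEN, TokenizationError, tokenize


class DeepSmilesError(ValueError):
    """Raised when a string cannot be converted to or from DeepSMILES."""


_BOND_ORDERS = {
    "-": Chem.BondType.SINGLE,
    "=": Chem.BondType.DOUBLE,
    "#": Chem.BondType.TRIPLE,
    ":": Chem.BondType.AROMATIC,
}


def _payload_tokens(s: str) -> list[str]:
    try:
        toks = tokenize(s)
    except TokenizationError as exc:
        raise DeepSmilesError(str(exc)) from None
    return [t for t in toks if t not in (BEGIN_TOKEN, END_TOKEN)]


def _is_atom_token(tok: str) -> bool:
    return tok[0] == "[" or tok in (
        "B", "C", "N", "O", "P", "S", "F", "I", "Cl", "Br",
        "b", "c", "n", "o", "p", "s",
    )


def _ring_number(tok: str) -> int:
    return int(tok[1:]) if tok.startswith("%") else int(tok)


def _ring_token(n: int) -> str:
    if n <= 9:
        return str(n)
    if n <= 99:
        return f"%{n:02d}"
    raise DeepSmilesError("ring distance above 99 not representable")


def encode_deepsmiles(smiles: str, *, rings: bool, branches: bool) -> str:
    """Rewrite a SMILES string in DeepSMILES syntax (selected transformations)."""
    out: list[str] = []
    stack: list[int] = []          # atom ids forming the current chain
    frames: list[int] = []         # stack depth at each open parenthesis
    open_rings: dict[int, int] = {}  # ring number -> opening atom id
    atom_counter = 0
    pending_bond = ""

    for tok in _payload_tokens(smiles):
        if _is_atom_token(tok):
            stack.append(atom_counter)
            atom_counter += 1
            out.append(pending_bond + tok)
            pending_bond = ""
        elif tok in _BOND_ORDERS or tok in ("/", "\\"):
            pending_bond += tok
        elif tok == "(":
            frames.append(len(stack))
            if not branches:
                out.append(tok)
        elif tok == ")":
            if not frames:
                raise DeepSmilesError("unbalanced ')'")
            depth = frames.pop()
            popped = len(stack) - depth
            del stack[depth:]
            out.append(")" * popped if branches else ")")
        elif tok.isdigit() or tok.startswith("%"):
            num = _ring_number(tok)
            if num in open_rings:
                opener = open_rings.pop(num)
                if not rings:
                    out.append(pending_bond + tok)
                else:
                    if opener not in stack:
                        raise DeepSmilesError(
                            "ring partner left the atom stack; not encodable"
                        )
                    dist = len(stack) - stack.index(opener)
                    out.append(pending_bond + _ring_token(dist))
                pending_bond = ""
            else:
                if not stack:
                    raise DeepSmilesError("ring opening before any atom")
                open_rings[num] = stack[-1]
                if not rings:
                    out.append(pending_bond + tok)
                    pending_bond = ""
                elif pending_bond:
                    # bond symbol re-emitted at the closing site instead
                    pending_bond = ""
        elif tok == ".":
            raise DeepSmilesError("disconnected structures not supported")
        else:
            raise DeepSmilesError(f"unexpected token {tok!r}")
    if open_rings:
        raise DeepSmilesError("unclosed ring in input")
    return "".join(out)


def decode_deepsmiles(deepsmiles: str, *, rings: bool, branches: bool) -> str:
    """Decode a DeepSMILES string by rebuilding the molecular graph.

    Returns an RDKit canonical SMILES of the decoded molecule; raises
    :class:`DeepSmilesError` for syntactically or chemically invalid input.
    """
    mol = Chem.RWMol()
    stack: list[int] = []          # RDKit atom indices of the current chain
    frames: list[int] = []
    open_rings: dict[int, tuple[int, str]] = {}
    pending_bond = ""

    def add_bond(a: int, b: int, bond_sym: str) -> None:
        if bond_sym in ("/", "\\"):
            bond_sym = "-"  # stereo direction dropped
        if bond_sym:
            btype = _BOND_ORDERS[bond_sym]
        else:
            both_arom = (
                mol.GetAtomWithIdx(a).GetIsAromatic()
                and mol.GetAtomWithIdx(b).GetIsAromatic()
            )
            btype = Chem.BondType.AROMATIC if both_arom else Chem.BondType.SINGLE
        if mol.GetBondBetweenAtoms(a, b) is not None:
            raise DeepSmilesError("duplicate bond")
        mol.AddBond(a, b, btype)

    for tok in _payload_tokens(deepsmiles):
        if _is_atom_token(tok):
            atom = Chem.AtomFromSmiles(tok)
            if atom is None:
                raise DeepSmilesError(f"bad atom token {tok!r}")
            idx = mol.AddAtom(atom)
            if stack:
                add_bond(stack[-1], idx, pending_bond)
            pending_bond = ""
            stack.append(idx)
        elif tok in _BOND_ORDERS or tok in ("/", "\\"):
            pending_bond += tok
            if len(pending_bond) > 1:
                raise DeepSmilesError("consecutive bond symbols")
        elif tok == "(":
            if branches:
                raise DeepSmilesError("'(' not part of the branch syntax")
            frames.append(len(stack))
        elif tok == ")":
            if branches:
                if len(stack) < 2:
                    raise DeepSmilesError("pop below stack bottom")
                stack.pop()
            else:
                if not frames:
                    raise DeepSmilesError("unbalanced ')'")
                del stack[frames.pop() :]
                if not stack:
                    raise DeepSmilesError("pop below stack bottom")
        elif tok.isdigit() or tok.startswith("%"):
            num = _ring_number(tok)
            if not stack:
                raise DeepSmilesError("ring reference before any atom")
            if rings:
                if num < 2 or num > len(stack):
                    raise DeepSmilesError(f"ring distance {num} exceeds chain")
                add_bond(stack[-1], stack[-num], pending_bond)
                pending_bond = ""
            else:
                if num in open_rings:
                    opener, obond = open_rings.pop(num)
                    add_bond(stack[-1], opener, pending_bond or obond)
                    pending_bond = ""
                else:
                    open_rings[num] = (stack[-1], pending_bond)
                    pending_bond = ""
        else:
            raise DeepSmilesError(f"unexpected token {tok!r}")
    if open_rings or frames:
        raise DeepSmilesError("unclosed ring or branch")
    if mol.GetNumAtoms() == 0:
        raise DeepSmilesError("no atoms")
    try:
        product = mol.GetMol()
        Chem.SanitizeMol(product)
    except Exception as exc:  # rdkit raises several sanitization error types
        raise DeepSmilesError(f"chemically invalid: {exc}") from None
    return Chem.MolToSmiles(product)
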