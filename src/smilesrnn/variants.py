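"""SMILES string variants: canonical, randomized and DeepSMILES.

A molecule admits up to ``n!`` SMILES strings, one per atom ordering.  The
two randomized variants here are produced by a deterministic depth-first
writer driven by an explicit atom permutation:

* **restricted** — the writer applies the customary traversal fix of
  canonical writers: at each atom, sidechain (non-ring) bonds are traversed
  before ring bonds, so a ring is always continued rather than entered
  through a parenthesized branch.  This forbids convoluted forms such as
  ``c1cc(c(cc1))`` for benzene.
* **unrestricted** — the writer follows the permutation literally (no
  sidechain-first reordering) and may additionally wrap the final branch of
  an atom in redundant parentheses (it does so whenever the child outranks
  its parent in the permutation).  Over all permutations the unrestricted
  string set is a strict superset of the restricted one.

Both variants write aromatic (lowercase) forms and always canonicalize back
to the input molecule.  Stereochemistry is not represented (the target
spaces here are stereo-free).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import factorial
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger

from .deepsmiles import DeepSmilesError, decode_deepsmiles, encode_deepsmiles
from .rngutil import child_seed, rng_for

# silence per-string parse warnings: invalid strings are an expected, counted
# outcome when evaluating samplers
RDLogger.DisableLog("rdApp.error")

CANONICAL = "canonical"
RANDOMIZED_RESTRICTED = "randomized_restricted"
RANDOMIZED_UNRESTRICTED = "randomized_unrestricted"
DEEPSMILES_RINGS = "deepsmiles_rings"
DEEPSMILES_BRANCHES = "deepsmiles_branches"
DEEPSMILES_BOTH = "deepsmiles_both"

VARIANT_KINDS = (
    CANONICAL,
    RANDOMIZED_RESTRICTED,
    RANDOMIZED_UNRESTRICTED,
    DEEPSMILES_RINGS,
    DEEPSMILES_BRANCHES,
    DEEPSMILES_BOTH,
)
RANDOMIZED_KINDS = (RANDOMIZED_RESTRICTED, RANDOMIZED_UNRESTRICTED)
DEEPSMILES_KINDS = (DEEPSMILES_RINGS, DEEPSMILES_BRANCHES, DEEPSMILES_BOTH)


def check_variant(variant: str, allowed: Sequence[str] = VARIANT_KINDS) -> str:
    if variant not in allowed:
        raise ValueError(f"unknown or disallowed variant {variant!r}; expected one of {allowed}")
    return variant


def canonicalize(smiles: str) -> str | None:
    """Canonical SMILES of a string, or ``None`` if it does not parse.

    Returning a failure value instead of raising lets samplers count invalid
    strings.  Idempotent on its own output.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def heavy_atom_count(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    return mol.GetNumHeavyAtoms()


# ---------------------------------------------------------------------------
# permutation-driven DFS writer


class _UnwritableMolecule(ValueError):
    pass


def _bond_char(bond: Chem.Bond) -> str:
    bt = bond.GetBondType()
    if bt == Chem.BondType.AROMATIC:
        return ""
    if bt == Chem.BondType.SINGLE:
        # explicit single between two aromatic atoms (e.g. biphenyl)
        if bond.GetBeginAtom().GetIsAromatic() and bond.GetEndAtom().GetIsAromatic():
            return "-"
        return ""
    if bt == Chem.BondType.DOUBLE:
        return "="
    if bt == Chem.BondType.TRIPLE:
        return "#"
    raise _UnwritableMolecule(f"unsupported bond type {bt}")


def _ring_digit(d: int) -> str:
    if d <= 9:
        return str(d)
    if d <= 99:
        return f"%{d:02d}"
    raise _UnwritableMolecule("more than 99 simultaneously open rings")


def write_smiles(mol: Chem.Mol, rank: Sequence[int], restricted: bool) -> str:
    """Write one SMILES of ``mol`` from the atom permutation ``rank``.

    ``rank[i]`` is the position of atom ``i`` in the random ordering; the
    traversal starts at the rank-0 atom and picks neighbors in rank order
    (restricted mode additionally visits non-ring bonds first).
    """
    n = mol.GetNumAtoms()
    if n == 0:
        raise _UnwritableMolecule("empty molecule")
    rank = list(rank)
    start = rank.index(0)

    visited = [False] * n
    order: list[int] = []  # preorder
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    closures: list[list[int]] = []  # [open_atom, close_atom, bond_idx, digit]
    used_edges: set[int] = set()

    def neighbor_key(atom_idx: int, bond: Chem.Bond):
        other = bond.GetOtherAtomIdx(atom_idx)
        if restricted:
            return (bond.IsInRing(), rank[other])
        return rank[other]

    stack: list[tuple[int, Iterable]] = []

    def sorted_bonds(a: int):
        atom = mol.GetAtomWithIdx(a)
        return sorted(atom.GetBonds(), key=lambda b: neighbor_key(a, b))

    visited[start] = True
    order.append(start)
    stack.append((start, iter(sorted_bonds(start))))
    while stack:
        a, it = stack[-1]
        advanced = False
        for bond in it:
            nb = bond.GetOtherAtomIdx(a)
            if bond.GetIdx() in used_edges:
                continue
            if visited[nb]:
                used_edges.add(bond.GetIdx())
                closures.append([nb, a, bond.GetIdx(), -1])
            else:
                used_edges.add(bond.GetIdx())
                children[a].append(nb)
                visited[nb] = True
                order.append(nb)
                stack.append((nb, iter(sorted_bonds(nb))))
                advanced = True
                break
        if not advanced:
            stack.pop()

    # assign ring-closure digits in string (preorder) emission order,
    # reusing a digit once its closing copy has been written
    pos = {a: i for i, a in enumerate(order)}
    opening_at: dict[int, list[list[int]]] = {}
    closing_at: dict[int, list[list[int]]] = {}
    for cl in closures:
        o, c = cl[0], cl[1]
        if pos[o] > pos[c]:
            cl[0], cl[1] = c, o
            o, c = cl[0], cl[1]
        opening_at.setdefault(o, []).append(cl)
        closing_at.setdefault(c, []).append(cl)
    # emission order of several digits at one atom is fixed by the partner's
    # preorder position so the string is a pure function of the traversal
    for lst in opening_at.values():
        lst.sort(key=lambda cl: pos[cl[1]])
    for lst in closing_at.values():
        lst.sort(key=lambda cl: pos[cl[0]])
    free = list(range(99, 0, -1))
    for a in order:
        for cl in closing_at.get(a, ()):  # free before re-assigning
            free.append(cl[3])
            free.sort(reverse=True)
        for cl in opening_at.get(a, ()):
            cl[3] = free.pop()

    def digit_string(a: int) -> str:
        parts = []
        for cl in closing_at.get(a, ()):
            parts.append(_bond_char(mol.GetBondWithIdx(cl[2])) + _ring_digit(cl[3]))
        for cl in opening_at.get(a, ()):
            parts.append(_bond_char(mol.GetBondWithIdx(cl[2])) + _ring_digit(cl[3]))
        return "".join(parts)

    # iterative emission to avoid deep recursion on long chains
    out: list[str] = []
    emit_stack: list[tuple[str, object]] = [("atom", start)]
    while emit_stack:
        kind, payload = emit_stack.pop()
        if kind == "str":
            out.append(payload)
            continue
        a = payload
        out.append(mol.GetAtomWithIdx(a).GetSmarts())
        out.append(digit_string(a))
        cs = children[a]
        items: list[tuple[str, object]] = []
        for i, c in enumerate(cs):
            bond = mol.GetBondBetweenAtoms(a, c)
            last = i == len(cs) - 1
            wrap = (not last) or (not restricted and rank[c] < rank[a])
            if wrap:
                items.append(("str", "("))
            items.append(("str", _bond_char(bond)))
            items.append(("atom", c))
            if wrap:
                items.append(("str", ")"))
        emit_stack.extend(reversed(items))
    return "".join(out)


def _parse(canonical_smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(canonical_smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {canonical_smiles!r}")
    return mol


def randomize(canonical_smiles: str, variant: str, seed: int) -> str:
    """One randomized SMILES of a molecule from a uniformly random atom permutation.

    The permutation is uniform over atom orderings, not over distinct
    strings: several orderings can collapse onto one string, so frequent
    strings are over-represented relative to a uniform draw on the distinct
    set.
    """
    check_variant(variant, RANDOMIZED_KINDS)
    mol = _parse(canonical_smiles)
    rng = rng_for(seed, "randomize")
    rank = rng.permutation(mol.GetNumAtoms())
    return write_smiles(mol, rank.tolist(), restricted=variant == RANDOMIZED_RESTRICTED)


EXHAUSTIVE_GUARD = 8


def enumerate_random_smiles(
    canonical_smiles: str, variant: str, max_heavy_atoms: int = EXHAUSTIVE_GUARD
) -> set[str]:
    """All distinct randomized SMILES of a molecule, one write per atom permutation.

    The result size is at most ``n!``.  Molecules above ``max_heavy_atoms``
    are refused (use :func:`count_random_smiles` to estimate instead).
    """
    check_variant(variant, RANDOMIZED_KINDS)
    mol = _parse(canonical_smiles)
    n = mol.GetNumAtoms()
    if n > max_heavy_atoms:
        raise ValueError(
            f"molecule has {n} heavy atoms > guard {max_heavy_atoms}; "
            "use count_random_smiles for an estimate"
        )
    restricted = variant == RANDOMIZED_RESTRICTED
    out: set[str] = set()
    for perm in itertools.permutations(range(n)):
        out.add(write_smiles(mol, perm, restricted=restricted))
    assert len(out) <= factorial(n)
    return out


def count_random_smiles(
    canonical_smiles: str, variant: str, n_draws: int, seed: int
) -> int:
    """Distinct strings observed in ``n_draws`` randomized writings (a lower
    bound on the true count)."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    check_variant(variant, RANDOMIZED_KINDS)
    mol = _parse(canonical_smiles)
    n = mol.GetNumAtoms()
    restricted = variant == RANDOMIZED_RESTRICTED
    rng = rng_for(seed, "count_random_smiles")
    seen: set[str] = set()
    for _ in range(n_draws):
        rank = rng.permutation(n)
        seen.add(write_smiles(mol, rank.tolist(), restricted=restricted))
    return len(seen)


def to_deepsmiles(smiles: str, mode: str) -> str:
    """Convert a SMILES string to the DeepSMILES syntax variant ``mode``."""
    check_variant(mode, DEEPSMILES_KINDS)
    return encode_deepsmiles(
        smiles,
        rings=mode in (DEEPSMILES_RINGS, DEEPSMILES_BOTH),
        branches=mode in (DEEPSMILES_BRANCHES, DEEPSMILES_BOTH),
    )


def from_deepsmiles(deepsmiles: str, mode: str) -> str | None:
    """Decode a DeepSMILES string back to a SMILES string.

    Returns ``None`` (counted as invalid downstream) when the string does
    not decode to a valid molecule.
    """
    check_variant(mode, DEEPSMILES_KINDS)
    try:
        return decode_deepsmiles(
            deepsmiles,
            rings=mode in (DEEPSMILES_RINGS, DEEPSMILES_BOTH),
            branches=mode in (DEEPSMILES_BRANCHES, DEEPSMILES_BOTH),
        )
    except DeepSmilesError:
        return None


# ---------------------------------------------------------------------------
# per-epoch augmentation streams


@dataclass(frozen=True)
class AugmentationPlan:
    """How training strings are (re)generated for each epoch."""

    variant: str = RANDOMIZED_RESTRICTED
    epochs: int = 1
    base_seed: int = 0
    regenerate_each_epoch: bool = True

    def __post_init__(self) -> None:
        check_variant(self.variant)
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def epoch_strings(
    canonical_smiles: Sequence[str], plan: AugmentationPlan, epoch: int
) -> list[str]:
    """The string per molecule used in a given epoch under ``plan``.

    Canonical and DeepSMILES-of-canonical variants are constant across
    epochs; randomized variants are rewritten with a per-epoch child seed
    (training and validation sets are both regenerated this way).
    """
    variant = plan.variant
    eff_epoch = epoch if plan.regenerate_each_epoch else 0
    if variant == CANONICAL:
        return list(canonical_smiles)
    if variant in DEEPSMILES_KINDS:
        return [to_deepsmiles(s, variant) for s in canonical_smiles]
    out = []
    for i, smi in enumerate(canonical_smiles):
        out.append(randomize(smi, variant, child_seed(plan.base_seed, "epoch", eff_epoch, i)))
    return out


def write_augmentation_epochs(
    records: Sequence, plan: AugmentationPlan, out_dir: str | Path
) -> list[Path]:
    """Write one ``.smi`` file per epoch, one freshly written string per molecule.

    File naming is ``epoch_<e>.smi`` zero-padded to four digits.  The
    molecule multiset per file is invariant across epochs; only the strings
    change (and only for randomized variants).
    """
    if len(records) == 0:
        raise ValueError("no molecules to write")
    smiles = [getattr(r, "canonical_smiles", r) for r in records]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for e in range(plan.epochs):
        lines = epoch_strings(smiles, plan, e)
        path = out_dir / f"epoch_{e:04d}.smi"
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths.append(path)
    return paths
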