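"""A small, fully enumerable target chemical space with exclusion filters.

Large combinatorial databases of fragment-like molecules (the GDB family)
are built by exhaustively enumerating molecular graphs and then excluding
molecules with undesirable features (strained rings, unstable functional
groups, ...).  This module builds a desk-scale analog: every neutral,
connected molecule over a small element set up to a heavy-atom limit,
minus a decidable exclusion class.  Membership of any molecule is then a
canonical-SMILES lookup, which is what the coverage metrics require, and
valid molecules *outside* the space exist by construction (anything caught
by a filter), which is what closedness measurement requires.

The default filters exclude triple bonds and rings smaller than five atoms
— cheap, decidable analogs of the strained-ring / unstable-group exclusions
of the real databases, with no claim of mirroring them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from pathlib import Path
from typing import Sequence

from rdkit import Chem

from .rngutil import rng_for
from .variants import canonicalize

_DEFAULT_VALENCE = {"C": 4, "N": 3, "O": 2}
SUPPORTED_ELEMENTS = tuple(_DEFAULT_VALENCE)


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule keyed by its canonical SMILES."""

    canonical_smiles: str
    heavy_atom_count: int
    id: str | None = None

    @classmethod
    def from_smiles(cls, smiles: str, id: str | None = None) -> "MoleculeRecord":
        can = canonicalize(smiles)
        if can is None:
            raise ValueError(f"invalid SMILES {smiles!r}")
        mol = Chem.MolFromSmiles(can)
        return cls(can, mol.GetNumHeavyAtoms(), id)


@dataclass(frozen=True)
class FilterConfig:
    """Decidable exclusion filters defining the space boundary."""

    exclude_triple_bonds: bool = True
    min_ring_size: int | None = 5  # rings smaller than this are excluded
    exclude_double_bonds: bool = False  # saturated-only spaces (alkane fixtures)

    def rejects(self, mol: Chem.Mol) -> bool:
        if self.exclude_triple_bonds and any(
            b.GetBondType() == Chem.BondType.TRIPLE for b in mol.GetBonds()
        ):
            return True
        if self.exclude_double_bonds and any(
            b.GetBondType() != Chem.BondType.SINGLE for b in mol.GetBonds()
        ):
            return True
        if self.min_ring_size is not None:
            for ring in mol.GetRingInfo().AtomRings():
                if len(ring) < self.min_ring_size:
                    return True
        return False

    def is_trivial(self) -> bool:
        return not self.exclude_triple_bonds and self.min_ring_size is None


@dataclass(frozen=True)
class ChemicalSpace:
    """A finite target set of molecules with decidable membership."""

    members: frozenset[str]
    max_heavy_atoms: int = 0
    elements: tuple[str, ...] = ()
    filters: FilterConfig | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def uniform_nll(self) -> float:
        """NLL of every molecule under the ideal uniform model, ln N nats."""
        return log(self.size)

    def __contains__(self, canonical_smiles: str) -> bool:
        return canonical_smiles in self.members

    def sorted_members(self) -> list[str]:
        return sorted(self.members)

    def save(self, path: str | Path) -> None:
        """Write as a sorted one-SMILES-per-line file (content-deterministic)."""
        Path(path).write_text("\n".join(self.sorted_members()) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ChemicalSpace":
        lines = [
            ln.split()[0]
            for ln in Path(path).read_text(encoding="utf-8").splitlines()
            if ln.strip()
        ]
        return cls(frozenset(lines))


@dataclass(frozen=True)
class SpaceSplit:
    """Disjoint training/validation subsets of a space."""

    training: tuple[MoleculeRecord, ...]
    validation: tuple[MoleculeRecord, ...]
    seed: int = 0

    @property
    def training_smiles(self) -> list[str]:
        return [r.canonical_smiles for r in self.training]

    @property
    def validation_smiles(self) -> list[str]:
        return [r.canonical_smiles for r in self.validation]


def _free_valence(atom: Chem.Atom) -> int:
    # implicit hydrogens are displaceable, so only heavy-atom bonds count
    return _DEFAULT_VALENCE[atom.GetSymbol()] - int(atom.GetExplicitValence())


def _try_canonical(mol: Chem.RWMol) -> str | None:
    """Sanitize a candidate graph; canonical SMILES on success, None otherwise."""
    try:
        out = mol.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


_ORDER_VAL = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
}


def _bond_orders(filters: FilterConfig) -> list[Chem.BondType]:
    orders = [Chem.BondType.SINGLE]
    if not filters.exclude_double_bonds:
        orders.append(Chem.BondType.DOUBLE)
        if not filters.exclude_triple_bonds:
            orders.append(Chem.BondType.TRIPLE)
    return orders


def _grow(parent: Chem.Mol, filters: FilterConfig, elements: Sequence[str]):
    """Yield canonical SMILES of every filter-passing one-step extension."""
    bond_orders = _bond_orders(filters)
    n = parent.GetNumAtoms()
    for a in range(n):
        if _free_valence(parent.GetAtomWithIdx(a)) < 1:
            continue
        avail = _free_valence(parent.GetAtomWithIdx(a))
        for elem in elements:
            for bt in bond_orders:
                if _ORDER_VAL[bt] > min(avail, _DEFAULT_VALENCE[elem]):
                    continue
                rw = Chem.RWMol(parent)
                idx = rw.AddAtom(Chem.Atom(elem))
                rw.AddBond(a, idx, bt)
                can = _try_canonical(rw)
                if can is None:
                    continue
                grown = Chem.MolFromSmiles(can)
                if grown is not None and not filters.rejects(grown):
                    yield can


def _close_rings(parent: Chem.Mol, filters: FilterConfig):
    """Yield canonical SMILES from adding one bond between existing atoms."""
    bond_orders = _bond_orders(filters)
    n = parent.GetNumAtoms()
    for a in range(n):
        fa = _free_valence(parent.GetAtomWithIdx(a))
        if fa < 1:
            continue
        for b in range(a + 1, n):
            if parent.GetBondBetweenAtoms(a, b) is not None:
                continue
            fb = _free_valence(parent.GetAtomWithIdx(b))
            if fb < 1:
                continue
            for bt in bond_orders:
                if _ORDER_VAL[bt] > min(fa, fb):
                    continue
                rw = Chem.RWMol(parent)
                rw.AddBond(a, b, bt)
                can = _try_canonical(rw)
                if can is None:
                    continue
                closed = Chem.MolFromSmiles(can)
                if closed is not None and not filters.rejects(closed):
                    yield can


def enumerate_toy_space(
    max_heavy_atoms: int,
    elements: Sequence[str] = ("C", "N", "O"),
    filters: FilterConfig | None = None,
) -> ChemicalSpace:
    """Exhaustively enumerate the filtered space up to ``max_heavy_atoms``.

    Breadth-first molecular-graph growth with canonical-string deduplication:
    each level adds one atom to every graph of the previous level, then adds
    ring-closing bonds to a fixpoint within the level.  Filter-violating
    intermediates are pruned — both default filters are monotone (a triple
    bond or a small ring never disappears by adding atoms or bonds), so
    pruning does not change the result.
    """
    if not 1 <= max_heavy_atoms <= 10:
        raise ValueError("max_heavy_atoms must be in [1, 10]")
    for e in elements:
        if e not in SUPPORTED_ELEMENTS:
            raise ValueError(f"unsupported element {e!r}")
    if filters is None:
        filters = FilterConfig()

    members: set[str] = set()
    level: set[str] = set()
    for e in elements:
        can = canonicalize(e)
        if can is not None:
            level.add(can)
    members |= level

    for _size in range(2, max_heavy_atoms + 1):
        nxt: set[str] = set()
        for smi in level:
            mol = Chem.MolFromSmiles(smi)
            nxt.update(_grow(mol, filters, elements))
        # ring-closure fixpoint within this size
        frontier = set(nxt)
        while frontier:
            fresh: set[str] = set()
            for smi in frontier:
                mol = Chem.MolFromSmiles(smi)
                for can in _close_rings(mol, filters):
                    if can not in nxt:
                        fresh.add(can)
            nxt |= fresh
            frontier = fresh
        members |= nxt
        level = nxt

    if not members:
        raise ValueError("degenerate space: no molecule passes the filters")
    return ChemicalSpace(
        frozenset(members), max_heavy_atoms, tuple(elements), filters
    )


def split_train_validation(
    space: ChemicalSpace, n_train: int, n_valid: int, seed: int
) -> SpaceSplit:
    """Disjoint uniform random training/validation subsets, reproducible by seed."""
    if n_train + n_valid > space.size:
        raise ValueError(
            f"requested {n_train}+{n_valid} molecules from a space of {space.size}"
        )
    rng = rng_for(seed, "split")
    members = space.sorted_members()
    picked = rng.choice(len(members), size=n_train + n_valid, replace=False)
    train = [MoleculeRecord.from_smiles(members[i]) for i in picked[:n_train]]
    valid = [MoleculeRecord.from_smiles(members[i]) for i in picked[n_train:]]
    return SpaceSplit(tuple(train), tuple(valid), seed)


def ideal_sample(space: ChemicalSpace, k: int, seed: int) -> list[str]:
    """``k`` uniform draws with replacement from the space (the ideal model)."""
    if space.size == 0:
        raise ValueError("empty space")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = rng_for(seed, "ideal_sample")
    members = space.sorted_members()
    idx = rng.integers(0, len(members), size=k)
    return [members[i] for i in idx]
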