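"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by a different route than the library
(exhaustive adjacency-matrix enumeration, direct formula evaluation,
Monte-Carlo simulation) so that agreement is evidence of correctness rather
than of shared code.
"""

from __future__ import annotations

import itertools

import numpy as np
from rdkit import Chem

_VALENCE = {"C": 4, "N": 3, "O": 2}
_BOND = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


def brute_force_space(max_heavy_atoms: int, elements, min_ring_size=5,
                      allow_triple=False) -> set[str]:
    """All filtered molecules by exhaustive upper-triangular bond-matrix search.

    Completely independent of the library's breadth-first graph growth: for
    every atom count, every element assignment and every bond-order matrix is
    tried, validity is delegated to sanitization, connectivity to a
    union-find, and the filters are applied to the finished molecule.
    """
    out: set[str] = set()
    max_order = 3 if allow_triple else 2
    for n in range(1, max_heavy_atoms + 1):
        pairs = list(itertools.combinations(range(n), 2))
        for elems in itertools.product(elements, repeat=n):
            cap = [_VALENCE[e] for e in elems]
            for orders in itertools.product(range(max_order + 1), repeat=len(pairs)):
                # cheap valence pre-check
                deg = [0] * n
                ok = True
                for (a, b), o in zip(pairs, orders):
                    deg[a] += o
                    deg[b] += o
                for a in range(n):
                    if deg[a] > cap[a] or (n > 1 and deg[a] == 0):
                        ok = False
                        break
                if not ok:
                    continue
                # connectivity (union-find)
                parent = list(range(n))

                def find(x):
                    while parent[x] != x:
                        parent[x] = parent[parent[x]]
                        x = parent[x]
                    return x

                for (a, b), o in zip(pairs, orders):
                    if o:
                        parent[find(a)] = find(b)
                if n > 1 and len({find(i) for i in range(n)}) != 1:
                    continue
                rw = Chem.RWMol()
                for e in elems:
                    rw.AddAtom(Chem.Atom(e))
                for (a, b), o in zip(pairs, orders):
                    if o:
                        rw.AddBond(a, b, _BOND[o])
                try:
                    mol = rw.GetMol()
                    Chem.SanitizeMol(mol)
                except Exception:
                    continue
                if not allow_triple and any(
                    b.GetBondType() == Chem.BondType.TRIPLE for b in mol.GetBonds()
                ):
                    continue
                if min_ring_size is not None and any(
                    len(r) < min_ring_size for r in mol.GetRingInfo().AtomRings()
                ):
                    continue
                out.add(Chem.MolToSmiles(mol))
    return out


def trailing_moving_average(values, window: int):
    """Plain-loop trailing moving average (prefix uses available history)."""
    out = []
    for i in range(len(values)):
        acc = 0.0
        cnt = 0
        for j in range(max(0, i - window + 1), i + 1):
            acc += values[j]
            cnt += 1
        out.append(acc / cnt)
    return out


def jsd_by_formula(dists, weights):
    """Direct evaluation of H(sum a_i d_i) - sum a_i H(d_i) with plain loops."""

    def H(p):
        return -sum(x * np.log(x) for x in p if x > 0)

    mix = [sum(w * d[i] for w, d in zip(weights, dists)) for i in range(len(dists[0]))]
    return H(mix) - sum(w * H(d) for w, d in zip(weights, dists))


def mc_unique_fraction(N: int, k: int, n_rep: int, seed: int):
    """Monte-Carlo mean and standard error of the unique fraction of k draws
    with replacement on N items (birthday-style simulation)."""
    rng = np.random.default_rng(seed)
    fracs = np.empty(n_rep)
    for r in range(n_rep):
        fracs[r] = len(np.unique(rng.integers(0, N, size=k))) / N
    return float(fracs.mean()), float(fracs.std(ddof=1) / np.sqrt(n_rep))
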