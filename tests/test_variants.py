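import itertools
from math import factorial

import pytest
from rdkit import Chem

from smilesrnn import variants as V
from smilesrnn.tokenizer import build_vocabulary

ASPIRIN = "CC(=O)Oc1ccccc1C(=O)O"


def test_canonicalize_basic():
    can = V.canonicalize("OCC")
    # idempotent and graph-preserving, whatever the exact canonical string
    assert can == V.canonicalize(can)
    assert Chem.MolToSmiles(Chem.MolFromSmiles("OCC")) == can
    assert V.canonicalize("C") == "C"
    assert V.canonicalize("C1CC") is None  # unclosed ring -> failure value
    assert V.canonicalize("not a molecule") is None


def test_unknown_variant_rejected():
    with pytest.raises(ValueError):
        V.check_variant("randomised")
    with pytest.raises(ValueError):
        V.randomize("C", V.CANONICAL, 0)


def test_single_atom_has_one_writing():
    for variant in V.RANDOMIZED_KINDS:
        assert V.randomize("C", variant, 123) == "C"
        assert V.enumerate_random_smiles("C", variant) == {"C"}


def test_randomize_preserves_graph_many_seeds():
    """canonicalize(randomize(x)) = x over molecules x seeds x variants."""
    mols = [ASPIRIN, "CCO", "C1CCNC1", "O=C1CCCO1", "c1cc[nH]c1", "N#Cc1ccccc1"]
    for smi in mols:
        can = V.canonicalize(smi)
        for variant in V.RANDOMIZED_KINDS:
            for seed in range(100):
                assert V.canonicalize(V.randomize(can, variant, seed)) == can


def test_enumerate_matches_independent_permutation_loop():
    """An independently coded loop over all n! orderings finds the same set."""
    can = V.canonicalize("CCO")
    mol = Chem.MolFromSmiles(can)
    for variant, restricted in [
        (V.RANDOMIZED_RESTRICTED, True),
        (V.RANDOMIZED_UNRESTRICTED, False),
    ]:
        expected = set()
        for perm in itertools.permutations(range(mol.GetNumAtoms())):
            expected.add(V.write_smiles(mol, list(perm), restricted=restricted))
        assert V.enumerate_random_smiles(can, variant) == expected
        assert len(expected) <= factorial(3)


def test_enumerate_guard():
    with pytest.raises(ValueError, match="count_random_smiles"):
        V.enumerate_random_smiles(ASPIRIN, V.RANDOMIZED_RESTRICTED, 8)


def test_restricted_subset_of_unrestricted_exhaustive(small_space):
    """Restricted string sets are contained in unrestricted ones, molecule by
    molecule, verified by exhaustive enumeration over the whole toy space."""
    checked = 0
    for smi in small_space.sorted_members():
        res = V.enumerate_random_smiles(smi, V.RANDOMIZED_RESTRICTED)
        unr = V.enumerate_random_smiles(smi, V.RANDOMIZED_UNRESTRICTED)
        assert res <= unr, smi
        n = Chem.MolFromSmiles(smi).GetNumAtoms()
        assert len(unr) <= factorial(n)
        checked += 1
    assert checked == small_space.size


def test_roundtrip_exhaustive_over_space_sample(small_space):
    """Every enumerated writing canonicalizes back to its molecule (>=1000 pairs)."""
    pairs = 0
    for smi in small_space.sorted_members()[::7]:
        for variant in V.RANDOMIZED_KINDS:
            for out in V.enumerate_random_smiles(smi, variant):
                assert V.canonicalize(out) == smi
                pairs += 1
    assert pairs >= 1000


def test_unrestricted_emits_convoluted_ring_entry_restricted_never_does():
    """On benzene the unrestricted writer can open a ring into nested branches
    (the c1cc(c(cc1)) pattern family); the restricted writer never can."""
    benzene = V.canonicalize("c1ccccc1")
    res = V.enumerate_random_smiles(benzene, V.RANDOMIZED_RESTRICTED)
    unr = V.enumerate_random_smiles(benzene, V.RANDOMIZED_UNRESTRICTED)
    assert res == {"c1ccccc1"}
    convoluted = {s for s in unr if "(" in s and s.index("1", 2) > s.index("(")}
    assert convoluted, "expected ring closures inside branches"
    assert not any("(" in s for s in res)


def test_count_random_smiles_saturates_to_exhaustive_count():
    can = V.canonicalize("CCO")
    exact = len(V.enumerate_random_smiles(can, V.RANDOMIZED_RESTRICTED))
    est = V.count_random_smiles(can, V.RANDOMIZED_RESTRICTED, n_draws=50 * 6, seed=0)
    assert est == exact
    # determinism and monotonicity in expectation (lower bound property)
    assert est == V.count_random_smiles(can, V.RANDOMIZED_RESTRICTED, 300, seed=0)
    few = V.count_random_smiles(can, V.RANDOMIZED_RESTRICTED, 2, seed=0)
    assert few <= est
    assert V.count_random_smiles("C", V.RANDOMIZED_RESTRICTED, 100, seed=1) == 1


# -- DeepSMILES --------------------------------------------------------------


def test_deepsmiles_trivial_and_benzene():
    for mode in V.DEEPSMILES_KINDS:
        assert V.to_deepsmiles("C", mode) == "C"
    ds = V.to_deepsmiles("c1ccccc1", V.DEEPSMILES_RINGS)
    assert ds == "cccccc6"  # ring size digit at the closing site only
    back = V.from_deepsmiles(ds, V.DEEPSMILES_RINGS)
    assert V.canonicalize(back) == V.canonicalize("c1ccccc1")


def test_deepsmiles_branch_syntax():
    assert V.to_deepsmiles("CC(C)C", V.DEEPSMILES_BRANCHES) == "CCC)C"
    assert V.to_deepsmiles("CC(C)(C)C", V.DEEPSMILES_BRANCHES) == "CCC)C)C"


@pytest.mark.parametrize("mode", V.DEEPSMILES_KINDS)
def test_deepsmiles_roundtrip_over_space(small_space, mode):
    for smi in small_space.sorted_members()[::5]:
        ds = V.to_deepsmiles(smi, mode)
        back = V.from_deepsmiles(ds, mode)
        assert back is not None and V.canonicalize(back) == smi, (smi, ds)


def test_deepsmiles_vocabulary_differs(small_space):
    corpus = small_space.sorted_members()
    base = build_vocabulary(corpus)
    conv = build_vocabulary([V.to_deepsmiles(s, V.DEEPSMILES_BOTH) for s in corpus])
    assert set(base.tokens) != set(conv.tokens)
    assert "(" not in conv.tokens  # branch rewrite removes open parentheses


def test_deepsmiles_failure_is_typed():
    assert V.from_deepsmiles(")))", V.DEEPSMILES_BRANCHES) is None
    assert V.from_deepsmiles("ccc9", V.DEEPSMILES_RINGS) is None


# -- augmentation epochs ------------------------------------------------------


def test_epoch_files_constant_molecule_multiset(tmp_path, small_space):
    smiles = small_space.sorted_members()[:100]
    plan = V.AugmentationPlan(V.RANDOMIZED_RESTRICTED, epochs=4, base_seed=7)
    paths = V.write_augmentation_epochs(smiles, plan, tmp_path)
    assert [p.name for p in paths] == [f"epoch_{e:04d}.smi" for e in range(4)]
    seen_multisets = []
    all_lines = set()
    for p in paths:
        lines = p.read_text().splitlines()
        assert sorted(V.canonicalize(l) for l in lines) == sorted(smiles)
        seen_multisets.append(sorted(lines))
        all_lines.update(lines)
    # augmentation produced different strings in at least one epoch pair,
    # and never more distinct strings than epochs x molecules
    assert len({tuple(m) for m in seen_multisets}) > 1
    assert len(all_lines) <= 4 * len(smiles)


def test_canonical_epoch_files_identical(tmp_path):
    plan = V.AugmentationPlan(V.CANONICAL, epochs=5, base_seed=0)
    paths = V.write_augmentation_epochs(["C"], plan, tmp_path)
    contents = {p.read_text() for p in paths}
    assert contents == {"C\n"}
    assert len(paths) == 5


def test_empty_record_list_rejected(tmp_path):
    with pytest.raises(ValueError):
        V.write_augmentation_epochs(
            [], V.AugmentationPlan(V.CANONICAL, epochs=1), tmp_path
        )
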