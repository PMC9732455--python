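"""Fragmentation, fragment-space bookkeeping, and the RAFSF score."""

from collections import Counter

import pytest
from rdkit import Chem
from rdkit.Chem import BRICS

from molforge import fixtures, rafsf
from molforge.errors import ConfigurationError
from molforge.rafsf import FragmentSpace


def _erase_isotopes(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetIsotope(0)
    return Chem.MolToSmiles(mol)


class TestFragmentMolecule:
    def test_no_cleavable_bond_returns_self(self):
        frags, bonds = rafsf.fragment_molecule("CC")
        assert frags == frozenset({"CC"})
        assert bonds == frozenset()

    def test_matches_reference_brics_decomposition(self):
        """Independent oracle: RDKit's own one-level BRICS decomposition."""
        smiles = "CC(=O)Nc1ccccc1"
        frags, bonds = rafsf.fragment_molecule(smiles)
        oracle = {
            _erase_isotopes(f)
            for f in BRICS.BRICSDecompose(Chem.MolFromSmiles(smiles))
        }
        assert frags == oracle
        assert len(bonds) == len(list(BRICS.FindBRICSBonds(Chem.MolFromSmiles(smiles))))

    def test_invariant_to_input_atom_ordering(self):
        a = rafsf.fragment_molecule("CC(=O)Nc1ccccc1")
        b = rafsf.fragment_molecule("c1ccccc1NC(C)=O")
        assert a == b

    def test_brics_labels_kept_when_configured(self):
        frags, _ = rafsf.fragment_molecule(
            "CC(=O)Nc1ccccc1", erase_attachment_labels=False
        )
        assert any("[1*]" in f or "[5*]" in f for f in frags)

    def test_extra_amide_rule_is_a_superset(self):
        # exocyclic amide not covered by standard BRICS (acetamide itself)
        frags_std, _ = rafsf.fragment_molecule("CC(N)=O")
        frags_ext, bonds_ext = rafsf.fragment_molecule(
            "CC(N)=O", cleave_exocyclic_amides=True
        )
        assert frags_std == frozenset({"CC(N)=O"})
        assert "amide-amide" in bonds_ext
        assert len(frags_ext) == 2


class TestFragmentSpace:
    def test_multiplicity(self):
        space = rafsf.build_fragment_space(["CC(=O)Nc1ccccc1"] * 10)
        assert set(space.fragments.values()) == {10}
        assert set(space.bonds.values()) == {10}

    def test_merge_additivity(self, corpus60):
        left = rafsf.build_fragment_space(corpus60[:30], "left")
        right = rafsf.build_fragment_space(corpus60[30:], "right")
        merged = left.merge(right)
        whole = rafsf.build_fragment_space(corpus60, "whole")
        assert merged.fragments == whole.fragments
        assert merged.bonds == whole.bonds

    def test_totals_equal_brute_force_recount(self, corpus60):
        space = rafsf.build_fragment_space(corpus60)
        n_frags = sum(len(rafsf.fragment_molecule(s)[0]) for s in corpus60)
        n_bonds = sum(len(rafsf.fragment_molecule(s)[1]) for s in corpus60)
        assert space.fragment_total == n_frags
        assert space.bond_total == n_bonds

    def test_empty_corpus_error(self):
        with pytest.raises(ConfigurationError):
            rafsf.build_fragment_space([])

    def test_file_round_trip(self, fragment_space, tmp_path):
        path = tmp_path / "space.tsv"
        fragment_space.save(path)
        loaded = FragmentSpace.load(path)
        assert loaded.fragments == fragment_space.fragments
        assert loaded.bonds == fragment_space.bonds
        assert loaded.n_molecules == fragment_space.n_molecules
        assert loaded.corpus_id == fragment_space.corpus_id

    def test_merge_rules_must_match(self, fragment_space):
        other = FragmentSpace(cleave_exocyclic_amides=True)
        with pytest.raises(ConfigurationError):
            fragment_space.merge(other)


class TestScore:
    def test_everything_at_max_count_scores_one(self):
        space = rafsf.build_fragment_space(["CC(=O)Nc1ccccc1"] * 5)
        result = rafsf.rafsf_score("CC(=O)Nc1ccccc1", space)
        assert result.score == pytest.approx(1.0)

    def test_absent_fragment_scores_ten(self, fragment_space):
        # a phosphonate appears nowhere in the fixture corpus
        result = rafsf.rafsf_score("CCP(=O)(OCC)OCC", fragment_space)
        assert result.score == 10.0

    def test_log_midpoint_scores_five_and_a_half(self):
        # count 9 against Cmax 99: log10(10)/log10(100) = 1/2 -> penalty 0.5
        space = FragmentSpace(
            fragments=Counter({"CC": 9, "c1ccccc1": 99}), n_molecules=99
        )
        result = rafsf.rafsf_score("CC", space)
        assert result.score == pytest.approx(5.5)

    def test_bounds_on_fixture_molecules(self, fragment_space):
        mols = fixtures.generate_corpus(
            fixtures.FixtureSpec(corpus_size=200, seed=7)
        )
        for smiles in mols:
            score = rafsf.rafsf_score(smiles, fragment_space).score
            assert 1.0 <= score <= 10.0

    def test_monotone_in_fragment_frequency(self, corpus60):
        space = rafsf.build_fragment_space(corpus60)
        target = corpus60[0]
        base = rafsf.rafsf_score(target, space).score
        frags, _ = rafsf.fragment_molecule(target)
        for frag in frags:
            # below the table maximum, so the calibration count Cmax is fixed
            if 1 < space.fragments[frag] < space.max_fragment_count:
                poorer = FragmentSpace(
                    fragments=space.fragments.copy(),
                    bonds=space.bonds.copy(),
                    n_molecules=space.n_molecules,
                )
                poorer.fragments[frag] -= 1
                assert rafsf.rafsf_score(target, poorer).score >= base - 1e-12

    def test_deterministic(self, fragment_space, corpus60):
        a = rafsf.rafsf_score(corpus60[3], fragment_space)
        b = rafsf.rafsf_score(corpus60[3], fragment_space)
        assert a.score == b.score and a.details == b.details

    def test_rarest_fragment_reported(self, fragment_space):
        result = rafsf.rafsf_score("CCP(=O)(OCC)OCC", fragment_space)
        assert result.rarest in {d[0] for d in result.details}
        assert any(count == 0 for _, count, _ in result.details)

    def test_empty_space_rejected(self):
        with pytest.raises(ConfigurationError):
            rafsf.rafsf_score("CC", FragmentSpace())
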