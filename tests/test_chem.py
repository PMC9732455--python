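"""Canonicalization, fingerprints, and the six similarity measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import DataStructs

from molforge import chem
from molforge.chem import FingerprintKind, SimilarityMeasure
from molforge.errors import (
    ConfigurationError,
    InvalidSmilesError,
    SimilarityUndefinedError,
)


class TestCanonicalize:
    def test_aromatic_perception_identity(self):
        assert chem.canonicalize("C1=CC=CC=C1") == chem.canonicalize("c1ccccc1")

    def test_atom_order_invariance(self):
        assert chem.canonicalize("OCC") == chem.canonicalize("CCO")

    @pytest.mark.parametrize("bad", ["C1CC", "", "not smiles", "C(C"])
    def test_invalid_input_raises_with_offender(self, bad):
        with pytest.raises(InvalidSmilesError):
            chem.canonicalize(bad)

    def test_idempotent_on_corpus(self, corpus60):
        for smiles in corpus60:
            canonical = chem.canonicalize(smiles)
            assert chem.canonicalize(canonical) == canonical

    def test_salt_stripping_is_opt_in(self):
        salted = "CCO.[Na+].[Cl-]"
        assert "." in chem.canonicalize(salted)
        assert chem.canonicalize(salted, strip_salts=True) == chem.canonicalize("CCO")


class TestFingerprints:
    def test_deterministic(self):
        a = chem.fingerprint("c1ccccc1O", FingerprintKind.CIRCULAR)
        b = chem.fingerprint("c1ccccc1O", FingerprintKind.CIRCULAR)
        assert np.array_equal(a, b)

    def test_lengths(self):
        mol = chem.mol_from_smiles("CCO")
        assert len(chem.fingerprint(mol, FingerprintKind.MACCS166)) == 166
        for kind in FingerprintKind:
            if kind is not FingerprintKind.MACCS166:
                assert len(chem.fingerprint(mol, kind, n_bits=512)) == 512

    def test_path_and_circular_nonzero_for_heavy_atoms(self):
        # circular invariants cover a lone heavy atom; path enumeration
        # needs at least one bond
        assert chem.fingerprint("C", FingerprintKind.CIRCULAR).sum() >= 1
        for kind in (FingerprintKind.PATH, FingerprintKind.CIRCULAR):
            assert chem.fingerprint("CC", kind).sum() >= 1

    def test_unknown_kind_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            chem.fingerprint("CCO", "morgan")  # type: ignore[arg-type]

    def test_self_similarity_maccs(self):
        fp = chem.fingerprint("c1ccccc1", FingerprintKind.MACCS166)
        assert chem.similarity(fp, fp, SimilarityMeasure.TANIMOTO) == 1.0


def _vec(bits, length=16):
    v = np.zeros(length, dtype=bool)
    v[list(bits)] = True
    return v


class TestSimilarity:
    A = _vec({1, 2, 3})
    B = _vec({2, 3, 4})

    @pytest.mark.parametrize(
        "measure,expected",
        [
            (SimilarityMeasure.TANIMOTO, 0.5),
            (SimilarityMeasure.DICE, 2 / 3),
            (SimilarityMeasure.COSINE, 2 / 3),
            (SimilarityMeasure.SOKAL, 1 / 3),
            (SimilarityMeasure.KULCZYNSKI, 2 / 3),
            (SimilarityMeasure.MCCONNAUGHEY, 1 / 3),
        ],
    )
    def test_hand_worked_pair(self, measure, expected):
        # a=3, b=3, c=2 plugged into each closed form
        assert chem.similarity(self.A, self.B, measure) == pytest.approx(expected)

    @pytest.mark.parametrize("measure", list(SimilarityMeasure))
    def test_self_similarity_is_one(self, measure):
        assert chem.similarity(self.A, self.A, measure) == pytest.approx(1.0)

    def test_disjoint_tanimoto_zero(self):
        assert chem.similarity(_vec({0, 1}), _vec({2, 3}), SimilarityMeasure.TANIMOTO) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            chem.similarity(_vec({1}, 8), _vec({1}, 16), SimilarityMeasure.DICE)

    def test_all_zero_conventions(self):
        z = _vec(set())
        for measure in SimilarityMeasure:
            if measure is SimilarityMeasure.MCCONNAUGHEY:
                with pytest.raises(SimilarityUndefinedError):
                    chem.similarity(z, z, measure)
            else:
                assert chem.similarity(z, z, measure) == 0.0
        assert chem.similarity(z, self.A, SimilarityMeasure.COSINE) == 0.0


def _oracle(fa, fb, measure):
    """Independent route: explicit python-set arithmetic on on-bit index sets."""
    sa = {i for i, bit in enumerate(fa) if bit}
    sb = {i for i, bit in enumerate(fb) if bit}
    a, b, c = len(sa), len(sb), len(sa & sb)
    if measure is SimilarityMeasure.MCCONNAUGHEY:
        return (c * (a + b) - a * b) / (a * b)
    if a == 0 or b == 0:
        return 0.0
    return {
        SimilarityMeasure.TANIMOTO: c / (a + b - c),
        SimilarityMeasure.DICE: 2 * c / (a + b),
        SimilarityMeasure.COSINE: c / math.sqrt(a * b),
        SimilarityMeasure.SOKAL: c / (2 * a + 2 * b - 3 * c),
        SimilarityMeasure.KULCZYNSKI: c * (a + b) / (2 * a * b),
    }[measure]


@settings(max_examples=250, derandomize=True)
@given(
    st.lists(st.booleans(), min_size=8, max_size=64),
    st.data(),
)
def test_similarity_matches_set_oracle(bits_a, data):
    fa = np.array(bits_a, dtype=bool)
    fb = np.array(data.draw(st.lists(st.booleans(), min_size=len(fa), max_size=len(fa))), dtype=bool)
    for measure in SimilarityMeasure:
        if measure is SimilarityMeasure.MCCONNAUGHEY and (not fa.any() or not fb.any()):
            continue
        assert chem.similarity(fa, fb, measure) == pytest.approx(_oracle(fa, fb, measure))
    if fa.any() or fb.any():
        assert chem.similarity(fa, fb, SimilarityMeasure.TANIMOTO) <= chem.similarity(
            fa, fb, SimilarityMeasure.DICE
        ) + 1e-12


def test_similarity_agrees_with_rdkit_bitvector_routines():
    """Cross-check against RDKit's own similarity implementations."""
    rng = np.random.default_rng(11)
    rdkit_fns = {
        SimilarityMeasure.TANIMOTO: DataStructs.TanimotoSimilarity,
        SimilarityMeasure.DICE: DataStructs.DiceSimilarity,
        SimilarityMeasure.COSINE: DataStructs.CosineSimilarity,
        SimilarityMeasure.SOKAL: DataStructs.SokalSimilarity,
        SimilarityMeasure.KULCZYNSKI: DataStructs.KulczynskiSimilarity,
        SimilarityMeasure.MCCONNAUGHEY: DataStructs.McConnaugheySimilarity,
    }
    for _ in range(50):
        fa = rng.random(128) < 0.25
        fb = rng.random(128) < 0.25
        if not (fa.any() and fb.any()):
            continue
        bva = DataStructs.CreateFromBitString("".join("1" if x else "0" for x in fa))
        bvb = DataStructs.CreateFromBitString("".join("1" if x else "0" for x in fb))
        for measure, fn in rdkit_fns.items():
            assert chem.similarity(fa, fb, measure) == pytest.approx(fn(bva, bvb), abs=1e-9)


class TestRecordsAndIO:
    def test_record_fields(self):
        rec = chem.MoleculeRecord.from_smiles("OCC", "m1")
        assert rec.smiles_canonical == chem.canonicalize("CCO")
        assert rec.mw == pytest.approx(46.07, abs=0.01)
        assert rec.mw > 0

    def test_smiles_file_round_trip(self, tmp_path, corpus60):
        path = tmp_path / "mols.smi"
        path.write_text("\n".join(f"{s}\tid{i}" for i, s in enumerate(corpus60[:10])))
        records = chem.read_smiles_file(path)
        assert [r.smiles_canonical for r in records] == corpus60[:10]
        out = tmp_path / "out.csv"
        chem.write_records_csv(records, out)
        assert len(out.read_text().splitlines()) == 11

    def test_csv_reader_checks_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ConfigurationError):
            chem.read_smiles_csv(path)

    def test_bundled_reference_lookup(self):
        smiles = chem.load_reference_smiles("PCW-A1001")
        assert chem.canonicalize(smiles) == chem.canonicalize(chem.PCW_A1001_SMILES)
        with pytest.raises(LookupError, match="not bundled"):
            chem.load_reference_smiles("NOT-A-RECORD")
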