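"""Structure standardization, identity keys, descriptors and fingerprints."""

import pytest
from rdkit import Chem

from patgen import chemstd
from patgen.errors import (
    InvalidSmiles,
    KindMismatch,
    StandardizationFailure,
    UnsupportedKind,
)


class TestParseSmiles:
    @pytest.mark.parametrize(
        "smiles,n_heavy",
        [("CCO", 3), ("c1ccccc1", 6), ("CC(=O)O", 4)],
    )
    def test_valid(self, smiles, n_heavy):
        mol = chemstd.parse_smiles(smiles)
        assert mol.GetNumAtoms() == n_heavy

    @pytest.mark.parametrize("bad", ["C1CC", "not-a-molecule", "C(", ""])
    def test_invalid_raises(self, bad):
        with pytest.raises(InvalidSmiles):
            chemstd.parse_smiles(bad)


class TestStandardize:
    def test_salt_reduced_to_neutral_parent(self):
        std = chemstd.standardize_smiles("CC(=O)[O-].[Na+]")
        assert std.canonical_smiles == "CC(=O)O"

    def test_already_standard_unchanged(self):
        std = chemstd.standardize_smiles("CCO")
        assert std.canonical_smiles == "CCO"

    def test_all_inorganic_rejected(self):
        with pytest.raises(StandardizationFailure):
            chemstd.standardize_smiles("[Na+].[Cl-]")

    def test_idempotent_on_universe_sample(self, universe):
        for rec in universe[:1000]:
            once = chemstd.standardize_smiles(rec.smiles)
            twice = chemstd.standardize_smiles(once.canonical_smiles)
            assert once.canonical_smiles == twice.canonical_smiles
            assert once.inchikey_nostereo == twice.inchikey_nostereo

    def test_canonical_smiles_round_trips(self, universe):
        for rec in universe[:200]:
            std = chemstd.standardize_smiles(rec.smiles)
            again = Chem.MolToSmiles(Chem.MolFromSmiles(std.canonical_smiles))
            assert again == std.canonical_smiles


class TestInchikeyNostereo:
    def test_ethanol_reference_key(self):
        # reference InChI value for ethanol
        mol = chemstd.parse_smiles("CCO")
        assert chemstd.inchikey_nostereo(mol) == "LFQSCWFLJHTTHZ-UHFFFAOYSA-N"

    def test_stereoisomers_collide(self):
        l_ala = chemstd.parse_smiles("C[C@H](N)C(=O)O")
        d_ala = chemstd.parse_smiles("C[C@@H](N)C(=O)O")
        flat = chemstd.parse_smiles("CC(N)C(=O)O")
        keys = {chemstd.inchikey_nostereo(m) for m in (l_ala, d_ala, flat)}
        assert len(keys) == 1

    def test_distinct_connectivity_distinct_keys(self):
        assert chemstd.inchikey_nostereo(chemstd.parse_smiles("CCO")) != \
            chemstd.inchikey_nostereo(chemstd.parse_smiles("CCN"))

    def test_key_shape(self, universe):
        import re

        pattern = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")
        for rec in universe[:100]:
            key = chemstd.inchikey_nostereo(chemstd.parse_smiles(rec.smiles))
            assert pattern.match(key)

    def test_stereo_erasure_invariant(self, universe):
        """Keys never change when stereo annotations are wiped from input."""
        from rdkit.Chem import AllChem

        for rec in universe[:50]:
            mol = chemstd.parse_smiles(rec.smiles)
            flat = Chem.Mol(mol)
            Chem.RemoveStereochemistry(flat)
            assert chemstd.inchikey_nostereo(mol) == chemstd.inchikey_nostereo(flat)


class TestDescriptors:
    def test_benzene(self):
        d = chemstd.compute_descriptors(chemstd.parse_smiles("c1ccccc1"))
        assert d.n_aromatic_rings == 1
        assert d.fraction_csp3 == 0.0
        assert d.murcko_scaffold == "c1ccccc1"

    def test_methane_acyclic_scaffold_empty(self):
        d = chemstd.compute_descriptors(chemstd.parse_smiles("C"))
        assert d.murcko_scaffold == ""

    def test_cyclohexane(self):
        d = chemstd.compute_descriptors(chemstd.parse_smiles("C1CCCCC1"))
        assert d.max_ring_size == 6
        assert d.n_radical_electrons == 0

    def test_ranges(self, universe):
        for rec in universe[:100]:
            d = chemstd.compute_descriptors(chemstd.parse_smiles(rec.smiles))
            assert 0.0 <= d.qed <= 1.0
            assert 1.0 <= d.sa_score <= 10.0
            assert 0.0 <= d.fraction_csp3 <= 1.0
            assert d.n_heavy_atoms <= d.n_atoms
            assert (d.murcko_scaffold == "") == (d.max_ring_size == 0)


class TestFingerprints:
    def test_deterministic(self):
        mol = chemstd.parse_smiles("CC(=O)Nc1ccc(O)cc1")
        for kind in chemstd.FINGERPRINT_KINDS:
            assert chemstd.fingerprint(mol, kind) == chemstd.fingerprint(mol, kind)

    def test_same_structure_same_fingerprints(self):
        a = chemstd.parse_smiles("OCC")  # ethanol, alternative atom order
        b = chemstd.parse_smiles("CCO")
        for kind in chemstd.FINGERPRINT_KINDS:
            assert chemstd.fingerprint(a, kind) == chemstd.fingerprint(b, kind)

    def test_unsupported_kind(self):
        with pytest.raises(UnsupportedKind):
            chemstd.fingerprint(chemstd.parse_smiles("CCO"), "maccs")

    def test_mhfp_length(self):
        fp = chemstd.fingerprint(chemstd.parse_smiles("CCO"), "mhfp6")
        assert len(fp.payload) == 2048


class TestTanimoto:
    def test_self_similarity_one(self, universe):
        for rec in universe[:20]:
            mol = chemstd.parse_smiles(rec.smiles)
            for kind in chemstd.FINGERPRINT_KINDS:
                fp = chemstd.fingerprint(mol, kind)
                assert chemstd.tanimoto(fp, fp) == 1.0

    def test_hand_computed_bit_sets(self):
        a = chemstd.Fingerprint("morgan_r2", 2048, (1, 2, 3))
        b = chemstd.Fingerprint("morgan_r2", 2048, (2, 3, 4))
        assert chemstd.tanimoto(a, b) == 0.5

    def test_disjoint_sets_zero(self):
        a = chemstd.Fingerprint("morgan_r2", 2048, (1, 2))
        b = chemstd.Fingerprint("morgan_r2", 2048, (3, 4))
        assert chemstd.tanimoto(a, b) == 0.0

    def test_symmetry(self, universe):
        mols = [chemstd.parse_smiles(r.smiles) for r in universe[:10]]
        fps = [chemstd.fingerprint(m, "morgan_r2") for m in mols]
        for i in range(len(fps)):
            for j in range(i):
                assert chemstd.tanimoto(fps[i], fps[j]) == \
                    chemstd.tanimoto(fps[j], fps[i])

    def test_kind_mismatch(self):
        a = chemstd.Fingerprint("morgan_r2", 2048, (1,))
        b = chemstd.Fingerprint("morgan_r3", 2048, (1,))
        with pytest.raises(KindMismatch):
            chemstd.tanimoto(a, b)


from hypothesis import given, settings, strategies as st  # noqa: E402

bits = st.sets(st.integers(min_value=0, max_value=2047), max_size=200)


@given(a=bits, b=bits)
@settings(deadline=None, max_examples=200, derandomize=True)
def test_tanimoto_equals_set_formula(a, b):
    """Bit-set Tanimoto equals |a∩b|/|a∪b| for arbitrary index sets."""
    fa = chemstd.Fingerprint("morgan_r2", 2048, tuple(sorted(a)))
    fb = chemstd.Fingerprint("morgan_r2", 2048, tuple(sorted(b)))
    expected = len(a & b) / len(a | b) if (a | b) else 1.0
    assert chemstd.tanimoto(fa, fb) == pytest.approx(expected)
    assert chemstd.tanimoto(fa, fb) == chemstd.tanimoto(fb, fa)
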