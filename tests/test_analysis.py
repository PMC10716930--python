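"""Metrics formulas, similarity binning, QED, embedding, analog search."""

import numpy as np
import pytest

from patgen import analysis, chemstd, fixtures, generator
from patgen.errors import EmptyLog, EmptyReferenceSet, InvalidQuery, TooFewMolecules
from patgen.generator import GeneratedMolecule, GenerationConfig, GenerationLog


def _log(entries):
    """entries: list of (smiles, parse_valid, passed)."""
    records = []
    for i, (smi, ok, passed) in enumerate(entries):
        records.append(
            GeneratedMolecule(
                smiles=smi,
                parse_valid=ok,
                filter_verdicts={"lipinski": passed} if ok else None,
                reward=0.0 if (ok and passed) else None,
                first_seen_iteration=i,
                canonical_smiles=smi if ok else None,
            )
        )
    return GenerationLog(GenerationConfig(), records)


class TestComputeMetrics:
    def test_hand_computed_fractions(self):
        log = _log([
            ("CCO", True, True),
            ("CCN", True, True),
            ("CCO", True, True),     # duplicate valid
            ("C1CC", False, False),  # invalid
        ])
        m = analysis.compute_metrics(log)
        assert m.validity == pytest.approx(3 / 4)
        assert m.uniqueness == pytest.approx(2 / 3)
        # count consistency: both numerators are integers
        assert m.validity * m.n_all == pytest.approx(round(m.validity * m.n_all))
        assert m.uniqueness * m.n_valid == pytest.approx(round(m.uniqueness * m.n_valid))

    def test_filtered_records_count_as_invalid(self):
        log = _log([("CCO", True, True), ("C1CCCCCC1", True, False)])
        m = analysis.compute_metrics(log)
        assert m.validity == pytest.approx(1 / 2)

    def test_all_invalid_flagged(self):
        with pytest.raises(EmptyLog):
            analysis.compute_metrics(_log([("xx", False, False)]))

    def test_empty_log_flagged(self):
        with pytest.raises(EmptyLog):
            analysis.compute_metrics(GenerationLog(GenerationConfig()))

    def test_db_match_count_over_unique_valid(self, db, split):
        pat = split.patented[0].smiles
        nov = split.novel[0].smiles
        log = _log([(pat, True, True), (pat, True, True), (nov, True, True)])
        m = analysis.compute_metrics(log, db=db)
        assert m.n_db_matches == 1
        assert m.n_db_matches <= m.n_valid_unique

    def test_record_order_invariance(self, db, split):
        entries = [(e.smiles, True, True) for e in split.patented[:5]] + \
            [(e.smiles, True, True) for e in split.novel[:5]]
        m1 = analysis.compute_metrics(_log(entries), db=db)
        m2 = analysis.compute_metrics(_log(entries[::-1]), db=db)
        assert (m1.validity, m1.uniqueness, m1.n_db_matches) == \
            (m2.validity, m2.uniqueness, m2.n_db_matches)

    def test_aggregate_replicates(self):
        runs = [
            analysis.GenerationMetrics(0.4, 0.8, 10, 4, 3, 2),
            analysis.GenerationMetrics(0.6, 0.9, 10, 6, 5, 4),
        ]
        agg = analysis.aggregate_metrics(runs)
        assert agg.validity_mean == pytest.approx(0.5)
        assert agg.db_matches_mean == pytest.approx(3.0)
        assert agg.db_matches_std == pytest.approx(1.0)


class TestSimilarityDistribution:
    def test_self_references_all_one(self, patented_std):
        mols = patented_std[:20]
        dist = analysis.max_similarity_distribution(mols, mols)
        assert dist.fraction_eq_1 == 1.0
        assert dist.counts.sum() == 20
        assert dist.counts[-1] == 20  # closed top bin holds the 1.0 values

    def test_manual_tanimoto_oracle(self):
        # hand-checkable pair: ethane vs ethanol fingerprints
        q = chemstd.standardize_smiles("CCO")
        r = chemstd.standardize_smiles("CC")
        fp_q = chemstd.fingerprint(q.to_mol(), "morgan_r2")
        fp_r = chemstd.fingerprint(r.to_mol(), "morgan_r2")
        expected = chemstd.tanimoto(fp_q, fp_r)
        dist = analysis.max_similarity_distribution([q], [r])
        assert dist.max_similarities[0] == pytest.approx(expected)

    def test_binning_oracle(self):
        assert analysis.bin_similarity(1.0) == 19    # top bin closed
        assert analysis.bin_similarity(0.45) == 9    # [0.45, 0.50)
        assert analysis.bin_similarity(0.4499) == 8
        assert analysis.bin_similarity(0.0) == 0

    def test_empty_refs_rejected(self, patented_std):
        with pytest.raises(EmptyReferenceSet):
            analysis.max_similarity_distribution(patented_std[:2], [])


class TestQedDistribution:
    def test_range_and_duplication(self, patented_std):
        mols = patented_std[:15]
        d1 = analysis.qed_distribution(mols)
        assert ((d1["values"] >= 0) & (d1["values"] <= 1)).all()
        d2 = analysis.qed_distribution(list(mols) + list(mols))
        assert (d2["counts"] == 2 * d1["counts"]).all()

    def test_druglike_beats_flagged_panel(self, patented_std):
        bad = [chemstd.standardize_smiles(s) for s in
               ("ClCCl", "O=C(Cl)C(=O)Cl", "OCC(O)C(O)C(O)C(O)CO",
                "C1CCCCCC1", "[CH2]CC")]
        good = patented_std[:30]
        assert analysis.qed_distribution(good)["median"] > \
            analysis.qed_distribution(bad)["median"]


class TestEmbedding:
    def test_shapes_and_determinism(self, patented_std):
        mols, refs = patented_std[:15], patented_std[15:40]
        e1 = analysis.embed_chemical_space(mols, refs, seed=3)
        e2 = analysis.embed_chemical_space(mols, refs, seed=3)
        assert e1.coordinates.shape == (40, 2)
        assert e1.n_inputs == 15
        assert np.allclose(e1.coordinates, e2.coordinates)

    def test_structural_families_separate(self):
        fam_a = [chemstd.standardize_smiles("c1ccccc1" + "C" * i) for i in range(1, 16)]
        fam_b = [chemstd.standardize_smiles("C1CCNCC1" + "N" * 0 + "C" * i) for i in range(1, 16)]
        emb = analysis.embed_chemical_space(fam_a, fam_b, seed=0)
        xy = emb.coordinates
        a, b = xy[:15], xy[15:]
        intra = np.linalg.norm(a - a.mean(0), axis=1).mean() + \
            np.linalg.norm(b - b.mean(0), axis=1).mean()
        inter = np.linalg.norm(a.mean(0) - b.mean(0))
        assert inter > intra / 2

    def test_too_few_molecules(self, patented_std):
        with pytest.raises(TooFewMolecules):
            analysis.embed_chemical_space(patented_std[:3], [], seed=0)


class TestFindAnalogs:
    def test_drug_itself_similarity_one(self, split):
        drug = split.patented[0].smiles
        log = _log([(drug, True, True), (split.novel[0].smiles, True, True)])
        hits = analysis.find_analogs(log, drug, threshold=0.5)
        assert hits and hits[0].similarity == 1.0

    def test_impossible_threshold_empty(self, split):
        log = _log([(split.patented[0].smiles, True, True)])
        assert analysis.find_analogs(log, split.patented[0].smiles, 1.01) == []

    def test_agrees_with_similarity_machinery(self, split, db):
        drug = split.patented[0].smiles
        entries = [(e.smiles, True, True) for e in split.patented[:30]]
        log = _log(entries)
        hits = analysis.find_analogs(log, drug, threshold=0.3, db=db)
        ref = chemstd.standardize_smiles(drug)
        for h in hits:
            dist = analysis.max_similarity_distribution(
                [chemstd.standardize_smiles(h.smiles)], [ref]
            )
            assert h.similarity == pytest.approx(dist.max_similarities[0])
            assert h.db_match is True  # all drawn from the patented set

    def test_invalid_query(self):
        with pytest.raises(InvalidQuery):
            analysis.find_analogs(GenerationLog(GenerationConfig()), "xxxx")
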