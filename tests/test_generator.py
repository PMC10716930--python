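"""Rewards, generation filters, UCT selection and the tree search."""

import itertools

import numpy as np
import pytest
from rdkit import Chem

from patgen import chemstd, fixtures, generator, langmodel
from patgen.errors import DbNotBuilt, NoExpandableChild
from patgen.generator import (
    Budget,
    FilterSwitches,
    GenerationConfig,
    RewardFunction,
    SearchNode,
    apply_filters,
    overall_pass,
    uct_select,
)


class TestRewards:
    def test_patent_reward_on_partition(self, db, patented_std, novel_std):
        rp = generator.r_patent(db)
        assert all(rp.evaluate(m) == 1.0 for m in patented_std[:100])
        assert all(rp.evaluate(m) == 0.0 for m in novel_std[:100])

    def test_complementarity(self, db, patented_std, novel_std):
        rp, rn = generator.r_patent(db), generator.r_not_patent(db)
        for m in patented_std[:100] + novel_std[:100]:
            assert rp.evaluate(m) + rn.evaluate(m) == 1.0

    def test_unbuilt_db_rejected(self):
        with pytest.raises(DbNotBuilt):
            generator.r_patent(None)

    def test_r_rand_seeded_stream(self, patented_std):
        r1, r2 = generator.r_rand(9), generator.r_rand(9)
        v1 = [r1.evaluate(patented_std[0]) for _ in range(20)]
        v2 = [r2.evaluate(patented_std[0]) for _ in range(20)]
        assert v1 == v2
        assert all(0.0 <= v < 1.0 for v in v1)

    def test_r_rand_mean_near_half(self, patented_std):
        rr = generator.r_rand(123)
        draws = [rr.evaluate(patented_std[0]) for _ in range(10_000)]
        assert abs(np.mean(draws) - 0.5) < 0.01


PANEL = {
    # molecule -> the single filter it must trip
    "CC(=O)Nc1ccc(C(=O)NCCOCCOCCOCCNC(=O)c2ccc(NC(C)=O)cc2)cc1": "lipinski",
    "C1CCCCCC1": "ring",
    "[CH2]c1ccc(NC(C)=O)cc1": "radical",
    "C1(C2C3C14)C5C4C3C25": "sa",
    "O=C(Cl)c1ccccc1": "rare_pattern",
}


class TestFilters:
    def test_cyclohexane_passes(self):
        mol = Chem.MolFromSmiles("C1CCCCC1")
        v = apply_filters(mol, chemstd.compute_descriptors(mol))
        assert v["lipinski"] and v["radical"] and v["ring"]

    @pytest.mark.parametrize("smiles,expected_trip", PANEL.items())
    def test_panel_trips_exactly_one_filter(self, smiles, expected_trip):
        mol = Chem.MolFromSmiles(smiles)
        verdicts = apply_filters(mol, chemstd.compute_descriptors(mol))
        tripped = {name for name, ok in verdicts.items() if not ok}
        assert tripped == {expected_trip}

    def test_seven_ring_threshold_exact(self):
        mol6 = Chem.MolFromSmiles("C1CCCCC1")
        mol7 = Chem.MolFromSmiles("C1CCCCCC1")
        assert apply_filters(mol6, chemstd.compute_descriptors(mol6))["ring"]
        assert not apply_filters(mol7, chemstd.compute_descriptors(mol7))["ring"]

    def test_switches_disable_filters(self):
        mol = Chem.MolFromSmiles("C1CCCCCC1")
        sw = FilterSwitches(ring=False)
        verdicts = apply_filters(mol, chemstd.compute_descriptors(mol), sw)
        assert not verdicts["ring"]          # verdict still reported
        assert overall_pass(verdicts, sw)    # but not counted


class TestUctSelect:
    def _node(self, children_stats):
        node = SearchNode((), None, None, [])
        for tok, (n, w) in children_stats.items():
            child = SearchNode((tok,), None, None, [])
            child.N, child.W = n, w
            node.children[tok] = child
        node.N = sum(n for n, _ in children_stats.values())
        return node

    def test_exploitation_only(self):
        node = self._node({0: (9, 4.5), 1: (1, 0.0)})
        assert uct_select(node, 0.0) == 0

    def test_exploration_dominates(self):
        node = self._node({0: (9, 4.5), 1: (1, 0.0)})
        assert uct_select(node, 10.0) == 1

    def test_unexpanded_prioritized(self):
        node = self._node({0: (3, 1.0)})
        node.untried = [7, 2]
        assert uct_select(node, 1.0) == 7

    def test_no_expandable_child(self):
        with pytest.raises(NoExpandableChild):
            uct_select(SearchNode((), None, None, []), 1.0)

    def test_matches_bruteforce_oracle_on_random_trees(self, rng):
        """Selection equals explicit argmax of the UCT formula, 1000 trees."""
        import math

        for _ in range(1000):
            k = rng.integers(2, 8)
            stats = {}
            for tok in range(k):
                n = int(rng.integers(1, 50))
                w = float(rng.random() * n)
                stats[tok] = (n, w)
            node = self._node(stats)
            c = float(rng.random() * 2)
            scores = {
                tok: w / n + c * math.sqrt(2 * math.log(node.N) / n)
                for tok, (n, w) in stats.items()
            }
            best = max(scores, key=lambda t: (scores[t], -t))
            # tie-break: lowest token index
            top = max(scores.values())
            best = min(t for t, s in scores.items() if abs(s - top) < 1e-12)
            assert uct_select(node, c) == best


class _ToyLM:
    """Uniform toy language over {C, O} with max length 3 (enumerable)."""

    def __init__(self):
        self.vocab = langmodel.TokenVocabulary(
            tokens=(langmodel.PAD, langmodel.START, langmodel.END, "C", "O"),
            max_len=3,
        )
        probs = np.zeros(5)
        probs[[2, 3, 4]] = 1 / 3
        self._probs = probs

    def init_state(self):
        return [np.zeros((1, 1))]

    def step(self, state, token_id):
        return self._probs.copy(), state

    def sample_completion(self, prefix=(), rng=None, temperature=1.0,
                          greedy=False, state=None, probs=None):
        out = list(prefix)
        while len(out) < self.vocab.max_len:
            tok = int(rng.choice(5, p=self._probs))
            if tok == 2:
                break
            out.append(tok)
        return "".join(self.vocab.tokens[t] for t in out)


class TestMctsToyLanguage:
    def test_budget_zero_empty_log(self, trained_lm):
        log = generator.mcts_generate(trained_lm, generator.r_rand(0),
                                      GenerationConfig(budget=Budget()))
        assert log.records == [] and log.totals["n_all"] == 0

    def test_finds_unique_reward_one_string(self):
        """Search finds the enumerable target within 200 iterations."""
        toy = _ToyLM()
        # exhaustive enumeration oracle over the whole language
        def canon(s):
            m = Chem.MolFromSmiles(s)
            return Chem.MolToSmiles(m) if m else None

        language = [
            "".join(p)
            for ln in range(1, 4)
            for p in itertools.product("CO", repeat=ln)
        ]
        winners = {s for s in language if canon(s) == "CCO"}
        assert winners == {"CCO", "OCC"}  # ethanol up to canonicalization

        reward = RewardFunction(
            "target", lambda m: 1.0 if m.canonical_smiles == "CCO" else 0.0
        )
        config = GenerationConfig(
            c_explore=0.5, seed=5,
            filter_switches=FilterSwitches(False, False, False, False, False),
            budget=Budget(max_iterations=200),
        )
        log, tree = generator.mcts_generate(toy, reward, config, return_tree=True)
        hits = [r for r in log.records if r.reward == 1.0]
        assert hits, "target not found within 200 iterations"
        assert {r.canonical_smiles for r in hits} == {"CCO"}
        assert generator.check_tree(tree)

    def test_tree_consistency_and_reward_gating(self, trained_lm, db):
        config = GenerationConfig(
            c_explore=0.4, seed=1, budget=Budget(max_iterations=300),
        )
        log, tree = generator.mcts_generate(
            trained_lm, generator.r_patent(db), config, return_tree=True
        )
        assert generator.check_tree(tree)
        for r in log.records:
            if r.reward is not None:  # reward present <=> valid and unfiltered
                assert r.parse_valid
                assert all(r.filter_verdicts.values()) or overall_pass(
                    r.filter_verdicts, config.filter_switches
                )
            else:
                assert (not r.parse_valid) or not overall_pass(
                    r.filter_verdicts, config.filter_switches
                )

    def test_skip_backprop_mode(self):
        toy = _ToyLM()
        reward = RewardFunction("zero", lambda m: 0.0)
        config = GenerationConfig(
            seed=2, filtered_reward_mode="skip",
            filter_switches=FilterSwitches(False, False, False, False, False),
            budget=Budget(max_iterations=50),
        )
        log, tree = generator.mcts_generate(toy, reward, config, return_tree=True)
        assert generator.check_tree(tree)
        # only valid proposals were backpropagated
        assert tree.N == sum(1 for r in log.records if r.reward is not None)

    def test_log_round_trip(self, trained_lm, tmp_path):
        config = GenerationConfig(seed=4, budget=Budget(max_iterations=50))
        log = generator.mcts_generate(trained_lm, generator.r_rand(0), config)
        path = tmp_path / "log.jsonl"
        log.write_jsonl(path, summary_path=tmp_path / "summary.json")
        loaded = generator.GenerationLog.read_jsonl(path)
        assert loaded.totals == log.totals
        assert [r.smiles for r in loaded.records] == [r.smiles for r in log.records]
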