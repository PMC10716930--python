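"""Monte-Carlo tree search over SMILES token space with plug-in rewards.

The search tree's nodes are token prefixes; the trained language model
supplies both the admissible child tokens at each node (tokens whose prior
probability exceeds a pruning threshold) and the rollout policy that
completes a prefix into a full SMILES string. Every completed string is
parsed, standardized and screened by the five generation filters; the reward
— patent membership, its complement, or a seeded uniform baseline — is
computed only for strings that survive, and is backpropagated along the
selection path (filtered and unparseable strings backpropagate zero by
default).

Selection uses the UCT rule W/N + C * sqrt(2 ln N_parent / N_child) with
unexpanded children prioritized; the exploration constant C is the knob that
trades deep exploitation of rewarding subtrees (small C) against broad
exploration of new chemistry (large C).
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field, asdict
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem

from . import chemstd
from .chemstd import DescriptorSet, StandardMolecule
from .errors import DbNotBuilt, NoExpandableChild
from .langmodel import TrainedLM
from .patentdb import DrugPatentDB

#: C values studied for the exploration-strength sweep
C_EXPLORE_GRID = (0.1, 0.2, 0.4, 0.6, 0.8, 1.0)

FILTER_NAMES = ("rare_pattern", "lipinski", "radical", "sa", "ring")

#: default "rarely occurring pattern" list: reactive or odd motifs that are
#: uncommon in large small-molecule collections. Configurable; a frequency
#: table derived from such a collection can replace it wholesale.
DEFAULT_RARE_PATTERNS: Tuple[str, ...] = (
    "[CX3](=O)[F,Cl,Br,I]",
    "[NX2]=C=O",
    "[OX2][OX2]",
    "[NX3][NX2]=O",
    "N=[N+]=[N-]",
    "C=C=C",
    "[SX2][SX2]",
    "[N;R0]=[N;R0]",
)

SA_THRESHOLD = 3.5
MAX_RING = 6


@dataclass(frozen=True)
class RewardFunction:
    name: str
    evaluate: Callable[[StandardMolecule], float]


def r_patent(db: DrugPatentDB) -> RewardFunction:
    """1 if the molecule's stereo-free key is in the drug-patent DB, else 0."""
    if not isinstance(db, DrugPatentDB):
        raise DbNotBuilt("r_patent needs a built database")
    return RewardFunction(
        "patent", lambda m: 1.0 if db.contains(m.inchikey_nostereo) else 0.0
    )


def r_not_patent(db: DrugPatentDB) -> RewardFunction:
    """Complement of r_patent: 1 iff the molecule is absent from the DB."""
    if not isinstance(db, DrugPatentDB):
        raise DbNotBuilt("r_not_patent needs a built database")
    return RewardFunction(
        "not-patent", lambda m: 0.0 if db.contains(m.inchikey_nostereo) else 1.0
    )


def r_rand(seed: int) -> RewardFunction:
    """Baseline reward: uniform [0,1) draws from a seeded stream."""
    rng = np.random.default_rng(seed)
    return RewardFunction("random", lambda m: float(rng.random()))


@dataclass(frozen=True)
class FilterSwitches:
    rare_pattern: bool = True
    lipinski: bool = True
    radical: bool = True
    sa: bool = True
    ring: bool = True
    rare_patterns: Tuple[str, ...] = DEFAULT_RARE_PATTERNS

    def enabled(self) -> Tuple[str, ...]:
        return tuple(n for n in FILTER_NAMES if getattr(self, n))


_pattern_cache: Dict[Tuple[str, ...], list] = {}


def _compiled_patterns(patterns: Tuple[str, ...]):
    if patterns not in _pattern_cache:
        _pattern_cache[patterns] = [Chem.MolFromSmarts(p) for p in patterns]
    return _pattern_cache[patterns]


def apply_filters(
    mol: Chem.Mol,
    descriptors: DescriptorSet,
    switches: Optional[FilterSwitches] = None,
) -> Dict[str, bool]:
    """Per-filter pass verdicts (True = passes) for a parse-valid molecule."""
    sw = switches or FilterSwitches()
    d = descriptors
    verdicts = {
        "rare_pattern": not any(
            mol.HasSubstructMatch(p) for p in _compiled_patterns(sw.rare_patterns)
        ),
        "lipinski": not (d.mol_weight > 500 or d.slogp > 5 or d.hbd > 5 or d.hba > 10),
        "radical": d.n_radical_electrons == 0,
        "sa": d.sa_score < SA_THRESHOLD,
        "ring": d.max_ring_size <= MAX_RING,
    }
    return verdicts


def overall_pass(verdicts: Dict[str, bool], switches: Optional[FilterSwitches] = None) -> bool:
    sw = switches or FilterSwitches()
    return all(verdicts[n] for n in sw.enabled())


@dataclass
class Budget:
    max_seconds: Optional[float] = None
    target_valid_unique: Optional[int] = None
    max_iterations: Optional[int] = None

    def positive(self) -> bool:
        return any(
            v is not None and v > 0
            for v in (self.max_seconds, self.target_valid_unique, self.max_iterations)
        )


@dataclass
class GenerationConfig:
    c_explore: float = 1.0
    filter_switches: FilterSwitches = field(default_factory=FilterSwitches)
    budget: Budget = field(default_factory=Budget)
    seed: int = 0
    replicate_id: int = 0
    # prior-probability pruning: tokens below this model probability are not
    # added as children. Tight enough that the tree stays inside the language
    # model's plausible continuations; loosening it makes the bonus-driven
    # breadth of UCT spill into garbage prefixes whenever rewards are sparse.
    expansion_threshold: float = 0.02
    filtered_reward_mode: str = "zero"  # or "skip": no backprop for filtered
    temperature: float = 1.0


class SearchNode:
    __slots__ = ("token_prefix", "N", "W", "children", "untried", "state",
                 "probs", "terminal", "exhausted")

    def __init__(self, token_prefix: Tuple[int, ...], state, probs, untried,
                 terminal: bool = False):
        self.token_prefix = token_prefix
        self.N = 0
        self.W = 0.0
        self.children: Dict[int, "SearchNode"] = {}
        self.untried: List[int] = untried
        self.state = state
        self.probs = probs
        self.terminal = terminal
        # a terminal that has been evaluated, or an inner node whose whole
        # subtree is evaluated, is exhausted: selection never re-enters it,
        # so the search keeps producing new molecules instead of duplicates
        self.exhausted = False


def uct_select(node: SearchNode, c_explore: float) -> int:
    """Child token by UCT; unexpanded tokens first, ties to the lowest token id.

    Exhausted children (fully sampled subtrees) are skipped.
    """
    if node.untried:
        return node.untried[0]
    live = [t for t in sorted(node.children) if not node.children[t].exhausted]
    if not live:
        raise NoExpandableChild(f"prefix {node.token_prefix}")
    ln_n = math.log(max(node.N, 1))
    best_tok, best_score = None, -math.inf
    for tok in live:
        child = node.children[tok]
        if child.N == 0:
            return tok
        score = child.W / child.N + c_explore * math.sqrt(2.0 * ln_n / child.N)
        if score > best_score + 1e-12:
            best_tok, best_score = tok, score
    return best_tok


@dataclass
class GeneratedMolecule:
    smiles: str
    parse_valid: bool
    filter_verdicts: Optional[Dict[str, bool]]
    reward: Optional[float]
    first_seen_iteration: int
    canonical_smiles: Optional[str] = None

    @property
    def is_valid(self) -> bool:
        """Parseable *and* filter-passing (the combined validity notion)."""
        return self.reward is not None


@dataclass
class GenerationLog:
    config: GenerationConfig
    records: List[GeneratedMolecule] = field(default_factory=list)

    @property
    def totals(self) -> Dict[str, int]:
        n_all = len(self.records)
        valid = [r for r in self.records if r.is_valid]
        uniq = {r.canonical_smiles for r in valid}
        return {"n_all": n_all, "n_valid": len(valid), "n_valid_unique": len(uniq)}

    def valid_unique_smiles(self) -> List[str]:
        """Canonical SMILES of valid molecules, first-seen order, deduplicated."""
        seen, out = set(), []
        for r in self.records:
            if r.is_valid and r.canonical_smiles not in seen:
                seen.add(r.canonical_smiles)
                out.append(r.canonical_smiles)
        return out

    def write_jsonl(self, path, summary_path=None) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(json.dumps(asdict(r)) + "\n")
        if summary_path is not None:
            summary = {
                "totals": self.totals,
                "c_explore": self.config.c_explore,
                "seed": self.config.seed,
                "replicate_id": self.config.replicate_id,
            }
            with open(summary_path, "w") as fh:
                json.dump(summary, fh, indent=2)

    @classmethod
    def read_jsonl(cls, path, config: Optional[GenerationConfig] = None) -> "GenerationLog":
        records = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    records.append(GeneratedMolecule(**json.loads(line)))
        return cls(config or GenerationConfig(), records)


class _Processed:
    __slots__ = ("parse_valid", "std", "verdicts", "passed")

    def __init__(self, parse_valid, std, verdicts, passed):
        self.parse_valid = parse_valid
        self.std = std
        self.verdicts = verdicts
        self.passed = passed


def _process(smiles: str, switches: FilterSwitches,
             cache: Dict[str, _Processed]) -> _Processed:
    hit = cache.get(smiles)
    if hit is not None:
        return hit
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        out = _Processed(False, None, None, False)
    else:
        try:
            std = chemstd.standardize(mol)
            descriptors = chemstd.compute_descriptors(std.to_mol())
            verdicts = apply_filters(std.to_mol(), descriptors, switches)
            out = _Processed(True, std, verdicts, overall_pass(verdicts, switches))
        except Exception:
            out = _Processed(False, None, None, False)
    cache[smiles] = out
    return out


def check_tree(node: SearchNode) -> bool:
    """Invariant: N >= sum(child N) and W <= N at every node."""
    if node.W > node.N + 1e-9:
        return False
    if node.N < sum(c.N for c in node.children.values()):
        return False
    return all(check_tree(c) for c in node.children.values())


def mcts_generate(
    lm: TrainedLM,
    reward: RewardFunction,
    config: GenerationConfig,
    return_tree: bool = False,
):
    """Run the tree search until the budget is exhausted.

    Every proposed SMILES string — valid or not, filtered or not — is
    appended to the log in proposal order; rewards are attached only to
    parse-valid, filter-passing molecules. Budget modes: wall-clock seconds,
    a target count of valid-and-unique molecules, or an iteration cap.
    """
    log = GenerationLog(config)
    if not config.budget.positive():
        return (log, None) if return_tree else log

    rng = np.random.default_rng(config.seed + 1_000_003 * config.replicate_id)
    end_id = lm.vocab.token_to_id[lm.vocab.end_symbol]
    pad_id = lm.vocab.token_to_id[lm.vocab.pad_symbol]
    start_id = lm.vocab.token_to_id[lm.vocab.start_symbol]

    def admissible(probs) -> List[int]:
        order = np.argsort(-probs, kind="stable")
        out = []
        for tok in order:
            if probs[tok] < config.expansion_threshold:
                break
            if tok in (pad_id, start_id):
                continue
            out.append(int(tok))
        return out

    probs0, state0 = lm.step(lm.init_state(), start_id)
    root = SearchNode((), state0, probs0, admissible(probs0))

    cache: Dict[str, _Processed] = {}
    valid_unique: set = set()
    t0 = time.perf_counter()
    iteration = 0
    budget = config.budget
    while True:
        if budget.max_iterations is not None and iteration >= budget.max_iterations:
            break
        if budget.max_seconds is not None and time.perf_counter() - t0 >= budget.max_seconds:
            break
        if (budget.target_valid_unique is not None
                and len(valid_unique) >= budget.target_valid_unique):
            break
        if root.exhausted:
            break  # the admissible token space is fully enumerated
        iteration += 1

        # selection (skipping exhausted subtrees)
        node, path = root, [root]
        dead_end = False
        while not node.terminal and not node.untried and node.children:
            try:
                tok = uct_select(node, config.c_explore)
            except NoExpandableChild:
                node.exhausted = True  # every child subtree fully sampled
                dead_end = True
                break
            node = node.children[tok]
            path.append(node)
        if dead_end:
            continue

        # expansion
        if not node.terminal and node.untried:
            tok = node.untried.pop(0)
            prefix = node.token_prefix + (tok,)
            if tok == end_id:
                child = SearchNode(prefix, node.state, None, [], terminal=True)
            else:
                probs, state = lm.step(node.state, tok)
                untried = [] if len(prefix) >= lm.vocab.max_len else admissible(probs)
                child = SearchNode(prefix, state, probs, untried,
                                   terminal=not untried)
            node.children[tok] = child
            node = child
            path.append(node)

        # rollout
        if node.terminal or node.probs is None:
            body = node.token_prefix[:-1] if node.token_prefix and \
                node.token_prefix[-1] == end_id else node.token_prefix
            smiles = "".join(lm.vocab.tokens[t] for t in body)
        else:
            smiles = lm.sample_completion(
                prefix=list(node.token_prefix), rng=rng,
                temperature=config.temperature, state=node.state,
                probs=node.probs,
            )

        # evaluation
        proc = _process(smiles, config.filter_switches, cache)
        value: Optional[float] = None
        if proc.passed:
            value = float(reward.evaluate(proc.std))
            valid_unique.add(proc.std.canonical_smiles)
        log.records.append(
            GeneratedMolecule(
                smiles=smiles,
                parse_valid=proc.parse_valid,
                filter_verdicts=proc.verdicts,
                reward=value,
                first_seen_iteration=iteration,
                canonical_smiles=proc.std.canonical_smiles if proc.std else None,
            )
        )

        # a terminal has exactly one molecule: evaluated once, then closed
        if node.terminal:
            node.exhausted = True

        # backpropagation
        if value is None and config.filtered_reward_mode == "skip":
            continue
        backprop_value = value if value is not None else 0.0
        for n in path:
            n.N += 1
            n.W += backprop_value

    return (log, root) if return_tree else log
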