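"""Structure standardization, identity keys, descriptors and fingerprints.

Every other module funnels structures through here so that one notion of
identity — the stereo-free 27-character InChIKey of the desalted, neutralized
parent structure — is used everywhere: when building the drug-patent database,
when matching generated molecules against it, and when computing rewards.

Standardization follows the ChEMBL-style ruleset (normalize functional groups,
keep the largest organic fragment, neutralize charges) as implemented by
RDKit's ``rdMolStandardize``. Stereochemistry is deliberately erased before
key generation so that stereoisomers collide: patent claims rarely distinguish
them reliably, and the membership oracle must not either.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski, QED, rdMolDescriptors
from rdkit.Chem import rdMHFPFingerprint
from rdkit.Chem.MolStandardize import rdMolStandardize
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import (
    DescriptorFailure,
    InvalidSmiles,
    KeyGenerationFailure,
    KindMismatch,
    StandardizationFailure,
    UnsupportedKind,
)
from . import sa_score

# RDKit is chatty about every unparseable rollout string; silence the app log.
RDLogger.DisableLog("rdApp.*")

FINGERPRINT_KINDS = ("morgan_r2", "morgan_r3", "mhfp6")
N_BITS = 2048
_MHFP_SEED = 42  # fixed permutation seed: minhash vectors must be reproducible


@dataclass(frozen=True)
class MoleculeRecord:
    """One raw compound row as ingested from a patent-compound table."""

    source_id: str
    smiles: str
    ocr_flag: bool = False


@dataclass(frozen=True)
class StandardMolecule:
    """Canonical standardized structure plus its stereo-free InChIKey."""

    canonical_smiles: str
    inchikey_nostereo: str
    parent_of: Optional[str] = None
    # cached RDKit mol; excluded from equality/hash so identity is structural
    _mol: Optional[Chem.Mol] = field(default=None, compare=False, repr=False)

    def to_mol(self) -> Chem.Mol:
        mol = self._mol if self._mol is not None else Chem.MolFromSmiles(self.canonical_smiles)
        if mol is None:  # pragma: no cover - canonical SMILES always parse
            raise InvalidSmiles(self.canonical_smiles)
        return mol


@dataclass(frozen=True)
class DescriptorSet:
    mol_weight: float
    slogp: float
    n_atoms: int
    n_heavy_atoms: int
    n_aromatic_rings: int
    fraction_csp3: float
    hbd: int
    hba: int
    qed: float
    sa_score: float
    max_ring_size: int
    n_radical_electrons: int
    murcko_scaffold: str


@dataclass(frozen=True)
class Fingerprint:
    """Either a Morgan bit set or an MHFP6 minhash vector, 2048 wide."""

    kind: str
    n_bits_or_perms: int
    payload: tuple  # sorted on-bit indices (morgan) or 2048 minhash ints (mhfp6)


def parse_smiles(s: str) -> Chem.Mol:
    """Parse a SMILES string, raising :class:`InvalidSmiles` on failure."""
    if not s:
        raise InvalidSmiles("empty SMILES string")
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise InvalidSmiles(s)
    return mol


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())


_uncharger = rdMolStandardize.Uncharger()


def standardize(mol: Chem.Mol, source_id: Optional[str] = None) -> StandardMolecule:
    """Normalize, desalt to the largest organic fragment and neutralize.

    All-inorganic records (no carbon in any fragment) are rejected: they can
    serve neither as training data nor as reward-lookup subjects.
    """
    if not _has_carbon(mol):
        raise StandardizationFailure(
            f"no organic component in {Chem.MolToSmiles(mol)!r}"
        )
    try:
        clean = rdMolStandardize.Cleanup(mol)
        parent = rdMolStandardize.FragmentParent(clean)
        parent = _uncharger.uncharge(parent)
    except Exception as exc:  # RDKit raises plain Exceptions from C++
        raise StandardizationFailure(str(exc)) from exc
    if parent is None or parent.GetNumAtoms() == 0 or not _has_carbon(parent):
        raise StandardizationFailure("no organic parent fragment remained")
    canonical = Chem.MolToSmiles(parent)
    key = inchikey_nostereo(parent)
    return StandardMolecule(canonical, key, parent_of=source_id, _mol=parent)


def inchikey_nostereo(mol: Chem.Mol) -> str:
    """27-character InChIKey of the structure with all stereo descriptors removed.

    The full key (not just the connectivity block) is kept comparable: with
    stereo erased before key generation, the second block is identical for
    every stereoisomer, so full-string equality is the membership test.
    """
    flat = Chem.Mol(mol)
    Chem.RemoveStereochemistry(flat)
    try:
        key = Chem.MolToInchiKey(flat)
    except Exception as exc:
        raise KeyGenerationFailure(str(exc)) from exc
    if not key or len(key) != 27:
        raise KeyGenerationFailure(f"malformed key {key!r}")
    return key


def murcko_scaffold_smiles(mol: Chem.Mol) -> str:
    """Bemis–Murcko framework (ring systems + linkers); '' for acyclic input."""
    if mol.GetRingInfo().NumRings() == 0:
        return ""
    return Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(mol))


def compute_descriptors(mol: Chem.Mol) -> DescriptorSet:
    """All descriptors used by corpus curation, the generation filters and QED."""
    name = "?"
    try:
        name = "mol_weight"
        mw = Descriptors.MolWt(mol)
        name = "slogp"
        slogp = Crippen.MolLogP(mol)
        name = "n_atoms"
        n_heavy = mol.GetNumAtoms()
        n_atoms = n_heavy + sum(a.GetTotalNumHs() for a in mol.GetAtoms())
        name = "n_aromatic_rings"
        n_arom = rdMolDescriptors.CalcNumAromaticRings(mol)
        name = "fraction_csp3"
        fcsp3 = rdMolDescriptors.CalcFractionCSP3(mol)
        name = "hbd/hba"
        hbd = Lipinski.NumHDonors(mol)
        hba = Lipinski.NumHAcceptors(mol)
        name = "qed"
        qed = QED.qed(mol)
        name = "sa_score"
        sa = sa_score.calculate_sa(mol)
        name = "max_ring_size"
        rings = mol.GetRingInfo().AtomRings()
        max_ring = max((len(r) for r in rings), default=0)
        name = "n_radical_electrons"
        n_rad = sum(a.GetNumRadicalElectrons() for a in mol.GetAtoms())
        name = "murcko_scaffold"
        scaffold = murcko_scaffold_smiles(mol)
    except DescriptorFailure:
        raise
    except Exception as exc:
        raise DescriptorFailure(f"descriptor {name} failed: {exc}") from exc
    return DescriptorSet(
        mol_weight=mw,
        slogp=slogp,
        n_atoms=n_atoms,
        n_heavy_atoms=n_heavy,
        n_aromatic_rings=n_arom,
        fraction_csp3=fcsp3,
        hbd=hbd,
        hba=hba,
        qed=qed,
        sa_score=sa,
        max_ring_size=max_ring,
        n_radical_electrons=n_rad,
        murcko_scaffold=scaffold,
    )


_mhfp_encoder = rdMHFPFingerprint.MHFPEncoder(N_BITS, _MHFP_SEED)


def morgan_bitvect(mol: Chem.Mol, radius: int):
    """Raw RDKit ExplicitBitVect (hot path for bulk Tanimoto)."""
    return AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=N_BITS)


def mhfp_vector(mol: Chem.Mol) -> tuple:
    """Raw 2048-permutation MHFP6 minhash vector (fixed permutation seed)."""
    return tuple(_mhfp_encoder.EncodeMol(mol))


def fingerprint(mol: Chem.Mol, kind: str) -> Fingerprint:
    if kind == "morgan_r2":
        bv = morgan_bitvect(mol, 2)
        return Fingerprint(kind, N_BITS, tuple(bv.GetOnBits()))
    if kind == "morgan_r3":
        bv = morgan_bitvect(mol, 3)
        return Fingerprint(kind, N_BITS, tuple(bv.GetOnBits()))
    if kind == "mhfp6":
        return Fingerprint(kind, N_BITS, mhfp_vector(mol))
    raise UnsupportedKind(kind)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard similarity of bit sets; minhash position-agreement for mhfp6."""
    if a.kind != b.kind:
        raise KindMismatch(f"{a.kind} vs {b.kind}")
    if a.kind == "mhfp6":
        agree = sum(x == y for x, y in zip(a.payload, b.payload))
        return agree / len(a.payload)
    sa_, sb = set(a.payload), set(b.payload)
    union = len(sa_ | sb)
    if union == 0:
        return 1.0  # two empty fingerprints: identical by convention
    return len(sa_ & sb) / union


def standardize_smiles(s: str, source_id: Optional[str] = None) -> StandardMolecule:
    """Convenience: parse + standardize in one call."""
    return standardize(parse_smiles(s), source_id=source_id)


def read_smiles_file(path) -> Iterable[tuple[str, str]]:
    """Yield (id, smiles) from a SMILES line file.

    Accepts either one SMILES per line or ``smiles<TAB>id``; line numbers are
    used as ids when absent.
    """
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) >= 2:
                yield parts[1], parts[0]
            else:
                yield f"line{i + 1}", parts[0]
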