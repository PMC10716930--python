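"""Training-corpus curation from patented-compound records.

The language model should learn ordinary, ring-containing, drug-like
chemistry, so raw patent-compound records pass through a staged pipeline:
seeded subsample, parseability, ring requirement, element/isotope/
substructure screens, desalting, property-tail trimming, final seeded
subsample, and standardization to canonical SMILES. Every stage's surviving
count is recorded so a curation run is auditable, and the whole pipeline is
a fixed point: re-curating its own output removes nothing.

The property-tail quantiles and the reactive-substructure blacklist are
config with shipped defaults (the tails at 0.5% per side; a small list of
groups nobody wants a generator to propose). Both are explicitly replaceable
— upstream collections differ in what they consider "atypical".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from . import chemstd
from .chemstd import MoleculeRecord
from .errors import ConfigError, EmptySource
from .patentdb import CompoundEntry

DEFAULT_ALLOWED_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"]
)

#: reactive / undesirable groups excluded from training data by default
DEFAULT_BLACKLIST: Tuple[str, ...] = (
    "[CX3](=O)[F,Cl,Br,I]",          # acyl halide
    "[NX2]=C=O",                     # isocyanate
    "[OX2][OX2]",                    # peroxide
    "[NX3][NX2]=O",                  # N-nitroso
    "N=[N+]=[N-]",                   # azide
    "[CX4;!$(C-c);!$(C-a)][Cl,Br,I]",  # non-benzylic alkyl halide
)

TRIM_DESCRIPTORS = (
    "n_atoms", "n_heavy_atoms", "mol_weight", "slogp",
    "n_aromatic_rings", "fraction_csp3",
)


@dataclass(frozen=True)
class CurationConfig:
    initial_sample_size: int = 5_000_000
    allowed_elements: frozenset = DEFAULT_ALLOWED_ELEMENTS
    substructure_blacklist: Tuple[str, ...] = DEFAULT_BLACKLIST
    forbid_isotopes: bool = True
    property_trim_quantiles: Tuple[float, float] = (0.005, 0.995)
    final_sample_size: int = 250_000
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.property_trim_quantiles
        if not (0 <= lo < hi <= 1):
            raise ConfigError(f"bad trim quantiles ({lo}, {hi})")
        if self.final_sample_size > self.initial_sample_size:
            raise ConfigError("final_sample_size exceeds initial_sample_size")
        for patt in self.substructure_blacklist:
            if Chem.MolFromSmarts(patt) is None:
                raise ConfigError(f"unparseable blacklist pattern {patt!r}")


@dataclass
class CurationReport:
    stage_counts: List[Tuple[str, int]]
    n_unique_scaffolds: int
    output_path: Optional[str] = None

    def as_dict(self) -> dict:
        return {
            "stage_counts": self.stage_counts,
            "n_unique_scaffolds": self.n_unique_scaffolds,
            "output_path": self.output_path,
        }


def murcko_scaffold(mol: Chem.Mol) -> str:
    """Bemis–Murcko framework SMILES; '' for acyclic molecules."""
    return chemstd.murcko_scaffold_smiles(mol)


def _trim_values(mol: Chem.Mol) -> Dict[str, float]:
    n_heavy = mol.GetNumAtoms()
    return {
        "n_atoms": n_heavy + sum(a.GetTotalNumHs() for a in mol.GetAtoms()),
        "n_heavy_atoms": n_heavy,
        "mol_weight": Descriptors.MolWt(mol),
        "slogp": Crippen.MolLogP(mol),
        "n_aromatic_rings": rdMolDescriptors.CalcNumAromaticRings(mol),
        "fraction_csp3": rdMolDescriptors.CalcFractionCSP3(mol),
    }


def _element_ok(mol: Chem.Mol, allowed: frozenset, forbid_isotopes: bool) -> bool:
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in allowed:
            return False
        if forbid_isotopes and atom.GetIsotope() != 0:
            return False
    return True


def _as_records(source) -> List[Tuple[str, str]]:
    out = []
    for i, item in enumerate(source):
        if isinstance(item, (MoleculeRecord,)):
            out.append((item.source_id, item.smiles))
        elif isinstance(item, CompoundEntry):
            out.append((item.external_id, item.smiles))
        elif isinstance(item, str):
            out.append((f"rec{i}", item))
        else:
            out.append((str(item[0]), str(item[1])))
    return out


def curate_training_set(
    source: Union[Sequence, Iterable],
    config: CurationConfig,
) -> Tuple[List[str], CurationReport]:
    """Run the staged curation pipeline; returns (canonical SMILES, report)."""
    config.validate()
    records = _as_records(list(source))
    if not records:
        raise EmptySource("no input records")
    rng = np.random.default_rng(config.seed)
    stages: List[Tuple[str, int]] = [("input", len(records))]

    # 1. seeded initial sample
    n0 = min(config.initial_sample_size, len(records))
    idx = rng.permutation(len(records))[:n0]
    sample = [records[i] for i in idx]
    stages.append(("initial_sample", len(sample)))

    # 2. parseable, non-empty SMILES
    mols = []
    for rid, smi in sample:
        if not smi:
            continue
        mol = Chem.MolFromSmiles(smi)
        if mol is not None:
            mols.append(mol)
    stages.append(("parseable", len(mols)))

    # 3. must contain a ring
    mols = [m for m in mols if m.GetRingInfo().NumRings() > 0]
    stages.append(("has_ring", len(mols)))

    # 4. allowed elements, no isotopes, no blacklisted substructure
    patterns = [Chem.MolFromSmarts(p) for p in config.substructure_blacklist]
    kept = []
    for m in mols:
        if not _element_ok(m, config.allowed_elements, config.forbid_isotopes):
            continue
        if any(m.HasSubstructMatch(p) for p in patterns):
            continue
        kept.append(m)
    mols = kept
    stages.append(("element_isotope_substructure", len(mols)))

    # 5. desalt to the largest organic fragment
    desalted = []
    for m in mols:
        try:
            parent = rdMolStandardize.FragmentParent(m)
        except Exception:
            continue
        if parent is not None and parent.GetNumAtoms() > 0:
            desalted.append(parent)
    mols = desalted
    stages.append(("desalted", len(mols)))

    # 6. trim property tails (quantiles on the post-desalt population)
    lo_q, hi_q = config.property_trim_quantiles
    values = {d: np.array([v[d] for v in map(_trim_values, mols)])
              for d in TRIM_DESCRIPTORS} if mols else {}
    if mols:
        table = np.vstack([values[d] for d in TRIM_DESCRIPTORS])  # (6, n)
        lo = np.quantile(table, lo_q, axis=1, keepdims=True)
        hi = np.quantile(table, hi_q, axis=1, keepdims=True)
        ok = ((table >= lo) & (table <= hi)).all(axis=0)
        mols = [m for m, keep in zip(mols, ok) if keep]
    stages.append(("property_trimmed", len(mols)))

    # 7. seeded final subsample
    n_final = min(config.final_sample_size, len(mols))
    idx = rng.permutation(len(mols))[:n_final]
    mols = [mols[i] for i in idx]
    stages.append(("final_sample", len(mols)))

    # 8. standardize and emit canonical SMILES
    out: List[str] = []
    for m in mols:
        try:
            std = chemstd.standardize(m)
        except Exception:
            continue
        out.append(std.canonical_smiles)
    stages.append(("standardized", len(out)))

    scaffolds = {
        chemstd.murcko_scaffold_smiles(Chem.MolFromSmiles(s)) for s in out
    }
    report = CurationReport(stage_counts=stages, n_unique_scaffolds=len(scaffolds))
    return out, report


def write_corpus(path, smiles: Sequence[str], report: Optional[CurationReport] = None):
    """Write the SMILES line file (and remember where, in the report)."""
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")
    if report is not None:
        report.output_path = str(path)


def read_corpus(path) -> List[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
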