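"""Deterministic synthetic patent universe for tests and desk-scale studies.

Real patent-compound collections are tens of millions of rows and cannot ship
with the package, so every downstream module is exercised against an
enumerated scaffold x substituent universe with an exactly known
patented/unpatented partition. Enumeration (rather than random SMILES
mutation) keeps ground-truth membership exact and identical on every
platform: the same spec and seed always yield byte-identical universes.

The chemistry is deliberately plain — substituted aromatic and saturated
rings with common medicinal-chemistry substituents — so that enumerated
molecules pass the generation filters (Lipinski, synthetic accessibility,
ring size) and the search has something to find.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from rdkit import Chem

from . import chemstd
from .chemstd import MoleculeRecord, StandardMolecule
from .errors import SampleTooLarge, SpaceTooSmall
from .patentdb import CompoundEntry, PatentRecord

# Scaffold templates: '{k}' slots accept '(substituent)' or ''. Substituent
# ring-closure digits 8/9 avoid collision with template ring digits.
DEFAULT_SCAFFOLDS: Tuple[str, ...] = (
    "c1cc{0}cc{1}c1{2}",
    "c1cc{0}nc{1}c1{2}",
    "c1cnc{0}nc1{1}",
    "c1csc{0}c1{1}",
    "C1CC{0}CC{1}C1{2}",
    "C1CC{0}N{1}CC1{2}",
    "c1ccc2[nH]c{0}c{1}c2c1{2}",
    "c1cc{0}c(-c2ccc{1}cc2)cc1{2}",
    "C1COC{0}C1{1}",
    "c1ccc2cc{0}c{1}cc2c1{2}",
    "c1cc{0}c(N{1})cc1{2}",
)
DEFAULT_SUBSTITUENTS: Tuple[str, ...] = (
    "",
    "C",
    "CC",
    "CCC",
    "O",
    "OC",
    "N",
    "NC",
    "F",
    "Cl",
    "C#N",
    "C(=O)O",
    "C(=O)NC",
    "NC(=O)C",
)
# extra groups used only when a larger space is requested (benchmark scale)
EXTRA_SUBSTITUENTS: Tuple[str, ...] = (
    "OCC",
    "N(C)C",
    "C(C)C",
    "CO",
    "CN",
    "S(=O)(=O)C",
    "C(F)(F)F",
    "Br",
    "C(=O)OC",
    "Cc8ccccc8",
    "OCCO",
    "C(C)=O",
)


@dataclass(frozen=True)
class FixtureSpec:
    scaffolds: Tuple[str, ...] = DEFAULT_SCAFFOLDS
    substituents: Tuple[str, ...] = DEFAULT_SUBSTITUENTS
    max_substitutions: int = 3
    frac_patented: float = 0.6
    n_target: int = 5000
    seed: int = 20240101
    frac_ocr: float = 0.1


def benchmark_spec(n_target: int = 100_000, seed: int = 20240101) -> FixtureSpec:
    """A spec whose enumerable space comfortably exceeds benchmark scale."""
    return FixtureSpec(
        substituents=DEFAULT_SUBSTITUENTS + EXTRA_SUBSTITUENTS,
        n_target=n_target,
        seed=seed,
    )


@dataclass(frozen=True)
class SplitUniverse:
    """Known-ground-truth partition plus its synthetic patent records."""

    patented: Tuple[CompoundEntry, ...]
    novel: Tuple[CompoundEntry, ...]
    patents: Tuple[PatentRecord, ...]


def _enumerate_raw(spec: FixtureSpec):
    for template in spec.scaffolds:
        n_slots = template.count("{")
        for combo in itertools.product(spec.substituents, repeat=n_slots):
            if sum(1 for s in combo if s) > spec.max_substitutions:
                continue
            yield template.format(*(f"({s})" if s else "" for s in combo))


def make_universe(spec: FixtureSpec) -> List[MoleculeRecord]:
    """Enumerate, canonicalize, dedupe by stereo-free key, truncate to n_target.

    The enumeration order is fixed; a seeded shuffle precedes truncation so
    the kept subset is not biased toward the first scaffold templates.
    """
    seen = set()
    smiles_list: List[str] = []
    for raw in _enumerate_raw(spec):
        mol = Chem.MolFromSmiles(raw)
        if mol is None:
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        smiles_list.append(canonical)

    # canonical-SMILES dedup first (cheap), then stereo-free-key dedup (exact)
    key_seen = set()
    keyed: List[str] = []
    for smi in smiles_list:
        key = chemstd.inchikey_nostereo(Chem.MolFromSmiles(smi))
        if key in key_seen:
            continue
        key_seen.add(key)
        keyed.append(smi)

    if len(keyed) < spec.n_target:
        raise SpaceTooSmall(
            f"enumeration yields {len(keyed)} distinct molecules < {spec.n_target}"
        )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(keyed))[: spec.n_target]
    records = []
    for i, idx in enumerate(order):
        ocr = bool(rng.random() < spec.frac_ocr)
        records.append(
            MoleculeRecord(source_id=f"FIX{i:06d}", smiles=keyed[idx], ocr_flag=ocr)
        )
    return records


def split_universe(
    universe: Sequence[MoleculeRecord], frac_patented: float, seed: int,
    compounds_per_patent: int = 25,
) -> SplitUniverse:
    """Partition into patented/novel sets wired to synthetic patent records.

    Patented compounds are grouped under A61K/A61P-classified patents; novel
    compounds are grouped under non-drug (C07D) patents so the database build
    filter has something to reject. The partition is key-disjoint because the
    universe is key-deduplicated.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(universe))
    n_pat = int(round(frac_patented * len(universe)))
    pat_idx, nov_idx = order[:n_pat], order[n_pat:]

    patents: List[PatentRecord] = []
    patented: List[CompoundEntry] = []
    for group_start in range(0, len(pat_idx), compounds_per_patent):
        group = pat_idx[group_start:group_start + compounds_per_patent]
        num = f"SYNPAT-A61-{group_start // compounds_per_patent:05d}"
        # alternate IPC-only / CPC-only so both classification routes are hit
        if (group_start // compounds_per_patent) % 2 == 0:
            patents.append(PatentRecord(num, ipc_codes=("A61K31/00",)))
        else:
            patents.append(PatentRecord(num, cpc_codes=("A61P35/00",), ipc_codes=("C07D213/00",)))
        for i in group:
            rec = universe[i]
            patented.append(
                CompoundEntry(rec.source_id, rec.smiles, rec.ocr_flag, (num,))
            )

    novel: List[CompoundEntry] = []
    for group_start in range(0, len(nov_idx), compounds_per_patent):
        group = nov_idx[group_start:group_start + compounds_per_patent]
        num = f"SYNPAT-C07-{group_start // compounds_per_patent:05d}"
        patents.append(PatentRecord(num, ipc_codes=("C07D498/04",)))
        for i in group:
            rec = universe[i]
            novel.append(
                CompoundEntry(rec.source_id, rec.smiles, rec.ocr_flag, (num,))
            )
    return SplitUniverse(tuple(patented), tuple(novel), tuple(patents))


def make_corpus(
    patented: Sequence[CompoundEntry], n: int, seed: int
) -> List[str]:
    """Seeded sample of n patented compounds as canonical SMILES strings."""
    if n > len(patented):
        raise SampleTooLarge(f"requested {n} from {len(patented)} compounds")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(patented))[:n]
    return [Chem.MolToSmiles(Chem.MolFromSmiles(patented[i].smiles)) for i in idx]


def write_smiles(path, smiles: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")


def standard_molecules(entries: Sequence[CompoundEntry]) -> List[StandardMolecule]:
    """Standardize a batch of entries (fixture molecules never fail)."""
    return [chemstd.standardize_smiles(e.smiles, source_id=e.external_id) for e in entries]


def as_standard(records: Sequence) -> List[StandardMolecule]:
    """Fast StandardMolecule view of enumerated records.

    Universe molecules are single-component, neutral and canonical by
    construction, so the full normalization pass is unnecessary: parse and
    key generation suffice. Accepts MoleculeRecord or CompoundEntry.
    """
    out = []
    for r in records:
        rid = getattr(r, "source_id", None) or getattr(r, "external_id", None)
        mol = Chem.MolFromSmiles(r.smiles)
        out.append(
            StandardMolecule(
                canonical_smiles=r.smiles,
                inchikey_nostereo=chemstd.inchikey_nostereo(mol),
                parent_of=rid,
                _mol=mol,
            )
        )
    return out
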