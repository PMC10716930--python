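"""Metrics and visual analytics over generation logs.

Definitions follow the generation-benchmark conventions used throughout the
package: *validity* is the fraction of all proposed SMILES strings that are
parseable **and** pass the generation filters; *uniqueness* is the fraction
of valid strings that are distinct (by canonical SMILES); the database match
count is over unique valid molecules. Structural similarity is the Tanimoto
coefficient of 2048-bit Morgan radius-2 fingerprints; chemical space is
projected with UMAP on those fingerprints under a Jaccard metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import QED
from rdkit.DataStructs import BulkTanimotoSimilarity

from . import chemstd
from .chemstd import StandardMolecule
from .errors import EmptyLog, EmptyReferenceSet, InvalidQuery, TooFewMolecules
from .generator import GenerationLog
from .patentdb import DrugPatentDB

SIM_BIN_EDGES = np.round(np.arange(0.0, 1.0001, 0.05), 2)


@dataclass
class GenerationMetrics:
    validity: float
    uniqueness: float
    n_all: int
    n_valid: int
    n_valid_unique: int
    n_db_matches: Optional[int] = None


@dataclass
class ReplicateMetrics:
    per_run: List[GenerationMetrics]
    validity_mean: float
    validity_std: float
    uniqueness_mean: float
    uniqueness_std: float
    db_matches_mean: Optional[float] = None
    db_matches_std: Optional[float] = None


@dataclass
class SimilarityDistribution:
    bin_edges: np.ndarray
    counts: np.ndarray
    fraction_ge_07: float
    fraction_eq_1: float
    max_similarities: np.ndarray = field(repr=False, default=None)


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (n, 2), inputs first then references
    n_inputs: int
    metric: str = "jaccard"
    fingerprint_kind: str = "morgan_r2"
    seed: int = 0


def compute_metrics(log: GenerationLog, db: Optional[DrugPatentDB] = None,
                    first_k_unique: Optional[int] = None) -> GenerationMetrics:
    """Validity, uniqueness and (optionally) DB match count for one log.

    ``first_k_unique`` restricts the match count to the first K valid-unique
    molecules in proposal order, the protocol used to compare runs at a
    fixed generation budget.
    """
    if not log.records:
        raise EmptyLog("no generated records")
    totals = log.totals
    n_all, n_valid = totals["n_all"], totals["n_valid"]
    if n_valid == 0:
        raise EmptyLog("no valid molecules: uniqueness undefined")
    validity = n_valid / n_all
    uniqueness = totals["n_valid_unique"] / n_valid
    n_matches = None
    if db is not None:
        uniq = log.valid_unique_smiles()
        if first_k_unique is not None:
            uniq = uniq[:first_k_unique]
        n_matches = 0
        for smi in uniq:
            # log canonical_smiles fields come out of standardize(), so key
            # generation alone suffices here
            key = chemstd.inchikey_nostereo(Chem.MolFromSmiles(smi))
            if db.contains(key):
                n_matches += 1
    return GenerationMetrics(
        validity=validity,
        uniqueness=uniqueness,
        n_all=n_all,
        n_valid=n_valid,
        n_valid_unique=totals["n_valid_unique"],
        n_db_matches=n_matches,
    )


def aggregate_metrics(per_run: Sequence[GenerationMetrics]) -> ReplicateMetrics:
    """Mean and standard deviation across replicate generations."""
    v = np.array([m.validity for m in per_run])
    u = np.array([m.uniqueness for m in per_run])
    out = ReplicateMetrics(
        per_run=list(per_run),
        validity_mean=float(v.mean()), validity_std=float(v.std()),
        uniqueness_mean=float(u.mean()), uniqueness_std=float(u.std()),
    )
    if all(m.n_db_matches is not None for m in per_run):
        d = np.array([m.n_db_matches for m in per_run], dtype=float)
        out.db_matches_mean = float(d.mean())
        out.db_matches_std = float(d.std())
    return out


def _morgan2_fps(mols: Sequence[StandardMolecule]):
    return [chemstd.morgan_bitvect(m.to_mol(), 2) for m in mols]


def bin_similarity(value: float) -> int:
    """Histogram bin index for a similarity: bins [x, x+0.05), last bin closed."""
    idx = int(value / 0.05)
    return min(idx, len(SIM_BIN_EDGES) - 2)


def max_similarity_distribution(
    mols: Sequence[StandardMolecule], refs: Sequence[StandardMolecule]
) -> SimilarityDistribution:
    """Per-molecule maximum Tanimoto to the reference set, binned at 0.05."""
    if not refs:
        raise EmptyReferenceSet("similarity needs a reference set")
    ref_fps = _morgan2_fps(refs)
    sims = np.empty(len(mols))
    for i, m in enumerate(mols):
        fp = chemstd.morgan_bitvect(m.to_mol(), 2)
        sims[i] = max(BulkTanimotoSimilarity(fp, ref_fps))
    counts = np.zeros(len(SIM_BIN_EDGES) - 1, dtype=int)
    for v in sims:
        counts[bin_similarity(v)] += 1
    n = max(len(sims), 1)
    return SimilarityDistribution(
        bin_edges=SIM_BIN_EDGES,
        counts=counts,
        fraction_ge_07=float((sims >= 0.7).sum() / n),
        fraction_eq_1=float((sims == 1.0).sum() / n),
        max_similarities=sims,
    )


def qed_distribution(mols: Sequence[StandardMolecule],
                     n_bins: int = 20) -> Dict[str, object]:
    """Per-molecule drug-likeness (QED) histogram plus summary statistics."""
    values = np.array([QED.qed(m.to_mol()) for m in mols])
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, 1.0))
    return {
        "values": values,
        "counts": counts,
        "bin_edges": edges,
        "mean": float(values.mean()) if len(values) else float("nan"),
        "median": float(np.median(values)) if len(values) else float("nan"),
    }


def embed_chemical_space(
    mols: Sequence[StandardMolecule],
    refs: Sequence[StandardMolecule] = (),
    seed: int = 0,
) -> EmbeddingResult:
    """2-D UMAP projection (Jaccard metric over Morgan r=2 bits)."""
    combined = list(mols) + list(refs)
    if len(combined) < 10:
        raise TooFewMolecules(f"{len(combined)} molecules < 10")
    import umap  # deferred: heavy import

    X = np.zeros((len(combined), chemstd.N_BITS), dtype=bool)
    for i, m in enumerate(combined):
        X[i, list(chemstd.morgan_bitvect(m.to_mol(), 2).GetOnBits())] = True
    n_neighbors = min(15, len(combined) - 1)
    reducer = umap.UMAP(
        n_components=2, metric="jaccard", random_state=seed,
        n_neighbors=n_neighbors,
    )
    coords = reducer.fit_transform(X)
    return EmbeddingResult(
        coordinates=np.asarray(coords), n_inputs=len(mols), seed=seed
    )


@dataclass
class AnalogHit:
    smiles: str
    similarity: float
    qed: float
    db_match: Optional[bool] = None


def find_analogs(
    log: GenerationLog,
    drug_smiles: str,
    threshold: float = 0.5,
    db: Optional[DrugPatentDB] = None,
) -> List[AnalogHit]:
    """Generated molecules with Tanimoto >= threshold to a query drug.

    Each hit carries its similarity, QED and — when a database is given — a
    flag marking whether the analog is itself a patented compound.
    """
    mol = Chem.MolFromSmiles(drug_smiles)
    if mol is None:
        raise InvalidQuery(drug_smiles)
    drug_fp = chemstd.morgan_bitvect(mol, 2)
    hits = []
    for smi in log.valid_unique_smiles():
        m = Chem.MolFromSmiles(smi)
        sim = BulkTanimotoSimilarity(drug_fp, [chemstd.morgan_bitvect(m, 2)])[0]
        if sim >= threshold:
            flag = None
            if db is not None:
                flag = db.contains(chemstd.inchikey_nostereo(m))
            hits.append(AnalogHit(smi, float(sim), float(QED.qed(m)), flag))
    hits.sort(key=lambda h: -h.similarity)
    return hits


# -- plotting -----------------------------------------------------------------

def plot_match_counts(means: Dict[str, float], stds: Dict[str, float], path):
    """Bar chart of replicate-mean DB match counts with error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(means)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(names, [means[n] for n in names],
           yerr=[stds.get(n, 0.0) for n in names], capsize=4)
    ax.set_ylabel("generated molecules matched to drug-patent DB")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_similarity_hist(dist: SimilarityDistribution, path, label=""):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    centers = (dist.bin_edges[:-1] + dist.bin_edges[1:]) / 2
    ax.bar(centers, dist.counts, width=0.045, label=label or None)
    ax.set_xlabel("max Tanimoto similarity to reference compounds")
    ax.set_ylabel("molecules")
    if label:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_embedding(result: EmbeddingResult, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = result.coordinates
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(xy[result.n_inputs:, 0], xy[result.n_inputs:, 1],
               s=4, c="lightgray", label="references")
    ax.scatter(xy[:result.n_inputs, 0], xy[:result.n_inputs, 1],
               s=4, c="tab:orange", label="generated")
    ax.set_xlabel("UMAP-1")
    ax.set_ylabel("UMAP-2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
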