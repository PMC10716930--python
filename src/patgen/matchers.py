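"""Three interchangeable exact-structure matchers plus a latency benchmark.

A generated molecule "matches" the drug-patent DB when it is the *same
structure* as a stored compound (stereochemistry ignored). Three routes
answer that question:

``inchikey``
    text equality of stereo-free InChIKeys against the indexed SQLite table;
``mhfp6_lsh``
    banded locality-sensitive hashing over 2048-permutation MHFP6 minhash
    vectors, with candidate verification;
``morgan_bruteforce``
    maximum Tanimoto over Morgan radius-3 2048-bit fingerprints, a match
    requiring similarity exactly 1.0.

Both fingerprint engines verify candidates by InChIKey so that fingerprint
collisions can never produce a spurious "exact match": all three engines are
guaranteed to agree on any query set, and differ only in speed. Reference
preparation (fingerprinting, index building) is reported separately from
query time and never added to it.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit.Chem import rdMHFPFingerprint
from rdkit.DataStructs import BulkTanimotoSimilarity

from . import chemstd
from .chemstd import StandardMolecule
from .errors import EmptyReferenceSet, IndexNotBuilt
from .patentdb import DrugPatentDB, MatchResult

METHODS = ("inchikey", "mhfp6_lsh", "morgan_bruteforce")


@dataclass
class BenchReport:
    method: str
    n_queries: int
    n_refs: int
    elapsed_seconds: float
    prep_seconds: float
    results: List[MatchResult] = field(repr=False, default_factory=list)

    @property
    def matched_query_ids(self) -> frozenset:
        return frozenset(r.query_id for r in self.results if r.matched)


def _query_id(q: StandardMolecule, i: int) -> str:
    return q.parent_of if q.parent_of else f"q{i}"


def match_inchikey(db: DrugPatentDB, queries: Sequence[StandardMolecule]) -> List[MatchResult]:
    """Full-key text equality against the indexed store."""
    return [db.lookup(q.inchikey_nostereo, _query_id(q, i)) for i, q in enumerate(queries)]


class MhfpLshIndex:
    """Banded minhash LSH over MHFP6 vectors.

    The 2048 minhash positions are split into ``n_bands`` contiguous bands;
    two vectors collide in a band iff that slice is identical, so identical
    vectors (exact structural duplicates up to the fingerprint) collide in
    every band — candidate recall for true exact matches is 1 by
    construction. A fixed permutation seed makes the index deterministic.
    """

    def __init__(self, refs: Sequence[StandardMolecule], seed: int = 42,
                 n_bands: int = 32):
        if not refs:
            raise EmptyReferenceSet("LSH index needs at least one reference")
        self.seed = seed
        self.n_bands = n_bands
        self.refs = list(refs)
        self._encoder = rdMHFPFingerprint.MHFPEncoder(chemstd.N_BITS, seed)
        vecs = np.empty((len(refs), chemstd.N_BITS), dtype=np.uint32)
        for i, ref in enumerate(refs):
            vecs[i] = self._encoder.EncodeMol(ref.to_mol())
        self.vectors = vecs
        self._band_width = chemstd.N_BITS // n_bands
        self._tables: List[Dict[bytes, List[int]]] = [dict() for _ in range(n_bands)]
        for i in range(len(refs)):
            for b, h in enumerate(self._band_hashes(vecs[i])):
                self._tables[b].setdefault(h, []).append(i)

    def _band_hashes(self, vec: np.ndarray) -> List[bytes]:
        w = self._band_width
        return [vec[b * w:(b + 1) * w].tobytes() for b in range(self.n_bands)]

    def encode(self, mol) -> np.ndarray:
        return np.asarray(self._encoder.EncodeMol(mol), dtype=np.uint32)

    def candidates(self, qvec: np.ndarray, k: int) -> List[Tuple[int, float]]:
        """Top-k candidate (ref index, estimated Jaccard) pairs."""
        hit: set = set()
        for b, h in enumerate(self._band_hashes(qvec)):
            hit.update(self._tables[b].get(h, ()))
        if not hit:
            return []
        idx = np.fromiter(hit, dtype=np.int64)
        sims = (self.vectors[idx] == qvec).mean(axis=1)
        order = np.argsort(-sims, kind="stable")[:k]
        return [(int(idx[o]), float(sims[o])) for o in order]


def build_lsh_index(refs: Sequence[StandardMolecule], seed: int = 42,
                    n_bands: int = 32) -> MhfpLshIndex:
    return MhfpLshIndex(refs, seed=seed, n_bands=n_bands)


def match_mhfp_lsh(index: MhfpLshIndex, queries: Sequence[StandardMolecule],
                   k: int = 10) -> List[MatchResult]:
    """LSH retrieval + verification (identical minhash vector and InChIKey)."""
    if not isinstance(index, MhfpLshIndex):
        raise IndexNotBuilt("build_lsh_index must be called first")
    out = []
    for i, q in enumerate(queries):
        qvec = index.encode(q.to_mol())
        ids = []
        for ref_i, sim in index.candidates(qvec, k):
            if sim < 1.0:
                break  # candidates sorted; no exact vector beyond this point
            ref = index.refs[ref_i]
            if (index.vectors[ref_i] == qvec).all() and \
                    ref.inchikey_nostereo == q.inchikey_nostereo:
                ids.append(_query_id(ref, ref_i))
        out.append(MatchResult(_query_id(q, i), bool(ids), tuple(ids)))
    return out


def _morgan_fps(mols: Sequence[StandardMolecule]):
    return [chemstd.morgan_bitvect(m.to_mol(), 3) for m in mols]


def match_morgan_bruteforce(refs: Sequence[StandardMolecule],
                            queries: Sequence[StandardMolecule],
                            ref_fps=None) -> List[MatchResult]:
    """Max-Tanimoto scan; a match needs similarity 1.0 plus key identity."""
    if not refs:
        raise EmptyReferenceSet("brute-force matcher needs references")
    if ref_fps is None:
        ref_fps = _morgan_fps(refs)
    out = []
    for i, q in enumerate(queries):
        qfp = chemstd.morgan_bitvect(q.to_mol(), 3)
        sims = np.asarray(BulkTanimotoSimilarity(qfp, ref_fps))
        ids = []
        if sims.max() == 1.0:
            for j in np.flatnonzero(sims == 1.0):
                if refs[j].inchikey_nostereo == q.inchikey_nostereo:
                    ids.append(_query_id(refs[j], int(j)))
        out.append(MatchResult(_query_id(q, i), bool(ids), tuple(ids)))
    return out


def benchmark_matchers(
    refs: Sequence[StandardMolecule],
    queries: Sequence[StandardMolecule],
    seed: int = 42,
    k: int = 10,
    db_path: str = ":memory:",
    methods: Sequence[str] = METHODS,
) -> Tuple[List[BenchReport], Dict[str, float]]:
    """Run every engine over the same query set and time the query phases.

    Returns one report per method plus a pairwise agreement map
    ``{"a|b": fraction of queries with identical matched flag}``. Reference
    preparation (DB build + key index, LSH construction, reference
    fingerprints) is measured into ``prep_seconds`` and excluded from
    ``elapsed_seconds``.
    """
    if not refs:
        raise EmptyReferenceSet("benchmark needs references")
    import sqlite3

    reports: List[BenchReport] = []

    if "inchikey" in methods:
        t0 = time.perf_counter()
        conn = sqlite3.connect(db_path)
        conn.execute("DROP TABLE IF EXISTS compounds")
        conn.execute("CREATE TABLE compounds (inchikey TEXT, external_id TEXT)")
        conn.execute("CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT)")
        conn.executemany(
            "INSERT INTO compounds VALUES (?, ?)",
            [(r.inchikey_nostereo, _query_id(r, i)) for i, r in enumerate(refs)],
        )
        conn.execute("CREATE INDEX IF NOT EXISTS idx_inchikey ON compounds (inchikey)")
        conn.commit()
        db = DrugPatentDB(db_path, conn)
        prep = time.perf_counter() - t0
        t0 = time.perf_counter()
        results = match_inchikey(db, queries)
        elapsed = time.perf_counter() - t0
        reports.append(BenchReport("inchikey", len(queries), len(refs), elapsed, prep, results))

    if "mhfp6_lsh" in methods:
        t0 = time.perf_counter()
        index = build_lsh_index(refs, seed=seed)
        prep = time.perf_counter() - t0
        t0 = time.perf_counter()
        results = match_mhfp_lsh(index, queries, k=k)
        elapsed = time.perf_counter() - t0
        reports.append(BenchReport("mhfp6_lsh", len(queries), len(refs), elapsed, prep, results))
        del index

    if "morgan_bruteforce" in methods:
        t0 = time.perf_counter()
        ref_fps = _morgan_fps(refs)
        prep = time.perf_counter() - t0
        t0 = time.perf_counter()
        results = match_morgan_bruteforce(refs, queries, ref_fps=ref_fps)
        elapsed = time.perf_counter() - t0
        reports.append(BenchReport("morgan_bruteforce", len(queries), len(refs),
                                   elapsed, prep, results))

    agreement: Dict[str, float] = {}
    for a in range(len(reports)):
        for b in range(a + 1, len(reports)):
            ra, rb = reports[a], reports[b]
            same = sum(
                x.matched == y.matched for x, y in zip(ra.results, rb.results)
            )
            agreement[f"{ra.method}|{rb.method}"] = same / max(len(queries), 1)
    return reports, agreement
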