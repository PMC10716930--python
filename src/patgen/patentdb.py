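"""Build and query the drug-related patented-compound database.

The database maps stereo-free InChIKeys to external compound accessions for
every compound linked to at least one drug-related patent (IPC/CPC code
starting with A61K, medicinal preparations, or A61P, therapeutic activity).
It is the membership oracle behind the patent reward functions, so lookups
must be fast: storage is a single-file SQLite table with an index on the key
column. Patent numbers themselves live only in the JSON build report; the hot
table holds (inchikey, external_id) pairs, duplicates permitted when distinct
accessions standardize to the same structure.
"""

from __future__ import annotations

import csv
import json
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

from . import chemstd
from .errors import DbNotBuilt, StandardizationFailure, InvalidSmiles

DRUG_CLASS_PREFIXES = ("A61K", "A61P")


@dataclass(frozen=True)
class PatentRecord:
    patent_number: str
    ipc_codes: Sequence[str] = ()
    cpc_codes: Sequence[str] = ()


@dataclass(frozen=True)
class CompoundEntry:
    external_id: str
    smiles: str
    ocr_flag: bool = False
    patent_numbers: Sequence[str] = ()


@dataclass(frozen=True)
class MatchResult:
    query_id: str
    matched: bool
    matched_ids: tuple = ()


def is_drug_related(p: PatentRecord) -> bool:
    """True iff any IPC or CPC code starts with A61K or A61P (subclass prefix)."""
    for code in list(p.ipc_codes) + list(p.cpc_codes):
        norm = str(code).strip().upper()
        if norm[:4] in DRUG_CLASS_PREFIXES:
            return True
    return False


class DrugPatentDB:
    """Indexed key -> external_id store over drug-related patented compounds."""

    def __init__(self, storage_path: str, conn: sqlite3.Connection,
                 build_report: Optional[dict] = None):
        self.storage_path = storage_path
        self._conn = conn
        self.build_report = build_report

    # -- construction ---------------------------------------------------------

    @classmethod
    def open(cls, path: str) -> "DrugPatentDB":
        if path != ":memory:" and not Path(path).exists():
            raise DbNotBuilt(f"no database at {path}")
        conn = sqlite3.connect(path)
        try:
            conn.execute("SELECT 1 FROM compounds LIMIT 1")
        except sqlite3.OperationalError as exc:
            raise DbNotBuilt(str(exc)) from exc
        report = None
        report_path = Path(str(path) + ".report.json")
        if report_path.exists():
            report = json.loads(report_path.read_text())
        return cls(path, conn, report)

    # -- queries --------------------------------------------------------------

    @property
    def n_entries(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM compounds").fetchone()[0]

    @property
    def has_key_index(self) -> bool:
        row = self._conn.execute(
            "SELECT COUNT(*) FROM sqlite_master WHERE type='index' AND name='idx_inchikey'"
        ).fetchone()
        return row[0] == 1

    def lookup(self, key: str, query_id: str = "") -> MatchResult:
        rows = self._conn.execute(
            "SELECT external_id FROM compounds WHERE inchikey = ?", (key,)
        ).fetchall()
        ids = tuple(r[0] for r in rows)
        return MatchResult(query_id=query_id, matched=bool(ids), matched_ids=ids)

    def contains(self, key: str) -> bool:
        return self.lookup(key).matched

    def iter_rows(self) -> Iterable[tuple]:
        """(inchikey, external_id) rows in insertion order (oracle scans)."""
        yield from self._conn.execute("SELECT inchikey, external_id FROM compounds")

    def keys(self) -> set:
        return {k for k, _ in self.iter_rows()}

    def _meta(self, key: str) -> Optional[str]:
        row = self._conn.execute("SELECT value FROM meta WHERE key=?", (key,)).fetchone()
        return row[0] if row else None

    def stats(self) -> dict:
        n_distinct = self._conn.execute(
            "SELECT COUNT(DISTINCT inchikey) FROM compounds"
        ).fetchone()[0]
        n_patents = self._meta("n_source_patents")
        return {
            "n_entries": self.n_entries,
            "n_distinct_keys": n_distinct,
            "n_source_patents": int(n_patents) if n_patents is not None else 0,
        }

    def close(self):
        self._conn.close()


def db_stats(db: DrugPatentDB) -> dict:
    if not isinstance(db, DrugPatentDB):
        raise DbNotBuilt("not a built database")
    return db.stats()


def lookup(db: DrugPatentDB, key: str, query_id: str = "") -> MatchResult:
    return db.lookup(key, query_id)


def build_db(
    compounds: Iterable[CompoundEntry],
    patents: Iterable[PatentRecord],
    path: str = ":memory:",
    exclude_ocr: bool = True,
) -> DrugPatentDB:
    """Filter, standardize and store compounds linked to drug-related patents.

    Stages (each counted in the build report): link compounds to their
    patents' classifications and keep those with >=1 drug-related patent; drop
    OCR-origin structures when ``exclude_ocr``; standardize/desalt and derive
    the stereo-free InChIKey; store (key, external_id). Malformed rows and
    standardization failures are skipped but always counted, and references to
    unknown patent numbers are treated as non-drug-related and tallied.
    """
    patent_index: Dict[str, PatentRecord] = {p.patent_number: p for p in patents}
    drug_related = {n for n, p in patent_index.items() if is_drug_related(p)}

    if path != ":memory:":
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        if Path(path).exists():
            Path(path).unlink()
    conn = sqlite3.connect(path)
    conn.execute("CREATE TABLE compounds (inchikey TEXT, external_id TEXT)")
    conn.execute("CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT)")

    counts = {
        "input": 0,
        "malformed": 0,
        "unknown_patent_refs": 0,
        "drug_related": 0,
        "ocr_removed": 0,
        "standardization_failed": 0,
        "stored": 0,
    }
    source_patents = set()
    rows = []
    for entry in compounds:
        counts["input"] += 1
        if not entry.external_id or not entry.smiles or not entry.patent_numbers:
            counts["malformed"] += 1
            continue
        linked = [n for n in entry.patent_numbers if n in drug_related]
        counts["unknown_patent_refs"] += sum(
            1 for n in entry.patent_numbers if n not in patent_index
        )
        if not linked:
            continue
        counts["drug_related"] += 1
        if exclude_ocr and entry.ocr_flag:
            counts["ocr_removed"] += 1
            continue
        try:
            std = chemstd.standardize_smiles(entry.smiles, source_id=entry.external_id)
        except (InvalidSmiles, StandardizationFailure):
            counts["standardization_failed"] += 1
            continue
        rows.append((std.inchikey_nostereo, entry.external_id))
        source_patents.update(linked)
        counts["stored"] += 1

    conn.executemany("INSERT INTO compounds VALUES (?, ?)", rows)
    conn.execute("CREATE INDEX idx_inchikey ON compounds (inchikey)")
    conn.execute(
        "INSERT INTO meta VALUES ('n_source_patents', ?)", (str(len(source_patents)),)
    )
    conn.commit()

    report = {
        "exclude_ocr": exclude_ocr,
        "stage_counts": counts,
        "n_source_patents": len(source_patents),
    }
    if path != ":memory:":
        Path(str(path) + ".report.json").write_text(json.dumps(report, indent=2))
    return DrugPatentDB(path, conn, report)


# -- delimited-text readers ---------------------------------------------------

def _split_codes(cell: str) -> List[str]:
    return [c for c in (cell or "").split(";") if c.strip()]


def read_compounds_table(path, delimiter: str = "\t") -> List[CompoundEntry]:
    """Columns: external_id, smiles, ocr_flag (0/1/true/false), patent_numbers (';'-joined)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter=delimiter):
            out.append(
                CompoundEntry(
                    external_id=row["external_id"],
                    smiles=row["smiles"],
                    ocr_flag=str(row.get("ocr_flag", "0")).strip().lower()
                    in ("1", "true", "yes"),
                    patent_numbers=tuple(_split_codes(row.get("patent_numbers", ""))),
                )
            )
    return out


def read_patents_table(path, delimiter: str = "\t") -> List[PatentRecord]:
    """Columns: patent_number, ipc_codes (';'-joined), cpc_codes (';'-joined)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter=delimiter):
            out.append(
                PatentRecord(
                    patent_number=row["patent_number"],
                    ipc_codes=tuple(_split_codes(row.get("ipc_codes", ""))),
                    cpc_codes=tuple(_split_codes(row.get("cpc_codes", ""))),
                )
            )
    return out


def read_key_table(path, delimiter: str = "\t",
                   key_column: int = 0, id_column: int = 1) -> DrugPatentDB:
    """Load a pre-built key + accession table (published DB layout) into SQLite.

    Accepts two-column delimited text of stereo-free InChIKey and external
    identifier, with or without a header line.
    """
    conn = sqlite3.connect(":memory:")
    conn.execute("CREATE TABLE compounds (inchikey TEXT, external_id TEXT)")
    conn.execute("CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT)")
    rows = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter=delimiter):
            if not row:
                continue
            key = row[key_column].strip()
            if len(key) != 27 or key[14] != "-":  # header or junk line
                continue
            rows.append((key, row[id_column].strip() if len(row) > id_column else ""))
    conn.executemany("INSERT INTO compounds VALUES (?, ?)", rows)
    conn.execute("CREATE INDEX idx_inchikey ON compounds (inchikey)")
    conn.execute("INSERT INTO meta VALUES ('n_source_patents', '0')")
    conn.commit()
    return DrugPatentDB(":memory:", conn, None)
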