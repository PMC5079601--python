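"""Embedded relational store for packed SNP genotype data.

Single-file SQLite database mirroring the classic SNP-repository schema:
``panel`` (one row per genotyping array) with its ordered ``snp`` map,
``individual`` (external sample IDs mapped to stable integer keys),
``genotype_data`` (one packed 2-bit vector per sample per import — the only
table that grows with genotype volume), plus the subset machinery:
``snp_selection`` (1-bit-per-SNP vectors), ``individual_selection`` (ordered
arrays of genotype-record keys) and ``genotype_set`` (a named pair of the
two).  Every row carries a creation timestamp.  Defining a new genotype set
costs one ``genotype_set`` row — genotype payload bytes never change, which
is what makes subset-per-analysis workflows affordable.

Individual selections hold genotype *record* keys rather than individual
keys: a sample genotyped twice on the same panel contributes two records, and
duplicate handling must be able to address each copy.  Each record key still
resolves to its external sample ID through the ``individual`` table.
"""

from __future__ import annotations

import contextlib
import os
import re
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np

from . import codec
from .codec import AllelePair, PackedGenotypeVector
from .errors import (
    DependentEntityError,
    DomainError,
    DuplicateEntityError,
    EmptySelectionError,
    StoreError,
    UnknownEntityError,
)

SCHEMA_VERSION = 1

_SCHEMA = """
CREATE TABLE meta (
    key TEXT PRIMARY KEY,
    value TEXT NOT NULL
);
CREATE TABLE panel (
    panel_name TEXT PRIMARY KEY,
    size INTEGER NOT NULL,
    created_at TEXT NOT NULL
);
CREATE TABLE snp (
    panel_name TEXT NOT NULL REFERENCES panel(panel_name),
    vector_index INTEGER NOT NULL,
    chromosome TEXT NOT NULL,
    snp_name TEXT NOT NULL,
    position_bp INTEGER NOT NULL,
    allele1 TEXT,
    allele2 TEXT,
    coding_inferred INTEGER NOT NULL DEFAULT 0,
    monomorphic INTEGER NOT NULL DEFAULT 0,
    PRIMARY KEY (panel_name, vector_index),
    UNIQUE (panel_name, snp_name)
);
CREATE TABLE individual (
    sample_key INTEGER PRIMARY KEY AUTOINCREMENT,
    sample_id TEXT NOT NULL UNIQUE,
    created_at TEXT NOT NULL
);
CREATE TABLE genotype_data (
    record_key INTEGER PRIMARY KEY AUTOINCREMENT,
    sample_key INTEGER NOT NULL REFERENCES individual(sample_key),
    panel_name TEXT NOT NULL REFERENCES panel(panel_name),
    genotype_bits BLOB NOT NULL,
    n_snps INTEGER NOT NULL,
    ped_fields TEXT,
    created_at TEXT NOT NULL
);
CREATE INDEX idx_gd_sample ON genotype_data(sample_key, panel_name);
CREATE INDEX idx_gd_panel ON genotype_data(panel_name);
CREATE TABLE snp_selection (
    name TEXT PRIMARY KEY,
    panel_name TEXT NOT NULL REFERENCES panel(panel_name),
    bits BLOB NOT NULL,
    n_bits INTEGER NOT NULL,
    n_active INTEGER NOT NULL,
    source TEXT NOT NULL,
    parent TEXT,
    created_at TEXT NOT NULL
);
CREATE TABLE individual_selection (
    name TEXT PRIMARY KEY,
    panel_name TEXT NOT NULL REFERENCES panel(panel_name),
    record_keys BLOB NOT NULL,
    n_keys INTEGER NOT NULL,
    source TEXT NOT NULL,
    parent TEXT,
    created_at TEXT NOT NULL
);
CREATE TABLE genotype_set (
    name TEXT PRIMARY KEY,
    snp_selection TEXT NOT NULL REFERENCES snp_selection(name),
    individual_selection TEXT NOT NULL REFERENCES individual_selection(name),
    comment TEXT,
    created_at TEXT NOT NULL
);
CREATE TABLE phenotype (
    sample_id TEXT NOT NULL,
    attribute TEXT NOT NULL,
    value TEXT NOT NULL,
    created_at TEXT NOT NULL,
    PRIMARY KEY (sample_id, attribute)
);
CREATE TABLE comment_log (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    entity_name TEXT NOT NULL,
    text TEXT NOT NULL,
    created_at TEXT NOT NULL
);
"""

_NAME_RE = re.compile(r"^(gs|is|ss)_(\d+)$")


@dataclass(frozen=True)
class SnpRecord:
    """One map row: a SNP's place on the genome and in the panel vector."""

    chromosome: str
    snp_name: str
    position_bp: int
    coding: AllelePair | None = None
    vector_index: int = -1


@dataclass(frozen=True)
class Panel:
    name: str
    size: int
    created_at: str


@dataclass(frozen=True)
class SnpSelection:
    name: str
    panel_name: str
    bits: np.ndarray = field(repr=False)  # bool, length = panel size
    source: str = ""
    parent: str | None = None
    created_at: str = ""

    @property
    def n_active(self) -> int:
        return int(self.bits.sum())


@dataclass(frozen=True)
class IndividualSelection:
    name: str
    panel_name: str
    record_keys: np.ndarray = field(repr=False)  # int64, ordered
    source: str = ""
    parent: str | None = None
    created_at: str = ""

    @property
    def n_keys(self) -> int:
        return int(self.record_keys.size)


@dataclass(frozen=True)
class GenotypeSet:
    name: str
    snp_selection: str
    individual_selection: str
    comment: str | None = None
    created_at: str = ""


def pack_bits(bits: np.ndarray) -> bytes:
    """Pack a boolean selection vector 1 bit/SNP, LSB-first within bytes."""
    return np.packbits(np.asarray(bits, dtype=np.uint8), bitorder="little").tobytes()


def unpack_bits(blob: bytes, n_bits: int) -> np.ndarray:
    out = np.unpackbits(np.frombuffer(blob, dtype=np.uint8), bitorder="little")
    return out[:n_bits].astype(bool)


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="microseconds")


class SnpStore:
    """Handle on one snpvault database file (or ``":memory:"``)."""

    def __init__(self, path: str | os.PathLike):
        self.path = str(path)
        try:
            self._con = sqlite3.connect(self.path, isolation_level=None)
        except sqlite3.OperationalError as e:  # unwritable / bad path
            raise StoreError(f"cannot open store at {self.path!r}: {e}") from e
        self._con.execute("PRAGMA synchronous=NORMAL")
        self._con.execute("PRAGMA cache_size=-65536")
        self._txn_depth = 0
        self._init_schema()

    @contextlib.contextmanager
    def transaction(self):
        """Re-entrant write transaction; only the outermost level commits."""
        if self._txn_depth == 0:
            self._con.execute("BEGIN")
        self._txn_depth += 1
        try:
            yield
        except BaseException:
            self._txn_depth -= 1
            if self._txn_depth == 0:
                self._con.rollback()
            raise
        self._txn_depth -= 1
        if self._txn_depth == 0:
            self._con.commit()

    # -- lifecycle -----------------------------------------------------------

    def _init_schema(self) -> None:
        cur = self._con.execute(
            "SELECT name FROM sqlite_master WHERE type='table' AND name='meta'"
        )
        if cur.fetchone() is None:
            try:
                with self.transaction():
                    self._con.executescript(_SCHEMA)
                    self._con.execute(
                        "INSERT INTO meta VALUES ('schema_version', ?)",
                        (str(SCHEMA_VERSION),),
                    )
            except sqlite3.OperationalError as e:
                raise StoreError(f"cannot initialise store: {e}") from e
        else:
            row = self._con.execute(
                "SELECT value FROM meta WHERE key='schema_version'"
            ).fetchone()
            if row is None or int(row[0]) != SCHEMA_VERSION:
                raise StoreError(
                    f"schema version mismatch in {self.path!r}: found "
                    f"{row[0] if row else None}, expected {SCHEMA_VERSION}"
                )

    def close(self) -> None:
        self._con.close()

    def __enter__(self) -> "SnpStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def connection(self) -> sqlite3.Connection:
        return self._con

    # -- panels --------------------------------------------------------------

    def add_panel(self, name: str, snps: list[SnpRecord]) -> Panel:
        """Persist a panel from an ordered SNP map; map-file order defines
        vector positions 0..size-1."""
        if self.has_panel(name):
            raise DuplicateEntityError(f"panel {name!r} already exists")
        names = [s.snp_name for s in snps]
        if len(set(names)) != len(names):
            seen, dup = set(), None
            for n in names:
                if n in seen:
                    dup = n
                    break
                seen.add(n)
            raise DuplicateEntityError(
                f"duplicate SNP name {dup!r} in map for panel {name!r}"
            )
        ts = _now()
        with self.transaction():
            self._con.execute(
                "INSERT INTO panel VALUES (?,?,?)", (name, len(snps), ts)
            )
            self._con.executemany(
                "INSERT INTO snp (panel_name, vector_index, chromosome,"
                " snp_name, position_bp, allele1, allele2, coding_inferred,"
                " monomorphic) VALUES (?,?,?,?,?,?,?,?,?)",
                (
                    (
                        name,
                        i,
                        s.chromosome,
                        s.snp_name,
                        int(s.position_bp),
                        s.coding.allele1 if s.coding else None,
                        s.coding.allele2 if s.coding else None,
                        0,
                        0,
                    )
                    for i, s in enumerate(snps)
                ),
            )
        return Panel(name=name, size=len(snps), created_at=ts)

    def has_panel(self, name: str) -> bool:
        return (
            self._con.execute(
                "SELECT 1 FROM panel WHERE panel_name=?", (name,)
            ).fetchone()
            is not None
        )

    def get_panel(self, name: str) -> Panel:
        row = self._con.execute(
            "SELECT panel_name, size, created_at FROM panel WHERE panel_name=?",
            (name,),
        ).fetchone()
        if row is None:
            raise UnknownEntityError(f"unknown panel {name!r}")
        return Panel(*row)

    def list_panels(self) -> list[Panel]:
        return [
            Panel(*r)
            for r in self._con.execute(
                "SELECT panel_name, size, created_at FROM panel ORDER BY panel_name"
            )
        ]

    def get_snp_table(self, panel_name: str):
        """Panel map as a pandas DataFrame ordered by vector_index."""
        import pandas as pd

        self.get_panel(panel_name)
        df = pd.read_sql_query(
            "SELECT vector_index, chromosome, snp_name, position_bp,"
            " allele1, allele2, coding_inferred, monomorphic"
            " FROM snp WHERE panel_name=? ORDER BY vector_index",
            self._con,
            params=(panel_name,),
        )
        return df

    def set_snp_codings(
        self,
        panel_name: str,
        codings: dict[int, tuple[str, str, bool]],
    ) -> None:
        """Persist inferred allele codings: vector_index -> (a1, a2, mono)."""
        with self.transaction():
            self._con.executemany(
                "UPDATE snp SET allele1=?, allele2=?, coding_inferred=1,"
                " monomorphic=? WHERE panel_name=? AND vector_index=?",
                (
                    (a1, a2, int(mono), panel_name, int(idx))
                    for idx, (a1, a2, mono) in codings.items()
                ),
            )

    # -- individuals & genotype records ---------------------------------------

    def _sample_key(self, sample_id: str, create: bool = True) -> int:
        row = self._con.execute(
            "SELECT sample_key FROM individual WHERE sample_id=?", (sample_id,)
        ).fetchone()
        if row is not None:
            return int(row[0])
        if not create:
            raise UnknownEntityError(f"unknown sample {sample_id!r}")
        cur = self._con.execute(
            "INSERT INTO individual (sample_id, created_at) VALUES (?,?)",
            (sample_id, _now()),
        )
        return int(cur.lastrowid)

    def add_genotype_record(
        self,
        sample_id: str,
        panel_name: str,
        codes,
        ped_fields: str | None = None,
    ) -> int:
        """Store one sample's genotypes; creates the individual if new.

        The same ``sample_id`` may be stored repeatedly — duplicates are data
        (re-genotyping happens), not errors.  Returns the new record key.
        """
        panel = self.get_panel(panel_name)
        if isinstance(codes, PackedGenotypeVector):
            packed = codes
        else:
            packed = codec.pack_codes(codes)
        if packed.n_snps != panel.size:
            raise DomainError(
                f"record of {packed.n_snps} genotypes does not fit panel "
                f"{panel_name!r} of size {panel.size}"
            )
        with self.transaction():
            key = self._sample_key(sample_id)
            cur = self._con.execute(
                "INSERT INTO genotype_data (sample_key, panel_name,"
                " genotype_bits, n_snps, ped_fields, created_at)"
                " VALUES (?,?,?,?,?,?)",
                (key, panel_name, packed.payload, packed.n_snps, ped_fields, _now()),
            )
        return int(cur.lastrowid)

    def add_genotype_records_bulk(
        self,
        panel_name: str,
        rows,  # iterable of (sample_id, payload_bytes, ped_fields|None)
        chunk: int = 512,
    ) -> list[int]:
        """Bulk insert pre-packed records, batched per ``chunk`` rows.

        Individuals are created (or resolved) per batch with a single
        statement each, keeping the per-record overhead flat across panel
        sizes.  Returns the new record keys in input order.
        """
        panel = self.get_panel(panel_name)
        nbytes = codec.packed_size(panel.size)
        keys: list[int] = []
        with self.transaction():
            buf: list[tuple] = []
            for row in rows:
                buf.append(row)
                if len(buf) >= chunk:
                    keys.extend(self._insert_chunk(panel, nbytes, buf))
                    buf = []
            if buf:
                keys.extend(self._insert_chunk(panel, nbytes, buf))
        return keys

    def _insert_chunk(self, panel: Panel, nbytes: int, buf: list[tuple]) -> list[int]:
        for sample_id, payload, _ in buf:
            if len(payload) != nbytes:
                raise DomainError(
                    f"payload of {len(payload)} bytes does not fit panel "
                    f"{panel.name!r} ({nbytes} bytes expected)"
                )
        ts = _now()
        ids = list({sid for sid, _, _ in buf})
        self._con.executemany(
            "INSERT OR IGNORE INTO individual (sample_id, created_at)"
            " VALUES (?,?)",
            ((s, ts) for s in ids),
        )
        ph = ",".join("?" * len(ids))
        keymap = dict(
            self._con.execute(
                f"SELECT sample_id, sample_key FROM individual"
                f" WHERE sample_id IN ({ph})",
                ids,
            )
        )
        seq = self._con.execute(
            "SELECT seq FROM sqlite_sequence WHERE name='genotype_data'"
        ).fetchone()
        before = int(seq[0]) if seq else 0
        self._con.executemany(
            "INSERT INTO genotype_data (sample_key, panel_name,"
            " genotype_bits, n_snps, ped_fields, created_at)"
            " VALUES (?,?,?,?,?,?)",
            (
                (keymap[sid], panel.name, payload, panel.size, pf, ts)
                for sid, payload, pf in buf
            ),
        )
        after = int(
            self._con.execute(
                "SELECT seq FROM sqlite_sequence WHERE name='genotype_data'"
            ).fetchone()[0]
        )
        if after - before != len(buf):
            raise StoreError("bulk insert produced non-consecutive record keys")
        # sequential inserts in one transaction get monotonically increasing
        # autoincrement keys, so input order is preserved
        return list(range(before + 1, after + 1))

    def get_record(self, record_key: int) -> tuple[str, str, PackedGenotypeVector]:
        """Return (sample_id, panel_name, packed vector) for one record."""
        row = self._con.execute(
            "SELECT i.sample_id, g.panel_name, g.genotype_bits, g.n_snps"
            " FROM genotype_data g JOIN individual i USING (sample_key)"
            " WHERE g.record_key=?",
            (record_key,),
        ).fetchone()
        if row is None:
            raise UnknownEntityError(f"unknown genotype record {record_key}")
        return row[0], row[1], PackedGenotypeVector(bytes(row[2]), int(row[3]))

    def iter_record_payloads(self, record_keys: np.ndarray, chunk: int = 256):
        """Yield ``(record_key, payload_bytes)`` following the given order.

        One SELECT per chunk of keys; each record is fetched exactly once.
        """
        keys = np.asarray(record_keys, dtype=np.int64)
        for start in range(0, keys.size, chunk):
            part = keys[start : start + chunk]
            ph = ",".join("?" * part.size)
            got = dict(
                self._con.execute(
                    f"SELECT record_key, genotype_bits FROM genotype_data"
                    f" WHERE record_key IN ({ph})",
                    [int(k) for k in part],
                )
            )
            for k in part:
                k = int(k)
                if k not in got:
                    raise UnknownEntityError(
                        f"genotype record {k} referenced by a selection no "
                        f"longer exists"
                    )
                yield k, got[k]

    def record_sample_ids(self, record_keys: np.ndarray) -> list[str]:
        """External sample IDs for record keys, preserving order."""
        keys = np.asarray(record_keys, dtype=np.int64)
        out: dict[int, str] = {}
        for start in range(0, keys.size, 500):
            part = keys[start : start + 500]
            ph = ",".join("?" * part.size)
            out.update(
                (int(k), s)
                for k, s in self._con.execute(
                    f"SELECT g.record_key, i.sample_id FROM genotype_data g"
                    f" JOIN individual i USING (sample_key)"
                    f" WHERE g.record_key IN ({ph})",
                    [int(k) for k in part],
                )
            )
        missing = [int(k) for k in keys if int(k) not in out]
        if missing:
            raise UnknownEntityError(
                f"genotype records {missing[:5]} referenced by a selection no "
                f"longer exist"
            )
        return [out[int(k)] for k in keys]

    def record_ped_fields(self, record_keys: np.ndarray) -> list[str | None]:
        keys = np.asarray(record_keys, dtype=np.int64)
        out: dict[int, str | None] = {}
        for start in range(0, keys.size, 500):
            part = keys[start : start + 500]
            ph = ",".join("?" * part.size)
            out.update(
                (int(k), v)
                for k, v in self._con.execute(
                    f"SELECT record_key, ped_fields FROM genotype_data"
                    f" WHERE record_key IN ({ph})",
                    [int(k) for k in part],
                )
            )
        return [out.get(int(k)) for k in keys]

    def find_duplicate_samples(self, panel_name: str) -> list[tuple[str, int]]:
        """Sample IDs with >= 2 genotype records on one panel, with counts."""
        self.get_panel(panel_name)
        return [
            (r[0], int(r[1]))
            for r in self._con.execute(
                "SELECT i.sample_id, COUNT(*) c FROM genotype_data g"
                " JOIN individual i USING (sample_key)"
                " WHERE g.panel_name=? GROUP BY g.sample_key HAVING c >= 2"
                " ORDER BY i.sample_id",
                (panel_name,),
            )
        ]

    # -- selections & sets -----------------------------------------------------

    def _next_name(self, prefix: str, table: str) -> str:
        high = 0
        for (name,) in self._con.execute(f"SELECT name FROM {table}"):
            m = _NAME_RE.match(name)
            if m and m.group(1) == prefix:
                high = max(high, int(m.group(2)))
        return f"{prefix}_{high + 1:03d}"

    def create_snp_selection(
        self,
        panel_name: str,
        bits: np.ndarray,
        source: str,
        parent: str | None = None,
    ) -> str:
        panel = self.get_panel(panel_name)
        bits = np.asarray(bits, dtype=bool)
        if bits.size != panel.size:
            raise DomainError(
                f"selection of {bits.size} bits does not fit panel "
                f"{panel_name!r} of size {panel.size}"
            )
        if parent is not None:
            self.get_snp_selection(parent)
        with self.transaction():
            name = self._next_name("ss", "snp_selection")
            self._con.execute(
                "INSERT INTO snp_selection VALUES (?,?,?,?,?,?,?,?)",
                (
                    name,
                    panel_name,
                    pack_bits(bits),
                    bits.size,
                    int(bits.sum()),
                    source,
                    parent,
                    _now(),
                ),
            )
        return name

    def get_snp_selection(self, name: str) -> SnpSelection:
        row = self._con.execute(
            "SELECT name, panel_name, bits, n_bits, source, parent, created_at"
            " FROM snp_selection WHERE name=?",
            (name,),
        ).fetchone()
        if row is None:
            raise UnknownEntityError(f"unknown SNP selection {name!r}")
        return SnpSelection(
            name=row[0],
            panel_name=row[1],
            bits=unpack_bits(bytes(row[2]), int(row[3])),
            source=row[4],
            parent=row[5],
            created_at=row[6],
        )

    def create_individual_selection(
        self,
        panel_name: str,
        record_keys,
        source: str,
        parent: str | None = None,
    ) -> str:
        self.get_panel(panel_name)
        keys = np.asarray(record_keys, dtype=np.int64)
        if keys.size != np.unique(keys).size:
            raise DomainError("individual selection keys must be distinct")
        if parent is not None:
            self.get_individual_selection(parent)
        with self.transaction():
            name = self._next_name("is", "individual_selection")
            self._con.execute(
                "INSERT INTO individual_selection VALUES (?,?,?,?,?,?,?)",
                (
                    name,
                    panel_name,
                    keys.tobytes(),
                    keys.size,
                    source,
                    parent,
                    _now(),
                ),
            )
        return name

    def get_individual_selection(self, name: str) -> IndividualSelection:
        row = self._con.execute(
            "SELECT name, panel_name, record_keys, n_keys, source, parent,"
            " created_at FROM individual_selection WHERE name=?",
            (name,),
        ).fetchone()
        if row is None:
            raise UnknownEntityError(f"unknown individual selection {name!r}")
        return IndividualSelection(
            name=row[0],
            panel_name=row[1],
            record_keys=np.frombuffer(bytes(row[2]), dtype=np.int64).copy(),
            source=row[4],
            parent=row[5],
            created_at=row[6],
        )

    def create_genotype_set(
        self,
        snp_selection: str,
        individual_selection: str,
        comment: str | None = None,
    ) -> str:
        """Define a new genotype set: one row pairing two existing selections."""
        ss = self.get_snp_selection(snp_selection)
        isel = self.get_individual_selection(individual_selection)
        if ss.panel_name != isel.panel_name:
            raise DomainError(
                f"selections {snp_selection!r} (panel {ss.panel_name!r}) and "
                f"{individual_selection!r} (panel {isel.panel_name!r}) belong "
                f"to different panels"
            )
        with self.transaction():
            name = self._next_name("gs", "genotype_set")
            self._con.execute(
                "INSERT INTO genotype_set VALUES (?,?,?,?,?)",
                (name, snp_selection, individual_selection, comment, _now()),
            )
        return name

    def get_genotype_set(self, name: str) -> GenotypeSet:
        row = self._con.execute(
            "SELECT name, snp_selection, individual_selection, comment,"
            " created_at FROM genotype_set WHERE name=?",
            (name,),
        ).fetchone()
        if row is None:
            raise UnknownEntityError(f"unknown genotype set {name!r}")
        return GenotypeSet(*row)

    def list_genotype_sets(self) -> list[GenotypeSet]:
        return [
            GenotypeSet(*r)
            for r in self._con.execute(
                "SELECT name, snp_selection, individual_selection, comment,"
                " created_at FROM genotype_set ORDER BY created_at, name"
            )
        ]

    def set_panel_of(self, set_name: str) -> str:
        gs = self.get_genotype_set(set_name)
        return self.get_snp_selection(gs.snp_selection).panel_name

    # -- comments --------------------------------------------------------------

    def entity_exists(self, name: str) -> bool:
        for table, col in (
            ("panel", "panel_name"),
            ("genotype_set", "name"),
            ("snp_selection", "name"),
            ("individual_selection", "name"),
            ("individual", "sample_id"),
        ):
            if self._con.execute(
                f"SELECT 1 FROM {table} WHERE {col}=?", (name,)
            ).fetchone():
                return True
        return False

    def set_comment(self, entity_name: str, text: str) -> None:
        """Attach a free-text comment; history of earlier comments is kept."""
        if not self.entity_exists(entity_name):
            raise UnknownEntityError(
                f"cannot comment on unknown entity {entity_name!r}"
            )
        with self.transaction():
            self._con.execute(
                "INSERT INTO comment_log (entity_name, text, created_at)"
                " VALUES (?,?,?)",
                (entity_name, text, _now()),
            )

    def get_comment(self, entity_name: str) -> str | None:
        row = self._con.execute(
            "SELECT text FROM comment_log WHERE entity_name=?"
            " ORDER BY id DESC LIMIT 1",
            (entity_name,),
        ).fetchone()
        return row[0] if row else None

    def comment_history(self, entity_name: str) -> list[tuple[str, str]]:
        return list(
            self._con.execute(
                "SELECT text, created_at FROM comment_log WHERE entity_name=?"
                " ORDER BY id",
                (entity_name,),
            )
        )

    # -- deletion ---------------------------------------------------------------

    def delete_entity(
        self, kind: str, name: str, cascade: bool = False
    ) -> dict[str, int]:
        """Delete one entity; dependents go transitively when ``cascade``.

        Returns counts of rows removed per table.  Deleting a selection that
        a genotype set references without ``cascade`` is refused with the
        dependent names listed.
        """
        handlers = {
            "panel": self._delete_panel,
            "genotype_set": self._delete_genotype_set,
            "snp_selection": self._delete_snp_selection,
            "individual_selection": self._delete_individual_selection,
            "individual": self._delete_individual,
            "genotype_record": self._delete_genotype_record,
        }
        if kind not in handlers:
            raise DomainError(
                f"unknown entity kind {kind!r}; expected one of "
                f"{sorted(handlers)}"
            )
        with self.transaction():
            return handlers[kind](name, cascade)

    def _delete_genotype_set(self, name: str, cascade: bool) -> dict[str, int]:
        self.get_genotype_set(name)
        self._con.execute("DELETE FROM genotype_set WHERE name=?", (name,))
        return {"genotype_set": 1}

    def _sets_referencing(self, col: str, name: str) -> list[str]:
        return [
            r[0]
            for r in self._con.execute(
                f"SELECT name FROM genotype_set WHERE {col}=?", (name,)
            )
        ]

    def _delete_snp_selection(self, name: str, cascade: bool) -> dict[str, int]:
        self.get_snp_selection(name)
        deps = self._sets_referencing("snp_selection", name)
        if deps and not cascade:
            raise DependentEntityError(
                f"SNP selection {name!r} is referenced by genotype sets "
                f"{deps}; pass cascade to delete them too",
                deps,
            )
        n = {"genotype_set": 0, "snp_selection": 1}
        for d in deps:
            n["genotype_set"] += self._delete_genotype_set(d, True)["genotype_set"]
        self._con.execute(
            "UPDATE snp_selection SET parent=NULL WHERE parent=?", (name,)
        )
        self._con.execute("DELETE FROM snp_selection WHERE name=?", (name,))
        return n

    def _delete_individual_selection(
        self, name: str, cascade: bool
    ) -> dict[str, int]:
        self.get_individual_selection(name)
        deps = self._sets_referencing("individual_selection", name)
        if deps and not cascade:
            raise DependentEntityError(
                f"individual selection {name!r} is referenced by genotype sets "
                f"{deps}; pass cascade to delete them too",
                deps,
            )
        n = {"genotype_set": 0, "individual_selection": 1}
        for d in deps:
            n["genotype_set"] += self._delete_genotype_set(d, True)["genotype_set"]
        self._con.execute(
            "UPDATE individual_selection SET parent=NULL WHERE parent=?", (name,)
        )
        self._con.execute(
            "DELETE FROM individual_selection WHERE name=?", (name,)
        )
        return n

    def _prune_record_keys(self, gone: set[int]) -> int:
        """Remove deleted record keys from every individual selection."""
        touched = 0
        for name, blob, nk in self._con.execute(
            "SELECT name, record_keys, n_keys FROM individual_selection"
        ).fetchall():
            keys = np.frombuffer(bytes(blob), dtype=np.int64)
            mask = ~np.isin(keys, list(gone))
            if mask.all():
                continue
            kept = keys[mask]
            self._con.execute(
                "UPDATE individual_selection SET record_keys=?, n_keys=?"
                " WHERE name=?",
                (kept.tobytes(), int(kept.size), name),
            )
            touched += 1
        return touched

    def _delete_genotype_record(self, name: str, cascade: bool) -> dict[str, int]:
        key = int(name)
        self.get_record(key)
        self._con.execute(
            "DELETE FROM genotype_data WHERE record_key=?", (key,)
        )
        pruned = self._prune_record_keys({key})
        return {"genotype_data": 1, "individual_selection_pruned": pruned}

    def _delete_individual(self, sample_id: str, cascade: bool) -> dict[str, int]:
        skey = self._sample_key(sample_id, create=False)
        keys = {
            int(r[0])
            for r in self._con.execute(
                "SELECT record_key FROM genotype_data WHERE sample_key=?",
                (skey,),
            )
        }
        self._con.execute(
            "DELETE FROM genotype_data WHERE sample_key=?", (skey,)
        )
        pruned = self._prune_record_keys(keys) if keys else 0
        self._con.execute(
            "DELETE FROM individual WHERE sample_key=?", (skey,)
        )
        return {
            "individual": 1,
            "genotype_data": len(keys),
            "individual_selection_pruned": pruned,
        }

    def _delete_panel(self, name: str, cascade: bool) -> dict[str, int]:
        self.get_panel(name)
        ss = [
            r[0]
            for r in self._con.execute(
                "SELECT name FROM snp_selection WHERE panel_name=?", (name,)
            )
        ]
        isel = [
            r[0]
            for r in self._con.execute(
                "SELECT name FROM individual_selection WHERE panel_name=?",
                (name,),
            )
        ]
        deps = sorted(
            {g for s in ss for g in self._sets_referencing("snp_selection", s)}
            | {
                g
                for s in isel
                for g in self._sets_referencing("individual_selection", s)
            }
        )
        if (deps or ss or isel) and not cascade:
            raise DependentEntityError(
                f"panel {name!r} has dependent selections/sets "
                f"{sorted(set(ss + isel + deps))}; pass cascade",
                sorted(set(ss + isel + deps)),
            )
        n = {"genotype_set": 0, "snp_selection": 0, "individual_selection": 0}
        for g in deps:
            n["genotype_set"] += 1
            self._con.execute("DELETE FROM genotype_set WHERE name=?", (g,))
        for s in ss:
            self._con.execute(
                "UPDATE snp_selection SET parent=NULL WHERE parent=?", (s,)
            )
            self._con.execute("DELETE FROM snp_selection WHERE name=?", (s,))
            n["snp_selection"] += 1
        for s in isel:
            self._con.execute(
                "UPDATE individual_selection SET parent=NULL WHERE parent=?",
                (s,),
            )
            self._con.execute(
                "DELETE FROM individual_selection WHERE name=?", (s,)
            )
            n["individual_selection"] += 1
        n["genotype_data"] = self._con.execute(
            "SELECT COUNT(*) FROM genotype_data WHERE panel_name=?", (name,)
        ).fetchone()[0]
        self._con.execute(
            "DELETE FROM genotype_data WHERE panel_name=?", (name,)
        )
        n["snp"] = self._con.execute(
            "SELECT COUNT(*) FROM snp WHERE panel_name=?", (name,)
        ).fetchone()[0]
        self._con.execute("DELETE FROM snp WHERE panel_name=?", (name,))
        self._con.execute("DELETE FROM panel WHERE panel_name=?", (name,))
        n["panel"] = 1
        return n

    # -- reporting ----------------------------------------------------------------

    def storage_report(self) -> dict[str, dict[str, int]]:
        """Rows and bytes per table plus a grand total.

        Genotype payload bytes are exact blob sizes (sum of ceil(size/4) per
        record); selection tables likewise; remaining tables report the summed
        length of their text/int content as an approximation.
        """
        rep: dict[str, dict[str, int]] = {}

        def _count(table: str) -> int:
            return int(
                self._con.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]
            )

        rep["genotype_data"] = {
            "rows": _count("genotype_data"),
            "bytes": int(
                self._con.execute(
                    "SELECT COALESCE(SUM(LENGTH(genotype_bits)),0)"
                    " FROM genotype_data"
                ).fetchone()[0]
            ),
        }
        rep["snp_selection"] = {
            "rows": _count("snp_selection"),
            "bytes": int(
                self._con.execute(
                    "SELECT COALESCE(SUM(LENGTH(bits)),0) FROM snp_selection"
                ).fetchone()[0]
            ),
        }
        rep["individual_selection"] = {
            "rows": _count("individual_selection"),
            "bytes": int(
                self._con.execute(
                    "SELECT COALESCE(SUM(LENGTH(record_keys)),0)"
                    " FROM individual_selection"
                ).fetchone()[0]
            ),
        }
        rep["genotype_set"] = {
            "rows": _count("genotype_set"),
            "bytes": int(
                self._con.execute(
                    "SELECT COALESCE(SUM(LENGTH(name)+LENGTH(snp_selection)"
                    "+LENGTH(individual_selection)+LENGTH(created_at)"
                    "+COALESCE(LENGTH(comment),0)),0) FROM genotype_set"
                ).fetchone()[0]
            ),
        }
        for table, expr in (
            ("panel", "LENGTH(panel_name)+8+LENGTH(created_at)"),
            (
                "snp",
                "LENGTH(panel_name)+8+LENGTH(chromosome)+LENGTH(snp_name)+8"
                "+COALESCE(LENGTH(allele1),0)+COALESCE(LENGTH(allele2),0)",
            ),
            ("individual", "8+LENGTH(sample_id)+LENGTH(created_at)"),
            (
                "phenotype",
                "LENGTH(sample_id)+LENGTH(attribute)+LENGTH(value)"
                "+LENGTH(created_at)",
            ),
            ("comment_log", "LENGTH(entity_name)+LENGTH(text)+LENGTH(created_at)"),
        ):
            rep[table] = {
                "rows": _count(table),
                "bytes": int(
                    self._con.execute(
                        f"SELECT COALESCE(SUM({expr}),0) FROM {table}"
                    ).fetchone()[0]
                ),
            }
        rep["total"] = {
            "rows": sum(v["rows"] for v in rep.values()),
            "bytes": sum(v["bytes"] for v in rep.values()),
        }
        return rep

    def validate_integrity(self) -> list[str]:
        """Full-scan referential checks; returns a list of problems (empty = ok)."""
        problems: list[str] = []
        for key, nsnps, panel in self._con.execute(
            "SELECT record_key, n_snps, panel_name FROM genotype_data"
        ):
            size = self._con.execute(
                "SELECT size FROM panel WHERE panel_name=?", (panel,)
            ).fetchone()
            if size is None:
                problems.append(f"record {key} references unknown panel {panel!r}")
            elif int(size[0]) != int(nsnps):
                problems.append(
                    f"record {key} length {nsnps} != panel {panel!r} size {size[0]}"
                )
        for name, panel, nbits in self._con.execute(
            "SELECT name, panel_name, n_bits FROM snp_selection"
        ):
            size = self._con.execute(
                "SELECT size FROM panel WHERE panel_name=?", (panel,)
            ).fetchone()
            if size is None or int(size[0]) != int(nbits):
                problems.append(f"snp_selection {name} inconsistent with panel")
        valid_keys = {
            int(r[0])
            for r in self._con.execute("SELECT record_key FROM genotype_data")
        }
        for name, blob in self._con.execute(
            "SELECT name, record_keys FROM individual_selection"
        ):
            keys = np.frombuffer(bytes(blob), dtype=np.int64)
            bad = [int(k) for k in keys if int(k) not in valid_keys]
            if bad:
                problems.append(
                    f"individual_selection {name} references missing records "
                    f"{bad[:5]}"
                )
        for name, ssn, isn in self._con.execute(
            "SELECT name, snp_selection, individual_selection FROM genotype_set"
        ):
            for tbl, ref in (
                ("snp_selection", ssn),
                ("individual_selection", isn),
            ):
                if not self._con.execute(
                    f"SELECT 1 FROM {tbl} WHERE name=?", (ref,)
                ).fetchone():
                    problems.append(
                        f"genotype_set {name} references missing {tbl} {ref!r}"
                    )
        for tbl, col in (
            ("snp_selection", "parent"),
            ("individual_selection", "parent"),
        ):
            for name, parent in self._con.execute(
                f"SELECT name, {col} FROM {tbl} WHERE {col} IS NOT NULL"
            ):
                if not self._con.execute(
                    f"SELECT 1 FROM {tbl} WHERE name=?", (parent,)
                ).fetchone():
                    problems.append(
                        f"{tbl} {name} has dangling parent {parent!r}"
                    )
        return problems


def init_store(path: str | os.PathLike) -> SnpStore:
    """Create (or idempotently reopen) a snpvault database at ``path``."""
    return SnpStore(path)
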