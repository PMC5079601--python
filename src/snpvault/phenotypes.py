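"""Entity-attribute-value phenotype storage with CSV import/export.

Phenotypes are arbitrary named attributes attached to sample IDs — the
store imposes no schema and no type system (values are uninterpreted text),
so any organism's trait set fits.  Samples need not be genotyped yet at
import time; the link is by name.  On export the store is scanned for
phenotypes of the samples included in a genotype set and written as CSV,
one row per sample that has any, with a union-of-attributes header
(attributes sorted lexicographically for determinism) and empty cells where
a sample lacks an attribute.
"""

from __future__ import annotations

import os

import pandas as pd

from .errors import DuplicateEntityError, PedFormatError
from .store import SnpStore


def import_phenotypes(store: SnpStore, csv_path: str | os.PathLike) -> int:
    """Load a phenotype CSV (sample-ID column first, then attribute names).

    One value is stored per non-empty cell.  Returns the number of values
    stored.  A (sample, attribute) pair already present — in the file or in
    the store — is a conflict, and the whole import is rolled back.
    """
    try:
        df = pd.read_csv(csv_path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as e:
        raise PedFormatError(f"{csv_path}: {e}") from e
    if df.shape[1] < 2:
        raise PedFormatError(
            f"{csv_path}: need a sample-ID column plus at least one attribute"
        )
    sample_col = df.columns[0]
    attributes = list(df.columns[1:])
    if len(set(attributes)) != len(attributes):
        raise DuplicateEntityError(f"{csv_path}: duplicate attribute in header")
    triples: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        sid = row[sample_col]
        for attr in attributes:
            val = row[attr]
            if val == "":
                continue
            if (sid, attr) in seen:
                raise DuplicateEntityError(
                    f"{csv_path}: duplicate value for sample {sid!r}, "
                    f"attribute {attr!r}"
                )
            seen.add((sid, attr))
            triples.append((sid, attr, val))
    from .store import _now

    con = store.connection
    with store.transaction():
        for sid, attr, val in triples:
            existing = con.execute(
                "SELECT 1 FROM phenotype WHERE sample_id=? AND attribute=?",
                (sid, attr),
            ).fetchone()
            if existing:
                raise DuplicateEntityError(
                    f"phenotype ({sid!r}, {attr!r}) already stored"
                )
            con.execute(
                "INSERT INTO phenotype VALUES (?,?,?,?)", (sid, attr, val, _now())
            )
    return len(triples)


def export_phenotypes(
    store: SnpStore, set_name: str, out_path: str | os.PathLike
) -> int:
    """Write phenotypes of a genotype set's samples as CSV.

    Samples without any phenotype are omitted; if none of the set's samples
    has phenotypes, no file is written and 0 is returned.
    """
    gs = store.get_genotype_set(set_name)
    isel = store.get_individual_selection(gs.individual_selection)
    sample_ids = store.record_sample_ids(isel.record_keys)
    seen: set[str] = set()
    ordered = [s for s in sample_ids if not (s in seen or seen.add(s))]
    rows: dict[str, dict[str, str]] = {}
    con = store.connection
    for start in range(0, len(ordered), 500):
        part = ordered[start : start + 500]
        ph = ",".join("?" * len(part))
        for sid, attr, val in con.execute(
            f"SELECT sample_id, attribute, value FROM phenotype"
            f" WHERE sample_id IN ({ph})",
            part,
        ):
            rows.setdefault(sid, {})[attr] = val
    if not rows:
        return 0
    attributes = sorted({a for d in rows.values() for a in d})
    df = pd.DataFrame(
        [
            {"sample_id": sid, **rows[sid]}
            for sid in ordered
            if sid in rows
        ],
        columns=["sample_id", *attributes],
    )
    df = df.fillna("")
    df.to_csv(out_path, index=False)
    return len(df)


def get_phenotypes(store: SnpStore, sample_id: str) -> dict[str, str]:
    """All stored attributes for one sample."""
    return dict(
        store.connection.execute(
            "SELECT attribute, value FROM phenotype WHERE sample_id=?"
            " ORDER BY attribute",
            (sample_id,),
        )
    )
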