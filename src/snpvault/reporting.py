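"""Housekeeping reports: database size, panels, duplicates, selections.

Every report is a pure read — the store is byte-identical before and after —
and each returns a plain data structure (dict / list) alongside a console
rendering, so pipelines can consume the numbers and humans the tables.
"""

from __future__ import annotations

from . import codec
from .store import SnpStore
from .errors import UnknownEntityError

import numpy as np


def report_database(store: SnpStore) -> dict:
    """Structured size report: per panel, per selection kind, grand totals.

    Genotype payload bytes per panel are the exact packed sizes,
    records x ceil(panel_size / 4).
    """
    storage = store.storage_report()
    panels = []
    for p in store.list_panels():
        n_records = int(
            store.connection.execute(
                "SELECT COUNT(*) FROM genotype_data WHERE panel_name=?",
                (p.name,),
            ).fetchone()[0]
        )
        panels.append(
            {
                "panel": p.name,
                "n_snps": p.size,
                "n_records": n_records,
                "payload_bytes": n_records * codec.packed_size(p.size),
            }
        )
    sets = {
        "genotype_set": storage["genotype_set"],
        "snp_selection": storage["snp_selection"],
        "individual_selection": storage["individual_selection"],
    }
    return {
        "panels": panels,
        "selections": sets,
        "n_individuals": storage["individual"]["rows"],
        "genotype_payload_bytes": storage["genotype_data"]["bytes"],
        "total_bytes": storage["total"]["bytes"],
        "tables": storage,
    }


def render_database_report(rep: dict) -> str:
    lines = ["panel            snps      records   payload_bytes"]
    for p in rep["panels"]:
        lines.append(
            f"{p['panel']:<15} {p['n_snps']:>9} {p['n_records']:>9} "
            f"{p['payload_bytes']:>15}"
        )
    lines.append("")
    for kind, v in rep["selections"].items():
        lines.append(f"{kind:<22} rows={v['rows']:<6} bytes={v['bytes']}")
    lines.append("")
    lines.append(f"individuals: {rep['n_individuals']}")
    lines.append(f"genotype payload bytes: {rep['genotype_payload_bytes']}")
    lines.append(f"total bytes: {rep['total_bytes']}")
    return "\n".join(lines)


def dump_selection(store: SnpStore, name: str) -> dict:
    """Contents of a named selection vector.

    SNP selections list their active SNP names and vector indices;
    individual selections their sample IDs in order.  Source, parent,
    timestamp and latest comment ride along.
    """
    if name.startswith("ss_"):
        ss = store.get_snp_selection(name)
        snp_table = store.get_snp_table(ss.panel_name)
        idx = np.flatnonzero(ss.bits)
        return {
            "kind": "snp_selection",
            "name": name,
            "panel": ss.panel_name,
            "n_active": int(idx.size),
            "indices": idx.tolist(),
            "snp_names": snp_table["snp_name"].to_numpy()[idx].tolist(),
            "source": ss.source,
            "parent": ss.parent,
            "created_at": ss.created_at,
            "comment": store.get_comment(name),
        }
    if name.startswith("is_"):
        isel = store.get_individual_selection(name)
        return {
            "kind": "individual_selection",
            "name": name,
            "panel": isel.panel_name,
            "n_keys": isel.n_keys,
            "record_keys": isel.record_keys.tolist(),
            "sample_ids": store.record_sample_ids(isel.record_keys),
            "source": isel.source,
            "parent": isel.parent,
            "created_at": isel.created_at,
            "comment": store.get_comment(name),
        }
    raise UnknownEntityError(
        f"{name!r} is not a selection name (expected ss_* or is_*)"
    )


def set_comment(store: SnpStore, entity_name: str, text: str) -> None:
    """Attach a comment to any named entity; earlier comments stay in history."""
    store.set_comment(entity_name, text)
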