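"""Panel and genotype import orchestration.

Map-first discipline: genotype data can only be loaded against a previously
imported panel, and every data import must present the map again — it is
compared SNP-for-SNP (name, chromosome, bp position, in order) against the
stored panel before a single genotype is read, so a ped file can never be
attached to the wrong annotation.

Each successful data import atomically creates, besides one genotype record
per ped row, the bookkeeping that makes the batch addressable: an individual
selection (``is_NNN``) listing the new records in file order, a SNP selection
(``ss_NNN``) with every panel bit set, and a genotype set (``gs_NNN``)
pairing the two.
"""

from __future__ import annotations

import os

import numpy as np

from . import codec, plink
from .codec import MISSING_TOKEN, MONOMORPHIC_PLACEHOLDER
from .errors import EmptySelectionError, MapMismatchError, SnpVaultError
from .store import Panel, SnpStore


def import_panel(
    store: SnpStore, map_path: str | os.PathLike, panel_name: str
) -> Panel:
    """Load a map file as a new named panel; touches no genotype data."""
    snps = plink.read_map(map_path)
    return store.add_panel(panel_name, snps)


def _check_map_identity(store: SnpStore, panel_name: str, map_path) -> None:
    stored = store.get_snp_table(panel_name)
    fresh = plink.read_map(map_path)
    if len(fresh) != len(stored):
        raise MapMismatchError(
            f"map {map_path} has {len(fresh)} SNPs but panel "
            f"{panel_name!r} has {len(stored)}"
        )
    names = stored["snp_name"].to_numpy()
    chroms = stored["chromosome"].to_numpy()
    pos = stored["position_bp"].to_numpy()
    for i, rec in enumerate(fresh):
        if (
            rec.snp_name != names[i]
            or rec.chromosome != str(chroms[i])
            or rec.position_bp != int(pos[i])
        ):
            raise MapMismatchError(
                f"map {map_path} disagrees with stored panel {panel_name!r} "
                f"at vector position {i}: "
                f"({rec.chromosome},{rec.snp_name},{rec.position_bp}) vs "
                f"({chroms[i]},{names[i]},{pos[i]})"
            )


def _infer_codings(
    ped_path, n_snps: int, known_a1: np.ndarray, known_mask: np.ndarray
) -> dict[int, tuple[str, str, bool]]:
    """First-observed allele order per SNP, lexicographic tie-break for SNPs
    first seen as heterozygotes, '0'-placeholder for monomorphic SNPs."""
    first = np.full(n_snps, "", dtype="U8")
    second = np.full(n_snps, "", dtype="U8")
    ambiguous = np.zeros(n_snps, dtype=bool)  # first sighting was a het
    for row in plink.read_ped(ped_path, n_snps):
        a, b = row.allele_a, row.allele_b
        called = (a != MISSING_TOKEN) & (b != MISSING_TOKEN) & ~known_mask
        # new first allele
        fresh = called & (first == "")
        if fresh.any():
            first[fresh] = a[fresh]
            het_first = fresh & (a != b)
            second[het_first] = b[het_first]
            ambiguous[het_first] = True
        # new second allele where only one known
        open_snps = called & (first != "") & (second == "")
        if open_snps.any():
            cand = np.where(a != first, a, b)
            newsec = open_snps & (cand != first)
            second[newsec] = cand[newsec]
        if not (second == "")[~known_mask].any() and not ambiguous.any():
            break
    out: dict[int, tuple[str, str, bool]] = {}
    for i in np.flatnonzero(~known_mask):
        f, s = str(first[i]), str(second[i])
        if not f:  # never called: placeholder coding, flagged monomorphic
            out[i] = ("A", MONOMORPHIC_PLACEHOLDER, True)
        elif not s:
            out[i] = (f, MONOMORPHIC_PLACEHOLDER, True)
        elif ambiguous[i]:
            lo, hi = sorted((f, s))
            out[i] = (lo, hi, False)
        else:
            out[i] = (f, s, False)
    return out


def import_data(
    store: SnpStore,
    ped_path: str | os.PathLike,
    map_path: str | os.PathLike,
    panel_name: str,
    comment: str | None = None,
) -> str:
    """Import a ped/map pair against an existing panel.

    Returns the name of the genotype set covering the imported batch.  The
    import is atomic: a parse or encoding error anywhere leaves no partial
    state.  Re-imported sample IDs attach new records to the existing
    individual (that is what makes duplicate detection possible).
    """
    store.get_panel(panel_name)
    _check_map_identity(store, panel_name, map_path)
    snp_table = store.get_snp_table(panel_name)
    n_snps = len(snp_table)

    coding_missing = snp_table["allele1"].isna() | snp_table["allele2"].isna()
    if coding_missing.any():
        inferred = _infer_codings(
            ped_path,
            n_snps,
            snp_table["allele1"].fillna("").to_numpy(dtype="U8"),
            (~coding_missing).to_numpy(),
        )
        store.set_snp_codings(panel_name, inferred)
        snp_table = store.get_snp_table(panel_name)

    allele1 = snp_table["allele1"].to_numpy(dtype="U8")
    allele2 = snp_table["allele2"].to_numpy(dtype="U8")

    with store.transaction():
        record_keys: list[int] = []
        for row in plink.read_ped(ped_path, n_snps):
            try:
                codes = codec.encode_pair_arrays(
                    row.allele_a, row.allele_b, allele1, allele2
                )
            except SnpVaultError as e:
                raise type(e)(
                    f"{ped_path}: sample {row.individual_id!r}: {e}"
                ) from e
            payload = codec.pack_payload(codes)
            ped_fields = " ".join(row.lead_fields)
            keys = store.add_genotype_records_bulk(
                panel_name, [(row.individual_id, payload, ped_fields)]
            )
            record_keys.extend(keys)
        if not record_keys:
            raise EmptySelectionError(f"{ped_path}: ped file contains no rows")
        is_name = store.create_individual_selection(
            panel_name,
            np.asarray(record_keys, dtype=np.int64),
            source=f"import {os.path.basename(str(ped_path))}",
        )
        ss_name = store.create_snp_selection(
            panel_name,
            np.ones(n_snps, dtype=bool),
            source=f"import {os.path.basename(str(map_path))}",
        )
        gs_name = store.create_genotype_set(ss_name, is_name, comment=comment)
    if comment:
        store.set_comment(gs_name, comment)
    return gs_name


def import_code_matrix(
    store: SnpStore,
    panel_name: str,
    records,  # iterable of (sample_id, codes-or-packed-payload)
    source: str = "bulk import",
    comment: str | None = None,
) -> str:
    """Bulk import of already-encoded genotype codes (no ped tokenisation).

    The workhorse behind the synthetic-data generator and the benchmark
    harness at panel sizes where a ped text file would be impractically
    large.  ``records`` yields ``(sample_id, codes)`` with codes either a
    uint8 array of panel length or pre-packed payload bytes.  Creates the
    same is/ss/gs bookkeeping as :func:`import_data`, atomically.
    """
    panel = store.get_panel(panel_name)
    with store.transaction():

        def _rows():
            for sample_id, codes in records:
                if isinstance(codes, (bytes, bytearray, memoryview)):
                    payload = bytes(codes)
                else:
                    payload = codec.pack_payload(
                        codec._as_code_array(codes)
                    )
                yield sample_id, payload, None

        record_keys = store.add_genotype_records_bulk(panel_name, _rows())
        if not record_keys:
            raise EmptySelectionError("bulk import contains no records")
        is_name = store.create_individual_selection(
            panel_name, np.asarray(record_keys, dtype=np.int64), source=source
        )
        ss_name = store.create_snp_selection(
            panel_name, np.ones(panel.size, dtype=bool), source=source
        )
        gs_name = store.create_genotype_set(ss_name, is_name, comment=comment)
    if comment:
        store.set_comment(gs_name, comment)
    return gs_name
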