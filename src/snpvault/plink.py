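"""Readers and writers for PLINK text formats and selection-list files.

Map dialects accepted (uniform within a file, detected from the first line):

* 3 columns — chromosome, SNP name, bp position
* 4 columns — standard PLINK: chromosome, SNP name, cM, bp (cM ignored), or
  3 columns plus a fused allele-coding token such as ``AB``
* 5 columns — 4-column PLINK plus a fused coding token, or 3 columns plus a
  two-token coding such as ``A T``
* 6 columns — 4-column PLINK plus a two-token coding

Chromosomes are text labels (``"W"``, ``"X"``, ``"MT"`` stay as-is).
Exported maps are always 4-column PLINK with cM = 0, tab-separated; ped files
are space-separated.  The ``0125`` export writes one line per sample —
sample ID, a tab, then one digit per active SNP: 0 hom-allele1, 1 het,
2 hom-allele2, 5 missing.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Iterator
from dataclasses import dataclass

import numpy as np

from .codec import MISSING_TOKEN, NOCALL, HET, HOM1, HOM2, AllelePair
from .errors import DuplicateEntityError, EmptySelectionError, PedFormatError
from .store import SnpRecord

#: digit emitted per genotype code in the 0125 format, indexed by code
DIGITS_0125 = np.array(["0", "1", "5", "2"])


@dataclass
class PedRow:
    """One ped line: six leading columns plus the allele pairs."""

    family_id: str
    individual_id: str
    paternal_id: str
    maternal_id: str
    sex: str
    phenotype: str
    allele_a: np.ndarray  # first token of each pair
    allele_b: np.ndarray  # second token of each pair

    @property
    def lead_fields(self) -> tuple[str, ...]:
        return (
            self.family_id,
            self.individual_id,
            self.paternal_id,
            self.maternal_id,
            self.sex,
            self.phenotype,
        )


def _parse_coding(tokens: list[str], path: str, lineno: int) -> AllelePair:
    if len(tokens) == 1:
        tok = tokens[0]
        if len(tok) != 2:
            raise PedFormatError(
                f"{path}:{lineno}: fused allele coding must be two characters,"
                f" got {tok!r}"
            )
        return AllelePair(tok[0], tok[1])
    return AllelePair(tokens[0], tokens[1])


def _is_int(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


def _is_float(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _map_dialect(tokens: list[str], path: str) -> tuple[bool, int]:
    """Return (has_cM_column, n_coding_tokens) for the first map line."""
    n = len(tokens)
    if n == 3:
        return False, 0
    if n == 4:
        # standard PLINK if col4 is an integer bp, else 3 cols + fused coding
        return (True, 0) if _is_int(tokens[3]) else (False, 1)
    if n == 5:
        if _is_float(tokens[2]) and _is_int(tokens[3]):
            return True, 1
        return False, 2
    if n == 6:
        return True, 2
    raise PedFormatError(f"{path}: cannot interpret a {n}-column map line")


def read_map(path: str | os.PathLike) -> list[SnpRecord]:
    """Parse a map file into ordered SNP records with vector indices."""
    path = str(path)
    records: list[SnpRecord] = []
    seen: set[str] = set()
    dialect: tuple[bool, int] | None = None
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if dialect is None:
                dialect = _map_dialect(tokens, path)
                ncols = len(tokens)
            if len(tokens) != ncols:
                raise PedFormatError(
                    f"{path}:{lineno}: {len(tokens)} columns, expected {ncols}"
                )
            has_cm, n_coding = dialect
            chrom, name = tokens[0], tokens[1]
            bp_tok = tokens[3] if has_cm else tokens[2]
            if not _is_int(bp_tok):
                raise PedFormatError(
                    f"{path}:{lineno}: non-integer bp position {bp_tok!r}"
                )
            if name in seen:
                raise DuplicateEntityError(
                    f"{path}:{lineno}: duplicate SNP name {name!r}"
                )
            seen.add(name)
            coding = None
            if n_coding:
                coding = _parse_coding(tokens[-n_coding:], path, lineno)
            records.append(
                SnpRecord(
                    chromosome=chrom,
                    snp_name=name,
                    position_bp=int(bp_tok),
                    coding=coding,
                    vector_index=len(records),
                )
            )
    return records


def read_ped(path: str | os.PathLike, n_snps: int) -> Iterator[PedRow]:
    """Stream ped rows one at a time (constant memory in sample count)."""
    path = str(path)
    expected = 6 + 2 * n_snps
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != expected:
                raise PedFormatError(
                    f"{path}:{lineno}: {len(tokens)} fields, expected "
                    f"{expected} (6 + 2 x {n_snps} SNPs)"
                )
            alleles = np.array(tokens[6:], dtype="U8")
            yield PedRow(
                family_id=tokens[0],
                individual_id=tokens[1],
                paternal_id=tokens[2],
                maternal_id=tokens[3],
                sex=tokens[4],
                phenotype=tokens[5],
                allele_a=alleles[0::2],
                allele_b=alleles[1::2],
            )


def write_map(snps: Iterable[SnpRecord] | "object", path: str | os.PathLike) -> int:
    """Write a 4-column PLINK map (tab-separated, cM=0); returns line count.

    Accepts an iterable of :class:`SnpRecord` or a DataFrame with columns
    ``chromosome``, ``snp_name``, ``position_bp``.
    """
    n = 0
    with open(path, "w") as fh:
        rows: Iterable
        if hasattr(snps, "itertuples"):
            rows = (
                (r.chromosome, r.snp_name, r.position_bp)
                for r in snps.itertuples()
            )
        else:
            rows = ((s.chromosome, s.snp_name, s.position_bp) for s in snps)
        for chrom, name, bp in rows:
            fh.write(f"{chrom}\t{name}\t0\t{bp}\n")
            n += 1
    return n


def write_ped_map(
    rows: Iterable[tuple[tuple[str, ...], str]],
    snps,
    prefix: str | os.PathLike,
) -> dict[str, str]:
    """Write ``prefix.ped`` and ``prefix.map``.

    ``rows`` yields ``(lead_fields, genotype_string)`` where the genotype
    string is the space-joined decoded allele pairs for the active SNPs.
    """
    prefix = str(prefix)
    ped_path, map_path = prefix + ".ped", prefix + ".map"
    n = 0
    with open(ped_path, "w") as fh:
        for lead, geno in rows:
            fh.write(" ".join(lead))
            if geno:
                fh.write(" ")
                fh.write(geno)
            fh.write("\n")
            n += 1
    if n == 0:
        os.remove(ped_path)
        raise EmptySelectionError("refusing to export an empty sample set")
    write_map(snps, map_path)
    return {"ped": ped_path, "map": map_path}


def write_0125(
    rows: Iterable[tuple[str, str]],
    snps,
    prefix: str | os.PathLike,
) -> dict[str, str]:
    """Write ``prefix.0125`` (+ ``prefix.map``): sample ID, tab, digit string."""
    prefix = str(prefix)
    out_path, map_path = prefix + ".0125", prefix + ".map"
    n = 0
    with open(out_path, "w") as fh:
        for sample_id, digits in rows:
            fh.write(f"{sample_id}\t{digits}\n")
            n += 1
    if n == 0:
        os.remove(out_path)
        raise EmptySelectionError("refusing to export an empty sample set")
    write_map(snps, map_path)
    return {"0125": out_path, "map": map_path}


def read_selection_lists(
    sample_list_path: str | os.PathLike | None = None,
    snp_list_path: str | os.PathLike | None = None,
) -> tuple[list[str] | None, dict[str, int] | None]:
    """Parse plain-text selection lists.

    Sample file: one sample ID per line, all kept.  SNP file: either one SNP
    name per line (named SNPs kept) or two columns ``name flag`` with flag in
    {0, 1} — SNPs flagged 0 are excluded.  Returns ``(sample_ids, snp_flags)``
    with ``None`` for a path not given.
    """
    if sample_list_path is None and snp_list_path is None:
        raise PedFormatError("at least one selection-list path is required")
    samples: list[str] | None = None
    if sample_list_path is not None:
        samples = []
        seen: set[str] = set()
        with open(sample_list_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                tokens = line.split()
                if not tokens:
                    continue
                if len(tokens) != 1:
                    raise PedFormatError(
                        f"{sample_list_path}:{lineno}: expected one sample ID"
                        f" per line"
                    )
                if tokens[0] in seen:
                    raise PedFormatError(
                        f"{sample_list_path}:{lineno}: duplicate sample ID "
                        f"{tokens[0]!r}"
                    )
                seen.add(tokens[0])
                samples.append(tokens[0])
        if not samples:
            raise EmptySelectionError(f"{sample_list_path}: empty sample list")
    flags: dict[str, int] | None = None
    if snp_list_path is not None:
        flags = {}
        width = None
        with open(snp_list_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                tokens = line.split()
                if not tokens:
                    continue
                if width is None:
                    width = len(tokens)
                if len(tokens) != width or width not in (1, 2):
                    raise PedFormatError(
                        f"{snp_list_path}:{lineno}: inconsistent or invalid"
                        f" column count"
                    )
                if tokens[0] in flags:
                    raise PedFormatError(
                        f"{snp_list_path}:{lineno}: duplicate SNP name "
                        f"{tokens[0]!r}"
                    )
                if width == 1:
                    flags[tokens[0]] = 1
                else:
                    if tokens[1] not in ("0", "1"):
                        raise PedFormatError(
                            f"{snp_list_path}:{lineno}: flag must be 0 or 1,"
                            f" got {tokens[1]!r}"
                        )
                    flags[tokens[0]] = int(tokens[1])
        if not flags:
            raise EmptySelectionError(f"{snp_list_path}: empty SNP list")
    return samples, flags


def decode_lut(allele1: np.ndarray, allele2: np.ndarray) -> np.ndarray:
    """Per-SNP lookup of decoded pair strings, shape (n_snps, 4).

    ``lut[i, code]`` is the two-token ped field for SNP *i*; heterozygotes use
    canonical (allele1, allele2) order, no-calls the missing token twice.
    """
    n = len(allele1)
    lut = np.empty((n, 4), dtype=object)
    a1 = np.asarray(allele1, dtype=object)
    a2 = np.asarray(allele2, dtype=object)
    lut[:, HOM1] = a1 + " " + a1
    lut[:, HET] = a1 + " " + a2
    lut[:, NOCALL] = MISSING_TOKEN + " " + MISSING_TOKEN
    lut[:, HOM2] = a2 + " " + a2
    return lut
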