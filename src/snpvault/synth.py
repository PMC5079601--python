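"""Synthetic ped/map generation, a bulk study builder, and a benchmark harness.

Genotypes are drawn per SNP under Hardy-Weinberg equilibrium at a minor-
allele frequency sampled per SNP (default Uniform(0.05, 0.5) — the range a
genotyping array's content is designed for), each genotype independently set
to missing with a fixed no-call probability.  That emulates a clean,
unstructured genotyping campaign: no linkage disequilibrium, no population
structure, no pedigree, no batch effects.  Duplicate samples are genuine
re-genotypings — a repeated sample ID receives fresh random genotypes under
the same ID, which is exactly the situation the duplicate machinery exists
for.

Everything is deterministic under a fixed seed, down to byte-identical
output files.
"""

from __future__ import annotations

import os
import time
from collections.abc import Callable

import numpy as np
import pandas as pd

from . import codec, export, ingest
from .errors import DomainError
from .store import SnpRecord, SnpStore
from .codec import AllelePair

_BASES = np.array(["A", "C", "G", "T"])


def _default_maf_dist(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.uniform(0.05, 0.5, size=n)


def gen_map(
    path: str | os.PathLike,
    n_snps: int,
    chromosomes: list[tuple[str, int]] | None = None,
    coding_scheme: str = "AB",
    seed: int = 0,
) -> list[SnpRecord]:
    """Write a map file with an allele-coding column; returns the records.

    ``chromosomes`` is a list of ``(label, snp_count)`` summing to
    ``n_snps`` (default: everything on chromosome "1").  Positions are
    strictly increasing within each chromosome; SNP names are unique across
    the panel.
    """
    if chromosomes is None:
        chromosomes = [("1", n_snps)]
    if sum(c for _, c in chromosomes) != n_snps:
        raise DomainError(
            f"chromosome SNP counts sum to {sum(c for _, c in chromosomes)}, "
            f"expected {n_snps}"
        )
    if coding_scheme not in ("AB", "ACGT"):
        raise DomainError(f"coding_scheme must be 'AB' or 'ACGT'")
    rng = np.random.default_rng(seed)
    records: list[SnpRecord] = []
    with open(path, "w") as fh:
        i = 0
        for label, count in chromosomes:
            pos = np.cumsum(rng.integers(1, 10_000, size=count))
            for p in pos:
                name = f"snp{i:07d}"
                if coding_scheme == "AB":
                    a1, a2 = "A", "B"
                else:
                    a1, a2 = _BASES[
                        rng.choice(4, size=2, replace=False)
                    ]
                fh.write(f"{label}\t{name}\t0\t{int(p)}\t{a1} {a2}\n")
                records.append(
                    SnpRecord(
                        chromosome=label,
                        snp_name=name,
                        position_bp=int(p),
                        coding=AllelePair(str(a1), str(a2)),
                        vector_index=i,
                    )
                )
                i += 1
    return records


def hw_codes(
    rng: np.random.Generator,
    maf: np.ndarray,
    n_samples: int,
    nocall_rate: float = 0.0,
) -> np.ndarray:
    """Hardy-Weinberg genotype codes, shape (n_samples, n_snps), uint8.

    ``maf`` is the per-SNP frequency of allele 2; genotype probabilities are
    ((1-q)^2, 2q(1-q), q^2) for codes (0, 1, 3); missingness (code 2) is
    applied independently at ``nocall_rate``.
    """
    q = np.asarray(maf, dtype=np.float64)
    p0 = (1.0 - q) ** 2
    p1 = 2.0 * q * (1.0 - q)
    c1 = p0
    c2 = p0 + p1
    u = rng.random((n_samples, q.size))
    out = np.full(u.shape, 3, dtype=np.uint8)
    out[u < c2] = 1
    out[u < c1] = 0
    if nocall_rate > 0:
        out[rng.random(u.shape) < nocall_rate] = 2
    return out


def _sample_ids(rng: np.random.Generator, n_samples: int, n_duplicate_ids: int):
    if not 0 <= n_duplicate_ids < n_samples:
        raise DomainError(
            f"n_duplicate_ids must be in [0, n_samples), got {n_duplicate_ids}"
        )
    n_unique = n_samples - n_duplicate_ids
    ids = [f"id{i + 1:06d}" for i in range(n_unique)]
    dup_of = rng.choice(n_unique, size=n_duplicate_ids, replace=False)
    return ids + [ids[int(j)] for j in dup_of]


def gen_ped(
    path: str | os.PathLike,
    snps: list[SnpRecord],
    n_samples: int,
    maf_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    nocall_rate: float = 0.0,
    n_duplicate_ids: int = 0,
    seed: int = 0,
) -> list[str]:
    """Write a ped file matching ``snps``; returns the sample IDs in order.

    The last ``n_duplicate_ids`` rows reuse earlier sample IDs (fresh
    genotypes — re-genotyped samples, not copies).
    """
    if not 0.0 <= nocall_rate <= 1.0:
        raise DomainError(f"nocall_rate {nocall_rate} outside [0, 1]")
    rng = np.random.default_rng(seed)
    if maf_dist is None:
        maf_dist = _default_maf_dist
    n_snps = len(snps)
    maf = np.asarray(maf_dist(rng, n_snps), dtype=np.float64)
    ids = _sample_ids(rng, n_samples, n_duplicate_ids)
    a1 = np.array([s.coding.allele1 for s in snps], dtype=object)
    a2 = np.array([s.coding.allele2 for s in snps], dtype=object)
    # per-SNP decoded pair strings per code
    lut = np.empty((n_snps, 4), dtype=object)
    lut[:, 0] = a1 + " " + a1
    lut[:, 1] = a1 + " " + a2
    lut[:, 2] = "0 0"
    lut[:, 3] = a2 + " " + a2
    col = np.arange(n_snps)
    with open(path, "w") as fh:
        for i, sid in enumerate(ids):
            codes = hw_codes(rng, maf, 1, nocall_rate)[0]
            geno = " ".join(lut[col, codes].tolist())
            fh.write(f"{sid} {sid} 0 0 0 -9 {geno}\n")
    return ids


def gen_study(
    store: SnpStore,
    panel_name: str,
    n_snps: int,
    n_samples: int,
    chromosomes: list[tuple[str, int]] | None = None,
    maf_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    nocall_rate: float = 0.01,
    n_duplicate_ids: int = 0,
    seed: int = 0,
    chunk: int = 64,
    bad_sample_frac: float = 0.0,
    bad_sample_rate: float = 0.08,
    bad_snp_frac: float = 0.0,
    bad_snp_rate: float = 0.06,
) -> str:
    """Generate and bulk-import a whole genotyping campaign into ``store``.

    The in-memory path for panel sizes where ped text files are impractical:
    the panel map goes in directly, genotype codes are drawn per chunk of
    samples, packed and inserted, and the usual import bookkeeping
    (is/ss/gs) is created.  Returns the import genotype set name.

    ``bad_sample_frac`` / ``bad_snp_frac`` optionally make a fraction of
    genotyping runs and assays fail at elevated missingness rates
    (``bad_sample_rate`` / ``bad_snp_rate``), emulating the low-quality
    records that call-rate QC exists to remove; the default is homogeneous
    missingness at ``nocall_rate``.
    """
    rng = np.random.default_rng(seed)
    if chromosomes is None:
        chromosomes = [("1", n_snps)]
    if maf_dist is None:
        maf_dist = _default_maf_dist
    records = []
    i = 0
    for label, count in chromosomes:
        pos = np.cumsum(rng.integers(1, 10_000, size=count))
        for p in pos:
            records.append(
                SnpRecord(
                    chromosome=label,
                    snp_name=f"snp{i:07d}",
                    position_bp=int(p),
                    coding=AllelePair("A", "B"),
                    vector_index=i,
                )
            )
            i += 1
    store.add_panel(panel_name, records)
    maf = np.asarray(maf_dist(rng, n_snps), dtype=np.float64)
    ids = _sample_ids(rng, n_samples, n_duplicate_ids)
    bad_rows = (
        set(
            rng.choice(
                n_samples, size=round(bad_sample_frac * n_samples), replace=False
            ).tolist()
        )
        if bad_sample_frac > 0
        else set()
    )
    bad_cols = (
        rng.choice(n_snps, size=round(bad_snp_frac * n_snps), replace=False)
        if bad_snp_frac > 0
        else np.empty(0, dtype=np.int64)
    )

    def _records():
        for start in range(0, n_samples, chunk):
            part = ids[start : start + chunk]
            codes = hw_codes(rng, maf, len(part), nocall_rate)
            if bad_cols.size:
                extra = rng.random((len(part), bad_cols.size)) < bad_snp_rate
                block = codes[:, bad_cols]
                block[extra] = 2
                codes[:, bad_cols] = block
            for j, sid in enumerate(part):
                if (start + j) in bad_rows:
                    codes[j, rng.random(n_snps) < bad_sample_rate] = 2
                yield sid, codec.pack_payload(codes[j])

    return ingest.import_code_matrix(
        store,
        panel_name,
        _records(),
        source=f"synthetic study seed={seed}",
    )


def gen_qc_campaign(store: SnpStore, seed: int = 0) -> str:
    """The reference large-scale QC study: one high-density livestock panel.

    580,961 SNPs of which 14 sit on the avian W chromosome, 5498 genotype
    records of which 11 are re-genotypings of already-seen sample IDs, 1%
    baseline missingness with 1% of genotyping runs failing at ~8%
    missingness and 0.5% of assays failing at ~6%.  Returns the import
    genotype set, ready for the duplicate / chromosome / call-rate / MAF
    filter chain.
    """
    return gen_study(
        store,
        "hd_panel",
        n_snps=580_961,
        n_samples=5498,
        chromosomes=[("1", 580_961 - 14), ("W", 14)],
        nocall_rate=0.01,
        n_duplicate_ids=11,
        seed=seed,
        bad_sample_frac=0.01,
        bad_snp_frac=0.005,
    )


def benchmark(
    panel_sizes: list[int],
    total_snps_per_batch: int,
    batches: int,
    seed: int = 0,
    store_path: str = ":memory:",
    export_dir: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Informational import/export throughput table (SNPs per second).

    For each panel size, ``batches`` consecutive imports of
    ``total_snps_per_batch / panel_size`` samples are timed, then one full
    export.  Rates depend on hardware and are reported, not asserted.
    """
    rows = []
    for size in panel_sizes:
        n_samples = max(1, total_snps_per_batch // size)
        with SnpStore(store_path) as store:
            name = f"bench_{size}"
            sets = []
            for b in range(batches):
                t0 = time.perf_counter()
                gs = gen_study(
                    store,
                    f"{name}_b{b}" if b else name,
                    n_snps=size,
                    n_samples=n_samples,
                    seed=seed + b,
                )
                dt = time.perf_counter() - t0
                sets.append((b, gs, f"{name}_b{b}" if b else name))
                rows.append(
                    {
                        "panel_size": size,
                        "batch": b,
                        "op": "import",
                        "n_samples": n_samples,
                        "snps": n_samples * size,
                        "seconds": dt,
                        "snps_per_sec": n_samples * size / dt if dt else np.nan,
                    }
                )
            if export_dir is not None:
                b, gs, panel = sets[0]
                prefix = os.path.join(str(export_dir), f"bench_{size}")
                t0 = time.perf_counter()
                export.export_set(store, gs, "plink", prefix)
                dt = time.perf_counter() - t0
                rows.append(
                    {
                        "panel_size": size,
                        "batch": 0,
                        "op": "export",
                        "n_samples": n_samples,
                        "snps": n_samples * size,
                        "seconds": dt,
                        "snps_per_sec": n_samples * size / dt if dt else np.nan,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "panel_size",
            "batch",
            "op",
            "n_samples",
            "snps",
            "seconds",
            "snps_per_sec",
        ],
    )
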