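"""Derived genotype sets: list-based selection and database-side filters.

Every operation here takes a parent genotype set and produces a new named
set without touching a single genotype byte: duplicates removal, chromosome
exclusion, per-sample / per-SNP no-call filtering, and a minor-allele-
frequency floor.  A dimension a filter leaves untouched is *referenced*, not
copied — removing duplicates reuses the parent's SNP selection, a chromosome
filter reuses the parent's individual selection — so a chain of five QC steps
adds a handful of small selection vectors and five one-row set definitions.

Filter conventions (documented because thresholds alone do not fix them):

* sample/SNP no-call frequencies use strict comparison — drop if
  ``freq > threshold``;
* the MAF filter drops SNPs with minor-allele frequency strictly below the
  threshold, computed over called genotypes of active samples
  (allele-1 count = 2*n0 + n1 over 2*(n0 + n1 + n3));
* a SNP with zero called genotypes fails any MAF threshold > 0 and, having
  no-call frequency 1, any SNP no-call threshold < 1;
* ``filter_nocall`` drops samples first (frequencies over the parent's
  active SNPs), then SNPs (frequencies over the retained samples);
* duplicate removal keeps each sample's earliest record (smallest record
  key, i.e. first inserted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .codec import unpack_payload
from .errors import DomainError, EmptySelectionError, UnknownEntityError
from .store import SnpStore

__all__ = [
    "SnpStats",
    "compute_snp_stats",
    "subset_by_lists",
    "remove_duplicates",
    "filter_chromosomes",
    "filter_nocall",
    "filter_maf",
    "provenance_report",
    "render_provenance",
]


@dataclass
class SnpStats:
    """Per-SNP genotype counts over the active samples of a genotype set.

    Arrays span the full panel (length ``n_snps``); positions outside the
    set's SNP selection are counted too but carry no meaning for filtering.
    ``n0``/``n1``/``n3`` are hom-allele1 / het / hom-allele2 counts, ``n2``
    the no-call count; per SNP they sum to ``n_samples``.
    """

    n0: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    n3: np.ndarray
    n_samples: int
    sample_nocall: np.ndarray  # per-sample no-call count over active SNPs
    active: np.ndarray  # the SNP-selection mask the stats were taken under

    @property
    def called(self) -> np.ndarray:
        return self.n0 + self.n1 + self.n3

    @property
    def nocall_freq(self) -> np.ndarray:
        """Per-SNP no-call frequency; 1.0 where no sample was called."""
        with np.errstate(invalid="ignore"):
            return np.where(
                self.n_samples > 0, self.n2 / max(self.n_samples, 1), 1.0
            )

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency over called alleles; NaN where none called."""
        called2 = 2.0 * self.called
        with np.errstate(invalid="ignore", divide="ignore"):
            af1 = (2.0 * self.n0 + self.n1) / called2
        maf = np.minimum(af1, 1.0 - af1)
        maf[self.called == 0] = np.nan
        return maf


def _counts_dtype(n_samples: int):
    return np.int32 if n_samples < 2**31 - 1 else np.int64


def compute_snp_stats(
    store: SnpStore, set_name: str, record_keys: np.ndarray | None = None
) -> SnpStats:
    """One pass over the set's records accumulating genotype counts.

    Each packed record is fetched from the store exactly once, unpacked with
    vectorized shifts and added to four per-SNP count arrays.  ``record_keys``
    overrides the set's individual selection (used internally to restrict to
    retained samples).
    """
    gs = store.get_genotype_set(set_name)
    ss = store.get_snp_selection(gs.snp_selection)
    if record_keys is None:
        record_keys = store.get_individual_selection(
            gs.individual_selection
        ).record_keys
    n_snps = ss.bits.size
    dt = _counts_dtype(record_keys.size)
    n0 = np.zeros(n_snps, dtype=dt)
    n1 = np.zeros(n_snps, dtype=dt)
    n2 = np.zeros(n_snps, dtype=dt)
    n3 = np.zeros(n_snps, dtype=dt)
    active = ss.bits
    sample_nocall = np.zeros(record_keys.size, dtype=np.int64)
    for i, (_, payload) in enumerate(store.iter_record_payloads(record_keys)):
        codes = unpack_payload(payload, n_snps)
        is0 = codes == 0
        is1 = codes == 1
        is2 = codes == 2
        n0 += is0
        n1 += is1
        n2 += is2
        n3 += ~(is0 | is1 | is2)
        sample_nocall[i] = np.count_nonzero(is2 & active)
    return SnpStats(
        n0=n0,
        n1=n1,
        n2=n2,
        n3=n3,
        n_samples=int(record_keys.size),
        sample_nocall=sample_nocall,
        active=active.copy(),
    )


def _parent_parts(store: SnpStore, parent_set: str):
    gs = store.get_genotype_set(parent_set)
    ss = store.get_snp_selection(gs.snp_selection)
    isel = store.get_individual_selection(gs.individual_selection)
    return gs, ss, isel


def subset_by_lists(
    store: SnpStore,
    parent_set: str,
    sample_keep: list[str] | None = None,
    snp_flags: dict[str, int] | set[str] | None = None,
    comment: str | None = None,
) -> str:
    """New set from explicit sample and/or SNP lists.

    ``sample_keep`` names the external sample IDs to retain (parent order is
    preserved); ``snp_flags`` is either a set of SNP names to keep or a
    name→{0,1} mapping whose 0-flagged SNPs are dropped.  Identifiers absent
    from the parent raise with the full offender list.
    """
    if sample_keep is None and snp_flags is None:
        raise DomainError("subset_by_lists needs at least one list")
    gs, ss, isel = _parent_parts(store, parent_set)
    with store.transaction():
        new_ss_name, new_is_name = gs.snp_selection, gs.individual_selection
        if sample_keep is not None:
            ids = store.record_sample_ids(isel.record_keys)
            present = set(ids)
            missing = [s for s in sample_keep if s not in present]
            if missing:
                raise UnknownEntityError(
                    f"sample IDs not in {parent_set}: {sorted(missing)}"
                )
            keep = set(sample_keep)
            kept = isel.record_keys[[s in keep for s in ids]]
            if kept.size == 0:
                raise EmptySelectionError(
                    "sample list leaves no samples in the subset"
                )
            new_is_name = store.create_individual_selection(
                isel.panel_name,
                kept,
                source=f"list: {len(keep)} samples on {parent_set}",
                parent=isel.name,
            )
        if snp_flags is not None:
            snp_table = store.get_snp_table(ss.panel_name)
            name_to_idx = {
                n: i for i, n in enumerate(snp_table["snp_name"].to_numpy())
            }
            if isinstance(snp_flags, set):
                snp_flags = {n: 1 for n in snp_flags}
            missing = [n for n in snp_flags if n not in name_to_idx]
            if missing:
                raise UnknownEntityError(
                    f"SNP names not on panel {ss.panel_name!r}: "
                    f"{sorted(missing)[:10]}"
                )
            flags = np.zeros(ss.bits.size, dtype=bool)
            for n, f in snp_flags.items():
                flags[name_to_idx[n]] = bool(f)
            bits = ss.bits & flags
            if not bits.any():
                raise EmptySelectionError(
                    "SNP list leaves no active SNPs in the subset"
                )
            new_ss_name = store.create_snp_selection(
                ss.panel_name,
                bits,
                source=f"list: {int(bits.sum())} SNPs on {parent_set}",
                parent=ss.name,
            )
        new_gs = store.create_genotype_set(
            new_ss_name, new_is_name, comment=comment
        )
    return new_gs


def remove_duplicates(store: SnpStore, parent_set: str) -> str:
    """Keep exactly one genotype record per sample ID (the earliest).

    The SNP selection is inherited from the parent by reference.  With no
    duplicates present the key list is copied unchanged — still a new named
    selection and set, so the operation always leaves a provenance row.
    """
    gs, ss, isel = _parent_parts(store, parent_set)
    ids = store.record_sample_ids(isel.record_keys)
    best: dict[str, int] = {}
    for key, sid in zip(isel.record_keys, ids):
        if sid not in best or key < best[sid]:
            best[sid] = int(key)
    chosen = set(best.values())
    kept = np.array(
        [k for k in isel.record_keys if int(k) in chosen], dtype=np.int64
    )
    with store.transaction():
        new_is = store.create_individual_selection(
            isel.panel_name,
            kept,
            source=f"dedup on {parent_set}",
            parent=isel.name,
        )
        return store.create_genotype_set(gs.snp_selection, new_is)


def filter_chromosomes(
    store: SnpStore, parent_set: str, exclude: list[str]
) -> str:
    """Zero the SNP-selection bits of SNPs on the excluded chromosomes."""
    gs, ss, isel = _parent_parts(store, parent_set)
    snp_table = store.get_snp_table(ss.panel_name)
    chroms = snp_table["chromosome"].to_numpy(dtype="U16")
    present = set(np.unique(chroms))
    absent = [c for c in exclude if c not in present]
    if absent:
        warnings.warn(
            f"chromosomes {absent} not present on panel {ss.panel_name!r}",
            stacklevel=2,
        )
    drop = np.isin(chroms, list(exclude))
    bits = ss.bits & ~drop
    if not bits.any():
        raise EmptySelectionError(
            "excluding these chromosomes would leave no active SNPs"
        )
    with store.transaction():
        new_ss = store.create_snp_selection(
            ss.panel_name,
            bits,
            source=f"chromosomes: exclude {','.join(exclude)} on {parent_set}",
            parent=ss.name,
        )
        return store.create_genotype_set(new_ss, gs.individual_selection)


def filter_nocall(
    store: SnpStore,
    parent_set: str,
    sample_threshold: float | None = None,
    snp_threshold: float | None = None,
) -> str:
    """Drop high-missingness samples, then high-missingness SNPs.

    Sample no-call frequencies are taken over the parent's active SNPs;
    SNP frequencies over the samples that survive the first step.  Both
    comparisons are strict (drop if frequency > threshold).
    """
    if sample_threshold is None and snp_threshold is None:
        raise DomainError("filter_nocall needs at least one threshold")
    for t in (sample_threshold, snp_threshold):
        if t is not None and not (0.0 <= t <= 1.0):
            raise DomainError(f"no-call threshold {t} outside [0, 1]")
    gs, ss, isel = _parent_parts(store, parent_set)
    stats = compute_snp_stats(store, parent_set)
    n_active = int(ss.bits.sum())

    keys = isel.record_keys
    if sample_threshold is not None and n_active > 0:
        freq = stats.sample_nocall / n_active
        keep_mask = ~(freq > sample_threshold)
        kept = keys[keep_mask]
    else:
        keep_mask = np.ones(keys.size, dtype=bool)
        kept = keys
    if kept.size == 0:
        raise EmptySelectionError(
            f"sample no-call threshold {sample_threshold} drops every sample"
        )

    bits = ss.bits
    if snp_threshold is not None:
        n2 = stats.n2.astype(np.int64)
        dropped_keys = keys[~keep_mask]
        if dropped_keys.size:
            # subtract dropped samples' contribution instead of re-scanning all
            for _, payload in store.iter_record_payloads(dropped_keys):
                codes = unpack_payload(payload, bits.size)
                n2 -= codes == 2
        n_retained = kept.size
        freq = n2 / n_retained if n_retained else np.ones_like(n2, dtype=float)
        bits = ss.bits & ~(freq > snp_threshold)
        if not bits.any():
            raise EmptySelectionError(
                f"SNP no-call threshold {snp_threshold} drops every SNP"
            )

    with store.transaction():
        new_is_name = gs.individual_selection
        if sample_threshold is not None:
            new_is_name = store.create_individual_selection(
                isel.panel_name,
                kept,
                source=f"nocall: is {sample_threshold} on {parent_set}",
                parent=isel.name,
            )
        new_ss_name = gs.snp_selection
        if snp_threshold is not None:
            new_ss_name = store.create_snp_selection(
                ss.panel_name,
                bits,
                source=f"nocall: ss {snp_threshold} on {parent_set}",
                parent=ss.name,
            )
        return store.create_genotype_set(new_ss_name, new_is_name)


def filter_maf(store: SnpStore, parent_set: str, threshold: float) -> str:
    """Drop active SNPs whose minor-allele frequency is below ``threshold``.

    Frequencies are computed over called genotypes of the set's samples.
    Chainable: applying 0.03 then 0.05 equals applying 0.05 directly on the
    same sample set.  All-no-call SNPs fail any threshold > 0.
    """
    if not (0.0 <= threshold <= 0.5):
        raise DomainError(f"MAF threshold {threshold} outside [0, 0.5]")
    gs, ss, isel = _parent_parts(store, parent_set)
    stats = compute_snp_stats(store, parent_set)
    maf = stats.maf
    with np.errstate(invalid="ignore"):
        fail = maf < threshold
    if threshold > 0:
        fail |= stats.called == 0
    bits = ss.bits & ~fail
    if not bits.any():
        raise EmptySelectionError(
            f"MAF threshold {threshold} drops every active SNP"
        )
    with store.transaction():
        new_ss = store.create_snp_selection(
            ss.panel_name,
            bits,
            source=f"maf: {threshold} on {parent_set}",
            parent=ss.name,
        )
        return store.create_genotype_set(new_ss, gs.individual_selection)


@dataclass
class ProvenanceRow:
    set_name: str
    snp_selection: str
    individual_selection: str
    n_samples: int
    n_active_snps: int
    panel_name: str
    depth: int
    source: str
    comment: str | None
    created_at: str


def _chain_depth(store: SnpStore, kind: str, name: str) -> int:
    getter = (
        store.get_snp_selection if kind == "ss" else store.get_individual_selection
    )
    depth = 0
    seen = {name}
    node = getter(name)
    while node.parent is not None:
        if node.parent in seen:  # cycle guard; validator would flag this
            break
        seen.add(node.parent)
        node = getter(node.parent)
        depth += 1
    return depth


def provenance_report(
    store: SnpStore, root: str | None = None
) -> list[ProvenanceRow]:
    """All genotype sets with counts, lineage depth and Source text.

    Depth is the longer of the two selection parent chains, which reproduces
    the indented hierarchical listing of chained QC workflows.
    """
    rows: list[ProvenanceRow] = []
    for gs in store.list_genotype_sets():
        ss = store.get_snp_selection(gs.snp_selection)
        isel = store.get_individual_selection(gs.individual_selection)
        depth = max(
            _chain_depth(store, "ss", ss.name),
            _chain_depth(store, "is", isel.name),
        )
        sources = []
        for sel in (isel, ss):
            if sel.source and sel.source not in sources:
                sources.append(sel.source)
        rows.append(
            ProvenanceRow(
                set_name=gs.name,
                snp_selection=ss.name,
                individual_selection=isel.name,
                n_samples=isel.n_keys,
                n_active_snps=ss.n_active,
                panel_name=ss.panel_name,
                depth=depth,
                source="; ".join(sources),
                comment=store.get_comment(gs.name) or gs.comment,
                created_at=gs.created_at,
            )
        )
    if root is not None:
        wanted = {root}
        # keep sets whose selections descend from the root set's selections
        root_gs = store.get_genotype_set(root)
        keep_ss = {root_gs.snp_selection}
        keep_is = {root_gs.individual_selection}
        changed = True
        while changed:
            changed = False
            for gs in store.list_genotype_sets():
                ss = store.get_snp_selection(gs.snp_selection)
                isel = store.get_individual_selection(gs.individual_selection)
                hit = (
                    gs.snp_selection in keep_ss
                    or gs.individual_selection in keep_is
                    or (ss.parent in keep_ss if ss.parent else False)
                    or (isel.parent in keep_is if isel.parent else False)
                )
                if hit and gs.name not in wanted:
                    wanted.add(gs.name)
                    changed = True
                if hit:
                    if gs.snp_selection not in keep_ss:
                        keep_ss.add(gs.snp_selection)
                        changed = True
                    if gs.individual_selection not in keep_is:
                        keep_is.add(gs.individual_selection)
                        changed = True
        rows = [r for r in rows if r.set_name in wanted]
    return rows


def render_provenance(rows: list[ProvenanceRow]) -> str:
    """Console rendering: indentation shows the derivation hierarchy."""
    lines = []
    for r in rows:
        pad = "  " * r.depth
        comment = f"  # {r.comment}" if r.comment else ""
        lines.append(
            f"{pad}{r.set_name}  ({r.individual_selection} x "
            f"{r.snp_selection})  samples={r.n_samples}  "
            f"snps={r.n_active_snps}  Source: {r.source}{comment}"
        )
    return "\n".join(lines)
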