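"""Subset engine: list subsets, QC filters, provenance, oracle equivalence.

The brute-force oracle works on the dense uint8 code matrix directly and is
shared with the acceptance suite via the module-level functions below.
"""

import numpy as np
import pytest

from snpvault import subsets
from snpvault.errors import (
    DomainError,
    EmptySelectionError,
    UnknownEntityError,
)
from snpvault.store import SnpStore

from conftest import import_matrix, make_snps

# ---------------------------------------------------------------- oracles


def oracle_sample_nocall(codes, active):
    """Per-sample no-call frequency over active SNPs (dense loop)."""
    out = []
    for row in codes:
        vals = [row[j] for j in range(len(row)) if active[j]]
        out.append(sum(v == 2 for v in vals) / len(vals))
    return np.array(out)


def oracle_snp_nocall(codes, sample_mask):
    rows = codes[sample_mask]
    return np.array(
        [sum(v == 2 for v in rows[:, j]) / max(len(rows), 1) for j in range(codes.shape[1])]
    )


def oracle_maf(codes, sample_mask):
    """Per-SNP minor-allele frequency over called genotypes; NaN if none."""
    rows = codes[sample_mask]
    out = []
    for j in range(codes.shape[1]):
        col = rows[:, j]
        n0 = int((col == 0).sum())
        n1 = int((col == 1).sum())
        n3 = int((col == 3).sum())
        called = n0 + n1 + n3
        if called == 0:
            out.append(np.nan)
            continue
        af1 = (2 * n0 + n1) / (2 * called)
        out.append(min(af1, 1 - af1))
    return np.array(out)


def oracle_filter_nocall(codes, active, sample_thr, snp_thr):
    """Returns (kept sample indices, surviving active mask)."""
    n = codes.shape[0]
    if sample_thr is not None:
        freq = oracle_sample_nocall(codes, active)
        keep_samples = np.array([freq[i] <= sample_thr for i in range(n)])
    else:
        keep_samples = np.ones(n, dtype=bool)
    bits = active.copy()
    if snp_thr is not None:
        freq = oracle_snp_nocall(codes, keep_samples)
        bits = active & ~(freq > snp_thr)
    return np.flatnonzero(keep_samples), bits


def oracle_filter_maf(codes, active, sample_mask, thr):
    maf = oracle_maf(codes, sample_mask)
    fail = np.zeros(len(maf), dtype=bool)
    for j, m in enumerate(maf):
        if np.isnan(m):
            fail[j] = thr > 0
        else:
            fail[j] = m < thr
    return active & ~fail


def set_state(store, gs_name):
    """(record keys, active mask) of a genotype set."""
    gs = store.get_genotype_set(gs_name)
    return (
        store.get_individual_selection(gs.individual_selection).record_keys,
        store.get_snp_selection(gs.snp_selection).bits,
    )


# ---------------------------------------------------------------- unit tests


class TestSubsetByLists:
    def test_classic_three_by_four(self, store):
        """Samples 23, 25, 35 and SNPs 3, 4, 6, 8 out of an 8-SNP panel."""
        store.add_panel("panel 1", make_snps(8))
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 4, size=(5, 8)).astype(np.uint8)
        gs = import_matrix(store, "panel 1", ["23", "25", "31", "35", "44"], codes)
        sub = subsets.subset_by_lists(
            store,
            gs,
            sample_keep=["23", "25", "35"],
            snp_flags={"snp3", "snp4", "snp6", "snp8"},
        )
        keys, bits = set_state(store, sub)
        assert store.record_sample_ids(keys) == ["23", "25", "35"]
        assert np.flatnonzero(bits).tolist() == [2, 3, 5, 7]

    def test_keep_all_is_identity(self, imported_set):
        store, gs, _ = imported_set
        sub = subsets.subset_by_lists(
            store,
            gs,
            sample_keep=["a", "b", "c", "d", "e"],
            snp_flags={f"snp{i}" for i in range(1, 9)},
        )
        k0, b0 = set_state(store, gs)
        k1, b1 = set_state(store, sub)
        assert k0.tolist() == k1.tolist()
        assert b0.tolist() == b1.tolist()

    def test_unknown_sample_listed(self, imported_set):
        store, gs, _ = imported_set
        with pytest.raises(UnknownEntityError, match="zz"):
            subsets.subset_by_lists(store, gs, sample_keep=["a", "zz"])

    def test_unknown_snp_listed(self, imported_set):
        store, gs, _ = imported_set
        with pytest.raises(UnknownEntityError, match="snpX"):
            subsets.subset_by_lists(store, gs, snp_flags={"snpX"})

    def test_needs_a_list(self, imported_set):
        store, gs, _ = imported_set
        with pytest.raises(DomainError):
            subsets.subset_by_lists(store, gs)

    def test_only_snp_list_reuses_individual_selection(self, imported_set):
        store, gs, _ = imported_set
        sub = subsets.subset_by_lists(store, gs, snp_flags={"snp1"})
        assert (
            store.get_genotype_set(sub).individual_selection
            == store.get_genotype_set(gs).individual_selection
        )


class TestRemoveDuplicates:
    def test_keeps_earliest_record(self, store):
        store.add_panel("p", make_snps(4))
        gs = import_matrix(
            store, "p", ["a", "b", "a", "c", "a"],
            np.zeros((5, 4), dtype=np.uint8),
        )
        sub = subsets.remove_duplicates(store, gs)
        keys, _ = set_state(store, sub)
        parent_keys, _ = set_state(store, gs)
        assert keys.tolist() == [parent_keys[0], parent_keys[1], parent_keys[3]]

    def test_no_duplicates_still_new_set(self, imported_set):
        store, gs, _ = imported_set
        sub = subsets.remove_duplicates(store, gs)
        assert sub != gs
        k0, _ = set_state(store, gs)
        k1, _ = set_state(store, sub)
        assert k0.tolist() == k1.tolist()

    def test_snp_selection_inherited_by_reference(self, imported_set):
        store, gs, _ = imported_set
        sub = subsets.remove_duplicates(store, gs)
        assert (
            store.get_genotype_set(sub).snp_selection
            == store.get_genotype_set(gs).snp_selection
        )


class TestFilterChromosomes:
    def test_excludes_w(self, imported_set):
        store, gs, _ = imported_set  # SNPs 7, 8 sit on W
        sub = subsets.filter_chromosomes(store, gs, ["W"])
        _, bits = set_state(store, sub)
        assert np.flatnonzero(bits).tolist() == [0, 1, 2, 3, 4, 5]

    def test_absent_chromosome_warns_identity(self, imported_set):
        store, gs, _ = imported_set
        with pytest.warns(UserWarning, match="XYZ"):
            sub = subsets.filter_chromosomes(store, gs, ["XYZ"])
        _, bits = set_state(store, sub)
        assert bits.all()

    def test_excluding_everything_refused(self, imported_set):
        store, gs, _ = imported_set
        with pytest.raises(EmptySelectionError):
            subsets.filter_chromosomes(store, gs, ["1", "W"])


class TestFilterNocall:
    def test_sample_with_one_eighth_missing_dropped_at_05(self, store):
        store.add_panel("p", make_snps(8))
        codes = np.zeros((3, 8), dtype=np.uint8)
        codes[1, 0] = 2  # 1 of 8 missing = 0.125 > 0.05
        gs = import_matrix(store, "p", ["a", "b", "c"], codes)
        sub = subsets.filter_nocall(store, gs, sample_threshold=0.05)
        keys, _ = set_state(store, sub)
        assert store.record_sample_ids(keys) == ["a", "c"]

    def test_thresholds_one_remove_nothing(self, imported_set):
        store, gs, codes = imported_set
        sub = subsets.filter_nocall(store, gs, 1.0, 1.0)
        k0, b0 = set_state(store, gs)
        k1, b1 = set_state(store, sub)
        assert k0.tolist() == k1.tolist() and b0.tolist() == b1.tolist()

    def test_snp_frequencies_use_retained_samples_only(self, store):
        store.add_panel("p", make_snps(4))
        codes = np.array(
            [
                [2, 2, 2, 2],  # dropped by the sample filter
                [0, 2, 0, 0],
                [0, 2, 0, 0],
            ],
            dtype=np.uint8,
        )
        gs = import_matrix(store, "p", ["a", "b", "c"], codes)
        sub = subsets.filter_nocall(store, gs, sample_threshold=0.5, snp_threshold=0.5)
        keys, bits = set_state(store, sub)
        assert store.record_sample_ids(keys) == ["b", "c"]
        # snp2 is missing in all retained samples -> dropped; others kept
        assert bits.tolist() == [True, False, True, True]

    def test_needs_a_threshold(self, imported_set):
        store, gs, _ = imported_set
        with pytest.raises(DomainError):
            subsets.filter_nocall(store, gs)


class TestFilterMaf:
    def test_counting_rule(self, store):
        # codes [0,0,0,1]: allele2 freq = 1/8 = 0.125
        store.add_panel("p", make_snps(2))
        codes = np.array([[0, 0], [0, 0], [0, 0], [1, 0]], dtype=np.uint8)
        gs = import_matrix(store, "p", list("abcd"), codes)
        kept_at_03 = subsets.filter_maf(store, gs, 0.03)
        _, bits = set_state(store, kept_at_03)
        assert bits.tolist() == [True, False]  # snp2 monomorphic, maf 0 < .03
        with pytest.raises(EmptySelectionError):
            # 0.2 kills snp1 too (0.125 < 0.2) and snp2 is already failing
            subsets.filter_maf(store, gs, 0.2)

    def test_threshold_zero_removes_nothing(self, imported_set):
        store, gs, _ = imported_set
        sub = subsets.filter_maf(store, gs, 0.0)
        _, b0 = set_state(store, gs)
        _, b1 = set_state(store, sub)
        assert b0.tolist() == b1.tolist()

    def test_all_nocall_snp_dropped(self, store):
        store.add_panel("p", make_snps(2))
        codes = np.array([[2, 1], [2, 1], [2, 1]], dtype=np.uint8)
        gs = import_matrix(store, "p", list("abc"), codes)
        sub = subsets.filter_maf(store, gs, 0.05)
        _, bits = set_state(store, sub)
        assert bits.tolist() == [False, True]

    def test_domain(self, imported_set):
        store, gs, _ = imported_set
        with pytest.raises(DomainError):
            subsets.filter_maf(store, gs, 0.6)

    def test_chaining_equals_direct(self, store):
        rng = np.random.default_rng(123)
        store.add_panel("p", make_snps(60))
        codes = rng.choice(
            [0, 1, 2, 3], p=[0.5, 0.25, 0.05, 0.2], size=(30, 60)
        ).astype(np.uint8)
        gs = import_matrix(store, "p", [f"s{i}" for i in range(30)], codes)
        chained = subsets.filter_maf(store, subsets.filter_maf(store, gs, 0.03), 0.05)
        direct = subsets.filter_maf(store, gs, 0.05)
        _, b1 = set_state(store, chained)
        _, b2 = set_state(store, direct)
        assert b1.tolist() == b2.tolist()


class TestProvenance:
    def test_import_only(self, imported_set):
        store, gs, _ = imported_set
        rows = subsets.provenance_report(store)
        assert len(rows) == 1
        assert rows[0].set_name == "gs_001"
        assert (rows[0].individual_selection, rows[0].snp_selection) == (
            "is_001",
            "ss_001",
        )
        assert rows[0].depth == 0

    def test_chain_monotone_and_indented(self, imported_set):
        store, gs, _ = imported_set
        g2 = subsets.remove_duplicates(store, gs)
        g3 = subsets.filter_chromosomes(store, g2, ["W"])
        g4 = subsets.filter_nocall(store, g3, 0.9, 0.9)
        g5 = subsets.filter_maf(store, g4, 0.01)
        rows = subsets.provenance_report(store)
        assert [r.set_name for r in rows] == [gs, g2, g3, g4, g5]
        for earlier, later in zip(rows, rows[1:]):
            assert later.n_samples <= earlier.n_samples
            assert later.n_active_snps <= earlier.n_active_snps
            assert later.depth >= earlier.depth
        text = subsets.render_provenance(rows)
        assert "maf: 0.01" in text and "dedup" in text

    def test_empty_store(self, store):
        assert subsets.provenance_report(store) == []

    def test_sources_name_parent_set(self, imported_set):
        store, gs, _ = imported_set
        g2 = subsets.filter_maf(store, gs, 0.01)
        row = [r for r in subsets.provenance_report(store) if r.set_name == g2][0]
        assert gs in row.source


class TestZeroCopy:
    def test_payload_untouched_by_any_subset(self, imported_set):
        store, gs, _ = imported_set
        before = store.storage_report()["genotype_data"]
        subsets.remove_duplicates(store, gs)
        subsets.filter_chromosomes(store, gs, ["W"])
        subsets.filter_maf(store, gs, 0.0)
        subsets.subset_by_lists(store, gs, sample_keep=["a", "b"])
        after = store.storage_report()["genotype_data"]
        assert after == before


# ------------------------------------------------------- oracle equivalence


@pytest.mark.parametrize("trial", range(20))
def test_filters_match_dense_oracle(trial):
    """Store-side filters agree with the dense brute-force implementation on
    random matrices (the acceptance suite runs many more trials)."""
    rng = np.random.default_rng(1000 + trial)
    n, m = int(rng.integers(4, 30)), int(rng.integers(5, 60))
    codes = rng.choice([0, 1, 2, 3], p=[0.4, 0.2, 0.15, 0.25], size=(n, m)).astype(
        np.uint8
    )
    with SnpStore(":memory:") as store:
        store.add_panel(
            "p", make_snps(m, chrom_of=lambda i: str(i % 3 + 1))
        )
        n_dup = int(rng.integers(0, max(1, n // 3)))
        ids = [f"s{i}" for i in range(n - n_dup)]
        ids += [ids[int(j)] for j in rng.choice(len(ids), n_dup, replace=False)]
        gs = import_matrix(store, "p", ids, codes)
        parent_keys, active = set_state(store, gs)

        # remove_duplicates
        sub = subsets.remove_duplicates(store, gs)
        keys, _ = set_state(store, sub)
        seen, expect = set(), []
        for k, sid in zip(parent_keys, ids):
            if sid not in seen:
                seen.add(sid)
                expect.append(k)
        assert keys.tolist() == expect

        # filter_chromosomes
        sub = subsets.filter_chromosomes(store, gs, ["2"])
        _, bits = set_state(store, sub)
        expect_bits = active & np.array(
            [str(i % 3 + 1) != "2" for i in range(m)]
        )
        assert bits.tolist() == expect_bits.tolist()

        # filter_nocall
        s_thr = float(rng.choice([0.05, 0.1, 0.2, 0.5]))
        g_thr = float(rng.choice([0.05, 0.1, 0.2, 0.5]))
        try:
            sub = subsets.filter_nocall(store, gs, s_thr, g_thr)
        except EmptySelectionError:
            kept_idx, bits_oracle = oracle_filter_nocall(
                codes, active, s_thr, g_thr
            )
            assert kept_idx.size == 0 or not bits_oracle.any()
        else:
            keys, bits = set_state(store, sub)
            kept_idx, bits_oracle = oracle_filter_nocall(
                codes, active, s_thr, g_thr
            )
            assert keys.tolist() == parent_keys[kept_idx].tolist()
            assert bits.tolist() == bits_oracle.tolist()

        # filter_maf
        thr = float(rng.choice([0.0, 0.03, 0.05, 0.2]))
        try:
            sub = subsets.filter_maf(store, gs, thr)
        except EmptySelectionError:
            assert not oracle_filter_maf(
                codes, active, np.ones(n, bool), thr
            ).any()
        else:
            _, bits = set_state(store, sub)
            expect_bits = oracle_filter_maf(codes, active, np.ones(n, bool), thr)
            assert bits.tolist() == expect_bits.tolist()
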