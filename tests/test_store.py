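"""Datastore: schema round trips, duplicates, deletes, storage accounting."""

import numpy as np
import pytest

from snpvault import codec
from snpvault.errors import (
    DependentEntityError,
    DomainError,
    DuplicateEntityError,
    StoreError,
    UnknownEntityError,
)
from snpvault.store import SnpStore, init_store

from conftest import make_snps


class TestLifecycle:
    def test_init_empty(self, tmp_path):
        with init_store(tmp_path / "v.db") as s:
            assert s.list_panels() == []
            rep = s.storage_report()
            assert rep["total"] == {"rows": 0, "bytes": 0}

    def test_reopen_preserves_content(self, tmp_path):
        path = tmp_path / "v.db"
        with init_store(path) as s:
            s.add_panel("p", make_snps(8))
            s.add_genotype_record("23", "p", [0, 1, 2, 3, 0, 1, 2, 3])
        with init_store(path) as s:
            assert s.get_panel("p").size == 8
            sid, panel, packed = s.get_record(1)
            assert (sid, panel) == ("23", "p")
            assert codec.unpack_codes(packed).tolist() == [0, 1, 2, 3, 0, 1, 2, 3]

    def test_unwritable_path(self):
        with pytest.raises(StoreError):
            SnpStore("/nonexistent-dir-xyz/v.db")

    def test_schema_version_mismatch(self, tmp_path):
        path = tmp_path / "v.db"
        with init_store(path) as s:
            s.connection.execute(
                "UPDATE meta SET value='999' WHERE key='schema_version'"
            )
            s.connection.commit()
        with pytest.raises(StoreError, match="schema version"):
            SnpStore(path)


class TestPanels:
    def test_sizes_and_order(self, two_panel_store):
        s = two_panel_store
        assert s.get_panel("panel 1").size == 8
        assert s.get_panel("panel 2").size == 4
        df = s.get_snp_table("panel 1")
        assert df["snp_name"].tolist() == [f"snp{i}" for i in range(1, 9)]
        assert df["vector_index"].tolist() == list(range(8))

    def test_duplicate_panel_name(self, two_panel_store):
        with pytest.raises(DuplicateEntityError):
            two_panel_store.add_panel("panel 1", make_snps(3))

    def test_duplicate_snp_name_in_map(self, store):
        snps = make_snps(3)
        snps[2] = snps[0]
        with pytest.raises(DuplicateEntityError):
            store.add_panel("p", snps)

    def test_unknown_panel(self, store):
        with pytest.raises(UnknownEntityError):
            store.get_panel("nope")


class TestGenotypeRecords:
    def test_new_sample_creates_individual(self, store):
        store.add_panel("p", make_snps(4))
        store.add_genotype_record("23", "p", [0, 1, 2, 3])
        n = store.connection.execute(
            "SELECT COUNT(*) FROM individual"
        ).fetchone()[0]
        assert n == 1

    def test_duplicate_record_same_individual(self, store):
        store.add_panel("p", make_snps(4))
        k1 = store.add_genotype_record("23", "p", [0, 0, 0, 0])
        k2 = store.add_genotype_record("23", "p", [1, 1, 1, 1])
        assert k1 != k2
        n = store.connection.execute(
            "SELECT COUNT(*) FROM individual"
        ).fetchone()[0]
        assert n == 1

    def test_length_mismatch(self, store):
        store.add_panel("p", make_snps(8))
        with pytest.raises(DomainError):
            store.add_genotype_record("23", "p", [0] * 7)

    def test_timestamps_on_all_rows(self, two_panel_store):
        s = two_panel_store
        for table in ("panel", "individual", "genotype_data"):
            for (ts,) in s.connection.execute(f"SELECT created_at FROM {table}"):
                assert ts  # non-empty ISO timestamp


class TestDuplicateDetection:
    def test_no_repeats(self, store):
        store.add_panel("p", make_snps(2))
        store.add_genotype_record("a", "p", [0, 1])
        assert store.find_duplicate_samples("p") == []

    def test_counts(self, store):
        store.add_panel("p", make_snps(2))
        for sid in ["a", "b", "b", "c", "c", "c"]:
            store.add_genotype_record(sid, "p", [0, 1])
        assert store.find_duplicate_samples("p") == [("b", 2), ("c", 3)]

    def test_cross_panel_repeats_are_not_duplicates(self, two_panel_store):
        # 23 and 25 are genotyped on both panels but only once each per panel
        assert two_panel_store.find_duplicate_samples("panel 1") == []
        assert two_panel_store.find_duplicate_samples("panel 2") == []

    def test_unknown_panel(self, store):
        with pytest.raises(UnknownEntityError):
            store.find_duplicate_samples("nope")


def _fixture_with_sets(store):
    store.add_panel("p1", make_snps(8))
    store.add_panel("p2", make_snps(4))
    keys = [
        store.add_genotype_record(sid, "p1", [0, 1, 2, 3, 0, 1, 2, 3])
        for sid in ["a", "b", "c"]
    ]
    store.add_genotype_record("z", "p2", [0, 1, 2, 3])
    ss = store.create_snp_selection("p1", np.ones(8, bool), "s")
    isel = store.create_individual_selection("p1", keys, "s")
    gs = store.create_genotype_set(ss, isel)
    return keys, ss, isel, gs


class TestDeletes:
    def test_delete_set_keeps_selections(self, store):
        _, ss, isel, gs = _fixture_with_sets(store)
        counts = store.delete_entity("genotype_set", gs)
        assert counts == {"genotype_set": 1}
        assert store.get_snp_selection(ss).n_active == 8
        assert store.get_individual_selection(isel).n_keys == 3

    def test_delete_selection_refused_without_cascade(self, store):
        _, ss, _, gs = _fixture_with_sets(store)
        with pytest.raises(DependentEntityError) as e:
            store.delete_entity("snp_selection", ss)
        assert gs in e.value.dependents

    def test_delete_selection_cascades_to_sets(self, store):
        _, ss, isel, gs = _fixture_with_sets(store)
        counts = store.delete_entity("snp_selection", ss, cascade=True)
        assert counts["genotype_set"] == 1
        with pytest.raises(UnknownEntityError):
            store.get_genotype_set(gs)
        # individual selection untouched
        assert store.get_individual_selection(isel).n_keys == 3

    def test_delete_panel_cascades_fully(self, store):
        _fixture_with_sets(store)
        counts = store.delete_entity("panel", "p1", cascade=True)
        assert counts["genotype_data"] == 3
        assert counts["snp"] == 8
        assert counts["genotype_set"] == 1
        # panel 2 untouched
        assert store.get_panel("p2").size == 4
        assert store.get_record(4)[1] == "p2"
        assert store.validate_integrity() == []

    def test_delete_individual_prunes_selections(self, store):
        keys, ss, isel, gs = _fixture_with_sets(store)
        counts = store.delete_entity("individual", "b")
        assert counts["genotype_data"] == 1
        kept = store.get_individual_selection(isel).record_keys
        assert kept.tolist() == [keys[0], keys[2]]
        assert store.validate_integrity() == []

    def test_delete_record_prunes_selections(self, store):
        keys, _, isel, _ = _fixture_with_sets(store)
        store.delete_entity("genotype_record", str(keys[0]))
        assert store.get_individual_selection(isel).record_keys.tolist() == keys[1:]

    def test_delete_unknown(self, store):
        with pytest.raises(UnknownEntityError):
            store.delete_entity("panel", "nope")
        with pytest.raises(DomainError):
            store.delete_entity("galaxy", "nope")


class TestStorageReport:
    def test_payload_arithmetic(self, store):
        store.add_panel("p8", make_snps(8))
        store.add_panel("p4", make_snps(4))
        store.add_genotype_record("a", "p8", [0] * 8)
        store.add_genotype_record("b", "p8", [0] * 8)
        store.add_genotype_record("c", "p4", [0] * 4)
        rep = store.storage_report()
        assert rep["genotype_data"]["bytes"] == 2 * 2 + 1 * 1
        assert rep["genotype_data"]["rows"] == 3

    def test_sets_cost_no_genotype_bytes(self, store):
        keys, ss, isel, _ = _fixture_with_sets(store)
        before = store.storage_report()["genotype_data"]["bytes"]
        for _ in range(20):
            store.create_genotype_set(ss, isel)
        after = store.storage_report()["genotype_data"]["bytes"]
        assert after == before


class TestComments:
    def test_comment_round_trip(self, store):
        store.add_panel("p", make_snps(2))
        store.set_comment("p", "first")
        assert store.get_comment("p") == "first"

    def test_overwrite_keeps_history(self, store):
        store.add_panel("p", make_snps(2))
        store.set_comment("p", "first")
        store.set_comment("p", "second")
        assert store.get_comment("p") == "second"
        assert [t for t, _ in store.comment_history("p")] == ["first", "second"]

    def test_comment_on_unknown_entity(self, store):
        with pytest.raises(UnknownEntityError):
            store.set_comment("ghost", "boo")


class TestNaming:
    def test_sequential_zero_padded(self, store):
        store.add_panel("p", make_snps(2))
        names = [
            store.create_snp_selection("p", np.ones(2, bool), "s")
            for _ in range(3)
        ]
        assert names == ["ss_001", "ss_002", "ss_003"]

    def test_widens_past_999(self, store):
        store.add_panel("p", make_snps(2))
        store.connection.execute(
            "INSERT INTO snp_selection VALUES ('ss_999','p',x'03',2,2,'s',NULL,'t')"
        )
        assert store.create_snp_selection("p", np.ones(2, bool), "s") == "ss_1000"
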