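import numpy as np
import pytest

from snpvault import ingest
from snpvault.codec import AllelePair
from snpvault.store import SnpRecord, SnpStore


@pytest.fixture
def store():
    with SnpStore(":memory:") as s:
        yield s


def make_snps(n, chrom="1", coding=("A", "B"), chrom_of=None):
    """n SNPs named snp1..snpN at increasing positions."""
    return [
        SnpRecord(
            chromosome=chrom_of(i) if chrom_of else chrom,
            snp_name=f"snp{i + 1}",
            position_bp=1000 * (i + 1),
            coding=AllelePair(*coding),
            vector_index=i,
        )
        for i in range(n)
    ]


@pytest.fixture
def two_panel_store(store):
    """The two-panel toy layout: 8-SNP panel 1 and 4-SNP panel 2, with the
    classic samples 23, 25, 35 (plus two more) genotyped on panel 1."""
    store.add_panel("panel 1", make_snps(8))
    store.add_panel("panel 2", make_snps(4))
    rng = np.random.default_rng(7)
    for sid in ["23", "25", "35", "44", "51"]:
        store.add_genotype_record(
            sid, "panel 1", rng.integers(0, 4, size=8).astype(np.uint8)
        )
    for sid in ["23", "25"]:
        store.add_genotype_record(
            sid, "panel 2", rng.integers(0, 4, size=4).astype(np.uint8)
        )
    return store


def import_matrix(store, panel_name, sample_ids, codes):
    """Bulk-import a dense code matrix, returning the created set name."""
    return ingest.import_code_matrix(
        store,
        panel_name,
        ((sid, codes[i]) for i, sid in enumerate(sample_ids)),
        source="test matrix",
    )


@pytest.fixture
def imported_set(store):
    """8-SNP panel, 5 samples, deterministic codes; returns (store, gs, codes)."""
    store.add_panel("p", make_snps(8, chrom_of=lambda i: "W" if i >= 6 else "1"))
    rng = np.random.default_rng(3)
    codes = rng.integers(0, 4, size=(5, 8)).astype(np.uint8)
    gs = import_matrix(store, "p", ["a", "b", "c", "d", "e"], codes)
    return store, gs, codes
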