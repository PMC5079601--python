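# Methods

## Storage model

A biallelic SNP genotype takes one of four states, encoded as integers:
0 = homozygous allele 1, 1 = heterozygous, 2 = no-call, 3 = homozygous
allele 2.  A sample's record on a panel of *n* SNPs is a packed vector of
⌈n/4⌉ bytes.  The bit layout is fixed and documented so payloads are
byte-exact and testable: code *i* occupies bits 2·(i mod 4) .. 2·(i mod 4)+1
of byte ⌊i/4⌋, least-significant bits first; pad bits of the final byte are
zero.  Packing `[0, 1, 2, 3]` yields the single byte `0xE4`.  Packing and
unpacking are vectorized numpy shift/mask operations; SNP-selection vectors
use 1 bit per position (`np.packbits`, little-endian bit order).

The relational store is a single SQLite file.  Tables: `panel` and its
ordered `snp` map; `individual` (external ID ↔ stable integer key);
`genotype_data` (one packed BLOB per sample per import — the only table
that grows with genotype volume); `snp_selection` and
`individual_selection` (the two halves of a subset, each with `source` and
`parent` provenance columns); `genotype_set` (a named pair of selections);
`phenotype` (entity–attribute–value, uninterpreted text values); and an
append-only `comment_log`.  Every row carries a creation timestamp.  Writes
go through a re-entrant transaction helper so multi-step operations
(imports, subset creation, deletes) are atomic.

Individual selections store genotype *record* keys rather than individual
keys.  A re-genotyped sample has two records under one sample ID; an import
selection of 5498 entries with 11 repeated IDs can only be represented at
record granularity, and duplicate removal must choose between copies.  Each
key resolves to its sample ID through the `individual` table.

## Allele codings

The map's optional trailing coding column ("A B", "AB", "AT GC") fixes
which homozygote is code 0 vs 3.  When absent, the coding is inferred
during a first ped scan: allele 1 is the first-observed allele per SNP;
SNPs first seen as heterozygotes (where file order carries no information)
get lexicographic order; SNPs where only one allele is ever observed get a
`"0"` placeholder second allele and a `monomorphic` flag — a later
conflicting allele is an error, never a silent reassignment.  The inferred
coding is persisted so exports are stable across re-imports.  Heterozygotes
are written in canonical (allele1, allele2) order on export; PLINK hets are
unordered, so the round trip preserves genotypes exactly.  The missing
token is `"0"` (PLINK convention).

## Filters

All filters derive a new genotype set from a parent without touching
genotype bytes.  A dimension a filter leaves unchanged is *referenced*, not
copied: duplicate removal reuses the parent's SNP selection row, a
chromosome or MAF filter reuses the parent's individual selection row.
Conventions, since thresholds alone do not determine behaviour:

* **Duplicates** — one record per sample ID survives: the earliest
  (smallest record key, i.e. first inserted).  Repeats of an ID across
  *different* panels are not duplicates.
* **No-call** — sample frequencies are computed over the parent's active
  SNPs; samples with frequency strictly above the threshold are dropped
  first; SNP frequencies are then computed over the *retained* samples.
  Implementation detail: one counting pass accumulates both per-sample and
  per-SNP missingness over all samples, then only the dropped samples are
  re-fetched and their contribution subtracted — avoiding a second full
  scan.
* **MAF** — allele-1 frequency f₁ = (2n₀+n₁)/2(n₀+n₁+n₃) over called
  genotypes of active samples; drop where min(f₁, 1−f₁) is strictly below
  the threshold.  A SNP with zero called genotypes fails any threshold > 0
  (and, having no-call frequency 1, any SNP no-call threshold < 1).  The
  flag is a minor-allele-frequency floor — the standard QC meaning of a
  `--maf` threshold.  Filters chain: applying 0.03 then 0.05 on the same
  sample set equals applying 0.05 directly.
* **Chromosomes** — labels are text (`W`, `X`, `MT`); excluding a label not
  on the panel warns and changes nothing.

Statistics passes fetch each packed record exactly once (chunked
`SELECT ... IN`), unpack it vectorized and accumulate four per-SNP count
arrays; a 5498 × 580,961 pass takes seconds, so a five-step QC chain on
that scale completes in minutes on one core.

## Export

For each record key in individual-selection order the packed vector is
fetched once, unpacked, and the active positions (precomputed from the SNP
selection) are decoded through a per-SNP lookup table — no per-SNP queries.
Ped rows re-emit the six leading columns persisted at import (defaults
`FID=sample_id 0 0 0 -9` for data imported without them); maps are always
4-column PLINK, tab-separated, cM = 0 (original cM values are not
retained).  The `0125` format writes `sample_id<TAB><digits>` with 0/1/2
for hom-1/het/hom-2 and 5 for missing; its exact layout is this package's
own convention.  If any exported sample carries phenotypes, a companion CSV
is written with a union-of-attributes header, attributes sorted
lexicographically; absent cells are empty, and samples with no phenotypes
are omitted.

## Synthetic data

The generator emulates an unstructured genotyping campaign: per-SNP minor
allele frequencies drawn Uniform(0.05, 0.5) (the design range of array
content), genotypes under Hardy–Weinberg equilibrium at that frequency,
independent missingness at a fixed rate (default 1%, a typical array-QC
input level), and duplicates as genuine re-genotypings (fresh genotypes
under a repeated ID).  The bulk study builder can additionally fail a
fraction of genotyping runs (default in the reference campaign: 1% of
samples at ~8% missingness) and assays (0.5% of SNPs at ~6%), which is what
per-sample and per-SNP call-rate QC exists to remove.  Not modelled:
linkage disequilibrium, population structure, pedigree, batch effects,
genotyping-error correlation — so passing tests demonstrate storage,
subset and export correctness, not robustness to structured real data.

The reference QC campaign used by the tests and the acceptance script is a
580,961-SNP panel with 14 SNPs on the avian W chromosome and 5498 genotype
records of which 11 reuse earlier sample IDs; the chained
duplicate → chromosome → call-rate (.05/.03) → MAF (.03) → MAF (.05)
workflow then has exactly determined steps (5498→5487 records,
580,961→580,947 SNPs) and stochastic but monotone ones.  At this scale a
ped text file would be ~13 GB, so the campaign is imported through the
bulk array path (`ingest.import_code_matrix`), which shares the packing,
storage and bookkeeping code with the ped path; the ped path itself is
round-trip-verified at 500 samples × 10K SNPs.

## Numerical and design choices

* Strict inequalities at thresholds (drop if no-call freq > t; drop if
  MAF < t); ties therefore survive.
* Subset names `gs_/is_/ss_NNN` are sequential, zero-padded to 3 digits,
  widening past 999.
* Deleting an individual removes its records and prunes them from
  individual selections; a set whose selection becomes empty is kept but
  refuses to export.
* Map identity at data import is verified SNP-for-SNP (name, chromosome,
  bp, order); cM differences are ignored.
* Benchmark timings cover encode+pack+insert and decode+write only; map
  loading and random-data generation are one-off setup.  Absolute rates are
  hardware-bound and only reported; asserted are two scale-invariance
  properties — a chromosome subset exports faster than its full parent at
  equal sample count, and per-SNP import rate for a 100K panel is within a
  factor 3 of a 10K panel at equal total volume (10M SNPs each, sizes
  chosen to keep each timing well above clock resolution on one core).

## Limitations

SQLite serialises writers, so there is no concurrent multi-user story;
biallelic only, unphased, no dosages; no cross-panel set algebra (selections
belong to one panel); phenotype values are untyped text; storage bytes for
non-BLOB tables in reports are content-length approximations, while
genotype and selection payload bytes are exact.
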