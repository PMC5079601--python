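# snpvault

Compact relational storage, subset algebra and fast lossless PLINK export for
large-scale biallelic SNP genotype data — a library plus a `snpvault`
command-line tool.

## The problem

High-throughput genotyping produces panels of hundreds of thousands to
millions of SNPs for thousands of samples, and every analysis wants a
different slice of them: duplicates removed, a chromosome excluded, low
call-rate samples and SNPs dropped, rare variants filtered.  Modelled as the
usual one-row-per-SNP relational schema, a single 96-well plate on an 800K
array is already 76.8 million rows, and each filtered copy of the data
multiplies the files to track.  `snpvault` is a data *repository* for this
situation — it stores, subsets and exports; analysis stays in PLINK & co.

## The model

A biallelic genotype has exactly four states — hom allele 1, het, hom
allele 2, no-call — so two bits per SNP suffice.  A sample's whole record on
a panel of $n$ SNPs is one packed byte vector of $\lceil n/4 \rceil$ bytes:
an 800K record fits in 1,600,000 bits, and one megabyte holds four million
genotypes.  The map (chromosome, name, bp position, allele coding) is stored
once per panel; a SNP's identity is its vector position.

Subsets are **genotype sets**: a named pair of

* a SNP selection vector — one bit per panel position (97.7 KB for an 800K
  panel), and
* an individual selection vector — an ordered list of genotype-record keys,

so defining a subset stores two small vectors and one row, never any
genotype bytes ("zero-cost subsets").  Sets are produced by explicit
sample/SNP lists or by database-side filters — duplicate removal, chromosome
exclusion, per-sample/per-SNP no-call frequency thresholds, and a
minor-allele-frequency floor (drop SNPs with $\mathrm{MAF} < t$, where
$\mathrm{MAF} = \min(f_1, 1-f_1)$ and $f_1 = (2n_0+n_1)/2(n_0+n_1+n_3)$
over called genotypes).  Each derived selection records its parent and a
Source string, so the whole QC history is queryable.

Export walks the individual selection, fetches each packed record **once**,
scans the SNP selection vector and decodes only active positions — the cost
of exporting any subset is one sequential pass over its compressed records,
independent of panel size.  Alleles come back exactly as imported (hets in
the map's canonical order); the `0125` format writes one digit per genotype
instead (0 hom-1, 1 het, 2 hom-2, 5 missing).

## Worked example

```sh
snpvault init demo.db
python - <<'PY'
from snpvault import synth
snps = synth.gen_map("demo.map", 1000, [("1", 950), ("W", 50)], "ACGT", seed=1)
synth.gen_ped("demo.ped", snps, 100, nocall_rate=0.02, n_duplicate_ids=4, seed=2)
PY
snpvault panel add --db demo.db --map demo.map --name hd
snpvault import --db demo.db --ped demo.ped --map demo.map --panel hd
snpvault subset --db demo.db --parent gs_001 --remove-duplicates
snpvault subset --db demo.db --parent gs_002 --exclude-chr W
snpvault subset --db demo.db --parent gs_003 --maf 0.05
snpvault report --db demo.db sets
snpvault export --db demo.db --set gs_004 --format plink --out qc_ready
```

The report prints the provenance tree (indentation = derivation depth):

```
gs_001  (is_001 x ss_001)  samples=100  snps=1000  Source: import demo.ped; import demo.map
  gs_002  (is_002 x ss_001)  samples=96  snps=1000  Source: dedup on gs_001; import demo.map
  gs_003  (is_002 x ss_002)  samples=96  snps=950  Source: dedup on gs_001; chromosomes: exclude W on gs_002
    gs_004  (is_002 x ss_003)  samples=96  snps=940  Source: dedup on gs_001; maf: 0.05 on gs_003
```

and the export writes `qc_ready.ped` / `qc_ready.map` with 96 rows × 940
genotype pairs: the 4 re-genotyped IDs contribute one record each, the 50
W-chromosome SNPs are gone, and 10 SNPs fell under the 5% MAF floor.
Re-importing `qc_ready.ped` reproduces it byte for byte on export.

Everything is equally reachable as a library (`snpvault.ingest`,
`snpvault.subsets`, `snpvault.export`, …); the CLI is a thin wrapper.

## Schema

```
panel ──< snp                        (map: chromosome, name, bp, coding)
panel ──< genotype_data >── individual   (genotype_bits: 2-bit packed BLOB)
panel ──< snp_selection              (1 bit per panel position, + parent)
panel ──< individual_selection       (ordered record keys, + parent)
genotype_set = (snp_selection, individual_selection) + comment
phenotype                            (sample_id, attribute, value — EAV)
comment_log                          (append-only comment history)
```

All rows carry creation timestamps; deletes cascade (panel → records,
selections, sets; selection → referencing sets, with `--cascade`).

## Scope

Multi-allelic sites, phased genotypes, dosages, VCF, binary PLINK,
cross-panel set algebra and multi-user access control are out of scope.
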