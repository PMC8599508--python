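# egtscan

Sister-clade sorting of unrooted gene trees to separate putative
**endosymbiotic gene transfers** (EGT: eukaryote clades containing the focal
taxa that branch sister to a clade of cyanobacteria) from a background of
**horizontal gene transfers** (HGT: focal clades sister to clades of other
bacteria), plus the supporting phylogenomic-matrix and single-cell-genome QC
procedures, and a seed-deterministic simulator so every stage is verifiable
without external data.

## What is in the box

| module | what it does |
| --- | --- |
| `egtscan.taxa` | taxon annotation table (plastid-ancestry groups, focal flags, assemblies) and leaf-label resolution |
| `egtscan.genetrees` | newick I/O, unrooted topology queries: bipartitions, clades, adjacent-subtree (sister) pair enumeration |
| `egtscan.transfer_scan` | the classification rules: EGT/HGT eligibility, sister-pair sorting with a contamination allowance (default ≤ 10%), donor-purity and donor-size minima, multi-assembly monophyly, per-tree counting, EGT:HGT ratio |
| `egtscan.matrixtools` | OTU merging, gene filtering by focal occupancy, supermatrix concatenation with partitions, Fitch parsimony site rates, stepwise fast-site removal (default 5000-site steps to 55,000), chi-square compositional site trimming, two-residue signature extraction |
| `egtscan.sagqc` | contig contamination flagging (≥ 60% prokaryotic/viral-only proteins), ribotype single-linkage clustering (> 99% identity), marker completeness incl. union completeness |
| `egtscan.simulate` | simulated taxon sets, gene trees with planted EGT/HGT events + truth table, alignments with gamma-like rate variation and taxon-restricted compositional bias, sparse presence matrices |
| `egtscan.cli` | `egtscan` command-line interface and the demo pipeline |

## CLI quick start

```sh
# simulate a dataset of 200 gene trees with planted events
egtscan simulate trees --seed 1 --out demo/

# scan them for EGT and HGT events
egtscan scan --trees demo/trees --taxa demo/taxa.tsv --focal Focal \
    --mode both --out demo/scan/
cat demo/scan/summary.tsv

# or run the whole thing from one config
printf '[simulate]\nn_genes = 200\nseed = 1\n' > run.cfg
egtscan run --config run.cfg --out demo_run/
```

Other subcommands: `egtscan ratio`, `egtscan matrix
concat|merge-otus|filter-genes|sitefilter`, `egtscan qc
contigs|ribotypes|completeness`, `egtscan signature`, `egtscan simulate
alignment|presence`. Every command writes a `manifest.json` with the
parameters, config hash and seed; reruns with the same seed are
byte-identical.

## Input formats

* taxon table: TSV with header `taxon_id group focal assembly_id higher_group`;
  `group` is one of `cyanobacteria`, `other_bacteria`,
  `plastid_photosynthetic`, `plastid_nonphotosynthetic`, `plastid_lacking`,
  `unknown`. Tree leaves are `taxon_id` or `taxon_id@sequence_id`.
* trees: newick, one file per cluster (or one tree per line).
* alignments: aligned FASTA (gap `-`, unknown `X`); partitions are
  RAxML-style `PROT, gene = start-end` lines.
* rate tables: whitespace-delimited `site rate` with optional `#` comments.
* QC tables: TSV as documented in `egtscan.sagqc`.

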