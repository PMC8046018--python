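# screp

Single-cell immune repertoire analysis: parse 10x-cellranger-style B/T-cell
VDJ output, assemble paired-chain cell records, call clonotypes under several
strategies, compute repertoire statistics, quantify somatic hypermutation,
build germline-rooted clone trees and clone similarity networks, and
integrate clonotypes with single-cell transcriptome clusters.

## Modules

| module | purpose |
| --- | --- |
| `screp.io` | read/validate contig annotation CSVs and FASTA, filter contigs, assemble one paired cell record per barcode, isotype assignment |
| `screp.clonotyping` | clonotype calling (`cdr3.nt`, `cdr3.aa`, `hvj.lvj`, `hvj.lvj.cdr3lengths`, `hvj.lvj.cdr3length.cdr3homology` with single-linkage Hamming homology) and expansion ranking |
| `screp.features` | isotype-per-clone tables, CDR3 length distributions, position probability matrices for logos, V/J usage, Shannon/Simpson diversity |
| `screp.phylo` | SHM as substitution columns of a global affine-gap alignment against extracted germline references; neighbor-joining clone trees rooted at the germline with identical-sequence collapsing |
| `screp.network` | clone similarity graphs from summed CDRH3+CDRL3 Levenshtein distances with a strict threshold; cross-sample components |
| `screp.gex` | mitochondrial/receptor-gene filtering, Leiden clustering, VDJ↔GEX barcode matching, clone cluster membership, rule-based phenotypes, expanded-vs-unexpanded Wilcoxon DE, hypergeometric enrichment, preranked GSEA |
| `screp.simulate` | deterministic synthetic fixtures: cellranger-dialect contig tables + FASTA with planted clonal lineages and mutation loads, MTX expression triplets with planted clusters, markers and mito fractions |

## CLI

```bash
# synthetic inputs with planted ground truth
screp simulate vdj --seed 1 --cells 200 --clones 20 --shm-rate 2.0 --out vdj/
screp simulate gex --seed 1 --vdj-dir vdj/ --out gex/

# repertoire analyses (directory layout follows cellranger naming)
screp load --contigs vdj/filtered_contig_annotations.csv --out summary.tsv
screp clonotype --in vdj/ --strategy hvj.lvj.cdr3length.cdr3homology --homology 0.7 --out clones.tsv
screp stats isotypes --in vdj/ --top 30 --out isotypes.tsv
screp stats lengths --in vdj/ --out lengths.tsv
screp stats logo --in vdj/ --length 29 --out ppm.csv
screp stats vjusage --in vdj/ --chain heavy --top 10 --out vj.tsv
screp stats diversity --in vdj/ --metric shannon
screp shm --in vdj/ --top 30 --out shm.tsv
screp tree --in vdj/ --clone 1 --out clone1.nwk
screp network --in vdj/ --threshold 10 --top 60 --out edges.tsv

# transcriptome integration
screp gex cluster --mtx-dir gex/ --resolution 0.5 --out annotation.tsv
screp gex integrate --mtx-dir gex/ --in vdj/ --top 10 --out membership.tsv
screp gex de --mtx-dir gex/ --in vdj/ --out de.tsv
screp gex go --genes genes.txt --gmt sets.gmt --universe universe.txt --out go.tsv
screp gex gsea --ranked ranked.tsv --gmt sets.gmt --out gsea.json
```

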