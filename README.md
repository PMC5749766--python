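# panmeta

Comparative-genomics toolkit for bacterial strain panels and ocean
metagenomes: greedy protein clustering, pangenome partitioning, Jaccard
bi-clustering, core-gene concatenated neighbor-joining phylogeny with
bootstrap, per-strain metagenome gene-coverage profiling, and KO
presence/absence functional screening — plus a synthetic-data generator
with machine-readable planted truth for end-to-end validation.

## Modules

| Module | What it does |
| --- | --- |
| `panmeta.seqio` | FASTA, 12-column BLAST-tabular TSV, CD-HIT-style `.clstr`, Newick and labeled-matrix TSV readers/writers with strict validation |
| `panmeta.clustering` | Greedy incremental clustering with identity-over-shorter-sequence and coverage thresholds (BLOSUM62, affine gaps 11/1; best-matching representative, deterministic) |
| `panmeta.pangenome` | core / dispensable / strain-specific classification, Jaccard similarity on dispensable clusters, average-linkage bi-clustering |
| `panmeta.phylogeny` | progressive alignment, fixed-order concatenation, Poisson-corrected distances with pairwise deletion, Saitou–Nei NJ, bootstrap support |
| `panmeta.metagenome_profile` | joint reference+sample clustering into coverage-ratio / mean-identity profiles; contig best-hit homology summaries |
| `panmeta.functional_screen` | KO assignment (best-hit with single second-hit fallback) and screening against bundled phycobilisome / recombination catalogs |
| `panmeta.synthetic_data` | planted trees, per-branch Poisson substitution, planted pangenomes, metagenome sample mixtures, all seed-deterministic with truth TSVs |

## CLI

```sh
# simulate a planted pangenome plus one metagenome sample
panmeta simulate --config spec.yaml --out sim/ --sample m1=strain_1:0.8:20

# cluster proteomes at 70% identity over 70% of the shorter sequence
panmeta cluster --identity 0.7 --coverage 0.7 --in sim/strain_1.faa \
    --in sim/strain_2.faa --out clusters.clstr --tsv clusters.tsv

# pangenome partition and Jaccard matrix (40/40 ortholog regime)
panmeta pangenome --in 'sim/strain_*.faa' --out partition.tsv
panmeta jaccard   --in 'sim/strain_*.faa' --out jaccard.tsv --row-tree rows.nwk

# concatenated core-gene NJ tree with bootstrap
panmeta tree --bootstrap 100 --seed 42 --in 'sim/strain_*.faa' --out tree.nwk

# metagenome coverage profile and contig homology summary
panmeta profile --identity 0.95 --coverage 0.95 --refs sim/ --sample sim/m1.faa
panmeta contig-summary --hits hits.tsv --contig-lengths contigs.tsv \
    --genome-lengths genomes.tsv

# KO presence/absence screen
panmeta ko-screen --catalog phycobilisome --mode strain \
    --hits hits.tsv --ko-map ko_map.tsv --out presence.tsv
```

(`--in` is repeatable; shells expand the globs above into repeated flags.)

## Notes on determinism

All stochastic components (tree generation, sequence evolution, sample
mixtures, bootstrap resampling) take explicit integer seeds and are
byte-reproducible. Clustering sorts records by decreasing length (ties by
id), so results are invariant to input order; alignment scoring constants
are fixed (BLOSUM62, gap open 11 / extend 1) and identity/coverage are
defined from the lexicographically optimal alignment, which makes them
independent of traceback tie-breaking.
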