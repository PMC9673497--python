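# stimgene

Toolkit for characterising and predicting interferon-stimulated human
genes (ISGs) from coding sequences, protein sequences and a
protein-interaction network.

It provides:

- **Feature encoding** — nucleotide composition, paired-base contents,
  dinucleotide and 4-mer compositions, within-family codon usage
  (`sequence_features`); amino-acid and 17 physicochemical/geometric group
  compositions (`protein_features`); eight per-node interaction-network
  metrics with zeros for unmapped/isolated proteins (`network_features`).
- **Pattern mining** — exhaustive degenerate nucleotide pattern spaces
  (lengths 3–5, 708,540 patterns) and gapped amino-acid patterns
  (1,312,000), presence testing, Pearson chi-squared enrichment with
  Benjamini–Hochberg adjustment, co-occurrence counts and
  disordered-region conditional frequencies (`pattern_mining`).
- **Association** — a fold-change-binned correlation statistic (0.1-wide
  bins over positive log2 fold changes, fixed standardisation constants
  6.4/3.7) with Student-t significance (`association`).
- **Machine learning** — percentile clamp-and-scale normalization,
  undersampling, an RBF-SVM with KNN/random-forest comparators,
  forward feature selection, and AUC-driven subtractive iteration (ASI):
  on frozen cross-validation folds, repeatedly drop every feature whose
  individual removal does not decrease the baseline AUC
  (`ml_framework`).
- **Synthetic benchmarks** — seeded generators for valid coding sequences
  with class-specific GC content and planted motifs, feature-linked fold
  changes, scale-free interaction graphs and smooth disorder scores, with
  a ground-truth manifest (`synthetic_data`).
- **Curation** — FASTA/TSV I/O, CDS validation, fold-change-based label
  refinement and repressed-gene tagging (`io_curation`).

## Command line

```bash
stimgene simulate --seed 1 --out bench/            # synthetic dataset
stimgene encode bench/cds.fasta --out features.tsv # 346 nucleotide features
stimgene encode bench/protein.fasta --kind protein --out aa.tsv
stimgene mine --pos pos.fasta --neg neg.fasta --lengths 3,4,5 --out slnps.tsv
stimgene network-metrics --edges bench/ppi_edges.tsv \
    --gene-map bench/gene_protein_map.tsv --out net.tsv
stimgene associate --features features.tsv --annotation bench/annotation.tsv \
    --out assoc.tsv                                # add --raw-moments for
                                                   # empirical bin moments
stimgene refine-labels --annotation bench/annotation.tsv \
    --fold-changes bench/fold_changes.tsv --out refined.tsv
stimgene train --features features.tsv --labels labels.tsv \
    --select asi --folds 5 --seed 0 --model-out model/
stimgene predict --model model/ --features features.tsv --out scores.tsv
stimgene evaluate --scores scores.tsv --labels labels.tsv
```

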