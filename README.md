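# isbreach

Analysis toolkit for insertion-sequence (IS) transpositions into
CRISPR-Cas and other defense loci:

- **Exact element scanning** — every full-length, 100%-identity occurrence
  of each catalog element in target sequences, both strands
  (`locus_scanner`).
- **Target-site-duplication (TSD) calling** — longest exact direct repeat
  flanking a hit, with canonical/aberrant classification per element
  family and an optional canonical-only mode (`tsd_caller`).
- **Insertion annotation** — disrupted gene by maximal CDS overlap,
  ±10 kb genomic-context extraction, insertion-spectrum matrix of unique
  TSD sites, diagnostic PCR amplicon-size prediction
  (`insertion_annotator`).
- **Motif statistics** — position frequency matrices (no pseudocounts),
  Pearson correlation between PFMs, IUPAC consensus reduction, GC and
  length-mixture summaries with Welch/pooled t comparison (`motif_stats`).
- **CDS recoding** — synonymous elimination of IUPAC target-site motifs
  and of all exact repeats ≥ a threshold, translation-preserving, with
  provably-unavoidable residuals reported honestly (`cds_recoder`).
- **Spacer–protospacer matching** — exact both-strand search with
  optional PAM checking in protospacer orientation (`target_matcher`).
- **Synthetic data** — annotated loci, element implants with controlled
  TSD length mixtures and motif-biased sites, truth tables, and recovery
  metrics (`synthetic_data`).

Coordinates are 0-based half-open internally; all file formats use their
native conventions (GFF3 and output TSVs are 1-based inclusive, declared
in a header comment).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(printed-pattern TSD calls, implant→recover recall, length-mixture and
motif recovery, PFM identities, recoder safety, amplicon arithmetic).

## CLI

```sh
isbreach scan --catalog is.fasta --catalog-meta is.tsv --targets genome.fasta --out hits.tsv
isbreach tsd  --catalog is.fasta --catalog-meta is.tsv --targets genome.fasta --out calls.tsv
isbreach annotate --catalog is.fasta --catalog-meta is.tsv --targets genome.fasta \
    --gff genes.gff3 --window 10000 --outdir annot/
isbreach match-spacers --spacers spacers.fasta --targets plasmids.fasta \
    --pam AAG --pam-side 5prime --out matches.tsv
isbreach recode --cds genes.fasta --motif NRAWWWWN --motif YTAR --motif NRCWNWRYN \
    --min-repeat 10 --outdir recoded/
isbreach simulate --catalog is.fasta --catalog-meta is.tsv --element IS10x \
    --n-implants 20 --seed 1 --outdir sim/
isbreach evaluate --truth sim/truth.tsv --calls calls.tsv \
    --catalog is.fasta --catalog-meta is.tsv --out metrics.json
isbreach run --config config.yaml --outdir results/   # composite pipeline
```

The catalog metadata TSV has columns `name`, `family`,
`canonical_tsd_lengths` (comma-separated) and optional `tsd_motif`.
`isbreach run` takes a YAML config with keys `catalog`, `catalog_meta`,
`targets` and optional `gff`, `spacers`, `pam`, `pam_side`, `k_min`,
`k_max`, `canonical_only`, `window`, `seed`; flags override the config.
Every run writes a `manifest.json` with input checksums.

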