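# orfkit

Toolkit for analyzing noncanonical ORF calls from Ribo-Seq experiments:

- **orf_model** — domain types (transcript models, exon-block ORF records,
  provenance tags), 0-based half-open coordinate handling, GTF/BED12/TSV
  readers and writers. Stored ORF coordinates include the stop codon;
  reported lengths exclude it.
- **synthetic_data** — deterministic generators for transcriptomes,
  multi-caller/multi-replicate ORF call sets (start-site jitter around a
  shared stop codon, category bias, dropout, spurious calls), P-site count
  tables with a tunable in-frame fraction, and peptide-evidence scenarios —
  all with ground truth attached.
- **orf_classify** — assigns each ORF one category (uORF, uoORF, intORF,
  doORF, dORF, lncRNA-ORF, or a flagged canonical variant) by comparing its
  transcript-space interval and frame with the annotated CDS.
- **orf_compare** — the exon-containment / shared-stop / length-fraction
  similarity relation, transitive unique-ORF clustering, replicate-sharing
  curves, category composition, and length distributions.
- **catalog_harmonize** — inclusion filter (AUG start with internal-AUG
  rescue, ≥16 aa), per-dataset nomenclature remapping with exclusion rules,
  cross-dataset replication counting (meta-catalogs never count as primary
  support), and per-dataset summary arithmetic.
- **riboseq_qc** — codon periodicity (≥70% pass / 60–70% gray / <60% fail),
  detected-CDS counting (>9000 default threshold), footprint-yield bounds
  (15–30% of sequenced reads), and the CDS-mapping fraction (>80% pass).
- **evidence_tiers** — the two-peptide rule for tryptic evidence (≥2
  nonnested, uniquely mapping peptides, each ≥9 residues, joint extent ≥18
  aa) and the seven-tier evidence framework (1A Protein candidate …
  5 Predicted).

## CLI

```sh
orfkit simulate --seed 3 --outdir sim/           # synthetic data + ground truth
orfkit validate --gtf sim/transcripts.gtf --orfs sim/calls.tsv
orfkit convert  --orfs sim/calls.tsv --to bed12 --out calls.bed
orfkit classify --gtf sim/transcripts.gtf --orfs sim/calls.tsv --out classified.tsv
orfkit compare  --orfs sim/calls.tsv --group-by replicate \
                --min-frac-grid 0.5:1.0:0.05 --k 1,3,6 --out report/
orfkit qc       --psites sim/psites.tsv --gtf sim/transcripts.gtf \
                --total-reads 150000000 --detected-cds-threshold 50 --out qc.json
orfkit harmonize --catalogs chothani.tsv duffy.tsv --meta gencode --out harmonized/
orfkit tier     --evidence peptides.tsv --flags flags.tsv --out tiers.tsv
```

ORF calls use either BED12 or a TSV dialect with columns
`orf_id, transcript_id, chrom, strand, block_starts, block_sizes,
start_codon, dataset, caller, replicate, sample, category, aa_seq`.

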