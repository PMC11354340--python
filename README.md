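# pepmap

Peptide-to-genome proteogenomics mapping toolkit: six-frame translated
Smith–Waterman search of MS-identified peptides against genomic DNA, exact
spliced coordinate conversion through annotated gene models (including
genomic frame shifts across introns), High/Low-Confidence/novel
classification of mapped peptides, an alignment-parameter evaluation
harness, and standard-format exports (BED6/BED12, Circos tracks, summary
tables).

## What it does

- **`pepmap.seqcore`** — sequence primitives: genetic code, reverse
  complement, six-frame translation with coordinate bookkeeping, FASTA
  I/O, peptide deduplication, and NCBI-format substitution matrices
  (PAM30/PAM250/BLOSUM45/62/90 bundled as data files).
- **`pepmap.align6`** — tBLASTn-style search: exact affine-gap local
  alignment (numba-accelerated DP, no heuristic seeding) of each peptide
  against all six frame translations of each contig, Karlin–Altschul
  e-values, e-value/coverage/HSP filters, 25-column extended tabular
  output. Defaults match the optimized production run: PAM30, gap
  existence 10 / extension 1, e-value 0.01, 3 targets, 1 HSP, 25%
  minimum query coverage.
- **`pepmap.genemap`** — GFF3 parsing into confidence-labelled gene
  models, per-exon genomic reading frames and frame-shift detection,
  exact AA→genomic spliced block mapping, strict-containment hit-to-gene
  assignment (HC > LC > NOVEL), and frame-shift-aware stitching of
  adjacent partial hits.
- **`pepmap.physchem`** — peptide length, average MW, Kyte–Doolittle
  GRAVY, aromaticity, isoelectric point (bisection on net charge), and a
  risk flag for peptides likely to escape translated-search hits
  (GRAVY outside (−2.2, 0.6), aromaticity > 0.14, short length).
- **`pepmap.evalbench`** — ground-truth evaluation (correct / wrong /
  not-found peptides, intron-gap detection) and the 12-configuration
  matrix/gap-cost sweep with deterministic ranking.
- **`pepmap.report`** — per-tissue and per-chromosome summary tables
  with SUM/MIN/MAX/AVERAGE footers, descriptive statistics, Pearson
  correlation matrices, BED and Circos track writers.
- **`pepmap.synthgen`** — seeded synthetic fixtures: genomes, HC/LC gene
  models with controlled exon/intron structure (including introns whose
  length ≢ 0 mod 3, which shift the genomic reading frame of downstream
  exons), proteins, tryptic peptides with tissue labels, planted
  intergenic ORFs, and exact ground-truth genomic mappings.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: brute-force
alignment-oracle equivalence, the spliced-mapping round trip on ≥1000
generated peptides, brute-force containment equivalence on 1000 random
hits, the frame-shift reproduction (strict search recovers 0% of
junction-crossing peptides, stitching ≥95%), the worked-example
arithmetic on the published summary tables, and the defaults audit.

## CLI

```sh
# synthetic fixture bundle (genome.fa, genes_{hc,lc}.gff3, peptides_*.fa, ground truth)
pepmap simulate --seed 1 --out fixtures/

# six-frame search with the optimized defaults
pepmap map --genome fixtures/genome.fa --peptides fixtures/peptides_tissue01.fa \
    --matrix PAM30 --gap-open 10 --gap-extend 1 --evalue 0.01 \
    --max-targets 3 --max-hsps 1 --min-qcov 25 --out hits.tsv

# hit-to-gene assignment and per-chromosome summary
pepmap assign --hits hits.tsv --hc-gff3 fixtures/genes_hc.gff3 \
    --lc-gff3 fixtures/genes_lc.gff3 --out assignments.tsv
pepmap summarize --assignments assignments.tsv \
    --hc-gff3 fixtures/genes_hc.gff3 --lc-gff3 fixtures/genes_lc.gff3 \
    --out chromosome_summary.tsv

# track exports and peptide properties
pepmap bed --hits hits.tsv --out hits.bed
pepmap circos --hits hits.tsv --genome fixtures/genome.fa --out circos/
pepmap props --peptides fixtures/peptides_tissue01.fa --out props.tsv

# parameter sweep against the simulated ground truth
pepmap sweep --genome fixtures/genome.fa --peptides fixtures/peptides_tissue01.fa \
    --truth fixtures/ground_truth.tsv --out sweep.tsv
```

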