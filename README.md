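# mitorecomb

Toolkit for structural analysis of plant organelle genomes:

- **Recombination quantification** — for each two-copy long repeat in an
  assembly graph, build repeat windows (repeat copy plus up to 5 kb of
  flank per conformation), align long reads (k-mer anchoring + banded
  extension), apply the flank rule (a single contiguous alignment must
  cover ≥ 50 bp of unique flank on both sides of the repeat), and tally
  valid spanning reads into conformation proportions with Wilson
  confidence intervals.  A multi-copy spanning mode handles short repeat
  pairs close enough for one read to traverse both copies.
- **Graph resolution** — represent contigs and two-copy repeats, enumerate
  the two neighbor pairings of each repeat, and walk the graph under the
  majority pairings into representative linear/circular molecules with
  computed lengths and depths; a depth-consistency check flags repeats
  whose coverage contradicts the two-copy expectation.
- **Repeat detection** — SSRs as maximal perfect tandem runs of primitive
  1–6 bp motifs (thresholds 10, 5, 4, 3, 3, 3) and dispersed repeats in
  four orientation classes (forward / palindromic / reverse / complement,
  ≥ 30 bp, Hamming ≤ 3) via pigeonhole exact seeding + per-diagonal
  mismatch scanning, with length-bin summaries.
- **Codon usage** — codon counts and RSCU with family-sum conservation.
- **MTPT identification** — seed-and-extend local search of a mitogenome
  against a chloroplast genome on both strands, Karlin–Altschul E-value
  filtering (default 1e-5), deduplication of hits landing in the
  chloroplast inverted repeat, interval merging, genome-fraction totals,
  and fully-contained-gene reporting from GFF3/BED annotations.
- **Synthetic data** — seeded generators for toy multi-contig genomes with
  two-copy repeats, conformational isoform mixtures, long reads
  (truncated log-normal lengths, per-base substitution/indel errors),
  chloroplast genomes with planted inverted repeats, planted
  mitochondrion↔chloroplast homologous segments, and CDS sets with
  controlled codon bias — all returning exact ground truth.

Published contig geometry, spanning-read counts, and transfer totals for
the two study mitogenomes ship as packaged data (`mitorecomb/data/`), so
every in-table number can be recomputed offline.

## CLI

All pipeline stages are subcommands of one entry point:

```sh
# synthetic toy genome + isoform mixture + long reads (seeded)
mitorecomb simulate --seed 1 --mixture 0.3 --read-count 2000 --outdir run/

# spanning-read support per conformation path
mitorecomb quantify-recomb --graph run/genome.gfa --fasta run/elements.fasta \
    --reads run/reads.fasta --repeat-ids R1 --flank 5000 --min-flank 50 \
    --out run/support.tsv

# resolve representative molecules under chosen pairing proportions
mitorecomb resolve --graph run/genome.gfa --repeat-ids R1 --ratios R1=0.3 \
    --out run/molecules.tsv

# repeats, codon usage, plastid transfers
mitorecomb detect-repeats --fasta genome.fa --out-prefix rep
mitorecomb rscu --cds cds.fa --out rscu.tsv
mitorecomb mtpt --mt mt.fa --cp cp.fa --gff cp.gff3 --out mtpt

# recompute the published in-table numbers from packaged fixtures
mitorecomb report --out report.tsv
```

Every TSV carries a provenance header (version, seed, parameters); runs
are byte-identical under the same seed.  A YAML config can supply any
`simulate` parameter (CLI flag > config file > default).

## Layout

```
src/mitorecomb/
  io_formats.py     FASTA/FASTQ/GFA1/GFF3/BED + TSV report dialects
  graph_model.py    contigs, repeat pairings, molecule resolution
  read_sim.py       seeded synthetic-data generators + ground truth
  align.py          k-mer anchor / chain / extend alignment engine
  recomb_support.py windows, flank rule, tallying, ratio estimation
  repeat_finder.py  SSRs and dispersed repeats
  codon_usage.py    codon counts and RSCU
  mtpt_finder.py    plastid-transfer search, dedup, summaries
  cli.py            click subcommands
  fixtures.py       packaged published-table loaders
  data/             published tables as TSV/JSON
```
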