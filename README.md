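# rrbskit

Simulation and analysis toolkit for reduced-representation bisulfite
sequencing (RRBS) methylomes, entirely self-contained: every analysis runs on
synthetic data with a known per-CpG methylation truth, so the whole pipeline
is testable offline at desk scale.

The package covers six stages:

| module | what it does |
| --- | --- |
| `rrbskit.genome` | synthetic genome with CpG-poor background and CpG islands at gene starts, gene annotation, bimodal truth methylome, expression counts (60% repressed by default) |
| `rrbskit.library` | in-silico MspI digestion (`C^CGG`), 150–250 bp size selection, directional bisulfite read-pair simulation with fill-in artifact on read_2, conversion efficiency, sequencing error and quality model |
| `rrbskit.align` | BWA-style Phred-20 quality trimming, read_2 fill-in trimming, and a three-letter bisulfite paired aligner (50 bp exact seed, ≤1 mismatch per mate, unique FR placements, insert 150–250 bp) |
| `rrbskit.calls` | per-CpG methylated/unmethylated counts with strand merging and mate-overlap deduplication, bisulfite-conversion QC from non-CpG cytosines, coverage filtering, replicate Pearson correlation |
| `rrbskit.profiles` | gene/intergenic methylation histograms, TSS ±6 kb meta-profiles (1000 bp window, 50 bp step, 221 windows), TSS CpG-content classification (3.7% threshold), single-nucleotide histograms |
| `rrbskit.expression` | repressed/low/high expression grouping, stratified TSS profiles, paired t-tests across animals, cross-method per-site concordance |

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (conversion QC
bound, read-structure bound, digestion/trimming oracles, alignment
correctness, methylation recovery, figure-shape reproduction, statistics).
The suite builds one 500 kb scenario per session and finishes in well under
a minute.

## CLI

```bash
rrbskit simulate genome --n-contigs 5 --contig-length 100000 \
    --n-genes 25 --seed 1 --outdir data
rrbskit simulate reads --genome data/genome.fa --truth data/truth.tsv \
    --mean-depth 50 --seed 2 --outdir data
rrbskit align --genome data/genome.fa --r1 data/reads_1.fastq \
    --r2 data/reads_2.fastq --out data/aln.tsv
rrbskit call --alignments data/aln.tsv --genome data/genome.fa \
    --min-cov 10 --out-prefix data/calls
rrbskit profile tss --calls data/calls.cov10.tsv --genes data/genes.bed \
    --genome data/genome.fa --out data/profile.tsv
rrbskit profile genes --calls data/calls.cov10.tsv --genes data/genes.bed \
    --genome data/genome.fa --out-prefix data/genes
rrbskit integrate --calls data/calls.cov10.tsv --calls ... \
    --expression data/expression.tsv --genes data/genes.bed \
    --genome data/genome.fa --outdir data/integrate
```

All interchange formats are plain text: FASTA, BED6, FASTQ (Phred+33), TSV
(alignments, cytosine reports — 1-based in the file only), JSON (QC).

## Conventions

* Coordinates are 0-based, half-open everywhere in memory; BED is native
  0-based; the cytosine report is 1-based in the file only.
* A CpG site is keyed by the forward-strand position of its C; both strands
  pool into that site (symmetric CpG methylation).
* Insert length is the fragment span between MspI cut offsets; the 2-base
  fill-in is not part of the insert.
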