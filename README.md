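# mitochar

Descriptive and comparative statistics for annotated insect mitochondrial
genomes: genome-organization accounting, strand-asymmetry and codon-usage
statistics, per-gene divergence estimation, control-region repeat detection,
and phylogenomic supermatrix preparation — the complete analysis pipeline of a
mitogenome description paper, as a tested, reusable package.

The bundled reference is the annotation table of a drywood-termite
(Kalotermitidae) mitogenome: a 15,655-bp circular molecule with 13
protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs and an A+T-rich control region,
distributed over the majority (J) and minority (N) strands. A synthetic-data
generator reproduces that architecture — strands, overlaps, incomplete stop
codons, planted control-region repeats, target base composition — so every
pipeline stage is testable without downloading accessions.

## What it computes

- **Layout** — feature sizes and signed intergenic values recomputed from
  1-based inclusive circular coordinates (`next.start − prev.stop − 1`;
  negative = overlap), spacer/overlap extremes, per-strand gene tallies, and
  the coverage identity Σ sizes + Σ signed gaps = genome length.
- **Composition and skews** — AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C) per
  class (genome, PCG, tRNA, rRNA, control region, codon positions), with an
  explicit strand convention per class.
- **Codon usage** — codon counts over complete codons (stops excluded),
  relative synonymous codon usage RSCU_c = n_c·d_aa / Σ n_c′, and amino-acid
  percentages under the invertebrate mitochondrial code (NCBI table 5).
- **Divergence** — nucleotide diversity π = 2/[n(n−1)] Σ_{i<j} d_ij/L_ij with
  pairwise deletion, and Nei–Gojobori (1986) Ka/Ks: pathway-counted
  synonymous/nonsynonymous differences, fractional site counts
  (N + S = 3 × codons), Jukes–Cantor correction d = −¾ ln(1 − 4p/3),
  ω = dN/dS (undefined, never infinite, when dS = 0).
- **Repeats** — all maximal exact repeated motifs (default ≥ 9 bp) in the
  control region, with containment suppression and tandem-array
  canonicalization.
- **Phylogenomic prep** — terminal-stop stripping, codon-column gap filtering,
  canonical-order concatenation with RAxML/NEXUS partition files, and a
  neighbor-joining sanity tree (p-distance or JC).

## Worked example

```python
from mitochar import formats, layout_report, skew_from_fractions

record = formats.load_reference_record()      # bundled annotation table
lay = layout_report(record)
print(lay.genome_length, lay.sizes["cox1"], lay.sizes["nad5"])
print(lay.longest_spacer, lay.j_gene_count)
print(skew_from_fractions(41.8, 24.9, 12.3, 21.0))
```

prints

```
15655 1545 1726
('trnS2', 'nad1', 23) 23
(0.25337331334332835, -0.26126126126126126)
```

— the genome is 15,655 bp; cox1 spans 1,545 bp and nad5, the largest PCG,
1,726 bp; the longest intergenic spacer is 23 bp between trnS2 and nad1; the J
strand carries 23 genes; and the whole-genome AT-skew (+0.25) is positive
while the GC-skew (−0.26) is negative — the A-rich, C-over-G asymmetry typical
of insect mitogenomes.

The numbered scripts under `analysis/` walk the full pipeline (layout,
published skews, synthetic genome, codon usage/RSCU, divergence panel,
supermatrix + NJ tree) and write their tables under `results/`:

```sh
python analysis/01_reference_layout.py
python analysis/05_divergence_panel.py
...
```

The same functionality is exposed on the command line:

```sh
mitochar simulate genome --seed 42 --out sim/
mitochar characterize --genbank sim/genome.gb --out report/
mitochar codon-usage --genbank sim/genome.gb
mitochar divergence --alignments alignments/
mitochar supermatrix --alignments alignments/ --out sm/
```

## Layout of the package

| module | contents |
| --- | --- |
| `mitochar.core` | domain types, circular layout arithmetic, start/stop classification |
| `mitochar.formats` | GenBank/FASTA/feature-table/TSV/JSON readers and writers |
| `mitochar.composition` | per-class base composition and skews |
| `mitochar.codons` | codon counts, RSCU, amino-acid usage |
| `mitochar.divergence` | π and Nei–Gojobori Ka/Ks |
| `mitochar.repeats` | exact repeat / tandem-array detection |
| `mitochar.phylo` | supermatrix, partitions, NJ tree |
| `mitochar.synthetic` | genome and ortholog simulators (with truth records) |
| `mitochar.report`, `mitochar.cli` | orchestration and the `mitochar` CLI |

See `docs/methods.md` for the statistical methods, conventions, simulator
design, and known limitations.
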