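# phasepan

Ploidy-aware pangenome analyses for haplotype-resolved genome assemblies.

Phased assemblies reconstruct every chromosome copy as its own sequence.
Conventional pangenome tooling collapses those copies into one genome-level
bag of genes, hiding exactly the variation phasing was meant to expose:
haplotype-specific gene loss, allelic diversity, and the traces of
whole-genome duplication (WGD). `phasepan` keeps the hierarchy — genome →
sequence → haplotype identifier (chromosome number + phase letter, e.g.
`1A`) — and runs every comparative analysis at the level where the signal
lives. Sequences of one genome sharing a phase letter form a *subgenome*, an
analysis construct for counting gene presence per chromosome copy; unphased
sequences are labelled chromosome 0 and belong to no subgenome.

## What it computes

* **Pangenome model** — per-genome FASTA assemblies, GFF3 gene models
  (gene → mRNA → CDS, spliced and translated), a 4-column phasing table,
  optional repeat annotations; plain-text on-disk store; round-trip I/O.
* **Homology grouping** — all-vs-all protein similarity
  `sim(A,B) = 100 · 2·score(A,B) / (score(A,A) + score(B,B))`
  (global BLOSUM62 alignment, affine gaps) thresholded by *relaxation mode*
  m at 95 − 10·(m−1) percent, then Markov clustering (MCL). Grouping quality
  is scored against single-copy families with F1 = 2pr/(p+r) and by the mean
  Jaccard overlap of the group sets hit by sibling haplotypes.
* **Gene classification** — core (all genomes) / accessory (some) / cloud
  (one genome) per homology group, plus subgenome-presence and per-chromosome
  haplotype counts; single-copy detection at genome, subgenome (one copy per
  subgenome) or chromosome scope; allele census (each distinct CDS string is
  a nucleotide allele, each distinct protein a protein allele).
* **Distances and trees** — per-sequence canonical k-mer sets (default
  k = 19) and the Mash distance `D = −(1/k)·ln(2J/(1+J))` on the exact
  Jaccard J; gene-content distance 1 − Jaccard over shared groups;
  neighbor joining with deterministic tie-breaks; midpoint rooting;
  chromosome-clade validation; per-chromosome core SNP matrices from
  two-round trimmed alignments and parsimony-informative columns; adapters
  for external aligners and tree programs.
* **Synteny and retention** — collinear-block detection in gene-rank space
  (MCScanX default constants: match 50, max gap 25, min 5 pairs;
  format-compatible `.collinearity` reader/writer), syntenic-pair relations,
  and gene retention in sliding windows of 100 genes, step 10: the percent of
  query genes with a homologue (or syntelog) on each target, depth ignored.
* **Substitution rates** — codon alignments back-translated from protein
  alignments (gap and in-frame-stop columns excluded, <30 aa members
  dropped) and Nei–Gojobori (1986) Dn/Ds with Jukes–Cantor correction;
  within- and between-genome scans; log-binned Ds histograms with mode
  detection — within one phased genome, allele pairs produce a young Ds peak
  and WGD remnants an old one.
* **Tracks and figures** — gene bars colored by class, subgenome count, or
  presence of copies on *other* chromosome numbers; gene/repeat coverage in
  1 Mb windows; homeologous (same chromosome number) alignment pairing plans
  and variant-quality filtering (< 10 dropped); stacked chromosome figures
  with synteny ribbons, every plotted value also emitted as a table.
* **Simulator** — a deterministic phased-pangenome generator with planted
  homology, gene loss, inversions, a calibrated synonymous-divergence
  channel, and an optional fractionated WGD chromosome; every planted fact
  is written to truth tables, so each analysis above is testable end to end.

## Worked example

`examples/04_substitution_rates.py` simulates one diploid genome with
haplotype divergence Ds ≈ 0.005 plus a WGD remnant at Ds ≈ 0.7 fractionated
to 40% retention, groups the proteins, and scans all within-genome pairs:

```
95 valid Ds estimates from 40 homology groups
detected modes (Ds): 0.0091, 0.7499
young peak: 51 pairs (allele pairs across haplotypes)
old peak:   44 pairs (WGD-derived duplicate copies)
```

The bimodal distribution is the phasing dividend: in a collapsed assembly
only the duplication peak would be visible, whereas haplotype-resolved
sequences also align allelic copies, exposing heterozygosity as its own
peak. The other examples cover classification (`01`), Mash/NJ trees with
chromosome-clade checks (`02`), inversion-aware synteny and retention
windows (`03`), and allele censuses plus track tables (`05`).

A thin CLI mirrors the library for shell pipelines:

```
phasepan simulate --seed 17 -o sim/ --genomes 2 --genes 30 --inversions 1
phasepan build -o store/ --fasta sim/genome1.fa --fasta sim/genome2.fa -k 19
phasepan add-annotations --store store/ --gff sim/genome1.gff3 --genome 1
phasepan add-phasing --store store/ --table sim/phasing.tsv
phasepan group --store store/ --mode 2 && phasepan classify --store store/
```

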