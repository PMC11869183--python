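# Methods

## The pangenome model

A pangenome is an ordered collection of genomes, each contributed as one
FASTA assembly. Every FASTA entry is a *sequence*; a 4-column phasing table
(`genome, sequence, chromosome, phase`) assigns each sequence a haplotype
identifier — chromosome number plus phase letter, rendered `1A` — unique
within its genome. Sequences of one genome sharing a phase letter form a
*subgenome*. The subgenome is an accounting construct, not a biological
unit: assembled chromosome copies carry no linkage between chromosomes, so
subgenome letters are only meaningful for counting gene presence per
chromosome copy, never for cross-genome comparison of "the A subgenome".
Unphased sequences are labelled chromosome 0, contribute to genome-level
statistics, and are excluded from all subgenome and haplotype counts.
Fragmented assemblies may map several sequences to one haplotype identifier;
such fragments are treated as one haplotype wherever haplotypes are counted.

Coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted only in the readers/writers, so no other code ever
shifts an index. Gene models follow the GFF3 gene → mRNA → CDS hierarchy;
proteins come from splicing CDS parts in strand order and translating with
the standard code (ambiguous codons → `X`; an internal stop is kept as `*`
and flags the model; a CDS length not divisible by 3 flags the model
unreliable but keeps it). The longest transcript (by CDS length, ties by
lexicographic mRNA id) represents each gene in homology analyses. The store
persists as a plain-text directory (FASTA + GFF3 + TSV) and round-trips
exactly.

## Homology grouping

Pairwise protein similarity is a global alignment score (BLOSUM62, gap open
10, extend 1 — configurable) normalized by the mean self-score:

    sim(A, B) = 100 · 2·score(A, B) / (score(A, A) + score(B, B)), clipped to [0, 100].

Relaxation mode m ∈ 1..8 sets the edge threshold at 95 − 10·(m−1) percent.
The all-vs-all stage is restricted by a shared-6-mer prefilter (an inverted
peptide-6-mer index; two proteins are aligned only if they share at least
one 6-mer). At a 95% similarity threshold this prefilter is lossless by a
counting argument — two 100-aa proteins above even 45% identity share many
exact 6-mers — and the simulator-based tests confirm no planted family pair
is ever pruned. Connected components of the thresholded similarity graph are
partitioned by Markov clustering (expansion = matrix squaring, inflation
default 2.0, self-loops at the column maximum); clusters are read off as
connected components of the converged matrix, so every protein lands in
exactly one group and isolated proteins become singletons. Gene ids are
processed in sorted order and group ids assigned canonically, making the
grouping independent of input order.

Grouping quality uses two instruments. Against single-copy families
(BUSCO-style, one expected member per subgenome), each family is matched to
the group holding the plurality of its members (ties to the smaller group
id); per family, recall = matched members / family size and precision =
matched members / matched-group size; precision and recall are averaged over
families and F1 = 2pr/(p+r) computed from the averages. Averaging per family
(rather than pooling counts) weights every family equally and keeps the
score insensitive to family size; this aggregation is a design choice, as is
plurality matching. The second instrument is the mean percentage of shared
groups between sibling haplotypes: per chromosome, the Jaccard index of the
group sets hit by each haplotype's genes, averaged over haplotype pairs and
then over chromosomes. Pairing haplotypes within chromosomes (not whole
phase letters) was chosen because phase letters are arbitrary across
chromosomes.

## Gene classification

A genome contains a group if at least one member gene lies on any of its
sequences, phased or not. Core = present in all genomes, cloud = exactly
one, accessory = otherwise; the three classes partition the groups.
Subgenome counts use phased sequences only. Single-copy scopes: *genome* —
exactly one member per genome; *subgenome* — exactly one member per
subgenome of every genome, a haploid or unphased genome counting as one
subgenome; *chromosome:c* — exactly one member on every haplotype of
chromosome c. For subgenome and chromosome scopes, members outside the
scope's units (chromosome-0 genes; genes on other chromosomes) are invisible
rather than disqualifying, mirroring the restrict-then-count procedure used
for per-chromosome phylogenies. Gene-content distances are 1 − Jaccard over
the distinct groups hit by each unit (genome or sequence), so copy-number
changes never move the distance. Allele identity is exact string equality of
CDS (nucleotide alleles) or protein (protein alleles) — every polymorphism
separates alleles; near-identical alleles are deliberately not merged.

## K-mer distances and trees

K-mer sets are per sequence, not per genome, canonical (lexicographic
minimum of k-mer and reverse complement), distinct (set semantics), with
windows containing non-ACGT letters skipped; k defaults to 19 (odd, 11..31).
The Mash distance D = −(1/k)·ln(2J/(1+J)) is applied to the exact Jaccard
index; J = 0 is capped at D = 1.0, J = 1 gives 0. Full sets rather than
MinHash sketches: at the assembly sizes this package targets the exact
computation is cheap and removes sketch noise; a sketch mode would only
change the estimate of J, not the formula. Sequences with fewer than
`min_genes` (default 100) annotated genes are excluded from distance
matrices — gene-poor scaffolds otherwise distort trees.

Neighbor joining is the classical Saitou–Nei agglomeration with two
determinism rules: among tied Q values the lexicographically smallest label
pair is joined, and negative branch lengths are clamped to zero with a log
entry. Midpoint rooting bisects the longest leaf-to-leaf path (scikit-bio);
a zero-length tree roots at the first internal node with a warning.
Chromosome-clade validation midpoint-roots the tree, ignores chromosome-0
leaves, and reports every chromosome whose leaves are not exactly the
non-zero leaf set of their smallest containing clade.

## Two-round alignment and core SNP matrices

Group alignments are protein alignments (external MAFFT adapter when the
binary is on PATH, otherwise a built-in center-star aligner over the same
pairwise scorer — the fallback exists so the full pipeline runs with zero
external dependencies). Terminal trimming: the maximum number of leading and
of trailing gap columns over rows defines two terminal windows; every member
loses the residues its own row places inside those windows (CDS trimmed in
codon triples), and the trimmed proteins are re-aligned. "Longest start and
end gaps" could alternatively mean trimming each sequence's own overhang
only; the max-across-rows reading was chosen because it yields an idempotent
operation and symmetric treatment of members, and is recorded here as an
interpretation. Members trimmed below 10 aa drop their group from downstream
analyses.

A core SNP matrix for chromosome c concatenates, in ascending group-id
order, the parsimony-informative columns (≥ 2 non-gap states, each in ≥ 2
rows; gaps are not states) of the codon-expanded round-2 alignments of all
chromosome-c single-copy groups, one row per haplotype, with a provenance
map (group, column) for every site. Zero single-copy groups is an error —
the same failure mode low-quality phasing produces in practice.

## Synteny and retention

Gene pairs sharing a homology group between two sequences are placed in rank
space (position index in start-coordinate order, ties by gene id; tandem
copies each occupy a rank). Chains are built by dynamic programming
separately for parallel and antiparallel orientations: a pair extends a
previous one when both rank deltas are positive (target delta negative for
antiparallel) and at most 25; scoring is +50 per pair and −1 per skipped
rank (the MCScanX defaults); chains shorter than 5 pairs are never emitted.
Chains are selected greedily by score, then length, then smallest start
rank, with used ranks retired. A final pass splits any block that jumps over
query ranks anchored by a different block — a collinear chain may otherwise
legally bridge a 15-gene inversion (gap ≤ 25) and blur its boundaries. The
chaining algorithm is this package's own; it is validated on planted blocks
rather than on bit-compatibility with the external binary, whose
`.collinearity` dialect is read and written losslessly.

Retention of a query sequence against a target is computed in sliding
windows of 100 genes, step 10, full windows only: the percentage of window
genes with ≥ 1 homologue (homology mode) or ≥ 1 registered syntenic partner
(synteny mode) anywhere on the target. Counting presence rather than copies
("syntenic depth is ignored") keeps retention ≤ 100 even across tandem
arrays, and synteny-mode retention is bounded by homology-mode retention by
construction. Window positions are reported as the bp span from the first to
the last gene of the window. Whether a homologue must fall inside the
aligned block span in homology mode is unspecified in the field;
anywhere-on-target is implemented.

## NG86 substitution rates

Codon alignments are obtained by back-translating the round-2 protein
alignment; codon columns containing any gap or in-frame stop are excluded in
all members, and alignments with any member under 30 aa are dropped to avoid
short-alignment artefacts. For two gap-free codon rows, per-codon synonymous
site fractions are the proportion of the nine single-nucleotide changes that
preserve the amino acid, with changes into stop codons counted as
nonsynonymous; site counts are averaged over the two sequences. Observed
differences are partitioned over all shortest mutational pathways with equal
weights; pathways through stop codons are excluded and the remainder
re-weighted (if all pathways are blocked, all are used). The Jukes–Cantor
correction d = −(3/4)·ln(1 − 4p/3) is applied separately to ps and pn;
p ≥ 3/4 marks the estimate invalid (saturation), and invalid estimates are
excluded from summaries but logged. Within-genome scans pair group members
across different haplotypes (never two genes of one haplotype; copies on
different chromosomes of the same phase letter do qualify — that is exactly
where WGD paralogs sit); between-genome scans pair members across the two
genomes; all qualifying pairs are estimated rather than best-reciprocal
pairs only. The counting estimator replaces maximum-likelihood machinery by
design: it is dependency-free, exactly testable against a pathway-counting
oracle, and agrees closely with ML at the divergences of interest (Ds ≲ 1);
an adapter contract accommodates external ML tools where preferred.

Ds histograms are log-binned over [1e−4, 10] (60 bins), smoothed with a
3-bin moving average; modes are local maxima with prominence above 10% of
the tallest peak. Values outside the range are clamped into the edge bins so
counts always sum to the number of valid estimates.

## Tracks, pairing plans, variant filtering

Gene bars color by class, by subgenome-presence count, or grey a gene iff a
group member lies on a different non-zero chromosome number — copies on the
same chromosome number but another haplotype never trigger grey, separating
true translocated/duplicated copies from alleles. Coverage tracks report
100 × (union-covered bases)/(window length) in 1 Mb windows; the final
partial window is normalized by its own length (a convention this package
fixes; the alternative — padding to full size — deflates terminal values).
Alignment plans enumerate all unordered same-chromosome-number sequence
pairs (chromosome 0 excluded), h(h−1)/2 pairs for h haplotypes; variant
records from external whole-genome aligners are dropped below quality 10.
Figures are a thin matplotlib layer: every plotted value is first emitted as
a table, and the tables are the tested surface.

## The simulator

The generator emulates a phased plant pangenome: an ancestral catalogue of
random genes per chromosome (start codon, non-stop body, stop; ~70% forward
strand) separated by random intergenic spacers, copied into every genome ×
haplotype and diverged through four channels.

* **Synonymous channel.** A per-branch plan of n synonymous
  single-nucleotide events (never creating a stop; the precomputed
  synonymous-neighbor table of the standard code) where n is calibrated by
  bisection against a fixed-seed Monte-Carlo estimate of the event-count →
  NG86-Ds curve, so the expected estimate matches the target; targets
  ≥ 1.5 are refused as saturated. Haplotypes receive the plan for half the
  pairwise target.
* **Neutral channel.** Per-site substitutions at `haplotype_snp_rate` over
  genes and spacers, skipping changes that would create an in-frame stop.
* **Loss.** Genome-level loss (all haplotypes lose the gene — the source of
  accessory/cloud variation between genomes) and haplotype-level loss
  (subgenome mosaicism), both Bernoulli per gene.
* **Structure.** Inversions reverse a contiguous run of gene copies
  (strands flipped) on a chosen haplotype; with the WGD flag, chromosome 1
  is duplicated onto an extra chromosome at a deep synonymous divergence
  (`ds_wgd`) and fractionated to `wgd_retention` at the ancestral level, so
  all genomes share the same remnant gene set. WGD copies keep their source
  family identity — synonymous-only divergence leaves proteins identical,
  so homology grouping reunites them and within-genome rate scans see both
  the young allele pairs and the old duplicate pairs.

Defaults model the regime the analyses target: diploid genomes, haplotype
heterozygosity Ds 0.005 (the young-peak window), 0.5% neutral SNPs, 5%
haplotype and 10% genome gene loss, WGD at Ds 0.7 with 40% retention.
Everything emitted (FASTA, GFF3, phasing, repeats, truth tables) is a pure
function of the configuration — identical seeds give byte-identical files —
and all files re-enter through the package's own parsers.

What the simulator does *not* emulate bounds what green tests show about
real data: genes are single-exon and intron-free (splicing is exercised by
hand-built fixtures instead), intergenic sequence is i.i.d. uniform with an
optional tandem repeat array rather than a transposon landscape, there is no
recombination, no centromere/pericentromere structure, no assembly or
annotation error, no fragmented scaffolds, and divergence is uniform across
genes. Passing tests therefore demonstrate correctness of the algorithms on
clean planted signal, not robustness to annotation noise or phasing error.

## Benchmark problem sizes

The validation experiments run at desk scale, chosen to keep full planted
signal while completing quickly: classification on 4 genomes × ploidy 2 × 2
chromosomes × 100 genes; clade checks on 3 × 2 × 3 × 20 genes at 0.5% SNPs;
retention on a 500-gene chromosome with 40% loss; NG86 recovery at planted
Ds ∈ {0.01, 0.1, 0.3, 0.7} with 100 replicate pairs of 300 codons; Ds-peak
detection on 80 genes of 500 codons with a 40%-retention WGD layer; NJ on
100 random 8-leaf additive matrices; coverage against a per-base boolean
oracle on 5 Mb. Gene lengths of 500 codons in the peak experiment give the
synonymous channel enough sites to resolve Ds ≈ 0.005 as a distinct mode.

## Known limitations

* The center-star fallback aligner is a 2-approximation; for divergent
  groups an external aligner gives better alignments (the adapter is
  preferred when present).
* NG86 underestimates rates under strong transition/transversion bias or
  codon-usage bias; the estimator is intended for the Ds ≲ 1 regime, and
  deeper peaks (paleohexaploidy-scale, Ds 2–3) are outside its validity
  domain here.
* The collinear-chain detector shares MCScanX's constants but not its exact
  tie-breaking; block boundaries can differ by a gene or two around noisy
  breakpoints.
* MCL on very large components is dense-matrix (O(n³) per iteration);
  grouping is intended for desk-scale protein sets (≲ 10⁴ per component).
* Duplicate gene ids across genomes are rejected rather than namespaced.
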