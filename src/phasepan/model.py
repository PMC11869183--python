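"""Hierarchical pangenome data model and file I/O.

A pangenome here is a collection of genomes, each contributed as one FASTA
assembly; every FASTA entry becomes a *sequence* with an optional haplotype
identifier (chromosome number + phase letter, e.g. ``1A``).  Sequences of one
genome sharing a phase letter form a *subgenome* — an analysis construct that
lets gene presence be assessed per chromosome copy even though the grouped
chromosomes have no physical linkage.  Sequences without phasing information
are labelled chromosome 0 and belong to no subgenome.

Structural annotations (GFF3 gene → mRNA → CDS) attach gene models to
sequences; proteins are derived by splicing CDS parts in strand order and
translating with the standard genetic code.

Coordinates: GFF3 is 1-based inclusive on disk; internally every interval is
0-based half-open.  The conversion happens only in the GFF3 readers/writers.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("phasepan")

STANDARD_STOPS = {"TAA", "TAG", "TGA"}

__all__ = [
    "HaplotypeID",
    "GenomeRecord",
    "SequenceRecord",
    "Transcript",
    "GeneModel",
    "RepeatAnnotation",
    "PangenomeStore",
    "PangenomeError",
    "build_pangenome",
    "add_annotations",
    "add_phasing",
    "add_repeats",
    "select_sequences",
    "extract_feature_sequence",
    "translate_cds",
    "reverse_complement",
    "save_store",
    "load_store",
]


class PangenomeError(ValueError):
    """Raised on malformed inputs or unsatisfiable queries."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True, order=True)
class HaplotypeID:
    """Within-genome identifier: chromosome number plus phase letter.

    Chromosome 0 marks unphased sequences and carries no phase letter.
    """

    chromosome: int = 0
    phase: str | None = None

    def __post_init__(self) -> None:
        if self.chromosome < 0:
            raise PangenomeError(f"chromosome must be >= 0, got {self.chromosome}")
        if self.chromosome == 0 and self.phase is not None:
            raise PangenomeError("chromosome 0 cannot carry a phase letter")
        if self.chromosome > 0 and self.phase is not None:
            if len(self.phase) != 1 or not self.phase.isupper():
                raise PangenomeError(f"phase must be one uppercase letter, got {self.phase!r}")

    @property
    def phased(self) -> bool:
        return self.chromosome > 0 and self.phase is not None

    def render(self) -> str:
        if self.chromosome == 0:
            return "0"
        return f"{self.chromosome}{self.phase or ''}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


@dataclass
class GenomeRecord:
    genome_id: int
    name: str
    ploidy: int = 1

    def __post_init__(self) -> None:
        if self.genome_id < 1:
            raise PangenomeError("genome_id must be a positive integer")
        if self.ploidy < 1:
            raise PangenomeError("ploidy must be >= 1")


@dataclass
class SequenceRecord:
    genome_id: int
    name: str
    residues: str
    haplotype: HaplotypeID = field(default_factory=HaplotypeID)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def label(self) -> str:
        """Store-wide unique label, e.g. ``g3#chr11A``."""
        return f"g{self.genome_id}#{self.name}"


@dataclass
class Transcript:
    mrna_id: str
    # CDS parts as 0-based half-open intervals in genomic coordinates
    cds_intervals: list[tuple[int, int]]
    protein: str = ""

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)


@dataclass
class GeneModel:
    gene_id: str
    genome_id: int
    sequence_name: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)
    reliable: bool = True
    has_internal_stop: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise PangenomeError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise PangenomeError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def longest_transcript(self) -> Transcript:
        """Longest-CDS transcript; ties broken by lexicographic mRNA id."""
        if not self.transcripts:
            raise PangenomeError(f"gene {self.gene_id} has no transcripts")
        return min(self.transcripts, key=lambda t: (-t.cds_length, t.mrna_id))

    @property
    def sequence_key(self) -> tuple[int, str]:
        return (self.genome_id, self.sequence_name)


@dataclass
class RepeatAnnotation:
    genome_id: int
    sequence_name: str
    start: int
    end: int
    class_label: str


# ---------------------------------------------------------------------------
# sequence helpers

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> tuple[str, bool]:
    """Translate a coding sequence with the standard code.

    Returns ``(protein, has_internal_stop)``.  A trailing stop codon is
    trimmed; internal stops stay as ``*`` and raise the flag; ambiguous codons
    translate to ``X``.
    """
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa, "*" in aa


# ---------------------------------------------------------------------------
# the store


@dataclass
class PangenomeStore:
    """In-memory pangenome: genomes, sequences, gene models, phasing, repeats.

    Homology groups and synteny relations computed by downstream modules are
    attached here so a single object can be carried through an analysis.
    """

    k: int = 19
    genomes: dict[int, GenomeRecord] = field(default_factory=dict)
    sequences: dict[tuple[int, str], SequenceRecord] = field(default_factory=dict)
    genes: dict[str, GeneModel] = field(default_factory=dict)
    repeats: list[RepeatAnnotation] = field(default_factory=list)
    homology_groups: list = field(default_factory=list)  # list[HomologyGroup]
    synteny_blocks: list = field(default_factory=list)  # list[SyntenyBlock]
    syntenic_partners: dict[str, set[str]] = field(default_factory=dict)

    # -- lookups ------------------------------------------------------------
    def sequence(self, genome_id: int, name: str) -> SequenceRecord:
        try:
            return self.sequences[(genome_id, name)]
        except KeyError:
            raise PangenomeError(f"unknown sequence {name!r} in genome {genome_id}") from None

    def sequence_by_label(self, label: str) -> SequenceRecord:
        gid, _, name = label.partition("#")
        return self.sequence(int(gid.lstrip("g")), name)

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self.genes[gene_id]
        except KeyError:
            raise PangenomeError(f"unknown gene {gene_id!r}") from None

    def genes_on(self, genome_id: int, sequence_name: str) -> list[GeneModel]:
        """Genes of one sequence, ordered by start coordinate then gene id."""
        out = [
            g
            for g in self.genes.values()
            if g.genome_id == genome_id and g.sequence_name == sequence_name
        ]
        out.sort(key=lambda g: (g.start, g.gene_id))
        return out

    def subgenomes(self, genome_id: int) -> dict[str, list[SequenceRecord]]:
        """Phase letter -> member sequences (phased sequences only)."""
        out: dict[str, list[SequenceRecord]] = {}
        for rec in self.sequences.values():
            if rec.genome_id == genome_id and rec.haplotype.phased:
                out.setdefault(rec.haplotype.phase, []).append(rec)
        for members in out.values():
            members.sort(key=lambda r: (r.haplotype.chromosome, r.name))
        return dict(sorted(out.items()))

    def inferred_ploidy(self, genome_id: int) -> int:
        sub = self.subgenomes(genome_id)
        return max(1, len(sub))


# ---------------------------------------------------------------------------
# operations


def build_pangenome(
    fasta_paths: Sequence[str | os.PathLike],
    k: int = 19,
    names: Sequence[str] | None = None,
) -> PangenomeStore:
    """Load one genome per FASTA file, in order, into a new store.

    ``k`` is the k-mer size recorded for downstream shared-k-mer analyses
    (odd, 11..31; default 19).
    """
    if k % 2 == 0 or not 11 <= k <= 31:
        raise PangenomeError(f"k must be odd and in [11, 31], got {k}")
    store = PangenomeStore(k=k)
    for i, path in enumerate(fasta_paths, start=1):
        path = Path(path)
        name = names[i - 1] if names else path.stem
        store.genomes[i] = GenomeRecord(genome_id=i, name=name)
        n = 0
        for rec in SeqIO.parse(str(path), "fasta"):
            if len(rec.seq) == 0:
                raise PangenomeError(f"empty FASTA record {rec.id!r} in {path}")
            if (i, rec.id) in store.sequences:
                raise PangenomeError(f"duplicate sequence name {rec.id!r} in {path}")
            store.sequences[(i, rec.id)] = SequenceRecord(
                genome_id=i, name=rec.id, residues=str(rec.seq).upper()
            )
            n += 1
        if n == 0:
            raise PangenomeError(f"no FASTA records in {path}")
        logger.info("genome %d (%s): %d sequences", i, name, n)
    return store


def _gff3_to_internal(start: int, end: int) -> tuple[int, int]:
    return start - 1, end


def _internal_to_gff3(start: int, end: int) -> tuple[int, int]:
    return start + 1, end


def _spliced_cds(residues: str, intervals: list[tuple[int, int]], strand: str) -> str:
    parts = [residues[s:e] for s, e in sorted(intervals)]
    cds = "".join(parts)
    if strand == "-":
        cds = reverse_complement(cds)
    return cds


def add_annotations(store: PangenomeStore, gff3_path: str | os.PathLike, genome_id: int) -> int:
    """Attach GFF3 gene models (gene → mRNA → CDS) to one genome.

    Returns the number of gene models added.  Features on unknown sequences
    are skipped with a warning; genes whose longest-transcript CDS length is
    not divisible by 3 are kept but flagged unreliable.
    """
    if genome_id not in store.genomes:
        raise PangenomeError(f"unknown genome {genome_id}")
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    added = skipped = 0
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        if (genome_id, gene.seqid) not in store.sequences:
            logger.warning("gene %s: sequence %r not in genome %d; skipped", gene.id, gene.seqid, genome_id)
            skipped += 1
            continue
        seq = store.sequences[(genome_id, gene.seqid)]
        start, end = _gff3_to_internal(gene.start, gene.end)
        if end > seq.length:
            raise PangenomeError(f"gene {gene.id} extends beyond sequence {gene.seqid}")
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            intervals = [
                _gff3_to_internal(c.start, c.end) for c in db.children(mrna, featuretype="CDS")
            ]
            if not intervals:
                continue
            transcripts.append(Transcript(mrna_id=mrna.id, cds_intervals=sorted(intervals)))
        if not transcripts:
            logger.warning("gene %s has no mRNA/CDS; skipped", gene.id)
            skipped += 1
            continue
        model = GeneModel(
            gene_id=gene.id,
            genome_id=genome_id,
            sequence_name=gene.seqid,
            start=start,
            end=end,
            strand=gene.strand if gene.strand in "+-" else "+",
        )
        model.transcripts = transcripts
        longest = model.longest_transcript
        if longest.cds_length % 3 != 0:
            logger.warning("gene %s: CDS length %d not divisible by 3; flagged unreliable", gene.id, longest.cds_length)
            model.reliable = False
        for t in transcripts:
            cds = _spliced_cds(seq.residues, t.cds_intervals, model.strand)
            t.protein, internal_stop = translate_cds(cds)
            if t is longest and internal_stop:
                model.has_internal_stop = True
        if gene.id in store.genes:
            raise PangenomeError(f"duplicate gene id {gene.id!r} across the store")
        store.genes[gene.id] = model
        added += 1
    logger.info("genome %d: %d gene models added, %d skipped", genome_id, added, skipped)
    return added


def add_phasing(store: PangenomeStore, table_path: str | os.PathLike) -> int:
    """Assign haplotype identifiers from a 4-column phasing table.

    Tab-separated with header ``genome<TAB>sequence<TAB>chromosome<TAB>phase``.
    Unlisted sequences keep chromosome 0.  Duplicate (chromosome, phase)
    assignments within a genome are allowed (fragmented assemblies) but
    logged.  Returns the number of sequences phased.
    """
    seen: dict[tuple[int, int, str], str] = {}
    count = 0
    with open(table_path) as fh:
        header = fh.readline()
        if not header.lower().startswith("genome"):
            raise PangenomeError(f"phasing table {table_path}: missing header line")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise PangenomeError(f"phasing table line {lineno}: expected 4 columns")
            gid, seq_name, chrom, phase = int(parts[0]), parts[1], int(parts[2]), parts[3].strip()
            if (gid, seq_name) not in store.sequences:
                raise PangenomeError(f"phasing table line {lineno}: unknown sequence {seq_name!r} in genome {gid}")
            hap = HaplotypeID(chrom, phase or None) if chrom > 0 else HaplotypeID()
            key = (gid, chrom, phase)
            if chrom > 0 and key in seen:
                logger.warning(
                    "genome %d: haplotype %s assigned to both %s and %s (fragmented assembly)",
                    gid, hap.render(), seen[key], seq_name,
                )
            seen[key] = seq_name
            store.sequences[(gid, seq_name)].haplotype = hap
            count += 1
    for rec in store.genomes.values():
        rec.ploidy = store.inferred_ploidy(rec.genome_id)
    logger.info("%d sequences phased", count)
    return count


def add_repeats(store: PangenomeStore, gff3_path: str | os.PathLike, genome_id: int) -> int:
    """Attach repeat annotations (any GFF3 feature type) to one genome."""
    if genome_id not in store.genomes:
        raise PangenomeError(f"unknown genome {genome_id}")
    added = 0
    with open(gff3_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                continue
            seqid, _, ftype, start, end = parts[0], parts[1], parts[2], int(parts[3]), int(parts[4])
            if (genome_id, seqid) not in store.sequences:
                logger.warning("repeat on unknown sequence %r skipped", seqid)
                continue
            s, e = _gff3_to_internal(start, end)
            if e > store.sequences[(genome_id, seqid)].length:
                raise PangenomeError(f"repeat interval beyond sequence {seqid}")
            store.repeats.append(RepeatAnnotation(genome_id, seqid, s, e, ftype))
            added += 1
    logger.info("genome %d: %d repeat annotations added", genome_id, added)
    return added


def select_sequences(
    store: PangenomeStore,
    genomes: Iterable[int] | None = None,
    chromosomes: Iterable[int] | None = None,
    phases: Iterable[str] | None = None,
) -> list[SequenceRecord]:
    """Filter sequences; deterministic (genome, chromosome, phase, name) order.

    An active chromosome filter excludes chromosome-0 (unphased) sequences
    even when 0 is listed.
    """
    genomes = set(genomes) if genomes is not None else None
    chromosomes = set(chromosomes) if chromosomes is not None else None
    phases = set(phases) if phases is not None else None
    out = []
    for rec in store.sequences.values():
        hap = rec.haplotype
        if genomes is not None and rec.genome_id not in genomes:
            continue
        if chromosomes is not None and (hap.chromosome == 0 or hap.chromosome not in chromosomes):
            continue
        if phases is not None and (hap.phase or "") not in phases:
            continue
        out.append(rec)
    out.sort(key=lambda r: (r.genome_id, r.haplotype.chromosome, r.haplotype.phase or "", r.name))
    return out


def extract_feature_sequence(store: PangenomeStore, gene_id: str, kind: str) -> str:
    """Extract gene / mRNA / CDS / protein sequence of one gene.

    gene and mRNA are strand-oriented genomic spans; CDS is the spliced coding
    sequence (reverse-complemented on minus strand); protein is the standard
    translation without trailing stop.  mRNA/CDS/protein use the longest
    transcript.
    """
    gene = store.gene(gene_id)
    seq = store.sequences[gene.sequence_key]
    if kind == "gene":
        span = seq.residues[gene.start : gene.end]
        return reverse_complement(span) if gene.strand == "-" else span
    t = gene.longest_transcript
    if kind == "mRNA":
        s = min(a for a, _ in t.cds_intervals)
        e = max(b for _, b in t.cds_intervals)
        span = seq.residues[s:e]
        return reverse_complement(span) if gene.strand == "-" else span
    if kind == "CDS":
        return _spliced_cds(seq.residues, t.cds_intervals, gene.strand)
    if kind == "protein":
        return t.protein
    raise PangenomeError(f"unknown feature kind {kind!r}")


# ---------------------------------------------------------------------------
# on-disk store: plain-text directory


def save_store(store: PangenomeStore, outdir: str | os.PathLike) -> Path:
    """Write the store to a directory of FASTA / GFF3 / TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "store.tsv", "w") as fh:
        fh.write(f"k\t{store.k}\n")
        for g in store.genomes.values():
            fh.write(f"genome\t{g.genome_id}\t{g.name}\t{g.ploidy}\n")
    for gid, g in store.genomes.items():
        with open(outdir / f"genome{gid}.fa", "w") as fh:
            for (sg, name), rec in sorted(store.sequences.items()):
                if sg != gid:
                    continue
                fh.write(f">{name}\n")
                for i in range(0, rec.length, 80):
                    fh.write(rec.residues[i : i + 80] + "\n")
        genes = sorted(
            (g2 for g2 in store.genes.values() if g2.genome_id == gid),
            key=lambda m: (m.sequence_name, m.start, m.gene_id),
        )
        with open(outdir / f"genome{gid}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for m in genes:
                s, e = _internal_to_gff3(m.start, m.end)
                fh.write(f"{m.sequence_name}\tphasepan\tgene\t{s}\t{e}\t.\t{m.strand}\t.\tID={m.gene_id}\n")
                for t in m.transcripts:
                    ts = min(a for a, _ in t.cds_intervals)
                    te = max(b for _, b in t.cds_intervals)
                    s1, e1 = _internal_to_gff3(ts, te)
                    fh.write(
                        f"{m.sequence_name}\tphasepan\tmRNA\t{s1}\t{e1}\t.\t{m.strand}\t.\t"
                        f"ID={t.mrna_id};Parent={m.gene_id}\n"
                    )
                    for cs, ce in t.cds_intervals:
                        s2, e2 = _internal_to_gff3(cs, ce)
                        fh.write(
                            f"{m.sequence_name}\tphasepan\tCDS\t{s2}\t{e2}\t.\t{m.strand}\t0\t"
                            f"ID={t.mrna_id}.cds;Parent={t.mrna_id}\n"
                        )
        reps = [r for r in store.repeats if r.genome_id == gid]
        if reps:
            with open(outdir / f"genome{gid}.repeats.gff3", "w") as fh:
                fh.write("##gff-version 3\n")
                for i, r in enumerate(sorted(reps, key=lambda r: (r.sequence_name, r.start))):
                    s, e = _internal_to_gff3(r.start, r.end)
                    fh.write(f"{r.sequence_name}\tphasepan\t{r.class_label}\t{s}\t{e}\t.\t+\t.\tID=rep{i}\n")
    with open(outdir / "phasing.tsv", "w") as fh:
        fh.write("genome\tsequence\tchromosome\tphase\n")
        for (gid, name), rec in sorted(store.sequences.items()):
            hap = rec.haplotype
            if hap.phased:
                fh.write(f"{gid}\t{name}\t{hap.chromosome}\t{hap.phase}\n")
    return outdir


def load_store(indir: str | os.PathLike) -> PangenomeStore:
    """Re-read a directory written by :func:`save_store`."""
    indir = Path(indir)
    meta = indir / "store.tsv"
    if not meta.exists():
        raise PangenomeError(f"{indir} is not a pangenome store (no store.tsv)")
    k = 19
    genome_rows = []
    with open(meta) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "k":
                k = int(parts[1])
            elif parts[0] == "genome":
                genome_rows.append((int(parts[1]), parts[2], int(parts[3])))
    fastas = [indir / f"genome{gid}.fa" for gid, _, _ in genome_rows]
    store = build_pangenome(fastas, k=k, names=[n for _, n, _ in genome_rows])
    for gid, _, ploidy in genome_rows:
        store.genomes[gid].ploidy = ploidy
        gff = indir / f"genome{gid}.gff3"
        if gff.exists() and gff.stat().st_size > 20:
            add_annotations(store, gff, gid)
        reps = indir / f"genome{gid}.repeats.gff3"
        if reps.exists():
            add_repeats(store, reps, gid)
    phasing = indir / "phasing.tsv"
    if phasing.exists():
        add_phasing(store, phasing)
    return store
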